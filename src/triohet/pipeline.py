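"""End-to-end trio analysis pipeline.

Stages run in order qc -> means -> de/spe -> additivity -> ase -> cistrans
-> enrichment, each stage's TSV outputs written before the next starts, and
a single summary JSON collecting per-tissue counts and proportions at the
end. The ASE-dependent stages (ase, cistrans, enrichment) are skipped when
no allele-count table is supplied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import additivity as _additivity
from . import ase as _ase
from . import breadth as _breadth
from . import cistrans as _cistrans
from . import enrichment as _enrichment
from . import parental as _parental
from .io import (
    ExpressionMatrix,
    SampleSheet,
    group_means,
    read_expression_matrix,
    read_sample_sheet,
    replicate_qc,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and threshold overrides for one pipeline run.

    Every statistical threshold defaults to the convention of the analysis
    it parameterizes; unknown keys in a YAML config are rejected.
    """

    tpm_path: str = ""
    counts_path: str | None = None
    sample_sheet_path: str = ""
    allele_counts_path: str | None = None
    deg_table_path: str | None = None
    outdir: str = "triohet_out"
    seed: int = 0
    min_corr: float = 0.85
    active_tpm: float = 1.0
    deg_alpha: float = 0.05
    deg_min_log2fc: float = 1.0
    spe_percentile_q: float = 0.01
    spe_min_expressed_tpm: float = 1.0
    spe_max_silent_tpm: float = 0.1
    additivity_alpha: float = 0.05
    fisher_scale: int = 1_000_000
    ase_alpha: float = 0.05
    ase_min_reads_per_allele: int = 10
    ase_min_minor_fraction: float = 0.02
    cistrans_alpha: float = 0.05
    min_tissues: int = 2
    skip_ase: bool = False
    tissues: list[str] | None = None
    # per-replicate library size of the sequencing experiment; defaults to
    # pooled column totals, which is right only for genome-complete matrices
    library_size: int | None = None

    def validate(self) -> None:
        for name in ("deg_alpha", "additivity_alpha", "ase_alpha", "cistrans_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not (0.0 < self.min_corr <= 1.0):
            raise ValueError("min_corr must be in (0, 1]")
        if not (0.0 <= self.spe_percentile_q <= 1.0):
            raise ValueError("spe_percentile_q must be in [0, 1]")
        if self.ase_min_reads_per_allele < 0:
            raise ValueError("ase_min_reads_per_allele must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


def run_pipeline(
    config: PipelineConfig,
    matrix: ExpressionMatrix | None = None,
    sheet: SampleSheet | None = None,
    allele_counts: pd.DataFrame | None = None,
) -> dict[str, Any]:
    """Run all stages; returns the summary dict (also written as JSON).

    Inputs may be passed in memory; otherwise they are read from the paths
    in ``config``. A stage failure aborts with the stage name logged;
    outputs of completed stages are retained in ``outdir``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"stages": []}

    def stage(name: str):
        logger.info("stage: %s", name)
        summary["stages"].append(name)

    try:
        stage("load")
        if matrix is None:
            matrix = read_expression_matrix(config.tpm_path, layer="tpm")
            if config.counts_path:
                cm = read_expression_matrix(config.counts_path, layer="counts")
                matrix.counts = cm.counts
        if sheet is None:
            sheet = read_sample_sheet(config.sample_sheet_path)
        if config.tissues:
            keep = sheet.table["tissue"].isin(config.tissues)
            sheet = SampleSheet(sheet.table[keep])

        stage("qc")
        qc = replicate_qc(matrix, sheet, min_corr=config.min_corr)
        qc.to_json(outdir / "qc_report.json")

        stage("means")
        means = group_means(matrix, sheet, exclude=qc.flagged)
        flat = means.values.copy()
        flat.columns = [f"{g}|{t}" for g, t in flat.columns]
        flat.index.name = "gene_id"
        flat.to_csv(outdir / "group_means.tsv", sep="\t", float_format="%.6g")
        breadth_df = _breadth.breadth_table(
            means, genotype="F1", active_threshold=config.active_tpm
        )
        breadth_df.to_csv(outdir / "breadth.tsv", sep="\t")

        stage("de")
        if config.deg_table_path:
            deg = _parental.read_deg_table(
                config.deg_table_path, config.deg_alpha, config.deg_min_log2fc
            )
        else:
            deg_frames = []
            for tissue in means.tissues:
                p1_ids = [s for s in sheet.sample_ids
                          if _geno(sheet, s) == "P1" and _tis(sheet, s) == tissue
                          and s not in qc.flagged]
                p2_ids = [s for s in sheet.sample_ids
                          if _geno(sheet, s) == "P2" and _tis(sheet, s) == tissue
                          and s not in qc.flagged]
                cts = matrix.counts
                if cts is None:
                    # TPM-derived pseudo-counts against a per-million library
                    cts = np.rint(matrix.layer("tpm"))
                col = {s: i for i, s in enumerate(matrix.sample_ids)}
                if matrix.counts is None:
                    lib = 1_000_000.0 * len(p1_ids)
                elif config.library_size:
                    lib = float(config.library_size) * len(p1_ids)
                else:
                    lib = None
                deg_frames.append(
                    _parental.call_de_internal(
                        cts[:, [col[s] for s in p1_ids]],
                        cts[:, [col[s] for s in p2_ids]],
                        matrix.gene_ids,
                        tissue=tissue,
                        lib_p1=lib,
                        lib_p2=lib,
                        alpha=config.deg_alpha,
                        min_log2fc=config.deg_min_log2fc,
                    )
                )
            deg = pd.concat(deg_frames, ignore_index=True)
        deg.to_csv(outdir / "deg_calls.tsv", sep="\t", index=False)
        fc_bins = _parental.bin_fold_changes(deg)
        fc_bins.to_csv(outdir / "deg_fold_change_bins.tsv", sep="\t", index=False)

        stage("spe")
        spe = _parental.spe_table(
            means,
            q=config.spe_percentile_q,
            min_expressed_tpm=config.spe_min_expressed_tpm,
            max_silent_tpm=config.spe_max_silent_tpm,
        )
        spe.to_csv(outdir / "spe_calls.tsv", sep="\t", index=False)

        stage("additivity")
        add = _additivity.classify_table(
            means, deg, alpha=config.additivity_alpha, scale=config.fisher_scale
        )
        add.to_csv(outdir / "additivity_calls.tsv", sep="\t", index=False)
        add_summary = {
            tissue: _additivity.summarize_additivity(add[add["tissue"] == tissue])
            for tissue in means.tissues
        }
        spe_fate = None
        if len(spe):
            fate = _additivity.spe_fate(spe, add)
            spe_fate = {
                "counts": fate.counts,
                "n_events": fate.n_events,
                "fraction_at_or_above_high": fate.fraction_at_or_above_high,
            }

        summary.update(
            {
                "qc": {"flagged": qc.flagged, "threshold": qc.threshold},
                "deg_counts": {
                    t: int(deg[(deg["tissue"] == t) & deg["is_deg"]].shape[0])
                    for t in means.tissues
                },
                "spe_counts": {
                    t: int((spe["tissue"] == t).sum()) for t in means.tissues
                },
                "additivity": add_summary,
                "spe_fate": spe_fate,
            }
        )

        do_ase = not config.skip_ase
        if do_ase and allele_counts is None:
            if config.allele_counts_path:
                allele_counts = _ase.read_allele_counts(config.allele_counts_path)
            else:
                do_ase = False
                logger.info("no allele-count input; skipping ase/cistrans/enrichment")

        if do_ase:
            stage("ase")
            ase_calls = _ase.ase_table(
                allele_counts,
                min_reads_per_allele=config.ase_min_reads_per_allele,
                min_minor_fraction=config.ase_min_minor_fraction,
                alpha=config.ase_alpha,
            )
            ase_calls.to_csv(outdir / "ase_calls.tsv", sep="\t", index=False)
            aseg = _ase.aseg_summary(ase_calls, min_tissues=config.min_tissues)
            aseg.to_csv(outdir / "aseg_summary.tsv", sep="\t", index=False)
            summary["aseg_counts"] = {
                t: int(ase_calls[(ase_calls["tissue"] == t) & ase_calls["is_ase"]].shape[0])
                for t in means.tissues
            }

            stage("cistrans")
            reg = _cistrans_table(
                matrix, sheet, qc.flagged, ase_calls, means, config
            )
            reg.to_csv(outdir / "regulatory_calls.tsv", sep="\t", index=False)
            summary["regulatory"] = {
                t: {
                    c: int(((reg["tissue"] == t) & (reg["category"] == c)).sum())
                    for c in _cistrans.REGULATORY_CATEGORIES
                }
                for t in means.tissues
            }

            stage("enrichment")
            try:
                result = _enrichment.analyze_contingency(reg, add)
            except ValueError as exc:
                logger.warning("enrichment skipped: %s", exc)
                result = None
            if result is not None:
                result.table.to_csv(outdir / "pattern_contingency.tsv", sep="\t")
                result.residuals.to_csv(outdir / "pattern_residuals.tsv", sep="\t")
                result.to_json(outdir / "pattern_chisq.json")
                summary["enrichment"] = {
                    "chi2": result.chi2,
                    "df": result.df,
                    "p_global": result.p_global,
                }
    except Exception:
        failed = summary["stages"][-1] if summary["stages"] else "load"
        logger.error("pipeline aborted in stage %r", failed)
        raise

    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=_json_default) + "\n")
    return summary


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _geno(sheet: SampleSheet, sample_id: str) -> str:
    row = sheet.table.loc[sheet.table["sample_id"] == sample_id].iloc[0]
    return row["genotype"]


def _tis(sheet: SampleSheet, sample_id: str) -> str:
    row = sheet.table.loc[sheet.table["sample_id"] == sample_id].iloc[0]
    return row["tissue"]


def _cistrans_table(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    flagged: list[str],
    ase_calls: pd.DataFrame,
    means,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Regulatory calls for every gene with an ASE call, per tissue.

    Parental reads are pooled counts across retained replicates (or
    per-million pseudo-counts from TPM when no counts layer exists);
    libraries are the corresponding pooled totals.
    """
    cts = matrix.counts
    pseudo = cts is None
    if pseudo:
        cts = np.rint(matrix.layer("tpm"))
    col = {s: i for i, s in enumerate(matrix.sample_ids)}
    gene_pos = {g: i for i, g in enumerate(matrix.gene_ids)}
    rows = []
    for tissue, sub in ase_calls.groupby("tissue", sort=False):
        p1_ids = [s for s in sheet.sample_ids
                  if _geno(sheet, s) == "P1" and _tis(sheet, s) == tissue
                  and s not in flagged]
        p2_ids = [s for s in sheet.sample_ids
                  if _geno(sheet, s) == "P2" and _tis(sheet, s) == tissue
                  and s not in flagged]
        pooled1 = cts[:, [col[s] for s in p1_ids]].sum(axis=1)
        pooled2 = cts[:, [col[s] for s in p2_ids]].sum(axis=1)
        if pseudo:
            lib1 = 1_000_000 * len(p1_ids)
            lib2 = 1_000_000 * len(p2_ids)
        elif config.library_size:
            lib1 = int(config.library_size) * len(p1_ids)
            lib2 = int(config.library_size) * len(p2_ids)
        else:
            lib1, lib2 = int(pooled1.sum()), int(pooled2.sum())
        for r in sub.itertuples():
            g = gene_pos.get(r.gene_id)
            if g is None:
                continue
            call = _cistrans.classify_gene(
                int(round(pooled1[g])),
                int(round(pooled2[g])),
                int(r.p1_reads),
                int(r.p2_reads),
                lib1,
                lib2,
                alpha=config.cistrans_alpha,
                gene_id=r.gene_id,
                tissue=tissue,
            )
            rows.append(call.__dict__)
    cols = [
        "gene_id", "tissue", "category", "p_parental", "p_allelic", "p_trans",
        "dir_parental", "dir_allelic",
    ]
    return pd.DataFrame(rows)[cols] if rows else pd.DataFrame(columns=cols)
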