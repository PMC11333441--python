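"""Synthetic trio RNA-seq generator with planted ground truth.

Emulates a two-parent + F1 design (multiple tissues, replicated) with
negative-binomial counts, configurable parental fold changes, planted
additivity classes, planted single-parent-expression (SPE) genes, and F1
allele counts consistent with configured cis and trans regulatory
components. Every downstream stage of the package can be exercised, and
scored against the truth, without any external data.

Model per gene (per tissue):

* baseline expression b ~ log-normal (TPM units);
* a regulatory category is drawn; it fixes the parental log2 ratio
  Delta = log2(P2/P1) and the cis (allelic) log2 ratio gamma:
  conserved (0, 0); cis_only (L, L); trans_only (L, 0);
  cis_trans_enhancing (L, L/2); cis_trans_compensating (L, -L/2);
  compensatory (0, L/2); with L a signed truncated-normal log2 effect.
  Parental means are b*2^(-Delta/2) and b*2^(Delta/2); the F1 allelic
  P2-fraction is r = 2^gamma / (1 + 2^gamma), so the cis component of the
  allelic ratio equals the planted cis log2 effect by construction;
* an additivity class fixes the F1 total mean: mid-parent, high parent,
  low parent, 1.5 x high, or 0.5 x low for additive / dominant /
  recessive / over- / under-dominant. Dominant and recessive are only
  planted for genes with parental divergence;
* replicate counts ~ NB(mean = depth x TPM, Var = mu + alpha mu^2);
  allele counts ~ Binomial(Poisson(allele_depth), r). With
  ``nb_dispersion=None`` the generator is noise-free: counts equal their
  rounded means and the TPM layer carries the planted means exactly.

Planted effects are truncated below at ``parental_log2fc_min`` (default
1.5, ~2.8-fold) so that every planted class label is operationally
identifiable against the per-million Fisher test's resolution floor; see
the methods note for the power analysis behind this choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .io import ExpressionMatrix, SampleSheet

__all__ = ["SimConfig", "TrioSimResult", "simulate_trio", "simulate_null_ase"]

_DIVERGENT = ("cis_only", "trans_only", "cis_trans_enhancing", "cis_trans_compensating")
_PARENT_EQUAL = ("compensatory", "conserved")
_NONDEG_CLASSES = ("additive", "over_dominant", "under_dominant")


def _default_class_proportions() -> dict[str, float]:
    return {
        "additive": 0.55,
        "dominant": 0.15,
        "recessive": 0.10,
        "over_dominant": 0.12,
        "under_dominant": 0.08,
    }


def _default_regulatory_proportions() -> dict[str, float]:
    return {
        "cis_only": 0.12,
        "trans_only": 0.18,
        "cis_trans_enhancing": 0.05,
        "cis_trans_compensating": 0.10,
        "compensatory": 0.15,
        "conserved": 0.40,
    }


@dataclass
class SimConfig:
    """Study conditions for one simulated trio dataset.

    Parameters
    ----------
    depth
        Sequencing depth in reads per TPM unit (library size / 1e6 of the
        genome-complete experiment the simulated panel is drawn from); the
        default 20 corresponds to a 20M-read library.
    allele_depth
        Mean F1 allele-informative reads per gene and tissue.
    nb_dispersion
        Extra-Poisson dispersion alpha with Var = mu + alpha mu^2;
        ``None`` switches off all sampling noise (deterministic means).
    parental_log2fc_distribution
        (mean, sd) of the planted |log2 fold change| for genes with
        parental divergence, truncated below at ``parental_log2fc_min``.
    spe_fraction
        Fraction of gene x tissue slots planted as single-parent
        expression events (drawn among cis_only/trans_only genes).
    """

    n_genes: int = 2000
    n_tissues: int = 3
    n_replicates: int = 3
    depth: float = 20.0
    allele_depth: float = 500.0
    nb_dispersion: float | None = 0.002
    baseline_tpm_log_mean: float = float(np.log(50.0))
    baseline_tpm_log_sd: float = 0.6
    class_proportions: dict[str, float] = field(default_factory=_default_class_proportions)
    spe_fraction: float = 0.02
    regulatory_proportions: dict[str, float] = field(
        default_factory=_default_regulatory_proportions
    )
    parental_log2fc_distribution: tuple[float, float] = (2.0, 0.4)
    parental_log2fc_min: float = 1.5
    over_dominant_factor: float = 1.5
    under_dominant_factor: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_genes", "n_tissues", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.depth <= 0 or self.allele_depth <= 0:
            raise ValueError("depth and allele_depth must be positive")
        if self.nb_dispersion is not None and self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0 or None")
        for name, props, keys in (
            ("class_proportions", self.class_proportions,
             set(_default_class_proportions())),
            ("regulatory_proportions", self.regulatory_proportions,
             set(_default_regulatory_proportions())),
        ):
            if set(props) != keys:
                raise ValueError(f"{name} must have keys {sorted(keys)}")
            if any(v < 0 for v in props.values()):
                raise ValueError(f"{name} must be non-negative")
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        # a gene with equal parental means cannot be dominant/recessive
        equal_mass = sum(self.regulatory_proportions[c] for c in _PARENT_EQUAL)
        nondeg_mass = sum(self.class_proportions[c] for c in _NONDEG_CLASSES)
        if equal_mass > 0 and nondeg_mass == 0:
            raise ValueError(
                "infeasible configuration: conserved/compensatory genes have "
                "no parental divergence and cannot be planted as "
                "dominant/recessive; give additive/over/under dominant "
                "classes nonzero mass"
            )
        div_mass = sum(
            self.regulatory_proportions[c] for c in ("cis_only", "trans_only")
        )
        if self.spe_fraction > 0 and self.spe_fraction > div_mass:
            raise ValueError(
                "spe_fraction exceeds the cis_only + trans_only mass SPE "
                "genes are drawn from"
            )
        if not (0.0 <= self.spe_fraction <= 1.0):
            raise ValueError("spe_fraction must be in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["parental_log2fc_distribution"] = list(self.parental_log2fc_distribution)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "parental_log2fc_distribution" in d:
            d["parental_log2fc_distribution"] = tuple(d["parental_log2fc_distribution"])
        return cls(**d)


@dataclass
class TrioSimResult:
    matrix: ExpressionMatrix
    sheet: SampleSheet
    allele_counts: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig

    @property
    def library_per_sample(self) -> int:
        """True library size of each simulated sample.

        The gene panel is a subset of a genome-complete experiment whose
        library is depth reads per TPM unit x 1e6 TPM; column sums of the
        panel underestimate it.
        """
        return int(round(self.config.depth * 1e6))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float | None) -> np.ndarray:
    """NB counts with Var = mu + alpha mu^2 (alpha=0 -> Poisson)."""
    mean = np.asarray(mean, dtype=float)
    if alpha is None:
        return np.rint(mean)
    if alpha == 0.0:
        return rng.poisson(mean).astype(float)
    size = 1.0 / alpha
    p = size / (size + mean)
    return rng.negative_binomial(size, p).astype(float)


def simulate_trio(config: SimConfig) -> TrioSimResult:
    """Generate one trio dataset with ground truth.

    Returns counts+TPM :class:`~triohet.io.ExpressionMatrix`, a
    :class:`~triohet.io.SampleSheet`, a gene-level F1 allele-count table
    (columns gene_id, tissue, snp_id, p1_allele_reads, p2_allele_reads),
    and the ground-truth table. Bit-reproducible for a given seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, T, R = config.n_genes, config.n_tissues, config.n_replicates
    gene_ids = [f"g{i+1:05d}" for i in range(G)]
    tissues = [f"tissue{t+1}" for t in range(T)]

    baseline = np.exp(
        rng.normal(config.baseline_tpm_log_mean, config.baseline_tpm_log_sd, size=G)
    )

    cat_names = list(_default_regulatory_proportions())
    cat_p = np.array([config.regulatory_proportions[c] for c in cat_names])
    cls_names = list(_default_class_proportions())
    cls_p = np.array([config.class_proportions[c] for c in cls_names])
    nondeg_mask = np.array([c in _NONDEG_CLASSES for c in cls_names])

    fc_mean, fc_sd = config.parental_log2fc_distribution

    truth_rows = []
    sample_cols: list[str] = []
    sheet_rows = []
    counts_cols: list[np.ndarray] = []
    tpm_cols: list[np.ndarray] = []
    allele_rows = []

    for tissue in tissues:
        cats = rng.choice(len(cat_names), size=G, p=cat_p)
        L = np.maximum(rng.normal(fc_mean, fc_sd, size=G), config.parental_log2fc_min)
        sign = rng.choice([-1.0, 1.0], size=G)
        Ls = sign * L

        delta = np.zeros(G)
        gamma = np.zeros(G)
        for i, name in enumerate(cat_names):
            m = cats == i
            if name == "cis_only":
                delta[m], gamma[m] = Ls[m], Ls[m]
            elif name == "trans_only":
                delta[m], gamma[m] = Ls[m], 0.0
            elif name == "cis_trans_enhancing":
                delta[m], gamma[m] = Ls[m], Ls[m] / 2.0
            elif name == "cis_trans_compensating":
                delta[m], gamma[m] = Ls[m], -Ls[m] / 2.0
            elif name == "compensatory":
                delta[m], gamma[m] = 0.0, Ls[m] / 2.0
            # conserved: both zero

        # SPE events among cis_only / trans_only genes
        spe = np.zeros(G, dtype=bool)
        div_idx = np.flatnonzero(
            (cats == cat_names.index("cis_only")) | (cats == cat_names.index("trans_only"))
        )
        if config.spe_fraction > 0 and len(div_idx):
            p_spe = min(1.0, config.spe_fraction * G / len(div_idx))
            spe[div_idx] = rng.random(len(div_idx)) < p_spe

        tpm_p1 = baseline * np.exp2(-delta / 2.0)
        tpm_p2 = baseline * np.exp2(delta / 2.0)
        # SPE: silent parent exactly 0, expressed parent at baseline;
        # cis_only SPE gets an extreme allelic ratio, trans_only stays 50:50
        spe_cis = spe & (cats == cat_names.index("cis_only"))
        for idx in np.flatnonzero(spe):
            if sign[idx] > 0:  # P2 expressed
                tpm_p1[idx], tpm_p2[idx] = 0.0, baseline[idx]
            else:
                tpm_p1[idx], tpm_p2[idx] = baseline[idx], 0.0
        # cis-consistent SPE: the silent parent's allele is silent in the
        # hybrid too (allelic ratio exactly 0 or 1); trans SPE stays 50:50
        gamma[spe_cis] = np.where(sign[spe_cis] > 0, np.inf, -np.inf)
        gamma[spe & ~spe_cis] = 0.0

        is_deg = np.abs(delta) >= 1.0
        is_deg[spe] = True

        # additivity class, restricted for genes without parental divergence;
        # SPE genes have low parent exactly 0, where under_dominant
        # (0.5 x low = 0 = low) is indistinguishable from recessive, so it
        # is excluded from their draw
        classes = np.empty(G, dtype=object)
        deg_p = cls_p
        nondeg_raw = np.where(nondeg_mask, cls_p, 0.0)
        nondeg_p = nondeg_raw / nondeg_raw.sum() if nondeg_raw.sum() > 0 else None
        spe_raw = np.array(
            [0.0 if c == "under_dominant" else p for c, p in zip(cls_names, cls_p)]
        )
        spe_p = spe_raw / spe_raw.sum() if spe_raw.sum() > 0 else None
        for g in range(G):
            if spe[g]:
                if spe_p is None:
                    classes[g] = "additive"
                    continue
                p = spe_p
            elif is_deg[g]:
                p = deg_p
            else:
                p = nondeg_p
            classes[g] = cls_names[rng.choice(len(cls_names), p=p)]

        high = np.maximum(tpm_p1, tpm_p2)
        low = np.minimum(tpm_p1, tpm_p2)
        mpp = (tpm_p1 + tpm_p2) / 2.0
        f1 = np.empty(G)
        for g in range(G):
            c = classes[g]
            if c == "additive":
                f1[g] = mpp[g]
            elif c == "dominant":
                f1[g] = high[g]
            elif c == "recessive":
                f1[g] = low[g]
            elif c == "over_dominant":
                f1[g] = config.over_dominant_factor * high[g]
            else:
                f1[g] = config.under_dominant_factor * low[g]

        with np.errstate(invalid="ignore"):
            ratio = np.exp2(gamma) / (1.0 + np.exp2(gamma))  # P2-allele fraction
        ratio[gamma == np.inf] = 1.0
        ratio[gamma == -np.inf] = 0.0

        means = {"P1": tpm_p1, "P2": tpm_p2, "F1": f1}
        for geno in ("P1", "P2", "F1"):
            for rep in range(1, R + 1):
                sid = f"{geno}_{tissue}_r{rep}"
                sample_cols.append(sid)
                sheet_rows.append(
                    {"sample_id": sid, "genotype": geno, "tissue": tissue, "replicate": rep}
                )
                mu = means[geno] * config.depth
                cts = _nb_draw(rng, mu, config.nb_dispersion)
                counts_cols.append(cts)
                if config.nb_dispersion is None:
                    tpm_cols.append(means[geno].copy())
                else:
                    tpm_cols.append(cts / config.depth)

        # F1 allele counts (gene-level rows, one pseudo-SNP each)
        expressed = f1 > 0
        if config.nb_dispersion is None:
            totals = np.where(expressed, np.rint(config.allele_depth), 0).astype(int)
            p2_reads = np.rint(totals * ratio).astype(int)
        else:
            totals = np.where(expressed, rng.poisson(config.allele_depth, size=G), 0)
            p2_reads = rng.binomial(totals, ratio)
        p1_reads = totals - p2_reads
        for g in range(G):
            if totals[g] > 0:
                allele_rows.append(
                    {
                        "gene_id": gene_ids[g],
                        "tissue": tissue,
                        "snp_id": f"{gene_ids[g]}_snp1",
                        "p1_allele_reads": int(p1_reads[g]),
                        "p2_allele_reads": int(p2_reads[g]),
                    }
                )

        high_parent = np.where(tpm_p1 >= tpm_p2, "P1", "P2")
        low_parent = np.where(tpm_p1 >= tpm_p2, "P2", "P1")
        for g in range(G):
            c = classes[g]
            if c == "dominant":
                c_lbl = f"dominant_{high_parent[g]}"
            elif c == "recessive":
                c_lbl = f"recessive_{low_parent[g]}"
            else:
                c_lbl = c
            truth_rows.append(
                {
                    "gene_id": gene_ids[g],
                    "tissue": tissue,
                    "baseline_tpm": baseline[g],
                    "parental_log2fc": delta[g] if not spe[g] else np.inf * sign[g],
                    "cis_log2": gamma[g],
                    "allelic_ratio": ratio[g],
                    "additivity_class": c_lbl,
                    "regulatory_category": cat_names[cats[g]],
                    "is_deg": bool(is_deg[g]),
                    "is_spe": bool(spe[g]),
                    "tpm_p1": tpm_p1[g],
                    "tpm_p2": tpm_p2[g],
                    "tpm_f1": f1[g],
                }
            )

    counts = np.column_stack(counts_cols)
    tpm = np.column_stack(tpm_cols)
    matrix = ExpressionMatrix(
        gene_ids=gene_ids, sample_ids=sample_cols, tpm=tpm, counts=counts
    )
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    allele = pd.DataFrame(
        allele_rows,
        columns=["gene_id", "tissue", "snp_id", "p1_allele_reads", "p2_allele_reads"],
    )
    truth = pd.DataFrame(truth_rows)
    return TrioSimResult(
        matrix=matrix, sheet=sheet, allele_counts=allele, truth=truth, config=config
    )


def simulate_null_ase(n_genes: int, depth: int, seed: int = 0) -> pd.DataFrame:
    """Allele-count table with no true allelic imbalance (ratio 0.5).

    Totals are fixed at ``depth``; P2-allele reads ~ Binomial(depth, 0.5).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    p2 = rng.binomial(depth, 0.5, size=n_genes)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i+1:05d}" for i in range(n_genes)],
            "tissue": "null",
            "snp_id": [f"g{i+1:05d}_snp1" for i in range(n_genes)],
            "p1_allele_reads": depth - p2,
            "p2_allele_reads": p2,
        }
    )
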