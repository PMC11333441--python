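"""Data model and I/O for trio expression experiments.

A trio experiment profiles two inbred parents (P1, P2) and their F1 hybrid
across one or more tissues with replicated RNA-seq. This module holds the
core containers — :class:`ExpressionMatrix`, :class:`SampleSheet`,
:class:`GroupMeans`, :class:`QCReport` — plus the tab-delimited readers and
writers and the replicate-correlation quality control used to exclude
discordant samples before any downstream statistics.

All tables are plain TSV: expression matrices are genes x samples with a
``gene_id`` first column; sample sheets carry ``sample_id``, ``genotype``
(P1/P2/F1), ``tissue`` and ``replicate``; allele-count tables are handled in
:mod:`triohet.ase`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOTYPES = ("P1", "P2", "F1")

__all__ = [
    "GENOTYPES",
    "SampleSheet",
    "ExpressionMatrix",
    "GroupMeans",
    "QCReport",
    "read_expression_matrix",
    "read_sample_sheet",
    "replicate_qc",
    "group_means",
]


@dataclass
class SampleSheet:
    """Per-sample design metadata for a trio experiment.

    Parameters
    ----------
    table
        DataFrame with columns ``sample_id``, ``genotype``, ``tissue``,
        ``replicate``. Genotype labels are normalized to {P1, P2, F1}.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["sample_id", "genotype", "tissue", "replicate"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        tbl = self.table[required].copy()
        tbl["sample_id"] = tbl["sample_id"].astype(str)
        tbl["tissue"] = tbl["tissue"].astype(str)
        geno = tbl["genotype"].astype(str).str.upper()
        bad = sorted(set(geno) - set(GENOTYPES))
        if bad:
            raise ValueError(
                f"unknown genotype label(s) {bad}; expected one of {GENOTYPES}"
            )
        tbl["genotype"] = geno
        rep = pd.to_numeric(tbl["replicate"], errors="raise")
        if (rep < 1).any() or (rep != rep.astype(int)).any():
            raise ValueError("replicate must be a positive integer (>= 1)")
        tbl["replicate"] = rep.astype(int)
        dup = tbl["sample_id"][tbl["sample_id"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate sample_id(s): {sorted(set(dup))}")
        self.table = tbl.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def groups(self) -> dict[tuple[str, str], list[str]]:
        """Map (genotype, tissue) -> sample_ids, in sheet order."""
        out: dict[tuple[str, str], list[str]] = {}
        for _, row in self.table.iterrows():
            out.setdefault((row["genotype"], row["tissue"]), []).append(
                row["sample_id"]
            )
        return out

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for t in self.table["tissue"]:
            if t not in seen:
                seen.append(t)
        return seen

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> SampleSheet:
    """Read and validate a TSV sample sheet.

    Genotype strings are mapped case-insensitively onto {P1, P2, F1};
    anything else is a hard error, as is a duplicated sample_id or a
    replicate index below 1.
    """
    tbl = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(tbl)


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values (TPM and/or raw counts).

    Either layer may be absent; operations that need a missing layer say so.
    Values must be finite and non-negative; gene and sample ids unique.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    tpm: np.ndarray | None = None
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        for name, ids in (("gene", self.gene_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ValueError(f"duplicate {name} id: {i!r}")
                seen.add(i)
        shape = (len(self.gene_ids), len(self.sample_ids))
        for name in ("tpm", "counts"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(
                    f"{name} shape {arr.shape} inconsistent with "
                    f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
                )
            if arr.size and not np.isfinite(arr).all():
                raise ValueError(f"{name} contains non-finite values")
            if arr.size and (arr < 0).any():
                raise ValueError(f"{name} contains negative values")
            setattr(self, name, arr)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def layer(self, which: str) -> np.ndarray:
        arr = getattr(self, which, None)
        if arr is None:
            raise ValueError(f"expression matrix has no {which!r} layer")
        return arr

    def to_frame(self, layer: str = "tpm") -> pd.DataFrame:
        return pd.DataFrame(
            self.layer(layer), index=self.gene_ids, columns=self.sample_ids
        )

    def check_tpm_sums(self, rtol: float = 0.01) -> bool:
        """Warn (return False) if TPM column sums stray >1% from 1e6.

        Only meaningful for genome-complete matrices; a simulated or
        subsetted gene panel will not sum to one million.
        """
        if self.tpm is None or self.tpm.size == 0:
            return True
        sums = self.tpm.sum(axis=0)
        ok = np.allclose(sums, 1e6, rtol=rtol)
        if not ok:
            logger.warning(
                "TPM column sums deviate >%.0f%% from 1e6 "
                "(min %.3g, max %.3g); matrix may not be genome-complete",
                rtol * 100, sums.min(), sums.max(),
            )
        return bool(ok)

    def to_tsv(self, path: str | Path, layer: str = "tpm") -> None:
        df = self.to_frame(layer)
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t", float_format="%.10g")


def read_expression_matrix(path: str | Path, layer: str = "tpm") -> ExpressionMatrix:
    """Read a genes x samples TSV into the requested layer.

    First column is ``gene_id``, header row holds sample ids, body is
    numeric. Duplicated ids, non-numeric cells and negative values are hard
    errors naming the offending entry.
    """
    if layer not in ("tpm", "counts"):
        raise ValueError(f"layer must be 'tpm' or 'counts', got {layer!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    dup_g = pd.Index(gene_ids)[pd.Index(gene_ids).duplicated()]
    if len(dup_g):
        raise ValueError(f"duplicate gene_id(s) in {path}: {sorted(set(dup_g))}")
    dup_s = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()]
    if len(dup_s):
        raise ValueError(f"duplicate sample id(s) in {path}: {sorted(set(dup_s))}")
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy()
        except (ValueError, TypeError):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric value in column {col!r}, row(s) {list(bad)[:5]}"
            ) from None
    if values.size and (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative value at gene {gene_ids[i]!r}, sample {sample_ids[j]!r}"
        )
    kwargs = {layer: values}
    return ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids, **kwargs)


@dataclass
class QCReport:
    """Replicate-correlation QC result.

    ``correlations`` is the full symmetric Pearson matrix over samples
    (unit diagonal); ``flagged`` lists samples whose best within-group
    correlation fell below ``threshold``.
    """

    correlations: pd.DataFrame
    flagged: list[str]
    threshold: float
    n_pairs_evaluated: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "threshold": self.threshold,
            "flagged": list(self.flagged),
            "n_pairs_evaluated": self.n_pairs_evaluated,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def replicate_qc(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    min_corr: float = 0.85,
    layer: str = "tpm",
) -> QCReport:
    """Flag replicates that fail pairwise Pearson correlation.

    A sample is flagged iff its *maximum* Pearson correlation against any
    co-group (same genotype, same tissue) replicate is strictly below
    ``min_corr``; this removes the minimal discordant set. Groups with a
    single replicate are never flagged. A zero-variance sample has no
    defined correlation and is flagged, since it cannot demonstrate
    concordance.
    """
    missing = [s for s in sheet.sample_ids if s not in matrix.sample_ids]
    if missing:
        raise ValueError(f"sample(s) in sheet missing from matrix: {missing}")
    values = matrix.layer(layer)
    col = {s: i for i, s in enumerate(matrix.sample_ids)}
    ids = sheet.sample_ids
    sub = values[:, [col[s] for s in ids]]
    n = len(ids)
    if n and sub.shape[0] >= 2:
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.corrcoef(sub, rowvar=False)
        corr = np.atleast_2d(corr)
    else:
        corr = np.full((n, n), np.nan)
    np.fill_diagonal(corr, 1.0)
    cdf = pd.DataFrame(corr, index=ids, columns=ids)

    flagged: list[str] = []
    n_pairs = 0
    idx = {s: i for i, s in enumerate(ids)}
    for (_, _), members in sheet.groups().items():
        if len(members) < 2:
            continue
        for s in members:
            best = -np.inf
            for t in members:
                if t == s:
                    continue
                r = corr[idx[s], idx[t]]
                n_pairs += 1
                if np.isfinite(r) and r > best:
                    best = r
            if best < min_corr:  # strict: r == min_corr passes
                flagged.append(s)
    # each unordered pair was visited twice above
    return QCReport(
        correlations=cdf,
        flagged=flagged,
        threshold=min_corr,
        n_pairs_evaluated=n_pairs // 2,
    )


@dataclass
class GroupMeans:
    """Mean TPM per (genotype, tissue) group per gene.

    ``values`` is genes x groups with a (genotype, tissue) column
    MultiIndex; ``n_replicates`` records how many retained replicates fed
    each mean.
    """

    values: pd.DataFrame
    n_replicates: pd.Series

    def tpm(self, genotype: str, tissue: str) -> pd.Series:
        return self.values[(genotype, tissue)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def tissues(self) -> list[str]:
        seen: list[str] = []
        for _, t in self.values.columns:
            if t not in seen:
                seen.append(t)
        return seen

    def trio(self, tissue: str) -> pd.DataFrame:
        """Genes x {P1, P2, F1} mean-TPM frame for one tissue."""
        return pd.DataFrame(
            {g: self.values[(g, tissue)] for g in GENOTYPES if (g, tissue) in self.values}
        )


def group_means(
    matrix: ExpressionMatrix,
    sheet: SampleSheet,
    exclude: Iterable[str] = (),
    layer: str = "tpm",
) -> GroupMeans:
    """Arithmetic mean expression per (genotype, tissue) across replicates.

    ``exclude`` typically holds QC-flagged sample ids. A group emptied by
    exclusion is a hard error naming the group.
    """
    excl = set(exclude)
    values = matrix.layer(layer)
    col = {s: i for i, s in enumerate(matrix.sample_ids)}
    missing = [s for s in sheet.sample_ids if s not in col]
    if missing:
        raise ValueError(f"sample(s) in sheet missing from matrix: {missing}")
    data: dict[tuple[str, str], np.ndarray] = {}
    nreps: dict[tuple[str, str], int] = {}
    for key, members in sheet.groups().items():
        kept = [s for s in members if s not in excl]
        if not kept:
            raise ValueError(
                f"group {key} has no samples left after exclusion"
            )
        data[key] = values[:, [col[s] for s in kept]].mean(axis=1)
        nreps[key] = len(kept)
    cols = pd.MultiIndex.from_tuples(data.keys(), names=["genotype", "tissue"])
    frame = pd.DataFrame(
        np.column_stack(list(data.values())) if data else np.empty((matrix.n_genes, 0)),
        index=matrix.gene_ids,
        columns=cols,
    )
    return GroupMeans(values=frame, n_replicates=pd.Series(nreps))
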