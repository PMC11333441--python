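"""Allele-specific expression (ASE) in the F1 hybrid.

Inputs are allele-count tables: per gene (optionally per SNP) and tissue,
the number of F1 reads attributable to the P1 vs the P2 allele. SNP rows
are filtered (>= 10 reads per allele, minor-allele fraction >= 2%), summed
to gene level, and tested against a 50:50 null with an exact two-sided
binomial test. Effect size is the allelic fold change

    aFC = log2((P2 reads + c) / (P1 reads + c)),   c = 0.5

oriented P2 over P1 so a positive aFC means the P2 allele is the more
expressed one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "read_allele_counts",
    "filter_ase_snps",
    "aggregate_to_gene",
    "gene_ase_test",
    "allelic_fold_change",
    "ase_table",
    "aseg_summary",
    "parental_correlation",
    "ASECall",
]


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    """Read a TSV allele-count table.

    Columns: gene_id, tissue, snp_id (optional), p1_allele_reads,
    p2_allele_reads. Counts must be non-negative integers and
    (gene, tissue, snp) keys unique.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "tissue", "p1_allele_reads", "p2_allele_reads"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"allele-count table missing columns: {missing}")
    if "snp_id" not in df.columns:
        df["snp_id"] = ""
    for c in ("p1_allele_reads", "p2_allele_reads"):
        vals = pd.to_numeric(df[c], errors="raise")
        if (vals < 0).any() or (vals != vals.astype(int)).any():
            raise ValueError(f"{c} must be non-negative integers")
        df[c] = vals.astype(int)
    key = df[["gene_id", "tissue", "snp_id"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate (gene, tissue, snp) row: {dup}")
    return df[["gene_id", "tissue", "snp_id", "p1_allele_reads", "p2_allele_reads"]]


def filter_ase_snps(
    table: pd.DataFrame,
    min_reads_per_allele: int = 10,
    min_minor_fraction: float = 0.02,
) -> pd.DataFrame:
    """Keep SNP rows informative for ASE.

    A row is retained iff min(p1, p2) >= min_reads_per_allele and the
    minor allele carries at least ``min_minor_fraction`` of all reads.
    """
    p1 = table["p1_allele_reads"].to_numpy()
    p2 = table["p2_allele_reads"].to_numpy()
    minor = np.minimum(p1, p2)
    total = p1 + p2
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, minor / total, 0.0)
    keep = (minor >= min_reads_per_allele) & (frac >= min_minor_fraction)
    return table[keep].reset_index(drop=True)


def aggregate_to_gene(table: pd.DataFrame) -> pd.DataFrame:
    """Sum retained SNP counts to one row per (gene, tissue)."""
    if len(table) == 0:
        return pd.DataFrame(
            columns=["gene_id", "tissue", "p1_reads", "p2_reads"]
        )
    agg = (
        table.groupby(["gene_id", "tissue"], sort=False)[
            ["p1_allele_reads", "p2_allele_reads"]
        ]
        .sum()
        .reset_index()
        .rename(
            columns={"p1_allele_reads": "p1_reads", "p2_allele_reads": "p2_reads"}
        )
    )
    return agg


@dataclass(frozen=True)
class ASECall:
    gene_id: str
    tissue: str
    p1_reads: int
    p2_reads: int
    p_binom: float
    afc: float
    is_ase: bool
    direction: str  # P1_biased / P2_biased / none


def gene_ase_test(
    p1_reads: int,
    p2_reads: int,
    alpha: float = 0.05,
    method: str = "minlike",
    gene_id: str = "",
    tissue: str = "",
    pseudocount: float = 0.5,
) -> ASECall:
    """Exact binomial ASE test for one gene's aggregated allele counts.

    Two-sided p under H0: P(P2-allele read) = 0.5. ``method`` "minlike"
    (default) sums all outcomes whose null pmf does not exceed the
    observed one; "double" doubles the smaller one-sided tail (capped at
    1).
    """
    n = int(p1_reads) + int(p2_reads)
    if n < 1:
        raise ValueError("zero total allele reads")
    if method == "minlike":
        p = float(stats.binomtest(int(p2_reads), n, 0.5).pvalue)
    elif method == "double":
        tail = min(
            stats.binom.cdf(int(p2_reads), n, 0.5),
            stats.binom.sf(int(p2_reads) - 1, n, 0.5),
        )
        p = float(min(1.0, 2.0 * tail))
    else:
        raise ValueError(f"unknown method {method!r}")
    afc = allelic_fold_change(p1_reads, p2_reads, pseudocount)
    is_ase = p < alpha
    if not is_ase or p1_reads == p2_reads:
        direction = "none"
    else:
        direction = "P2_biased" if p2_reads > p1_reads else "P1_biased"
    return ASECall(
        gene_id=gene_id,
        tissue=tissue,
        p1_reads=int(p1_reads),
        p2_reads=int(p2_reads),
        p_binom=p,
        afc=afc,
        is_ase=is_ase,
        direction=direction,
    )


def allelic_fold_change(
    p1_reads: float, p2_reads: float, pseudocount: float = 0.5
) -> float:
    """log2 allelic fold change, P2 over P1, with a stabilizing pseudo-count."""
    if p1_reads < 0 or p2_reads < 0:
        raise ValueError("allele read counts must be non-negative")
    return float(np.log2((p2_reads + pseudocount) / (p1_reads + pseudocount)))


def ase_table(
    allele_counts: pd.DataFrame,
    min_reads_per_allele: int = 10,
    min_minor_fraction: float = 0.02,
    alpha: float = 0.05,
    method: str = "minlike",
) -> pd.DataFrame:
    """Full SNP-filter -> gene-aggregate -> binomial-test pipeline."""
    filtered = filter_ase_snps(allele_counts, min_reads_per_allele, min_minor_fraction)
    genes = aggregate_to_gene(filtered)
    rows = []
    for r in genes.itertuples():
        call = gene_ase_test(
            r.p1_reads, r.p2_reads, alpha=alpha, method=method,
            gene_id=r.gene_id, tissue=r.tissue,
        )
        rows.append(call.__dict__)
    cols = [
        "gene_id", "tissue", "p1_reads", "p2_reads", "afc", "p_binom",
        "is_ase", "direction",
    ]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


def aseg_summary(ase_calls: pd.DataFrame, min_tissues: int = 2) -> pd.DataFrame:
    """Per-gene ASE breadth and direction consistency across tissues.

    Breadth counts tissues with a significant ASE call. Consistency
    (consistent_P1 / consistent_P2 / mixed) is computed over ASE tissues
    only; genes with fewer than ``min_tissues`` ASE tissues get a null
    consistency (counted in breadth, excluded from the consistency split).
    """
    rows = []
    for gene, sub in ase_calls.groupby("gene_id", sort=False):
        sig = sub[sub["is_ase"]]
        breadth = int(len(sig))
        consistency = None
        if breadth >= min_tissues:
            dirs = set(sig["direction"]) - {"none"}
            if dirs == {"P1_biased"}:
                consistency = "consistent_P1"
            elif dirs == {"P2_biased"}:
                consistency = "consistent_P2"
            else:
                consistency = "mixed"
        rows.append(
            {"gene_id": gene, "n_tissues_ase": breadth, "consistency": consistency}
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_tissues_ase", "consistency"])


def parental_correlation(
    afc: Sequence[float], parental_log2fc: Sequence[float]
) -> dict:
    """OLS of hybrid allelic fold change on parental log2 fold change.

    Returns slope, intercept, adjusted R² (1 - (1-R²)(n-1)/(n-2)) and the
    regression p-value. Requires >= 3 paired genes.
    """
    y = np.asarray(afc, dtype=float)
    x = np.asarray(parental_log2fc, dtype=float)
    if y.shape != x.shape:
        raise ValueError("afc and parental log2fc must align")
    mask = np.isfinite(y) & np.isfinite(x)
    y, x = y[mask], x[mask]
    if y.size < 3:
        raise ValueError("need at least 3 genes with both values")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return {
        "slope": float(model.params[1]),
        "intercept": float(model.params[0]),
        "r2_adj": float(model.rsquared_adj),
        "p_value": float(model.f_pvalue),
        "n": int(y.size),
    }
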