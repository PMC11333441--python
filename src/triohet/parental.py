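"""Parental expression divergence: DE calls, fold-change bins, SPE detection.

Differential expression between the two parents is a pluggable input: an
external DE table (e.g. from a count-model tool run upstream) can be read
with :func:`read_deg_table`, or a simplified self-contained test
(:func:`call_de_internal`, pooled-count Fisher exact with BH adjustment)
keeps the pipeline runnable without external results. A gene is a DEG at
adjusted P < 0.05 and |log2 fold change| >= 1.

Single-parent expression (SPE) is the extreme of parental divergence: a
gene expressed in one parent (TPM >= 1) while effectively silent in the
other (TPM < 0.1, and within the bottom percentile of positive expression,
and at least tenfold below the expressed parent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "DEG_ALPHA",
    "DEG_MIN_LOG2FC",
    "read_deg_table",
    "call_de_internal",
    "bin_fold_changes",
    "percentile_threshold",
    "detect_spe",
    "spe_table",
    "direction_consistency",
    "consistency_summary",
]

DEG_ALPHA = 0.05
DEG_MIN_LOG2FC = 1.0


def _derive_deg_columns(df: pd.DataFrame, alpha: float, min_log2fc: float) -> pd.DataFrame:
    is_deg = (df["adj_p"] < alpha) & (df["log2fc"].abs() >= min_log2fc)
    higher = np.where(~is_deg, "none", np.where(df["log2fc"] > 0, "P2", "P1"))
    out = df.copy()
    out["is_deg"] = is_deg
    out["higher_parent"] = higher
    return out


def read_deg_table(
    path: str | Path, alpha: float = DEG_ALPHA, min_log2fc: float = DEG_MIN_LOG2FC
) -> pd.DataFrame:
    """Read an external DE table (gene_id, tissue, log2fc, adj_p).

    ``log2fc`` is oriented P2 over P1. ``is_deg`` and ``higher_parent`` are
    (re)derived from the threshold rule adj_p < alpha and |log2fc| >=
    min_log2fc, regardless of any columns present in the file.
    """
    df = pd.read_csv(path, sep="\t")
    required = ["gene_id", "tissue", "log2fc", "adj_p"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"DEG table missing columns: {missing}")
    df["log2fc"] = pd.to_numeric(df["log2fc"], errors="raise")
    df["adj_p"] = pd.to_numeric(df["adj_p"], errors="raise")
    if ((df["adj_p"] < 0) | (df["adj_p"] > 1)).any():
        bad = df.loc[(df["adj_p"] < 0) | (df["adj_p"] > 1), "gene_id"].tolist()
        raise ValueError(f"adj_p outside [0, 1] for gene(s) {bad[:5]}")
    return _derive_deg_columns(df[required], alpha, min_log2fc)


def call_de_internal(
    p1_counts: np.ndarray,
    p2_counts: np.ndarray,
    gene_ids: Sequence[str],
    tissue: str = "",
    lib_p1: float | None = None,
    lib_p2: float | None = None,
    alpha: float = DEG_ALPHA,
    min_log2fc: float = DEG_MIN_LOG2FC,
) -> pd.DataFrame:
    """Simplified internal parental DE test on replicate count matrices.

    Replicates are pooled per parent; each gene is tested with a two-sided
    Fisher exact test on [[gene reads, rest of library]] for the two
    parents, p-values are Benjamini–Hochberg adjusted across genes, and
    log2fc is computed from library-size-normalized pooled counts with a
    pseudo-count of 1. This is an explicit simplification (no dispersion
    model); externally produced DE tables can be used instead.

    Parameters
    ----------
    p1_counts, p2_counts
        genes x replicates integer count arrays (1-D accepted for a single
        replicate).
    lib_p1, lib_p2
        Library sizes of the pooled parents; default is the pooled column
        total of the supplied matrix (appropriate when the matrix is
        genome-complete).
    """
    a = np.atleast_2d(np.asarray(p1_counts, dtype=float).T).T
    b = np.atleast_2d(np.asarray(p2_counts, dtype=float).T).T
    if a.shape[0] != len(gene_ids) or b.shape[0] != len(gene_ids):
        raise ValueError("count matrices must have one row per gene")
    pooled1 = a.sum(axis=1)
    pooled2 = b.sum(axis=1)
    L1 = float(pooled1.sum()) if lib_p1 is None else float(lib_p1)
    L2 = float(pooled2.sum()) if lib_p2 is None else float(lib_p2)
    if L1 <= 0 or L2 <= 0:
        raise ValueError("zero total library size")
    k1 = np.rint(pooled1).astype(np.int64)
    k2 = np.rint(pooled2).astype(np.int64)
    n1 = int(round(L1))
    n2 = int(round(L2))
    pvals = np.ones(len(gene_ids))
    for i in range(len(gene_ids)):
        if k1[i] == 0 and k2[i] == 0:
            continue
        table = [[k1[i], n1 - k1[i]], [k2[i], n2 - k2[i]]]
        pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]
    adj = multipletests(pvals, method="fdr_bh")[1] if len(pvals) else pvals
    log2fc = np.log2(((pooled2 + 1.0) / L2) / ((pooled1 + 1.0) / L1))
    df = pd.DataFrame(
        {
            "gene_id": list(gene_ids),
            "tissue": tissue,
            "log2fc": log2fc,
            "adj_p": adj,
        }
    )
    return _derive_deg_columns(df, alpha, min_log2fc)


def bin_fold_changes(deg_table: pd.DataFrame) -> pd.DataFrame:
    """Cumulative fold-change bins per tissue and higher parent.

    Counts DEGs with |log2fc| >= 1, 2, 3 (>=2-, >=4-, >=8-fold); bins are
    cumulative, so a >=8-fold gene is counted in all three.
    """
    rows = []
    degs = deg_table[deg_table["is_deg"]]
    tissues = deg_table["tissue"].unique() if len(deg_table) else []
    for tissue in tissues:
        sub = degs[degs["tissue"] == tissue]
        for parent in ("P1", "P2"):
            ps = sub[sub["higher_parent"] == parent]
            fc = ps["log2fc"].abs()
            rows.append(
                {
                    "tissue": tissue,
                    "higher_parent": parent,
                    "ge_2_fold": int((fc >= 1).sum()),
                    "ge_4_fold": int((fc >= 2).sum()),
                    "ge_8_fold": int((fc >= 3).sum()),
                }
            )
    cols = ["tissue", "higher_parent", "ge_2_fold", "ge_4_fold", "ge_8_fold"]
    return pd.DataFrame(rows, columns=cols)


def percentile_threshold(tpm: Sequence[float] | np.ndarray, q: float = 0.01) -> float:
    """q-quantile (linear interpolation) of positive TPMs in one parent-tissue.

    Zeros are excluded before taking the quantile: with a zero-inflated
    genome-scale vector the 1st percentile of *all* values collapses to 0,
    which would reduce the silent-parent criterion to exact zero. Returns 0
    with a warning if no positive values remain.
    """
    vals = np.asarray(tpm, dtype=float)
    if vals.size == 0:
        raise ValueError("empty TPM vector")
    pos = vals[vals > 0]
    if pos.size == 0:
        logger.warning("all TPM values are zero; percentile threshold set to 0")
        return 0.0
    return float(np.percentile(pos, q * 100.0, method="linear"))


def detect_spe(
    tpm_p1: float,
    tpm_p2: float,
    percentile_threshold: float,
    min_expressed_tpm: float = 1.0,
    max_silent_tpm: float = 0.1,
) -> str | None:
    """Single-parent expression call for one gene in one tissue.

    Returns "P2_only", "P1_only" or None. A direction requires all four
    clauses on the silent parent A and the expressed parent B:
    TPM_A <= percentile threshold, TPM_B >= 10 x TPM_A,
    TPM_B >= min_expressed_tpm, and TPM_A < max_silent_tpm.
    """
    if tpm_p1 < 0 or tpm_p2 < 0:
        raise ValueError("negative TPM")
    if percentile_threshold < 0:
        raise ValueError("percentile threshold must be >= 0")

    def one_sided(silent: float, expressed: float) -> bool:
        return (
            silent <= percentile_threshold
            and expressed >= 10.0 * silent
            and expressed >= min_expressed_tpm
            and silent < max_silent_tpm
        )

    if one_sided(tpm_p1, tpm_p2):
        return "P2_only"
    if one_sided(tpm_p2, tpm_p1):
        return "P1_only"
    return None


def spe_table(
    means,
    q: float = 0.01,
    min_expressed_tpm: float = 1.0,
    max_silent_tpm: float = 0.1,
) -> pd.DataFrame:
    """SPE calls for every gene x tissue of a :class:`~triohet.io.GroupMeans`.

    The percentile threshold is computed per parent per tissue; the
    silent-parent clause uses the threshold of the parent being tested for
    silence.
    """
    rows = []
    for tissue in means.tissues:
        p1 = means.tpm("P1", tissue)
        p2 = means.tpm("P2", tissue)
        thr1 = percentile_threshold(p1.to_numpy(), q)
        thr2 = percentile_threshold(p2.to_numpy(), q)
        for gene in means.gene_ids:
            a, b = float(p1[gene]), float(p2[gene])
            # direction-specific threshold: silence is judged against the
            # silent parent's own expression distribution
            call = None
            if detect_spe(a, b, thr1, min_expressed_tpm, max_silent_tpm) == "P2_only":
                call = "P2_only"
            elif detect_spe(b, a, thr2, min_expressed_tpm, max_silent_tpm) == "P2_only":
                call = "P1_only"
            if call:
                rows.append(
                    {
                        "gene_id": gene,
                        "tissue": tissue,
                        "direction": call,
                        "tpm_p1": a,
                        "tpm_p2": b,
                    }
                )
    return pd.DataFrame(
        rows, columns=["gene_id", "tissue", "direction", "tpm_p1", "tpm_p2"]
    )


def direction_consistency(
    calls: Sequence[str], min_tissues: int = 2
) -> str | None:
    """Cross-tissue consistency of the higher/expressed parent for one gene.

    ``calls`` are per-tissue direction labels in {"P1", "P2"}. Returns
    "consistent_P1", "consistent_P2", "mixed", or None when fewer than
    ``min_tissues`` calls are available (gene excluded).
    """
    labels = [c for c in calls]
    bad = set(labels) - {"P1", "P2"}
    if bad:
        raise ValueError(f"direction labels must be P1/P2, got {sorted(bad)}")
    if len(labels) < min_tissues:
        return None
    uniq = set(labels)
    if uniq == {"P1"}:
        return "consistent_P1"
    if uniq == {"P2"}:
        return "consistent_P2"
    return "mixed"


def consistency_summary(
    per_gene_calls: dict[str, Sequence[str]], min_tissues: int = 2
) -> pd.DataFrame:
    """Apply :func:`direction_consistency` gene-wise; excluded genes dropped."""
    rows = []
    for gene, calls in per_gene_calls.items():
        cls = direction_consistency(calls, min_tissues)
        if cls is not None:
            rows.append(
                {"gene_id": gene, "n_tissues_with_call": len(list(calls)), "consistency": cls}
            )
    return pd.DataFrame(rows, columns=["gene_id", "n_tissues_with_call", "consistency"])
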