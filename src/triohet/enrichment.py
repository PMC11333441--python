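"""Regulatory-pattern vs expression-pattern enrichment.

Joins per-gene-per-tissue regulatory calls with hybrid additivity calls,
cross-tabulates them, and asks whether regulatory mechanism and expression
mode are independent: Pearson chi-square test of independence, signed
Pearson residuals (obs - exp)/sqrt(exp) per cell, and a per-cell Fisher
exact test obtained by collapsing each cell against the rest of its row,
column and table.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyResult",
    "pattern_contingency",
    "chisq_independence",
    "per_cell_fisher",
    "analyze_contingency",
    "plot_residual_heatmap",
]


@dataclass
class ContingencyResult:
    table: pd.DataFrame
    chi2: float
    df: int
    p_global: float
    residuals: pd.DataFrame
    per_cell_p: pd.DataFrame

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"chi2": self.chi2, "df": self.df, "p_global": self.p_global},
                indent=2,
            )
            + "\n"
        )


def pattern_contingency(
    regulatory_calls: pd.DataFrame, additivity_calls: pd.DataFrame
) -> pd.DataFrame:
    """Counts of (regulatory category x additivity class) over joined calls.

    Calls join on (gene_id, tissue); unmatched calls are dropped with a
    logged count, and an empty join is a hard error.
    """
    left = regulatory_calls[["gene_id", "tissue", "category"]]
    right = additivity_calls[["gene_id", "tissue", "additivity_class"]]
    merged = left.merge(right, on=["gene_id", "tissue"], how="inner")
    dropped = (len(left) - len(merged)) + (len(right) - len(merged))
    if dropped:
        logger.info("pattern_contingency: %d unmatched call(s) dropped", dropped)
    if len(merged) == 0:
        raise ValueError("no (gene, tissue) keys shared between call sets")
    table = pd.crosstab(merged["category"], merged["additivity_class"])
    return table


def chisq_independence(table: pd.DataFrame | np.ndarray):
    """Pearson chi-square test of independence, without continuity correction.

    Returns (chi2, df, p_global, residuals) where residual_ij =
    (obs_ij - exp_ij)/sqrt(exp_ij) and chi2 is the sum of squared
    residuals. All row and column margins must be positive.
    """
    tdf = pd.DataFrame(table)
    obs = tdf.to_numpy(dtype=float)
    r, c = obs.shape
    df = (r - 1) * (c - 1)
    if df < 1:
        raise ValueError(f"table {r}x{c} has zero degrees of freedom")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows <= 0).any():
        raise ValueError(f"zero row margin: {tdf.index[rows <= 0].tolist()}")
    if (cols <= 0).any():
        raise ValueError(f"zero column margin: {tdf.columns[cols <= 0].tolist()}")
    expected = np.outer(rows, cols) / obs.sum()
    residuals = (obs - expected) / np.sqrt(expected)
    chi2 = float((residuals**2).sum())
    p = float(stats.chi2.sf(chi2, df))
    res = pd.DataFrame(residuals, index=tdf.index, columns=tdf.columns)
    return chi2, df, p, res


def per_cell_fisher(table: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Per-cell enrichment significance by 2x2 collapse.

    Each cell is tested with a two-sided Fisher exact test on
    [[cell, rest of row], [rest of column, remainder]].
    """
    tdf = pd.DataFrame(table)
    obs = tdf.to_numpy(dtype=np.int64)
    r, c = obs.shape
    if r < 2 or c < 2:
        raise ValueError("need at least a 2x2 table")
    total = obs.sum()
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    out = np.ones((r, c))
    for i in range(r):
        for j in range(c):
            a = obs[i, j]
            b = rows[i] - a
            cc = cols[j] - a
            d = total - a - b - cc
            out[i, j] = stats.fisher_exact([[a, b], [cc, d]], alternative="two-sided")[1]
    return pd.DataFrame(out, index=tdf.index, columns=tdf.columns)


def analyze_contingency(
    regulatory_calls: pd.DataFrame, additivity_calls: pd.DataFrame
) -> ContingencyResult:
    """Full enrichment analysis from joined call tables."""
    table = pattern_contingency(regulatory_calls, additivity_calls)
    chi2, df, p, res = chisq_independence(table)
    cell_p = per_cell_fisher(table)
    return ContingencyResult(
        table=table, chi2=chi2, df=df, p_global=p, residuals=res, per_cell_p=cell_p
    )


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def plot_residual_heatmap(result: ContingencyResult, path: str | Path) -> None:
    """Optional residual heatmap with per-cell Fisher stars (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = result.residuals
    fig, ax = plt.subplots(figsize=(1.2 * res.shape[1] + 2, 0.8 * res.shape[0] + 2))
    vmax = max(1.0, np.abs(res.to_numpy()).max())
    im = ax.imshow(res.to_numpy(), cmap="RdBu_r", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(res.shape[1]), res.columns, rotation=45, ha="right")
    ax.set_yticks(range(res.shape[0]), res.index)
    for i in range(res.shape[0]):
        for j in range(res.shape[1]):
            s = _stars(result.per_cell_p.iloc[i, j])
            if s:
                ax.text(j, i, s, ha="center", va="center", fontsize=9)
    fig.colorbar(im, ax=ax, label="Pearson residual")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
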