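"""Additive vs non-additive hybrid expression classification.

The hybrid's expression TPM_F1 is compared against three references — the
mid-parent value TPM_MPP = (TPM_P1 + TPM_P2)/2, the high parent TPM_high
and the low parent TPM_low — with two-sided Fisher exact tests on
per-million contingency tables (TPM is a per-million measure, so a TPM
value is integerized against a fixed 1e6 denominator). The decision tree:

DEG branch (parents differentially expressed)
    additive           p_vs_mpp >= alpha
    dominant_<parent>  p_vs_high >= alpha and p_vs_low < alpha
                       (F1 matches the high parent's level)
    recessive_<parent> p_vs_low >= alpha and p_vs_high < alpha
                       (F1 matches the low parent's level)
    over_dominant      all three p < alpha and TPM_F1 > TPM_high
    under_dominant     all three p < alpha and TPM_F1 < TPM_low
    ambiguous_nonadditive  anything else

non-DEG branch
    additive / over_dominant / under_dominant / ambiguous_nonadditive
    (only p_vs_mpp is decisive; the parental range breaks the tie)

No multiple-testing correction is applied inside the classifier; a plain
P = 0.05 threshold is the convention for this decision tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ADDITIVITY_CLASSES",
    "AdditivityCall",
    "fisher_tpm_test",
    "classify_additivity",
    "classify_table",
    "summarize_additivity",
    "spe_fate",
    "SPEFate",
]

ADDITIVITY_CLASSES = (
    "additive",
    "dominant_P1",
    "dominant_P2",
    "recessive_P1",
    "recessive_P2",
    "over_dominant",
    "under_dominant",
    "ambiguous_nonadditive",
)


def fisher_tpm_test(tpm_x: float, tpm_y: float, scale: int = 1_000_000) -> float:
    """Two-sided Fisher exact p for two TPM values.

    The 2x2 table is [[round(x), scale - round(x)], [round(y), scale -
    round(y)]]: each TPM is treated as a per-``scale`` transcript count.
    """
    if tpm_x < 0 or tpm_y < 0:
        raise ValueError("TPM values must be non-negative")
    kx = int(round(tpm_x))
    ky = int(round(tpm_y))
    if kx > scale or ky > scale:
        raise ValueError(f"rounded TPM exceeds scale {scale}")
    if kx == ky:
        return 1.0
    table = [[kx, scale - kx], [ky, scale - ky]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


@dataclass(frozen=True)
class AdditivityCall:
    gene_id: str
    tissue: str
    tpm_p1: float
    tpm_p2: float
    tpm_f1: float
    is_deg: bool
    p_vs_mpp: float
    p_vs_high: float
    p_vs_low: float
    additivity_class: str

    @property
    def tpm_mpp(self) -> float:
        return (self.tpm_p1 + self.tpm_p2) / 2.0

    @property
    def tpm_high(self) -> float:
        return max(self.tpm_p1, self.tpm_p2)

    @property
    def tpm_low(self) -> float:
        return min(self.tpm_p1, self.tpm_p2)


def classify_additivity(
    tpm_p1: float,
    tpm_p2: float,
    tpm_f1: float,
    is_deg: bool,
    alpha: float = 0.05,
    scale: int = 1_000_000,
    gene_id: str = "",
    tissue: str = "",
) -> AdditivityCall:
    """Classify one gene's hybrid expression pattern.

    The dominant/recessive suffix names the parent whose *level* F1
    matches: dominant_P1 means F1 sits at P1's level with P1 the high
    parent; recessive_P1 means F1 sits at P1's level with P1 the low
    parent.
    """
    for v in (tpm_p1, tpm_p2, tpm_f1):
        if v < 0:
            raise ValueError("TPM values must be non-negative")
    mpp = (tpm_p1 + tpm_p2) / 2.0
    high = max(tpm_p1, tpm_p2)
    low = min(tpm_p1, tpm_p2)
    high_parent = "P1" if tpm_p1 >= tpm_p2 else "P2"
    low_parent = "P2" if high_parent == "P1" else "P1"

    p_mpp = fisher_tpm_test(tpm_f1, mpp, scale)
    p_high = fisher_tpm_test(tpm_f1, high, scale)
    p_low = fisher_tpm_test(tpm_f1, low, scale)

    if is_deg:
        if p_mpp >= alpha:
            cls = "additive"
        elif p_high >= alpha and p_low < alpha:
            cls = f"dominant_{high_parent}"
        elif p_low >= alpha and p_high < alpha:
            cls = f"recessive_{low_parent}"
        elif p_high < alpha and p_low < alpha:
            if tpm_f1 > high:
                cls = "over_dominant"
            elif tpm_f1 < low:
                cls = "under_dominant"
            else:
                cls = "ambiguous_nonadditive"
        else:
            cls = "ambiguous_nonadditive"
    else:
        if p_mpp >= alpha:
            cls = "additive"
        elif tpm_f1 > high:
            cls = "over_dominant"
        elif tpm_f1 < low:
            cls = "under_dominant"
        else:
            cls = "ambiguous_nonadditive"

    return AdditivityCall(
        gene_id=gene_id,
        tissue=tissue,
        tpm_p1=tpm_p1,
        tpm_p2=tpm_p2,
        tpm_f1=tpm_f1,
        is_deg=bool(is_deg),
        p_vs_mpp=p_mpp,
        p_vs_high=p_high,
        p_vs_low=p_low,
        additivity_class=cls,
    )


def classify_table(
    means,
    deg_table: pd.DataFrame,
    alpha: float = 0.05,
    scale: int = 1_000_000,
    tissues: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Additivity calls for every gene x tissue of a GroupMeans.

    ``deg_table`` provides the is_deg gate per (gene, tissue); genes absent
    from it are treated as non-DEG.
    """
    deg_lookup = {
        (r.gene_id, r.tissue): bool(r.is_deg) for r in deg_table.itertuples()
    }
    rows = []
    for tissue in tissues or means.tissues:
        trio = means.trio(tissue)
        for gene in means.gene_ids:
            call = classify_additivity(
                float(trio.loc[gene, "P1"]),
                float(trio.loc[gene, "P2"]),
                float(trio.loc[gene, "F1"]),
                deg_lookup.get((gene, tissue), False),
                alpha=alpha,
                scale=scale,
                gene_id=gene,
                tissue=tissue,
            )
            rows.append(call.__dict__)
    df = pd.DataFrame(rows)
    return df[
        [
            "gene_id",
            "tissue",
            "additivity_class",
            "is_deg",
            "p_vs_mpp",
            "p_vs_high",
            "p_vs_low",
            "tpm_p1",
            "tpm_p2",
            "tpm_f1",
        ]
    ]


def summarize_additivity(calls: pd.DataFrame) -> dict:
    """Per-branch class proportions for one set of calls.

    Returns {"deg": {...}, "non_deg": {...}} with counts and proportions;
    an empty branch keeps explicit zero counts.
    """
    if len(calls) == 0:
        raise ValueError("no calls to summarize")
    out: dict[str, dict] = {}
    for branch, mask in (("deg", calls["is_deg"]), ("non_deg", ~calls["is_deg"])):
        sub = calls[mask]
        counts = {c: int((sub["additivity_class"] == c).sum()) for c in ADDITIVITY_CLASSES}
        n = int(len(sub))
        props = {c: (counts[c] / n if n else 0.0) for c in ADDITIVITY_CLASSES}
        out[branch] = {"n": n, "counts": counts, "proportions": props}
    return out


@dataclass(frozen=True)
class SPEFate:
    """Hybrid expression fate of single-parent-expression events."""

    counts: dict
    n_events: int
    fraction_at_or_above_high: float


def spe_fate(spe_table: pd.DataFrame, additivity_calls: pd.DataFrame) -> SPEFate:
    """Cross-tabulate SPE events against hybrid additivity classes.

    The headline number is the fraction of SPE events whose hybrid
    expression is at or above the high parent: (additive + dominant +
    over_dominant) / total. Dominant_P1/P2 (and recessive) are pooled.
    """
    key = additivity_calls.set_index(["gene_id", "tissue"])["additivity_class"]
    counts = {
        "additive": 0,
        "dominant": 0,
        "recessive": 0,
        "over_dominant": 0,
        "under_dominant": 0,
        "ambiguous_nonadditive": 0,
    }
    missing = []
    for r in spe_table.itertuples():
        k = (r.gene_id, r.tissue)
        if k not in key.index:
            missing.append(k)
            continue
        cls = key.loc[k]
        if cls.startswith("dominant"):
            counts["dominant"] += 1
        elif cls.startswith("recessive"):
            counts["recessive"] += 1
        else:
            counts[cls] += 1
    if missing:
        raise ValueError(f"SPE event(s) without additivity call: {missing[:10]}")
    n = len(spe_table)
    if n == 0:
        raise ValueError("no SPE events")
    frac = (counts["additive"] + counts["dominant"] + counts["over_dominant"]) / n
    return SPEFate(counts=counts, n_events=n, fraction_at_or_above_high=frac)
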