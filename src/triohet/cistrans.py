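"""Cis/trans regulatory-divergence classification.

Expression divergence between two parents can arise from cis-acting
variation (linked to the allele; inherited as allelic imbalance in the
hybrid) or trans-acting variation (diffusible factors; both alleles in the
hybrid see the same trans environment, so the parental difference is not
mirrored in the allelic ratio). Three tests per gene and tissue:

A. parental difference — two-sided Fisher exact on read counts vs library
   sizes of the pooled parents;
B. hybrid allelic difference — the exact binomial ASE test
   (:func:`triohet.ase.gene_ase_test`);
C. trans component — two-sided Fisher exact comparing the parental read
   ratio with the hybrid allelic ratio; significance means the two ratios
   differ, i.e. some of the parental difference is not explained in cis.

Decision table (S = significant at alpha):

    A  B  C   category
    S  S  .   cis_only
    S  .  S   trans_only
    S  S  S   cis_trans_enhancing  (parental and allelic bias same way)
              cis_trans_compensating (opposite ways)
    .  S  S   compensatory
    .  .  .   conserved
    otherwise ambiguous
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ase import gene_ase_test

logger = logging.getLogger(__name__)

__all__ = [
    "REGULATORY_CATEGORIES",
    "RegulatoryCall",
    "test_parental",
    "test_trans",
    "classify_regulation",
    "classify_gene",
    "regulation_consistency",
    "flanking_variant_ttest",
]

REGULATORY_CATEGORIES = (
    "cis_only",
    "trans_only",
    "cis_trans_enhancing",
    "cis_trans_compensating",
    "compensatory",
    "conserved",
    "ambiguous",
)


@dataclass(frozen=True)
class RegulatoryCall:
    gene_id: str
    tissue: str
    p_parental: float
    p_allelic: float
    p_trans: float
    dir_parental: str  # P1 / P2 / none
    dir_allelic: str
    category: str


def test_parental(
    p1_reads: int, p2_reads: int, lib1: int, lib2: int
) -> tuple[float, str]:
    """Parental expression difference (test A).

    Fisher exact on [[p1, lib1-p1], [p2, lib2-p2]]; direction is the
    parent with the higher library-normalized rate ("none" on a tie).
    """
    if lib1 <= 0 or lib2 <= 0:
        raise ValueError("zero library size")
    if p1_reads > lib1 or p2_reads > lib2:
        raise ValueError("reads exceed library size")
    table = [[int(p1_reads), int(lib1) - int(p1_reads)],
             [int(p2_reads), int(lib2) - int(p2_reads)]]
    p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    r1 = p1_reads / lib1
    r2 = p2_reads / lib2
    direction = "none" if r1 == r2 else ("P1" if r1 > r2 else "P2")
    return p, direction


def test_trans(
    p1_reads: int, p2_reads: int, f1_p1_allele: int, f1_p2_allele: int
) -> float:
    """Trans component (test C): parental ratio vs hybrid allelic ratio.

    Fisher exact on [[p1, p2], [f1_p1, f1_p2]]. A zero row carries no
    ratio information; returns p = 1 with a warning.
    """
    for v in (p1_reads, p2_reads, f1_p1_allele, f1_p2_allele):
        if v < 0:
            raise ValueError("counts must be non-negative")
    if p1_reads + p2_reads == 0 or f1_p1_allele + f1_p2_allele == 0:
        logger.warning("zero row in trans test; returning p = 1")
        return 1.0
    table = [[int(p1_reads), int(p2_reads)], [int(f1_p1_allele), int(f1_p2_allele)]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def classify_regulation(
    p_parental: float,
    p_allelic: float,
    p_trans: float,
    dir_parental: str,
    dir_allelic: str,
    alpha: float = 0.05,
) -> str:
    """Map the three test outcomes onto the seven regulatory categories."""
    for p in (p_parental, p_allelic, p_trans):
        if not (0.0 <= p <= 1.0):
            raise ValueError("p-values must lie in [0, 1]")
    A = p_parental < alpha
    B = p_allelic < alpha
    C = p_trans < alpha
    if A and B and not C:
        return "cis_only"
    if A and not B and C:
        return "trans_only"
    if A and B and C:
        if dir_parental == "none" or dir_allelic == "none":
            return "ambiguous"
        return (
            "cis_trans_enhancing"
            if dir_parental == dir_allelic
            else "cis_trans_compensating"
        )
    if (not A) and B and C:
        return "compensatory"
    if not (A or B or C):
        return "conserved"
    return "ambiguous"


def classify_gene(
    p1_reads: int,
    p2_reads: int,
    f1_p1_allele: int,
    f1_p2_allele: int,
    lib1: int,
    lib2: int,
    alpha: float = 0.05,
    gene_id: str = "",
    tissue: str = "",
) -> RegulatoryCall:
    """Run all three tests for one gene and classify.

    The allelic direction comes from the ASE call (sign of the allelic
    imbalance); the parental direction from the library-normalized rates.
    """
    p_par, dir_par = test_parental(p1_reads, p2_reads, lib1, lib2)
    ase_call = gene_ase_test(
        f1_p1_allele, f1_p2_allele, alpha=alpha, gene_id=gene_id, tissue=tissue
    )
    if f1_p1_allele == f1_p2_allele:
        dir_all = "none"
    else:
        dir_all = "P2" if f1_p2_allele > f1_p1_allele else "P1"
    p_tr = test_trans(p1_reads, p2_reads, f1_p1_allele, f1_p2_allele)
    category = classify_regulation(
        p_par, ase_call.p_binom, p_tr, dir_par, dir_all, alpha
    )
    return RegulatoryCall(
        gene_id=gene_id,
        tissue=tissue,
        p_parental=p_par,
        p_allelic=ase_call.p_binom,
        p_trans=p_tr,
        dir_parental=dir_par,
        dir_allelic=dir_all,
        category=category,
    )


def regulation_consistency(categories: Sequence[str]) -> str | None:
    """"consistent" iff the same category in every classified tissue.

    Returns None (excluded) for genes classified in fewer than two
    tissues.
    """
    cats = list(categories)
    if len(cats) < 2:
        return None
    return "consistent" if len(set(cats)) == 1 else "dynamic"


def flanking_variant_ttest(
    variant_counts: Mapping[str, float] | pd.Series,
    category_per_gene: Mapping[str, str] | pd.Series,
) -> pd.DataFrame:
    """Pairwise Welch t-tests of flanking-variant density across categories.

    Returns a symmetric p-value matrix over the categories present;
    category pairs where either side has < 2 genes are skipped (NaN) with
    a warning.
    """
    counts = pd.Series(variant_counts, dtype=float)
    cats = pd.Series(category_per_gene)
    common = counts.index.intersection(cats.index)
    counts, cats = counts[common], cats[common]
    groups = {c: counts[cats == c].to_numpy() for c in cats.unique()}
    names = list(groups)
    mat = pd.DataFrame(np.full((len(names), len(names)), np.nan), index=names, columns=names)
    np.fill_diagonal(mat.values, 1.0)
    for a, b in combinations(names, 2):
        if len(groups[a]) < 2 or len(groups[b]) < 2:
            logger.warning("skipping t-test %s vs %s (singleton group)", a, b)
            continue
        if np.ptp(groups[a]) == 0 and np.ptp(groups[b]) == 0 and groups[a][0] == groups[b][0]:
            p = 1.0  # identical constant groups: no evidence of difference
        else:
            p = float(stats.ttest_ind(groups[a], groups[b], equal_var=False).pvalue)
        mat.loc[a, b] = mat.loc[b, a] = p
    return mat
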