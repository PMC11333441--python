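"""Expression-breadth classification across tissues.

Genes are binned by the fraction of tissues in which they are active
(mean TPM at or above a threshold, 1 TPM by convention):

* silent — active in no tissue
* tissue_specific — active in at most 20% of tissues
* intermediate — active in more than 20% and at most 80%
* constitutive — active in more than 80%

With 15 tissues these fractions give the integer bins 1–3 / 4–12 / 13–15.
Both 20% and 80% boundaries are inclusive on the lower class, so that a
gene active in exactly 3 of 15 tissues is tissue-specific and one active
in 12 of 15 is intermediate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GroupMeans

__all__ = ["BreadthCall", "classify_breadth", "breadth_table", "expressed_gene_counts"]

BREADTH_CLASSES = ("silent", "tissue_specific", "intermediate", "constitutive")


@dataclass(frozen=True)
class BreadthCall:
    gene_id: str
    n_tissues_expressed: int
    n_tissues_total: int
    breadth_class: str


def _classify_fraction(n_active: int, n_total: int) -> str:
    if n_total < 1:
        raise ValueError("need at least one tissue")
    f = n_active / n_total
    if f == 0:
        return "silent"
    if f <= 0.2:
        return "tissue_specific"
    if f <= 0.8:
        return "intermediate"
    return "constitutive"


def classify_breadth(
    tpm_by_tissue: Mapping[str, float] | Sequence[float],
    active_threshold: float = 1.0,
    gene_id: str = "",
) -> BreadthCall:
    """Classify one gene's breadth from its per-tissue mean TPMs."""
    vals = np.asarray(
        list(tpm_by_tissue.values())
        if isinstance(tpm_by_tissue, Mapping)
        else list(tpm_by_tissue),
        dtype=float,
    )
    if vals.size == 0:
        raise ValueError("need at least one tissue")
    if (vals < 0).any():
        raise ValueError("negative TPM")
    n_active = int((vals >= active_threshold).sum())
    return BreadthCall(
        gene_id=gene_id,
        n_tissues_expressed=n_active,
        n_tissues_total=int(vals.size),
        breadth_class=_classify_fraction(n_active, vals.size),
    )


def breadth_table(
    means: GroupMeans, genotype: str = "F1", active_threshold: float = 1.0
) -> pd.DataFrame:
    """Breadth calls for every gene of one genotype, as a DataFrame."""
    tissues = means.tissues
    cols = [(genotype, t) for t in tissues if (genotype, t) in means.values.columns]
    if not cols:
        raise ValueError(f"no tissues for genotype {genotype!r}")
    sub = means.values[cols].to_numpy()
    if (sub < 0).any():
        raise ValueError("negative TPM")
    n_active = (sub >= active_threshold).sum(axis=1).astype(int)
    total = len(cols)
    classes = [_classify_fraction(n, total) for n in n_active]
    return pd.DataFrame(
        {
            "gene_id": means.gene_ids,
            "n_tissues_expressed": n_active,
            "n_tissues_total": total,
            "breadth_class": pd.Categorical(classes, categories=BREADTH_CLASSES),
        }
    ).set_index("gene_id")


def expressed_gene_counts(
    means: GroupMeans, active_threshold: float = 1.0
) -> pd.Series:
    """Number of active genes per (genotype, tissue) group."""
    active = (means.values.to_numpy() >= active_threshold).sum(axis=0)
    return pd.Series(active.astype(int), index=means.values.columns)
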