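import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from triohet.io import ExpressionMatrix, SampleSheet
from triohet.simulate import SimConfig, simulate_trio


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 6 samples (P1/P2/F1 x 2 reps, one tissue)."""
    tpm = np.array(
        [
            [10.0, 12.0, 50.0, 52.0, 30.0, 31.0],
            [0.0, 0.0, 5.0, 6.0, 2.0, 3.0],
            [100.0, 98.0, 100.0, 102.0, 150.0, 149.0],
        ]
    )
    samples = ["P1_leaf_r1", "P1_leaf_r2", "P2_leaf_r1", "P2_leaf_r2",
               "F1_leaf_r1", "F1_leaf_r2"]
    return ExpressionMatrix(gene_ids=["g1", "g2", "g3"], sample_ids=samples, tpm=tpm)


@pytest.fixture
def small_sheet() -> SampleSheet:
    rows = []
    for geno in ("P1", "P2", "F1"):
        for rep in (1, 2):
            rows.append(
                {"sample_id": f"{geno}_leaf_r{rep}", "genotype": geno,
                 "tissue": "leaf", "replicate": rep}
            )
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def noisefree_sim():
    """Deterministic trio dataset, planted means realized exactly."""
    cfg = SimConfig(n_genes=400, n_tissues=2, nb_dispersion=None, seed=42)
    return simulate_trio(cfg)


@pytest.fixture(scope="session")
def noisy_sim():
    cfg = SimConfig(n_genes=400, n_tissues=2, seed=42)
    return simulate_trio(cfg)
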