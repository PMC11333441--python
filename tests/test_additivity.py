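"""Additivity classification and its Fisher primitive."""

import numpy as np
import pandas as pd
import pytest

from oracles import fisher_two_sided
from triohet.additivity import (
    classify_additivity,
    fisher_tpm_test,
    spe_fate,
    summarize_additivity,
)

SCALE = 1_000_000


class TestFisherTpmTest:
    def test_identical_values_give_p_one(self):
        assert fisher_tpm_test(100, 100) == 1.0
        assert fisher_tpm_test(0, 0) == 1.0

    def test_twofold_at_moderate_tpm_is_significant(self):
        p = fisher_tpm_test(200, 100)
        oracle = fisher_two_sided(200, SCALE - 200, 100, SCALE - 100)
        assert p == pytest.approx(oracle, rel=1e-9)
        assert p < 1e-6

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x, y = rng.integers(0, 2000, size=2)
            assert fisher_tpm_test(x, y) == fisher_tpm_test(y, x)

    def test_value_above_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            fisher_tpm_test(2e6, 10)


class TestClassifyAdditivity:
    def test_near_identical_non_deg_is_additive(self):
        call = classify_additivity(50, 50, 52, is_deg=False)
        assert call.additivity_class == "additive"
        assert call.p_vs_mpp > 0.05

    def test_deg_dominant_toward_high_parent(self):
        # F1 at P1's (high) level: differs from MPP=250 and low=100, not high
        call = classify_additivity(400, 100, 400, is_deg=True)
        assert call.additivity_class == "dominant_P1"
        assert call.p_vs_high == 1.0
        oracle_mpp = fisher_two_sided(400, SCALE - 400, 250, SCALE - 250)
        assert call.p_vs_mpp == pytest.approx(oracle_mpp, rel=1e-9)
        assert call.p_vs_mpp < 0.05 and call.p_vs_low < 0.05

    def test_non_deg_over_dominant(self):
        call = classify_additivity(100, 100, 300, is_deg=False)
        assert call.additivity_class == "over_dominant"
        oracle = fisher_two_sided(300, SCALE - 300, 100, SCALE - 100)
        # p_vs_mpp compares F1=300 with MPP=100
        assert call.p_vs_mpp == pytest.approx(oracle, rel=1e-9)

    def test_deg_recessive_toward_low_parent(self):
        call = classify_additivity(400, 100, 100, is_deg=True)
        assert call.additivity_class == "recessive_P2"

    def test_deg_under_dominant(self):
        call = classify_additivity(400, 100, 20, is_deg=True)
        assert call.additivity_class == "under_dominant"

    def test_deg_between_parents_all_significant_is_ambiguous(self):
        # F1 strictly between parents but far from all three references
        call = classify_additivity(1000, 100, 300, is_deg=True)
        assert call.p_vs_mpp < 0.05 and call.p_vs_high < 0.05 and call.p_vs_low < 0.05
        assert call.additivity_class == "ambiguous_nonadditive"

    def test_parent_swap_symmetry(self):
        rng = np.random.default_rng(4)
        swap = {
            "dominant_P1": "dominant_P2", "dominant_P2": "dominant_P1",
            "recessive_P1": "recessive_P2", "recessive_P2": "recessive_P1",
        }
        for _ in range(50):
            p1, p2 = rng.integers(0, 800, size=2).astype(float)
            f1 = float(rng.integers(0, 1200))
            deg = bool(rng.integers(0, 2))
            c1 = classify_additivity(p1, p2, f1, deg).additivity_class
            c2 = classify_additivity(p2, p1, f1, deg).additivity_class
            assert c2 == swap.get(c1, c1)

    def test_tied_parents_non_deg_handled(self):
        call = classify_additivity(100, 100, 100, is_deg=False)
        assert call.additivity_class == "additive"

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError):
            classify_additivity(-1, 5, 5, False)


class TestSummaries:
    def _calls(self, classes, deg):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(classes))],
                "tissue": "leaf",
                "additivity_class": classes,
                "is_deg": deg,
            }
        )

    def test_all_additive(self):
        s = summarize_additivity(self._calls(["additive"] * 10, [False] * 10))
        assert s["non_deg"]["proportions"]["additive"] == 1.0

    def test_proportions_sum_to_one(self):
        s = summarize_additivity(
            self._calls(["additive"] * 4 + ["over_dominant"], [False] * 5)
        )
        assert s["non_deg"]["proportions"]["additive"] == pytest.approx(0.8)
        assert s["non_deg"]["proportions"]["over_dominant"] == pytest.approx(0.2)
        assert sum(s["non_deg"]["proportions"].values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_branch_keeps_zero_counts(self):
        s = summarize_additivity(self._calls(["additive"], [False]))
        assert s["deg"]["n"] == 0
        assert all(v == 0 for v in s["deg"]["counts"].values())


class TestSpeFate:
    def _tables(self, class_counts):
        spe_rows, add_rows = [], []
        i = 0
        for cls, n in class_counts.items():
            for _ in range(n):
                gid = f"g{i}"
                i += 1
                spe_rows.append({"gene_id": gid, "tissue": "t",
                                 "direction": "P2_only", "tpm_p1": 0.0, "tpm_p2": 5.0})
                add_rows.append({"gene_id": gid, "tissue": "t",
                                 "additivity_class": cls})
        return pd.DataFrame(spe_rows), pd.DataFrame(add_rows)

    def test_reported_spe_fate_fraction(self):
        # 1,491 events split 712 additive / 255 recessive / 104 dominant /
        # 49 over-dominant / 371 under-dominant or ambiguous
        spe, add = self._tables(
            {"additive": 712, "recessive_P1": 255, "dominant_P2": 104,
             "over_dominant": 49, "under_dominant": 371}
        )
        fate = spe_fate(spe, add)
        assert fate.n_events == 1491
        # 865/1491 by direct division; the published headline 58.02% sums
        # the already-rounded class percentages (47.75 + 6.98 + 3.29)
        assert round(100 * fate.fraction_at_or_above_high, 2) == 58.01

    def test_all_additive_is_full_fraction(self):
        fate = spe_fate(*self._tables({"additive": 5}))
        assert fate.fraction_at_or_above_high == 1.0

    def test_all_under_dominant_is_zero(self):
        fate = spe_fate(*self._tables({"under_dominant": 5}))
        assert fate.fraction_at_or_above_high == 0.0

    def test_unmatched_event_is_hard_error(self):
        spe, add = self._tables({"additive": 2})
        with pytest.raises(ValueError, match="without additivity"):
            spe_fate(spe, add.iloc[:1])
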