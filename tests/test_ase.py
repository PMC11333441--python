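"""Allele-specific expression: filters, binomial test, aFC, summaries."""

import numpy as np
import pandas as pd
import pytest

from oracles import binom_two_sided
from triohet.ase import (
    aggregate_to_gene,
    allelic_fold_change,
    aseg_summary,
    filter_ase_snps,
    gene_ase_test,
    parental_correlation,
    read_allele_counts,
)


def _table(rows):
    return pd.DataFrame(
        rows, columns=["gene_id", "tissue", "snp_id",
                       "p1_allele_reads", "p2_allele_reads"]
    )


class TestSnpFilter:
    @pytest.mark.parametrize(
        "p1,p2,kept",
        [
            (10, 500, False),  # 10/510 < 2% minor fraction
            (10, 400, True),   # 10/410 = 2.44%
            (9, 9, False),     # below 10 reads per allele
            (10, 10, True),
        ],
    )
    def test_both_clauses(self, p1, p2, kept):
        t = _table([["g1", "leaf", "s1", p1, p2]])
        out = filter_ase_snps(t)
        assert (len(out) == 1) is kept

    def test_raising_read_floor_never_adds_rows(self):
        rng = np.random.default_rng(5)
        rows = [["g%d" % i, "t", "s%d" % i,
                 int(rng.integers(0, 100)), int(rng.integers(0, 100))]
                for i in range(200)]
        t = _table(rows)
        prev = set(filter_ase_snps(t, min_reads_per_allele=0)["snp_id"])
        for floor in (5, 10, 20, 50):
            cur = set(filter_ase_snps(t, min_reads_per_allele=floor)["snp_id"])
            assert cur <= prev
            prev = cur


class TestAggregate:
    def test_sums_snps_within_gene(self):
        t = _table([["g1", "t", "s1", 30, 60], ["g1", "t", "s2", 20, 40]])
        out = aggregate_to_gene(t)
        assert out.iloc[0][["p1_reads", "p2_reads"]].tolist() == [50, 100]

    def test_single_snp_identity(self):
        out = aggregate_to_gene(_table([["g1", "t", "s1", 12, 34]]))
        assert out.iloc[0][["p1_reads", "p2_reads"]].tolist() == [12, 34]

    def test_fully_filtered_gene_absent(self):
        t = _table([["g1", "t", "s1", 1, 1]])
        out = aggregate_to_gene(filter_ase_snps(t))
        assert len(out) == 0


class TestGeneAseTest:
    def test_balanced_counts_not_ase(self):
        call = gene_ase_test(50, 50)
        assert call.p_binom == 1.0 and not call.is_ase
        assert call.direction == "none"

    @pytest.mark.parametrize("p1,p2", [(40, 60), (30, 70), (100, 130), (3, 11)])
    def test_matches_pmf_summation_oracle(self, p1, p2):
        call = gene_ase_test(p1, p2)
        assert call.p_binom == pytest.approx(binom_two_sided(p2, p1 + p2), rel=1e-10)

    def test_borderline_imbalance_not_called(self):
        call = gene_ase_test(40, 60)
        assert call.p_binom == pytest.approx(0.0569, abs=2e-4)
        assert not call.is_ase

    def test_strong_imbalance_called_with_direction(self):
        call = gene_ase_test(30, 70)
        assert call.p_binom < 1e-4 and call.is_ase
        assert call.direction == "P2_biased"

    def test_swap_preserves_p_and_flips_direction(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            a, b = rng.integers(0, 200, size=2)
            if a + b == 0:
                continue
            c1 = gene_ase_test(int(a), int(b))
            c2 = gene_ase_test(int(b), int(a))
            assert c1.p_binom == pytest.approx(c2.p_binom, rel=1e-12)
            flip = {"P1_biased": "P2_biased", "P2_biased": "P1_biased",
                    "none": "none"}
            assert c2.direction == flip[c1.direction]

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            gene_ase_test(0, 0)

    def test_doubled_tail_variant_bounds_minlike(self):
        # the doubled one-sided tail is never smaller than the minlike p
        for p1, p2 in [(40, 60), (45, 55), (10, 30)]:
            assert (gene_ase_test(p1, p2, method="double").p_binom
                    >= gene_ase_test(p1, p2, method="minlike").p_binom - 1e-12)


class TestAllelicFoldChange:
    def test_balanced_is_zero(self):
        assert allelic_fold_change(50, 50) == 0.0

    def test_reference_values(self):
        assert allelic_fold_change(20, 80) == pytest.approx(np.log2(80.5 / 20.5))
        assert allelic_fold_change(0, 64) == pytest.approx(np.log2(64.5 / 0.5))

    def test_antisymmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b = rng.integers(0, 500, size=2)
            assert allelic_fold_change(a, b) == pytest.approx(
                -allelic_fold_change(b, a), abs=1e-12
            )


class TestAsegSummary:
    def _calls(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "tissue", "p1_reads", "p2_reads",
                           "afc", "p_binom", "is_ase", "direction"]
        )

    def test_consistent_and_mixed_classes(self):
        calls = self._calls([
            ["g1", "t1", 10, 90, 3.0, 1e-9, True, "P2_biased"],
            ["g1", "t2", 10, 80, 3.0, 1e-9, True, "P2_biased"],
            ["g1", "t3", 10, 70, 2.8, 1e-8, True, "P2_biased"],
            ["g2", "t1", 90, 10, -3.0, 1e-9, True, "P1_biased"],
            ["g2", "t2", 10, 90, 3.0, 1e-9, True, "P2_biased"],
        ])
        out = aseg_summary(calls).set_index("gene_id")
        assert out.loc["g1", "consistency"] == "consistent_P2"
        assert out.loc["g1", "n_tissues_ase"] == 3
        assert out.loc["g2", "consistency"] == "mixed"

    def test_single_tissue_gene_counted_but_not_classified(self):
        calls = self._calls([
            ["g1", "t1", 10, 90, 3.0, 1e-9, True, "P2_biased"],
            ["g1", "t2", 50, 50, 0.0, 1.0, False, "none"],
        ])
        out = aseg_summary(calls).set_index("gene_id")
        assert out.loc["g1", "n_tissues_ase"] == 1
        assert out.loc["g1", "consistency"] is None


class TestParentalCorrelation:
    def test_perfect_fit(self):
        x = np.linspace(-3, 3, 10)
        out = parental_correlation(x, x)
        assert out["slope"] == pytest.approx(1.0)
        assert out["r2_adj"] == pytest.approx(1.0)

    def test_permuted_values_give_near_zero_r2(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 2, 500)
        y = rng.permutation(x)
        out = parental_correlation(y, x)
        assert abs(out["r2_adj"]) < 0.02

    def test_adjusted_r2_formula(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 30)
        y = 0.5 * x + rng.normal(0, 1, 30)
        out = parental_correlation(y, x)
        # recompute adjusted R2 from plain R2 by its closed formula
        r = np.corrcoef(x, y)[0, 1] ** 2
        n = 30
        assert out["r2_adj"] == pytest.approx(1 - (1 - r) * (n - 1) / (n - 2), abs=1e-10)

    def test_two_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            parental_correlation([1.0, 2.0], [1.0, 2.0])


def test_read_allele_counts_round_trip(tmp_path):
    t = _table([["g1", "leaf", "s1", 30, 60], ["g2", "leaf", "s1", 0, 5]])
    p = tmp_path / "ac.tsv"
    t.to_csv(p, sep="\t", index=False)
    out = read_allele_counts(p)
    pd.testing.assert_frame_equal(out, t)


def test_read_allele_counts_rejects_duplicates(tmp_path):
    t = _table([["g1", "leaf", "s1", 1, 2], ["g1", "leaf", "s1", 3, 4]])
    p = tmp_path / "ac.tsv"
    t.to_csv(p, sep="\t", index=False)
    with pytest.raises(ValueError, match="duplicate"):
        read_allele_counts(p)
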