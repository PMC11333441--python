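"""Parental DE interface, fold-change bins, SPE detection, consistency."""

import numpy as np
import pandas as pd
import pytest

from oracles import fisher_two_sided
from triohet.parental import (
    bin_fold_changes,
    call_de_internal,
    detect_spe,
    direction_consistency,
    percentile_threshold,
    read_deg_table,
)


class TestReadDegTable:
    def _write(self, tmp_path, rows):
        p = tmp_path / "deg.tsv"
        lines = ["gene_id\ttissue\tlog2fc\tadj_p"]
        lines += ["\t".join(str(x) for x in r) for r in rows]
        p.write_text("\n".join(lines) + "\n")
        return p

    @pytest.mark.parametrize(
        "log2fc,adj_p,is_deg,higher",
        [
            (1.5, 0.01, True, "P2"),
            (0.5, 0.001, False, "none"),   # fold-change gate
            (-2.0, 0.04, True, "P1"),
            (2.0, 0.06, False, "none"),    # p gate
        ],
    )
    def test_threshold_rule(self, tmp_path, log2fc, adj_p, is_deg, higher):
        p = self._write(tmp_path, [["g1", "leaf", log2fc, adj_p]])
        df = read_deg_table(p)
        assert bool(df["is_deg"][0]) is is_deg
        assert df["higher_parent"][0] == higher

    def test_adj_p_out_of_range_rejected(self, tmp_path):
        p = self._write(tmp_path, [["g1", "leaf", 1.0, 1.5]])
        with pytest.raises(ValueError, match="adj_p"):
            read_deg_table(p)


class TestCallDeInternal:
    def test_symmetric_counts_not_de(self):
        df = call_de_internal(np.array([[1000]]), np.array([[1000]]),
                              ["g1"], lib_p1=1e6, lib_p2=1e6)
        assert df["log2fc"][0] == 0.0
        assert not df["is_deg"][0]

    def test_fourfold_gene_matches_fisher_oracle(self):
        df = call_de_internal(np.array([[2000]]), np.array([[500]]),
                              ["g1"], lib_p1=1e6, lib_p2=1e6)
        assert df["log2fc"][0] == pytest.approx(-2.0, abs=0.01)
        p_oracle = fisher_two_sided(2000, 10**6 - 2000, 500, 10**6 - 500)
        assert df["adj_p"][0] == pytest.approx(p_oracle, rel=1e-6)
        assert df["is_deg"][0] and df["higher_parent"][0] == "P1"

    def test_zero_gene_is_null(self):
        df = call_de_internal(np.array([[0]]), np.array([[0]]),
                              ["g1"], lib_p1=1e6, lib_p2=1e6)
        assert df["log2fc"][0] == 0.0 and df["adj_p"][0] == 1.0

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            call_de_internal(np.array([[0]]), np.array([[0]]), ["g1"])

    def test_parent_swap_negates_log2fc(self):
        a = np.array([[300, 310], [50, 55]])
        b = np.array([[100, 90], [500, 480]])
        d1 = call_de_internal(a, b, ["g1", "g2"], lib_p1=1e6, lib_p2=1e6)
        d2 = call_de_internal(b, a, ["g1", "g2"], lib_p1=1e6, lib_p2=1e6)
        np.testing.assert_allclose(d1["log2fc"], -d2["log2fc"], atol=1e-12)
        np.testing.assert_allclose(d1["adj_p"], d2["adj_p"], atol=1e-12)
        assert (d1["is_deg"] == d2["is_deg"]).all()


class TestFoldChangeBins:
    def _table(self, fcs):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(fcs))],
                "tissue": "leaf",
                "log2fc": fcs,
                "adj_p": 0.001,
                "is_deg": [abs(f) >= 1 for f in fcs],
                "higher_parent": ["P2" if f > 0 else "P1" if f <= -1 else "none"
                                  for f in fcs],
            }
        )

    def test_bins_are_cumulative(self):
        out = bin_fold_changes(self._table([3.0]))  # 8-fold
        row = out[out["higher_parent"] == "P2"].iloc[0]
        assert (row["ge_2_fold"], row["ge_4_fold"], row["ge_8_fold"]) == (1, 1, 1)

    def test_fourfold_gene_not_in_eightfold_bin(self):
        out = bin_fold_changes(self._table([2.0]))
        row = out[out["higher_parent"] == "P2"].iloc[0]
        assert (row["ge_2_fold"], row["ge_4_fold"], row["ge_8_fold"]) == (1, 1, 0)

    def test_empty_input_gives_empty_table(self):
        out = bin_fold_changes(self._table([]))
        assert len(out) == 0


class TestPercentileThreshold:
    def test_interpolated_first_percentile(self):
        assert percentile_threshold(np.arange(1, 101), 0.01) == pytest.approx(1.99)

    def test_constant_vector(self):
        assert percentile_threshold([3.0, 3.0, 3.0]) == 3.0

    def test_zeros_excluded_before_quantile(self):
        # with zeros included the 1st percentile would be 0
        vals = [0.0] * 90 + list(range(1, 11))
        assert percentile_threshold(vals, 0.01) > 0

    def test_all_zero_returns_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert percentile_threshold([0.0, 0.0]) == 0.0
        assert "zero" in caplog.text


class TestDetectSpe:
    def test_clear_spe_call(self):
        assert detect_spe(0.05, 5.0, 0.1) == "P2_only"
        assert detect_spe(5.0, 0.05, 0.1) == "P1_only"

    def test_low_expressed_parent_fails(self):
        assert detect_spe(0.05, 0.4, 0.1) is None

    def test_zero_silent_parent_boundary(self):
        assert detect_spe(0.0, 1.0, 0.0) == "P2_only"

    def test_negative_tpm_rejected(self):
        with pytest.raises(ValueError):
            detect_spe(-0.1, 5.0, 0.1)

    def test_parent_swap_flips_direction(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b = rng.exponential(1.0), rng.exponential(5.0)
            d1 = detect_spe(a, b, 0.1)
            d2 = detect_spe(b, a, 0.1)
            flip = {"P1_only": "P2_only", "P2_only": "P1_only", None: None}
            assert d2 == flip[d1]

    def test_monotone_in_expressed_parent(self):
        # increasing the expressed parent never destroys a call
        base = detect_spe(0.05, 2.0, 0.1)
        assert base == "P2_only"
        for tpm2 in (5.0, 50.0, 500.0):
            assert detect_spe(0.05, tpm2, 0.1) == "P2_only"


class TestDirectionConsistency:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            (["P2", "P2", "P2"], "consistent_P2"),
            (["P1", "P1"], "consistent_P1"),
            (["P1", "P2"], "mixed"),
            (["P2"], None),  # below min_tissues
        ],
    )
    def test_classes(self, calls, expected):
        assert direction_consistency(calls, min_tissues=2) == expected

    def test_classes_partition_called_genes(self):
        rng = np.random.default_rng(2)
        n = {"consistent_P1": 0, "consistent_P2": 0, "mixed": 0}
        total = 0
        for _ in range(300):
            k = rng.integers(2, 6)
            calls = rng.choice(["P1", "P2"], size=k).tolist()
            cls = direction_consistency(calls, min_tissues=2)
            assert cls is not None
            n[cls] += 1
            total += 1
        assert sum(n.values()) == total
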