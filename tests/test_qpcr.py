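"""Relative quantification (2^-ddCt) and the group-comparison t tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netswarm import (
    QpcrTable,
    benjamini_hochberg,
    delta_delta_ct,
    paired_t_test,
    welch_t_test,
)
from netswarm.errors import DataError, DegenerateDataError, GeneLookupError, PairingError


def _table(target_ct, ref_ct, groups, refs=("GAPDH",)):
    genes = ["TARGET", *refs]
    ct = np.vstack([target_ct] + [ref_ct] * len(refs))
    return QpcrTable(
        gene_ids=genes,
        sample_ids=[f"s{i}" for i in range(len(groups))],
        ct_values=ct,
        group_labels=list(groups),
        reference_genes=list(refs),
    )


class TestDeltaDeltaCt:
    def test_sample_at_calibrator_mean_has_rq_one(self):
        # dCt identical everywhere -> ddCt = 0 -> rq = 1
        table = _table([25, 25, 25, 25], [20, 20, 20, 20], ["c", "c", "t", "t"])
        for rel in delta_delta_ct(table, "TARGET", "c"):
            assert rel.rq == pytest.approx(1.0)

    def test_one_cycle_below_calibrator_mean_doubles_rq(self):
        table = _table([25, 25, 24, 24], [20, 20, 20, 20], ["c", "c", "t", "t"])
        rel = delta_delta_ct(table, "TARGET", "c")
        assert rel[2].rq == pytest.approx(2.0)
        assert rel[3].rq == pytest.approx(2.0)

    def test_hand_table_gives_rqs_four_and_one(self):
        # calibrator dCts {5, 7} (mean 6); test dCts {4, 6} -> ddCt {-2, 0} -> rq {4, 1}
        table = _table([25, 27, 24, 26], [20, 20, 20, 20], ["c", "c", "t", "t"])
        rel = delta_delta_ct(table, "TARGET", "c")
        test_rqs = [r.rq for r in rel if r.group_label == "t"]
        assert test_rqs == pytest.approx([4.0, 1.0])

    def test_unknown_gene_or_group_is_a_lookup_error(self):
        table = _table([25, 25, 25, 25], [20, 20, 20, 20], ["c", "c", "t", "t"])
        with pytest.raises(GeneLookupError):
            delta_delta_ct(table, "NOPE", "c")
        with pytest.raises(GeneLookupError):
            delta_delta_ct(table, "TARGET", "missing_group")
        with pytest.raises(GeneLookupError):
            delta_delta_ct(table, "GAPDH", "c")

    def test_calibrator_group_geometric_mean_rq_is_exactly_one(self, rng):
        ct_t = 25 + rng.standard_normal(8)
        ct_r = 20 + rng.standard_normal(8)
        table = _table(ct_t, ct_r, ["c"] * 4 + ["t"] * 4)
        rel = delta_delta_ct(table, "TARGET", "c")
        log2_cal = [np.log2(r.rq) for r in rel if r.group_label == "c"]
        assert np.mean(log2_cal) == pytest.approx(0.0, abs=1e-12)

    def test_per_sample_ct_shifts_cancel_in_dct(self, rng):
        ct_t = 25 + rng.standard_normal(6)
        ct_r = 20 + rng.standard_normal(6)
        shift = rng.uniform(0.5, 3.0, 6)
        base = _table(ct_t, ct_r, ["c"] * 3 + ["t"] * 3)
        shifted = _table(ct_t + shift, ct_r + shift, ["c"] * 3 + ["t"] * 3)
        rq_a = [r.rq for r in delta_delta_ct(base, "TARGET", "c")]
        rq_b = [r.rq for r in delta_delta_ct(shifted, "TARGET", "c")]
        assert rq_a == pytest.approx(rq_b, rel=1e-12)

    def test_multiple_reference_genes_averaged_on_ct_scale(self):
        genes = ["TARGET", "GAPDH", "ACTB"]
        ct = np.array([[25.0, 24.0], [20.0, 20.0], [22.0, 22.0]])
        table = QpcrTable(genes, ["s0", "s1"], ct, ["c", "c"], ["GAPDH", "ACTB"])
        rel = delta_delta_ct(table, "TARGET", "c")
        # dCt = 25 - 21 = 4 and 24 - 21 = 3; calibrator mean 3.5 -> rq 2^{-0.5}, 2^{+0.5}
        assert [r.rq for r in rel] == pytest.approx([2**-0.5, 2**0.5])

    def test_ct_values_must_be_positive_and_finite(self):
        with pytest.raises(DataError):
            _table([25, -1, 25, 25], [20, 20, 20, 20], ["c", "c", "t", "t"])


def _welch_oracle(a, b):
    """Textbook Welch statistic, Satterthwaite df, two-sided p."""
    from scipy.stats import t as tdist

    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


class TestWelch:
    def test_identical_groups_give_t_zero_p_one(self):
        t, df, p = welch_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_swapping_groups_negates_t_and_preserves_p(self):
        t1, df1, p1 = welch_t_test([1, 2, 3, 4], [3, 4, 5, 6])
        t2, df2, p2 = welch_t_test([3, 4, 5, 6], [1, 2, 3, 4])
        assert t1 == pytest.approx(-t2, abs=1e-15)
        assert p1 == pytest.approx(p2, abs=1e-15)
        assert df1 == pytest.approx(df2, abs=1e-12)

    def test_matches_direct_formula_oracle(self):
        a, b = [1, 2, 3, 4], [3, 4, 5, 6]
        t, df, p = welch_t_test(a, b)
        to, dfo, po = _welch_oracle(a, b)
        assert t == pytest.approx(to, abs=1e-10)
        assert df == pytest.approx(dfo, abs=1e-10)
        assert p == pytest.approx(po, abs=1e-10)

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_p_values_always_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        t, df, p = welch_t_test(r.standard_normal(5), r.standard_normal(7) + 0.3)
        assert 0 < p <= 1

    def test_degenerate_when_both_groups_constant(self):
        with pytest.raises(DegenerateDataError):
            welch_t_test([1, 1, 1], [2, 2, 2])

    def test_group_size_below_two_rejected(self):
        with pytest.raises(DataError):
            welch_t_test([1.0], [1, 2, 3])


class TestPaired:
    def test_balanced_alternating_differences_give_t_zero(self):
        pre = np.array([10.0, 11.0, 12.0, 13.0])
        post = pre + np.array([1.0, -1.0, 1.0, -1.0])
        t, df, p = paired_t_test(pre, post)
        assert t == pytest.approx(0.0, abs=1e-15)
        assert p == pytest.approx(1.0)
        assert df == 3

    def test_constant_shift_is_degenerate(self):
        pre = [10.0, 12.0, 14.0]
        with pytest.raises(DegenerateDataError):
            paired_t_test(pre, [x + 2 for x in pre])

    def test_matches_one_sample_formula_oracle(self):
        from scipy.stats import t as tdist

        pre, post = np.array([10.0, 12.0, 14.0]), np.array([11.0, 14.0, 15.0])
        d = post - pre
        t_o = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        p_o = 2 * tdist.sf(abs(t_o), len(d) - 1)
        t, df, p = paired_t_test(pre, post)
        assert t == pytest.approx(t_o, abs=1e-10)
        assert df == len(d) - 1
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_length_mismatch_is_a_pairing_error(self):
        with pytest.raises(PairingError):
            paired_t_test([1, 2, 3], [1, 2])


class TestBenjaminiHochberg:
    def test_adjusted_p_values_bounded_and_order_preserving(self):
        p = np.array([0.001, 0.02, 0.04, 0.8])
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1)
        assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-15)


class TestQpcrTableIO:
    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        ct = pd.DataFrame(
            [[25.0, 26.0, 24.5, 23.8], [20.0, 20.5, 19.8, 20.1]],
            index=["MYOD1", "GAPDH"],
            columns=["s0", "s1", "s2", "s3"],
        )
        ct.to_csv(tmp_path / "ct.csv", index_label="gene_id")
        pd.DataFrame(
            {"sample_id": ["s0", "s1", "s2", "s3"], "group": ["young", "young", "aged", "aged"]}
        ).to_csv(tmp_path / "groups.csv", index=False)
        table = QpcrTable.read_csv(tmp_path / "ct.csv", tmp_path / "groups.csv", ["GAPDH"])
        assert table.target_genes == ["MYOD1"]
        assert table.group_labels == ["young", "young", "aged", "aged"]
        np.testing.assert_array_equal(table.ct_values, ct.to_numpy())
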