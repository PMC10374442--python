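"""Welch statistics, BH correction, fold-difference and the hit gates."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from syntroscreen.hits import (
    PairAssay,
    bh_adjust,
    call_hits,
    fittest_monoculture,
    fold_difference,
    volcano_table,
    welch_test,
)
from syntroscreen.qc import ConditionSummary, summarize


def welch_oracle(x, y):
    """Direct evaluation of the Welch formulas in exact rational arithmetic."""
    x = [Fraction(v).limit_denominator(10**9) for v in x]
    y = [Fraction(v).limit_denominator(10**9) for v in y]
    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    s1 = sum((v - m1) ** 2 for v in x) / (n1 - 1)
    s2 = sum((v - m2) ** 2 for v in y) / (n2 - 1)
    se2 = s1 / n1 + s2 / n2
    t = float(m1 - m2) / math.sqrt(float(se2))
    df = float(se2**2 / ((s1 / n1) ** 2 / (n1 - 1) + (s2 / n2) ** 2 / (n2 - 1)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def bh_oracle(ps):
    """Hand evaluation of the step-up rule: adj_(i) = min_{j>=i} p_(j)*m/j."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])  # stable
    adj = [0.0] * m
    running_min = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running_min = min(running_min, ps[i] * m / (rank + 1))
        adj[i] = min(running_min, 1.0)
    return adj


class TestWelch:
    def test_identical_groups(self):
        res = welch_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    def test_zero_variance_distinct_means(self):
        res = welch_test([0, 0, 0], [1, 1, 1])
        assert math.isinf(res.t) and res.p == 0.0 and res.degenerate

    def test_zero_variance_equal_means(self):
        res = welch_test([2, 2], [2, 2])
        assert res.t == 0.0 and res.p == 1.0 and res.degenerate

    def test_against_exact_formula_evaluation(self):
        x = [0.8, 0.9, 1.0]
        y = [0.20, 0.25, 0.30]
        t, df, p = welch_oracle(x, y)
        res = welch_test(x, y)
        assert res.t == pytest.approx(t, rel=1e-12)
        assert res.df == pytest.approx(df, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-10)

    def test_small_group_grid_matches_oracle(self):
        grid = [0.0, 0.25, 0.5, 1.0]
        groups = [
            g
            for size in (2, 3)
            for g in itertools.combinations_with_replacement(grid, size)
        ]
        checked = 0
        for x in groups:
            for y in groups:
                if np.var(x) == 0 and np.var(y) == 0:
                    continue  # degenerate convention covered above
                t, df, p = welch_oracle(x, y)
                res = welch_test(x, y)
                assert res.t == pytest.approx(t, rel=1e-10, abs=1e-12)
                assert res.df == pytest.approx(df, rel=1e-10)
                assert res.p == pytest.approx(p, rel=1e-10, abs=1e-12)
                checked += 1
        assert checked > 500

    def test_requires_two_finite_values_per_group(self):
        with pytest.raises(ValueError):
            welch_test([1.0], [0.0, 0.1])
        with pytest.raises(ValueError):
            welch_test([1.0, math.nan], [0.0, 0.1])

    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=6),
        st.lists(st.floats(-5, 5), min_size=2, max_size=6),
        st.floats(-10, 10),
        st.floats(0.1, 10),
    )
    def test_swap_shift_and_scale_properties(self, x, y, shift, scale):
        x, y = np.asarray(x), np.asarray(y)
        r = welch_test(x, y)
        swapped = welch_test(y, x)
        if math.isfinite(r.t):
            assert swapped.t == pytest.approx(-r.t, rel=1e-9, abs=1e-12)
            assert swapped.p == pytest.approx(r.p, rel=1e-9, abs=1e-12)
            shifted = welch_test(x + shift, y + shift)
            assert shifted.t == pytest.approx(r.t, rel=1e-6, abs=1e-9)
            scaled = welch_test(scale * x, scale * y)
            assert abs(scaled.t) == pytest.approx(abs(r.t), rel=1e-6, abs=1e-9)


class TestBH:
    def test_hand_evaluated_step_up(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx(
            [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_value_is_identity(self):
        assert bh_adjust([0.3]).tolist() == [0.3]

    def test_capped_at_one(self):
        assert bh_adjust([1.0, 1.0]).tolist() == [1.0, 1.0]

    def test_all_permutations_up_to_six_match_oracle(self):
        base = [0.001, 0.008, 0.039, 0.041, 0.27, 0.9]
        for n in range(1, 7):
            for perm in itertools.permutations(base[:n]):
                expected = bh_oracle(list(perm))
                got = bh_adjust(list(perm))
                assert got.tolist() == pytest.approx(expected, rel=1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_monotone_and_bounded(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestFoldDifference:
    def s(self, mean, cid="c"):
        return ConditionSummary(cid, 3, mean, 0.0, mean, 0.0)

    def test_simple_ratio(self):
        fc, flagged = fold_difference(self.s(0.60), self.s(0.20))
        assert fc == pytest.approx(3.0) and not flagged

    def test_equal_means(self):
        fc, _ = fold_difference(self.s(0.5), self.s(0.5))
        assert fc == pytest.approx(1.0)

    def test_zero_denominator_floored_and_flagged(self):
        fc, flagged = fold_difference(self.s(0.4), self.s(0.0), fd_floor=1e-3)
        assert fc == pytest.approx(400.0) and flagged

    def test_fittest_pick_and_tie_break(self):
        a, b = self.s(0.30, "m_a"), self.s(0.10, "m_b")
        assert fittest_monoculture(a, b) == "m_a"
        assert fittest_monoculture(self.s(0.2, "m_b"), self.s(0.2, "m_a")) == "m_a"
        with pytest.raises(ValueError):
            fittest_monoculture(a, None)


class TestCallGates:
    def make_assay(self, fc, p_adj, cid="co"):
        a = PairAssay(cid, ("m1", "m2"), fittest_mono_id="m1")
        a.summary_co = summarize([0.5, 0.6], cid)
        a.summary_mono_a = summarize([0.1, 0.1], "m1")
        a.summary_mono_b = summarize([0.05, 0.05], "m2")
        a.fold_difference, a.p_adj, a.p_raw = fc, p_adj, p_adj
        a.call = "pending"
        return a

    def test_threshold_rule(self, config):
        assays = [
            self.make_assay(1.6, 0.01, "hit_case"),
            self.make_assay(1.4, 0.001, "fc_blocked"),
            self.make_assay(2.0, 0.06, "near"),
            self.make_assay(2.0, 0.3, "no_adv"),
        ]
        table, summary = call_hits(assays, config)
        calls = dict(zip(table["coculture_id"], table["call"]))
        assert calls == {
            "hit_case": "hit",
            "fc_blocked": "no_growth_advantage",
            "near": "near_hit",
            "no_adv": "no_growth_advantage",
        }
        assert summary["n_hits"] == 1 and summary["n_near_hits"] == 1

    def test_empty_assay_list_rejected(self, config):
        with pytest.raises(ValueError):
            call_hits([], config)

    def test_volcano_axes_and_clamp(self):
        a = self.make_assay(2.0, 1.0)
        b = self.make_assay(4.0, 0.0, "zero_p")
        b.p_raw = 0.0
        df = volcano_table([a, b]).set_index("coculture_id")
        assert df.loc["co", "log2_fc"] == pytest.approx(1.0)
        assert df.loc["co", "ln_p_adj"] == pytest.approx(0.0)
        assert df.loc["zero_p", "p_clamped"]
        assert math.isfinite(df.loc["zero_p", "ln_p_adj"])
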