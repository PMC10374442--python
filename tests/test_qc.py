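"""QC cascade: blank correction, robust flags, positional bias, Z-factor."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from syntroscreen.io_screen import TIDY_COLUMNS
from syntroscreen.qc import (
    activity_range_filter,
    blank_correct,
    classify_auxotroph,
    detect_contamination,
    loo_spread_flags,
    mad_spread_flags,
    median_polish,
    positional_bias_flags,
    scaled_mad,
    z_factor,
)


def make_tidy(rows):
    """rows: (plate, well, row, col, cid, kind, s1, od0, od48)"""
    records = []
    for plate, well, r, c, cid, kind, s1, od0, od48 in rows:
        base = (plate, "b1", well, r, c, cid, kind, s1, "")
        records.append(base + (0.0, od0))
        records.append(base + (48.0, od48))
    return pd.DataFrame(records, columns=TIDY_COLUMNS)


class TestBlankCorrect:
    def test_subtracts_plate_blank_median_and_floors(self, config):
        tidy = make_tidy(
            [
                ("P1", "A1", 0, 0, "BLANK", "blank", "", 0.00, 0.02),
                ("P1", "A2", 0, 1, "m", "monoculture", "s1", 0.10, 0.60),
                ("P1", "A3", 0, 2, "m2", "monoculture", "s2", 0.10, 0.11),
            ]
        )
        wells, flags = blank_correct(tidy, config)
        by_well = wells.set_index("well")
        assert by_well.loc["A2", "growth"] == pytest.approx(0.48)
        assert by_well.loc["A3", "growth"] == pytest.approx(0.0)  # floored
        assert by_well.loc["A2", "delta"] == pytest.approx(0.50)  # raw kept
        assert flags == []

    def test_plate_without_blanks_uses_raw_delta_and_warns(self, config):
        tidy = make_tidy(
            [("P1", "A1", 0, 0, "m", "monoculture", "s1", 0.10, 0.60)]
        )
        wells, flags = blank_correct(tidy, config)
        assert wells.loc[0, "growth"] == pytest.approx(0.50)
        assert len(flags) == 1 and not flags[0].hard


class TestClassifyAuxotroph:
    def test_below_threshold_and_grows_on_sc(self):
        assert classify_auxotroph(0.19, 1.0, 0.9, 1.0) == "auxotroph"

    def test_boundary_is_strict(self):
        assert classify_auxotroph(0.20, 1.0, 0.9, 1.0) == "leaky_or_prototroph"

    def test_poor_growth_on_both_media_is_not_auxotrophy(self):
        assert classify_auxotroph(0.10, 1.0, 0.2, 1.0) == "leaky_or_prototroph"

    def test_nonpositive_parent_rejected(self):
        with pytest.raises(ValueError):
            classify_auxotroph(0.1, 0.0, 0.9, 1.0)


class TestSpreadFlags:
    def test_identical_replicates_unflagged(self):
        assert not mad_spread_flags([1, 1, 1, 1]).any()

    def test_single_outlier_flagged(self):
        # median 1.05, raw MAD 0.10 -> only 5.0 deviates beyond 3*1.4826*0.10
        flags = mad_spread_flags([0.9, 1.0, 1.1, 5.0], k=3, scale=1.4826)
        assert flags.tolist() == [False, False, False, True]

    def test_zero_mad_fallback(self):
        flags = mad_spread_flags([1, 1, 1, 2], fallback_margin=0.05)
        assert flags.tolist() == [False, False, False, True]

    def test_fewer_than_three_unflagged(self):
        assert not mad_spread_flags([1.0, 9.0]).any()

    def test_loo_catches_masked_pair_of_outliers(self):
        # two coincident outliers inflate the plain MAD and mask each other
        vals = [0.336, 0.344, 0.566, 0.948]
        assert not mad_spread_flags(vals).any()
        assert loo_spread_flags(vals).tolist() == [False, False, True, True]

    @given(
        st.lists(st.floats(-10, 10), min_size=3, max_size=8),
        st.floats(0.1, 5.0),
        st.floats(-3.0, 3.0),
        st.permutations(range(8)),
    )
    def test_permutation_and_affine_invariance(self, xs, a, b, perm):
        xs = np.round(np.asarray(xs), 6)
        base = mad_spread_flags(xs)
        order = [p for p in perm if p < len(xs)]
        assert (mad_spread_flags(xs[order]) == base[order]).all()
        assert (mad_spread_flags(a * xs + b, fallback_margin=a * 0.05) == base).all()


class TestZFactor:
    def test_ideal_separation(self):
        assert z_factor([1.0, 1.0], [0.2, 0.2]) == 1.0

    def test_direct_arithmetic(self):
        # 1 - 3*(0.1+0.1)/0.8 = 0.25
        pos = [0.9, 1.1]  # mean 1.0, sd ~0.1414 -> use 3 values for sd 0.1
        pos = [0.9, 1.0, 1.1]
        neg = [0.1, 0.2, 0.3]
        sd = np.std(pos, ddof=1)
        expected = 1 - 3 * (2 * sd) / 0.8
        assert z_factor(pos, neg) == pytest.approx(expected)

    def test_equal_means_sentinel(self):
        assert z_factor([1.0, 2.0], [1.5, 1.5]) == -math.inf

    def test_requires_two_per_group(self):
        with pytest.raises(ValueError):
            z_factor([1.0], [0.0, 0.1])

    @given(
        st.lists(st.floats(-5, 5), min_size=2, max_size=6),
        st.lists(st.floats(-5, 5), min_size=2, max_size=6),
        st.floats(0.1, 10),
        st.floats(-5, 5),
    )
    def test_symmetry_and_affine_invariance(self, pos, neg, a, b):
        pos, neg = np.asarray(pos), np.asarray(neg)
        z = z_factor(pos, neg)
        assert z_factor(neg, pos) == pytest.approx(z, nan_ok=True) or (
            math.isinf(z) and math.isinf(z_factor(neg, pos))
        )
        z_t = z_factor(a * pos + b, a * neg + b)
        if math.isfinite(z):
            assert z_t == pytest.approx(z, rel=1e-9)
        assert z <= 1.0 or math.isinf(z)


class TestActivityRange:
    def test_adequate_window_kept(self):
        # Z = 1 - 3*(0.05+0.05)/0.7 ~ 0.571
        co = [0.75, 0.80, 0.85]
        mono = [0.05, 0.10, 0.15]
        sd = np.std(co, ddof=1)
        keep, reason = activity_range_filter(co, mono, 0.5)
        assert keep and reason is None

    def test_leaky_monoculture_erases_window(self):
        keep, reason = activity_range_filter([0.8, 0.8], [0.8, 0.8], 0.5)
        assert not keep and "activity range" in reason

    def test_single_replicate_dropped_with_reason(self):
        keep, reason = activity_range_filter([0.8], [0.1, 0.1], 0.5)
        assert not keep and reason == "insufficient replicates"


class TestContamination:
    def _wells(self, rows):
        """rows: (well, row, col, cid, kind, s1, growth)"""
        return pd.DataFrame(
            [
                {
                    "plate_id": "P1", "batch": "b", "well": w, "row": r,
                    "col": c, "condition_id": cid, "kind": kind,
                    "strain_1": s1, "strain_2": "", "growth": g,
                }
                for w, r, c, cid, kind, s1, g in rows
            ]
        )

    def test_clean_blanks_unflagged(self):
        wells = self._wells(
            [("A1", 0, 0, "BLANK", "blank", "", 0.03),
             ("A2", 0, 1, "BLANK", "blank", "", 0.01)]
        )
        assert detect_contamination(wells, set(), 0.05) == []

    def test_grown_blank_flagged(self):
        wells = self._wells([("A1", 0, 0, "BLANK", "blank", "", 0.40)])
        flags = detect_contamination(wells, set(), 0.05)
        assert len(flags) == 1 and flags[0].well == "A1" and flags[0].hard

    def test_strict_auxotroph_outgrowing_condition_median(self):
        wells = self._wells(
            [
                ("A1", 0, 0, "m", "monoculture", "s1", 0.01),
                ("A2", 0, 1, "m", "monoculture", "s1", 0.02),
                ("A3", 0, 2, "m", "monoculture", "s1", 0.55),
                ("C5", 2, 4, "m2", "monoculture", "s2", 0.60),  # leaky, not strict
            ]
        )
        flags = detect_contamination(wells, {"s1"}, 0.05)
        hard = [f for f in flags if f.hard]
        assert {f.well for f in hard} == {"A3"}

    def test_neighbourhood_soft_warning(self):
        wells = self._wells(
            [
                ("A1", 0, 0, "BLANK", "blank", "", 0.40),
                ("A2", 0, 1, "m", "monoculture", "s1", 0.30),
                ("C3", 2, 2, "m", "monoculture", "s1", 0.30),
            ]
        )
        flags = detect_contamination(wells, set(), 0.05)
        soft = [f for f in flags if not f.hard]
        assert {f.well for f in soft} == {"A2"}  # adjacent; C3 is not


class TestPositionalBias:
    def _uniform_plate(self, rng, sd=0.02, fmt=96):
        n_rows, n_cols = (8, 12) if fmt == 96 else (16, 24)
        rows = []
        for r in range(n_rows):
            for c in range(n_cols):
                rows.append(
                    {
                        "plate_id": "P1", "well": f"{chr(65 + r)}{c + 1}",
                        "row": r, "col": c,
                        "condition_id": f"cond{(r * n_cols + c) % 3}",
                        "kind": "coculture", "strain_1": "x", "strain_2": "y",
                        "growth": 0.5 + rng.normal(0, sd),
                    }
                )
        return pd.DataFrame(rows)

    def test_false_flag_rate_on_uniform_plates(self):
        rng = np.random.default_rng(2024)
        clean = sum(
            len(positional_bias_flags(self._uniform_plate(rng), 3.0)) == 0
            for _ in range(200)
        )
        assert clean >= 190  # >= 95% of simulations fully unflagged

    def test_planted_edge_offset_flags_all_edge_wells(self):
        rng = np.random.default_rng(5)
        plate = self._uniform_plate(rng)
        from syntroscreen.plate_model import is_edge

        edge = plate.apply(lambda r: is_edge(r["row"], r["col"], 96), axis=1)
        plate.loc[edge, "growth"] += 0.5
        flags = positional_bias_flags(plate, 3.0)
        flagged = {f.well for f in flags if f.detail == "edge effect"}
        assert flagged == set(plate.loc[edge, "well"])

    def test_column_gradient_matches_polish_oracle(self):
        rng = np.random.default_rng(8)
        plate = self._uniform_plate(rng, sd=0.01)
        slope = 0.08
        plate["growth"] += slope * (plate["col"] - plate["col"].mean())

        flags = positional_bias_flags(plate, 3.0)
        trend_wells = {f.well for f in flags if "trend" in f.detail}

        # independent oracle: brute-force polish on the small plate matrix
        # of condition-centred growth (the pipeline's stated input)
        centred = plate["growth"] - plate.groupby("condition_id")["growth"].transform(
            "median"
        )
        mat = np.full((8, 12), np.nan)
        for (_, r), v in zip(plate.iterrows(), centred):
            mat[r["row"], r["col"]] = v
        _, row_eff, col_eff, resid = median_polish(mat)
        thr = 3.0 * max(scaled_mad(resid[~np.isnan(resid)]), 0.05)
        expected = {
            r["well"]
            for _, r in plate.iterrows()
            if abs(row_eff[r["row"]] + col_eff[r["col"]]) > thr
        }
        assert expected  # the planted gradient must exceed the threshold
        assert trend_wells == expected

    def test_single_condition_plate_soft_warning_only(self):
        plate = self._uniform_plate(np.random.default_rng(0))
        plate["condition_id"] = "only"
        flags = positional_bias_flags(plate, 3.0)
        assert len(flags) == 1 and not flags[0].hard


def test_median_polish_recovers_planted_additive_structure():
    rng = np.random.default_rng(3)
    row_true = np.array([0.0, 0.2, -0.1, 0.3])
    col_true = np.array([0.0, -0.2, 0.1, 0.0, 0.25])
    grand = 1.0
    mat = grand + row_true[:, None] + col_true[None, :]
    overall, row_eff, col_eff, resid = median_polish(mat)
    fitted = overall + row_eff[:, None] + col_eff[None, :]
    assert np.allclose(fitted, mat, atol=1e-8)
    assert np.allclose(resid, 0.0, atol=1e-8)
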