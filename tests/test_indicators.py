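"""Performance indicators and their period summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import array_shapes, arrays

from hcrsim import (
    PeriodDefinition,
    ProjectionConfig,
    ReferencePoints,
    StabilityParams,
    catch_stability,
    effort_and_cpue,
    indicator_table,
    indicator_table_from_frame,
    make_life_history,
    prob_above_lrp,
    run_replicates,
    summarise,
    trp_proximity,
)
from hcrsim.indicators import INDICATOR_NAMES


class TestProbAboveLrp:
    def test_counts_strictly_above(self):
        bio = np.array([[0.3], [0.25], [0.1], [0.5]])
        assert prob_above_lrp(bio) == pytest.approx([0.75])

    def test_all_safe_is_one(self):
        assert np.all(prob_above_lrp(np.full((6, 4), 0.4)) == 1.0)

    def test_boundary_is_not_above(self):
        assert np.all(prob_above_lrp(np.full((3, 2), 0.2)) == 0.0)


class TestCatchStability:
    def setup_method(self):
        self.sp = StabilityParams(cvar_max=100.0)

    def test_constant_catches_are_perfectly_stable(self):
        assert np.all(catch_stability(np.full(10, 80.0), self.sp) == 1.0)

    def test_change_equal_to_cvar_max_is_zero(self):
        assert catch_stability(np.array([100.0, 200.0]), self.sp) == pytest.approx([0.0])

    def test_midpoint_is_half(self):
        assert catch_stability(np.array([100.0, 150.0]), self.sp) == pytest.approx([0.5])

    def test_changes_beyond_cvar_max_clamp_at_zero(self):
        assert catch_stability(np.array([0.0, 500.0]), self.sp) == pytest.approx([0.0])

    def test_single_year_series_rejected(self):
        with pytest.raises(ValueError):
            catch_stability(np.array([100.0]), self.sp)

    def test_default_cvar_max_is_k_over_10(self):
        lh = make_life_history("fast")
        assert StabilityParams.from_life_history(lh).cvar_max == pytest.approx(40.0)


class TestTrpProximity:
    def test_at_target_is_one(self):
        assert trp_proximity(np.array([0.5])) == pytest.approx([1.0])

    def test_collapsed_stock_is_zero(self):
        assert trp_proximity(np.array([0.0])) == pytest.approx([0.0])

    def test_quarter_above_target_is_half(self):
        assert trp_proximity(np.array([0.75])) == pytest.approx([0.5])

    @given(st.floats(0.0, 0.5))
    def test_symmetric_about_default_target(self, d):
        lo = trp_proximity(np.array([0.5 - d]))
        hi = trp_proximity(np.array([0.5 + d]))
        assert lo == pytest.approx(hi)

    def test_asymmetric_target_uses_max_distance(self):
        rp = ReferencePoints(lrp=0.1, trp=0.8)
        # farthest point is B = 0 at distance 0.8
        assert trp_proximity(np.array([0.0]), rp) == pytest.approx([0.0])
        assert trp_proximity(np.array([1.0]), rp) == pytest.approx([1 - 0.2 / 0.8])


class TestEffortAndCpue:
    def test_direct_evaluation(self):
        e, cpue = effort_and_cpue(np.array([100.0]), np.array([100.0]))
        assert e == pytest.approx([1.0])
        assert cpue == pytest.approx([100.0])

    def test_cpue_is_biomass_when_q_is_one(self):
        b = np.array([300.0, 200.0, 150.0])
        _, cpue = effort_and_cpue(np.array([50.0, 60.0, 0.0]), b)
        np.testing.assert_allclose(cpue, b)

    def test_no_fishing_no_effort(self):
        e, _ = effort_and_cpue(np.array([0.0]), np.array([250.0]))
        assert e == pytest.approx([0.0])

    def test_positive_catch_from_zero_biomass_rejected(self):
        with pytest.raises(ValueError):
            effort_and_cpue(np.array([10.0]), np.array([0.0]))


@given(
    arrays(
        float,
        array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=20),
        elements=st.floats(0, 1000),
    )
)
def test_indicators_stay_in_unit_interval_for_any_trajectory(mat):
    sp = StabilityParams(cvar_max=50.0)
    stab = catch_stability(mat, sp)
    assert np.all((stab >= 0) & (stab <= 1))
    rel = mat / 1000.0
    prox = trp_proximity(rel)
    assert np.all((prox >= 0) & (prox <= 1))
    p = prob_above_lrp(rel)
    assert np.all((p >= 0) & (p <= 1))


class TestPeriodDefinition:
    def test_equal_thirds_partition_with_remainder_to_long(self):
        years = list(range(2020, 2050))
        p = PeriodDefinition.equal_thirds(years)
        assert len(p.short) == len(p.medium) == len(p.long) == 10
        p31 = PeriodDefinition.equal_thirds(list(range(2020, 2051)))
        assert (len(p31.short), len(p31.medium), len(p31.long)) == (10, 10, 11)

    def test_windows_must_be_ordered_and_nonempty(self):
        with pytest.raises(ValueError):
            PeriodDefinition(short=(2021,), medium=(2020,), long=(2022,))
        with pytest.raises(ValueError):
            PeriodDefinition(short=(), medium=(2020,), long=(2021,))


class TestSummarise:
    def periods(self):
        return PeriodDefinition(short=(0, 1), medium=(2, 3), long=(4, 5))

    def test_median_of_period_means(self):
        # per-replicate period means over the short window are 1..5
        vals = pd.DataFrame(
            {0: [1, 2, 3, 4, 5], 1: [1, 2, 3, 4, 5], 2: 0, 3: 0, 4: 0, 5: 0},
            dtype=float,
        )
        out = summarise(vals, self.periods())
        short = out[out["period"] == "short"].iloc[0]
        assert short["median"] == 3.0
        assert short["lo90"] == pytest.approx(np.percentile([1, 2, 3, 4, 5], 5))

    def test_single_replicate_collapses_bounds(self):
        vals = pd.DataFrame([[2.0, 4.0, 1.0, 1.0, 6.0, 6.0]], columns=range(6))
        out = summarise(vals, self.periods())
        row = out[out["period"] == "short"].iloc[0]
        assert row["median"] == row["lo90"] == row["hi90"] == 3.0

    def test_identical_replicates_have_zero_width(self):
        vals = pd.DataFrame(np.full((10, 6), 7.0), columns=range(6))
        out = summarise(vals, self.periods())
        assert (out["hi90"] - out["lo90"]).abs().max() == 0.0

    @given(
        arrays(float, (7, 6), elements=st.floats(-100, 100)),
    )
    def test_median_lies_within_reported_bounds(self, mat):
        vals = pd.DataFrame(mat, columns=range(6))
        out = summarise(vals, self.periods())
        assert (out["lo90"] <= out["median"] + 1e-12).all()
        assert (out["median"] <= out["hi90"] + 1e-12).all()
        assert (out["lo80"] <= out["hi80"] + 1e-12).all()


class TestIndicatorTable:
    @pytest.fixture()
    def reps(self, lh_medium, fully, fig1_rule):
        cfg = ProjectionConfig(n_replicates=8, seed=21)
        return run_replicates(lh_medium, fully, fig1_rule, cfg)

    def test_all_indicators_and_periods_present(self, reps):
        table = indicator_table(reps)
        assert set(table["indicator"]) == set(INDICATOR_NAMES)
        assert len(table) == 7 * 3
        scaled = table[table["indicator"].isin(["catch_stability", "trp_proximity"])]
        assert scaled["median"].between(0, 1).all()

    def test_prob_row_has_no_percentile_bounds(self, reps):
        table = indicator_table(reps)
        p = table[table["indicator"] == "prob_above_lrp"]
        assert p["lo90"].isna().all() and p["hi90"].isna().all()
        assert p["median"].between(0, 1).all()

    def test_table_recomputable_from_saved_trajectories(self, reps, tmp_path):
        path = tmp_path / "traj.csv"
        reps.to_csv(path)
        again = indicator_table_from_frame(pd.read_csv(path))
        direct = indicator_table(reps)
        pd.testing.assert_frame_equal(again, direct, check_exact=False, rtol=1e-12)

    def test_relative_cpue_tracks_relative_biomass_without_noise(
        self, lh_medium, fully_noiseless, fig1_rule
    ):
        cfg = ProjectionConfig(n_replicates=1, seed=0, bio_sd=0.0, est_sd=0.0)
        reps = run_replicates(lh_medium, fully_noiseless, fig1_rule, cfg)
        d = reps.data
        base_rel = d.loc[d["year"] == cfg.last_hist_year, "biomass_rel"].iloc[0]
        np.testing.assert_allclose(d["cpue_rel"], d["biomass_rel"] / base_rel)

    def test_reference_point_defaults(self):
        rp = ReferencePoints()
        assert rp.lrp == 0.2 and rp.trp == 0.5
        with pytest.raises(ValueError):
            ReferencePoints(lrp=0.6, trp=0.5)
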