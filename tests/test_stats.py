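"""Descriptives, agreement, trends, Bonferroni and mixed models."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lungesym import (
    StudyEffects,
    bonferroni_adjust,
    estimated_marginal_means,
    fit_mixed_model,
    intra_horse_sd,
    limits_of_agreement,
    linear_trend,
    pairwise_direction_comparisons,
    simulate_study,
)
from lungesym.stats import descriptives, stride_time_model, summary_table
from conftest import wide_record, wide_table


class TestDescriptives:
    def test_symmetric_pair(self):
        df = wide_table([wide_record("A", HDmin=-3.0), wide_record("B", HDmin=3.0)])
        d = descriptives(df, "HDmin")
        assert d.mean == 0.0
        assert d.mean_abs == 3.0
        assert d.n_left == 1 and d.n_right == 1

    def test_single_value_sd_flagged(self):
        df = wide_table([wide_record("A", HDmin=5.0)])
        d = descriptives(df, "HDmin")
        assert d.mean == d.min == d.max == 5.0
        assert d.sd == 0.0 and not d.sd_defined

    def test_hand_computed_sd(self):
        df = wide_table([wide_record("A", PDmin=1.0), wide_record("B", PDmin=2.0),
                         wide_record("C", PDmin=3.0)])
        d = descriptives(df, "PDmin")
        assert d.mean == 2.0
        assert d.sd == pytest.approx(1.0)  # n-1 denominator

    def test_empty_input_rejected(self):
        df = wide_table([wide_record("A")]).iloc[0:0]
        with pytest.raises(ValueError):
            descriptives(df, "HDmin")


class TestIntraHorseSD:
    def test_identical_conditions_give_zero(self):
        df = wide_table([wide_record("A", HDmin=4.0), wide_record("A", HDmin=4.0),
                         wide_record("B", HDmin=-2.0), wide_record("B", HDmin=-2.0)])
        assert intra_horse_sd(df, "HDmin") == 0.0

    def test_hand_computed_single_horse(self):
        # values {4, 8}: deviations {-2, +2}, SD with n-1 denominator = 2*sqrt(2)
        df = wide_table([wide_record("A", HDmin=4.0), wide_record("A", HDmin=8.0)])
        assert intra_horse_sd(df, "HDmin") == pytest.approx(2.0 * np.sqrt(2.0))

    def test_single_condition_horses_excluded(self):
        df = wide_table([wide_record("A", HDmin=4.0), wide_record("B", HDmin=9.0)])
        with pytest.raises(ValueError, match="two straight-line"):
            intra_horse_sd(df, "HDmin")

    def test_summary_table_has_all_parameters(self, small_study):
        t = summary_table(small_study)
        assert len(t) == 11
        assert t["intra_horse_sd"].notna().all()


class TestLimitsOfAgreement:
    def test_identical_pairs(self):
        loa = limits_of_agreement([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert loa.bias == 0.0 and loa.sd == 0.0 and loa.band == 0.0

    def test_hand_computed_pair(self):
        # differences {1, 3}: bias 2, sd sqrt(2), band 2*sqrt(2)
        loa = limits_of_agreement([2.0, 6.0], [1.0, 3.0])
        assert loa.bias == pytest.approx(2.0)
        assert loa.sd == pytest.approx(np.sqrt(2.0))
        assert loa.band == pytest.approx(2.0 * np.sqrt(2.0))

    def test_sign_flip_negates_bias_only(self):
        rng = np.random.default_rng(5)
        s, a = rng.normal(size=12), rng.normal(size=12)
        fwd = limits_of_agreement(s, a)
        rev = limits_of_agreement(-s, -a)
        assert rev.bias == pytest.approx(-fwd.bias)
        assert rev.sd == pytest.approx(fwd.sd)

    def test_brute_force_oracle_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(2, 12)
            s = rng.normal(0, 10, n)
            a = rng.normal(0, 10, n)
            loa = limits_of_agreement(s, a)
            # explicit loop oracle
            diffs = [s[i] - a[i] for i in range(n)]
            mean = sum(diffs) / n
            var = sum((d - mean) ** 2 for d in diffs) / (n - 1)
            assert loa.bias == pytest.approx(mean, abs=1e-10)
            assert loa.sd == pytest.approx(var**0.5, abs=1e-10)
            assert loa.band == pytest.approx(2 * var**0.5, abs=1e-10)

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError):
            limits_of_agreement([1.0], [2.0])


class TestLinearTrend:
    def test_identity_line(self):
        fit = linear_trend([0, 1, 2, 3], [0, 1, 2, 3])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_constant_y(self):
        fit = linear_trend([0, 1, 2], [5.0, 5.0, 5.0])
        assert fit.slope == 0.0 and fit.r2 == 0.0

    def test_hand_computed_ols(self):
        fit = linear_trend([0, 1, 2], [0, 1, 3])
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(-1.0 / 6.0)

    def test_normal_equation_oracle_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n = int(rng.integers(3, 15))
            x = rng.normal(0, 5, n)
            if np.ptp(x) == 0:  # pragma: no cover
                continue
            y = rng.normal(0, 5, n)
            fit = linear_trend(x, y)
            xm, ym = x.mean(), y.mean()
            slope = ((x - xm) @ (y - ym)) / ((x - xm) @ (x - xm))
            intercept = ym - slope * xm
            assert fit.slope == pytest.approx(slope, abs=1e-10)
            assert fit.intercept == pytest.approx(intercept, abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            linear_trend([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestBonferroni:
    def test_stated_formula(self):
        assert bonferroni_adjust(0.01, 3) == pytest.approx(0.03)

    def test_capped_at_one(self):
        assert bonferroni_adjust(0.5, 4) == 1.0

    def test_single_comparison_identity(self):
        assert bonferroni_adjust(0.123, 1) == pytest.approx(0.123)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(p=st.floats(0, 1), q=st.floats(0, 1), m=st.integers(1, 50))
    def test_monotone_and_bounded(self, p, q, m):
        lo, hi = sorted([p, q])
        assert bonferroni_adjust(lo, m) <= bonferroni_adjust(hi, m)
        assert bonferroni_adjust(p, m) <= bonferroni_adjust(p, m + 1)
        assert 0.0 <= bonferroni_adjust(p, m) <= 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_adjust(1.5, 2)
        with pytest.raises(ValueError):
            bonferroni_adjust(0.5, 0)


class TestMixedModel:
    def test_zero_variance_limit_matches_ols(self):
        effects = StudyEffects(horse_sd=0.0, residual_sd=0.0, surface_effect=2.0,
                               lean_gain=0.0, side_prob=1.0)
        df = simulate_study(effects, seed=2)
        mr = fit_mixed_model(df, "PDmin", ("surface", "speed", "direction"),
                             drop_random_on_singular=True)
        assert mr.emm_diff["surface"] == pytest.approx(2.0, abs=1e-6)
        import statsmodels.formula.api as smf

        ols = smf.ols("PDmin ~ C(surface) + C(speed) + C(direction)", df).fit()
        assert np.allclose(mr.fe_params, ols.params.to_numpy(), atol=1e-6)

    def test_constant_response_is_flagged_with_p_one(self):
        df = wide_table([
            wide_record(h, surface=s, speed=sp, HDmin=3.0)
            for h in ("A", "B", "C")
            for s in ("hard", "soft")
            for sp in ("slow", "fast")
        ])
        mr = fit_mixed_model(df, "HDmin", ("surface", "speed"))
        assert mr.p_values["surface"] == 1.0
        assert mr.emms["surface"]["hard"] == mr.emms["surface"]["soft"] == 3.0

    def test_single_run_recovery_within_ci(self):
        effects = StudyEffects(n_horses=30, surface_effect=2.0, horse_sd=3.0,
                               residual_sd=2.0, lean_gain=0.0, side_prob=1.0)
        df = simulate_study(effects, seed=77)
        mr = fit_mixed_model(df, "PDmin", ("surface", "speed", "direction"))
        est = mr.emms["surface"]["hard"] - mr.emms["surface"]["soft"]
        # 95% CI half-width for the hard-soft contrast
        se = np.sqrt(4.0 * mr.var_resid / mr.n_obs) * np.sqrt(2)
        assert abs(est - 2.0) < 2.5 * se + 0.3

    def test_balanced_design_emm_equals_raw_mean(self):
        rng = np.random.default_rng(3)
        rows = []
        for h in ("A", "B", "C", "D"):
            for s in ("hard", "soft"):
                for sp in ("slow", "fast"):
                    rows.append(wide_record(h, surface=s, speed=sp,
                                            HDmin=rng.normal(5, 2)))
        df = wide_table(rows)
        mr = fit_mixed_model(df, "HDmin", ("surface", "speed"))
        raw = df.groupby("surface")["HDmin"].mean()
        for level in ("hard", "soft"):
            assert mr.emms["surface"][level] == pytest.approx(raw[level], abs=1e-6)

    def test_unbalanced_design_emm_recovers_injected_effect(self):
        # hard surface sampled mostly at fast speed: raw means confound the
        # two effects, the balanced-grid EMM does not
        rows = []
        for h in ("A", "B"):
            for s, sp, n in (("hard", "fast", 6), ("hard", "slow", 2),
                             ("soft", "fast", 2), ("soft", "slow", 6)):
                for _ in range(n):
                    y = 2.0 * (s == "hard") + 3.0 * (sp == "fast")
                    rows.append(wide_record(h, surface=s, speed=sp, HDmin=y))
        df = wide_table(rows)
        mr = fit_mixed_model(df, "HDmin", ("surface", "speed"),
                             drop_random_on_singular=True)
        assert mr.emm_diff["surface"] == pytest.approx(2.0, abs=1e-6)
        raw = df.groupby("surface")["HDmin"].mean()
        assert abs(raw["hard"] - raw["soft"]) != pytest.approx(2.0, abs=0.5)

    def test_unknown_factor_rejected(self):
        df = simulate_study(StudyEffects(n_horses=4), seed=1)
        mr = fit_mixed_model(df, "HDmin", ("surface", "speed"))
        with pytest.raises(ValueError, match="unknown factor"):
            estimated_marginal_means(mr, "gait")

    def test_insufficient_levels_rejected(self):
        df = simulate_study(StudyEffects(n_horses=4), seed=1)
        sub = df[df["surface"] == "hard"]
        with pytest.raises(ValueError, match="levels"):
            fit_mixed_model(sub, "HDmin", ("surface", "speed"))


class TestPairwiseComparisons:
    def test_three_level_adjustment_is_threefold(self):
        effects = StudyEffects(n_horses=12)
        df = simulate_study(effects, seed=4)
        mr, pairs = stride_time_model(df)
        for _, row in pairs.iterrows():
            assert row["p_adjusted"] == pytest.approx(
                min(1.0, 3.0 * row["p_raw"]), abs=1e-12
            )

    def test_straight_vs_rein_pattern(self):
        # injected: lunging slows the stride by ~38 ms, no rein difference
        effects = StudyEffects(n_horses=20, st_residual_sd=10.0)
        df = simulate_study(effects, seed=6)
        mr, pairs = stride_time_model(df)
        keyed = pairs.set_index(["level_a", "level_b"])
        assert keyed.loc[("left", "straight"), "p_adjusted"] < 0.05
        assert keyed.loc[("right", "straight"), "p_adjusted"] < 0.05
        assert keyed.loc[("left", "right"), "p_adjusted"] > 0.05

    def test_two_level_factor_rejected(self):
        df = simulate_study(StudyEffects(n_horses=6), seed=2)
        mr = fit_mixed_model(df, "stride_time", ("surface", "speed"))
        with pytest.raises(ValueError, match="three levels"):
            pairwise_direction_comparisons(mr, "surface")
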