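"""Statistical-moment transit-time estimators against analytic oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from gitransit import (
    ArrivalCurve,
    Meal,
    MomentConfig,
    RetentionCurve,
    Site,
    analyze_recording,
    mean_cecum_arrival_time,
    mean_gastric_emptying_time,
    small_intestinal_transit_time,
    t50,
)
from gitransit.exceptions import (
    CensoredPlateauWarning,
    DegenerateRecordingError,
    IncompleteEmptyingError,
    IncompleteEmptyingWarning,
)
from gitransit.moments import mget_rate_weighted

from conftest import exponential_arrival, exponential_retention, make_signal


def boxcar_retention(drop_after=100.0, t_max=420.0, dt=10.0):
    t = np.arange(0.0, t_max + 1e-9, dt)
    return RetentionCurve(t, (t <= drop_after).astype(float))


class TestMGET:
    def test_boxcar_mass_leaves_at_interval_midpoint(self):
        # all mass leaves in the single 100->110 interval: MGET = 105
        assert mean_gastric_emptying_time(boxcar_retention()) == pytest.approx(
            105.0, abs=1e-9
        )

    def test_exponential_matches_1_over_k(self):
        mget = mean_gastric_emptying_time(exponential_retention(k=0.01))
        assert mget == pytest.approx(100.0, rel=0.01)

    def test_power_exponential_matches_gamma_mean(self):
        t = np.arange(0.0, 400.0 + 1e-9, 10.0)
        r = RetentionCurve(t, np.exp(-((0.01 * t) ** 2)))
        expected = math.gamma(1.5) / 0.01  # 88.62 min
        dense, _ = quad(lambda u: math.exp(-((0.01 * u) ** 2)), 0, 400)
        assert expected == pytest.approx(dense, rel=1e-4)
        assert mean_gastric_emptying_time(r) == pytest.approx(expected,
                                                              rel=0.01)

    def test_incomplete_emptying_warns_and_truncates(self):
        trunc = exponential_retention(k=0.01, t_max=150.0)
        with pytest.warns(IncompleteEmptyingWarning):
            mget = mean_gastric_emptying_time(trunc)
        assert mget < 100.0  # truncation can only lose area

    def test_exponential_tail_extrapolation_recovers_lost_area(self):
        trunc = exponential_retention(k=0.01, t_max=300.0)
        config = MomentConfig(tail_policy="exponential_extrapolate")
        extrapolated = mean_gastric_emptying_time(trunc, config)
        with pytest.warns(IncompleteEmptyingWarning):
            truncated = mean_gastric_emptying_time(trunc)
        assert truncated < extrapolated
        assert extrapolated == pytest.approx(100.0, rel=0.01)

    def test_grid_refinement_converges_to_dense_oracle(self):
        errors = []
        for dt in (40.0, 20.0, 10.0):
            mget = mean_gastric_emptying_time(
                exponential_retention(k=0.01, t_max=720.0, dt=dt)
            )
            errors.append(abs(mget - 100.0))
        assert errors[0] > errors[1] > errors[2]

    def test_time_rescaling_scales_the_moment(self):
        r = exponential_retention(k=0.01, t_max=700.0)
        stretched = RetentionCurve(2.0 * r.times, r.fraction_remaining)
        assert mean_gastric_emptying_time(stretched) == pytest.approx(
            2.0 * mean_gastric_emptying_time(r), rel=1e-12
        )

    @given(
        drops=st.lists(st.floats(0.0, 1.0), min_size=3, max_size=40),
    )
    @settings(deadline=None, max_examples=80)
    def test_area_form_equals_rate_weighted_form(self, drops):
        # random fully-decaying monotone curve on a uniform grid
        drops = np.asarray(drops)
        total = drops.sum()
        if total == 0:
            drops = drops + 1.0
            total = drops.sum()
        r = 1.0 - np.cumsum(drops) / total  # R_0 would be 1, R_end = 0
        r = np.concatenate(([1.0], r))
        t = 10.0 * np.arange(r.size)
        curve = RetentionCurve(t, r)
        area = mean_gastric_emptying_time(curve)
        rate = mget_rate_weighted(curve)
        assert area == pytest.approx(rate, abs=1e-9)


class TestMCAT:
    def test_single_jump_at_interval_midpoint(self):
        t = np.arange(0.0, 420.0 + 1e-9, 10.0)
        c = (t >= 210.0).astype(float)
        assert mean_cecum_arrival_time(ArrivalCurve(t, c)) == pytest.approx(
            205.0, abs=1e-9
        )

    def test_exponential_arrival_matches_1_over_k(self):
        mcat = mean_cecum_arrival_time(exponential_arrival(k=0.01))
        assert mcat == pytest.approx(100.0, rel=0.01)

    def test_unreached_plateau_warns_censored(self):
        # max before the end (noise-like overshoot): final value below 1-eps
        t = np.arange(0.0, 60.0 + 1e-9, 10.0)
        curve = ArrivalCurve(t, [0.0, 0.2, 0.5, 1.0, 0.96, 0.9, 0.9])
        with pytest.warns(CensoredPlateauWarning):
            mean_cecum_arrival_time(curve)

    def test_truncating_unplateaued_tail_decreases_mcat(self, chain4_recording):
        # right-censoring bias: cutting the record earlier shrinks MCAT
        from gitransit import normalize_cecal

        _, (_, cecum) = chain4_recording
        full = mean_cecum_arrival_time(normalize_cecal(cecum))
        estimates = []
        for cut in (50, 40):  # keep first `cut` samples only
            truncated = make_signal(cecum.times[:cut],
                                    cecum.intensities[:cut],
                                    site=Site.CECUM)
            estimates.append(
                mean_cecum_arrival_time(normalize_cecal(truncated))
            )
        assert estimates[0] < full
        assert estimates[1] < estimates[0]


class TestMSITT:
    @pytest.mark.parametrize(
        "mget, mcat, expected",
        [(119.0, 209.0, 90.0), (203.0, 334.0, 131.0), (77.0, 77.0, 0.0)],
    )
    def test_difference(self, mget, mcat, expected):
        assert small_intestinal_transit_time(mget, mcat) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            small_intestinal_transit_time(float("nan"), 100.0)


class TestT50:
    def test_exact_sample_hit(self):
        r = RetentionCurve(np.arange(0, 50, 10.0), [1, 0.75, 0.5, 0.25, 0])
        assert t50(r) == pytest.approx(20.0)

    def test_linear_interpolation_between_samples(self):
        r = RetentionCurve(np.arange(0, 50, 10.0), [1, 0.6, 0.4, 0.2, 0])
        assert t50(r) == pytest.approx(15.0)

    def test_exponential_half_life(self):
        r = exponential_retention(k=0.01)
        assert abs(t50(r) - math.log(2) / 0.01) < 1.0

    def test_never_crossing_raises(self):
        r = RetentionCurve(np.arange(0, 50, 10.0), [1, 0.9, 0.8, 0.7, 0.6])
        with pytest.raises(IncompleteEmptyingError):
            t50(r)


class TestAnalyzeRecording:
    def test_constant_stomach_is_degenerate(self):
        t = np.arange(0, 60, 10.0)
        stomach = make_signal(t, [5.0] * 6)
        cecum = make_signal(t, [0, 0, 1, 2, 3, 3], site=Site.CECUM)
        with pytest.raises(DegenerateRecordingError):
            analyze_recording(stomach, cecum)

    def test_solid_regime_recovers_power_exponential_mean(self):
        from gitransit import NoiseParams, TransitModelParams, simulate_recording

        params = TransitModelParams(meal=Meal.SOLID, k=0.01, beta=2.0,
                                    n_compartments=4, k_t=0.05,
                                    duration_min=700.0)
        stomach, cecum = simulate_recording(
            params, noise=NoiseParams(sigma_fraction=0.0)
        )
        times = analyze_recording(stomach, cecum,
                                  gastric_baseline_mode="zero")
        assert times.mget == pytest.approx(math.gamma(1.5) / 0.01, rel=0.01)

    def test_warnings_attached_to_result(self):
        t = np.arange(0, 200.0 + 1e-9, 10.0)
        stomach = make_signal(t, np.exp(-0.01 * t))
        cecum = make_signal(t, 1 - np.exp(-0.005 * t), site=Site.CECUM)
        with pytest.warns(IncompleteEmptyingWarning):
            result = analyze_recording(stomach, cecum,
                                       gastric_baseline_mode="zero")
        assert any("truncated" in w or "censored" in w
                   for w in result.warnings)
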