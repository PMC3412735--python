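"""Compartmental transit simulator and gradiometric sensor model."""

import numpy as np
import pytest

from gitransit import (
    Meal,
    NoiseParams,
    SensorParams,
    TransitModelParams,
    liquid_like,
    sensor_response,
    simulate_compartments,
    simulate_recording,
    simulate_validation_study,
    solid_like,
)
from gitransit.simulator import draw_animal_params, tracer_front_distance

NOISELESS = NoiseParams(sigma_fraction=0.0)


@pytest.mark.parametrize(
    "params",
    [
        liquid_like(),
        solid_like(),
        TransitModelParams(meal=Meal.SOLID, k=0.01, beta=3.0,
                           n_compartments=2, k_t=0.02),
        liquid_like(k_e=0.05, n_compartments=15, k_t=0.3),
    ],
    ids=["liquid", "solid", "steep-solid", "fast-liquid"],
)
def test_mass_is_conserved(params):
    t = np.arange(0.0, params.duration_min + 1e-9, params.dt_sample_min)
    traj = simulate_compartments(params, t)
    np.testing.assert_allclose(traj.total, params.m0, rtol=1e-6)
    assert np.all(traj.masses >= -1e-12)


def test_liquid_stomach_matches_closed_form():
    params = liquid_like()
    t = np.arange(0.0, 420.0 + 1e-9, 10.0)
    traj = simulate_compartments(params, t)
    np.testing.assert_allclose(traj.stomach, np.exp(-0.01 * t), atol=1e-6)


def test_solid_stomach_matches_power_exponential():
    params = TransitModelParams(meal=Meal.SOLID, k=0.01, beta=2.0)
    t = np.arange(0.0, 420.0 + 1e-9, 10.0)
    traj = simulate_compartments(params, t)
    np.testing.assert_allclose(traj.stomach, np.exp(-((0.01 * t) ** 2)),
                               atol=1e-6)


def test_vanishing_emptying_rate_keeps_meal_gastric():
    params = liquid_like(k_e=1e-9)
    t = np.arange(0.0, 420.0 + 1e-9, 10.0)
    traj = simulate_compartments(params, t)
    np.testing.assert_allclose(traj.stomach, 1.0, atol=1e-6)
    assert np.all(traj.cecum < 1e-6)


def test_chain_mean_arrival_time_is_additive():
    # mean residence times add: 1/k_e + N/k_t = 100 + 80 = 180 min
    params = liquid_like(n_compartments=4, k_t=0.05, duration_min=3000.0)
    t = np.arange(0.0, 3000.0 + 1e-9, 1.0)
    traj = simulate_compartments(params, t)
    plateau = traj.cecum[-1]
    assert plateau == pytest.approx(1.0, abs=1e-3)
    mcat = np.trapezoid(1.0 - traj.cecum / plateau, t)
    assert mcat == pytest.approx(180.0, rel=0.01)


class TestSensorResponse:
    def test_hand_computed_value(self):
        sensor = SensorParams(gain=1.0, exponent_p=3.0, baseline_cm=15.0)
        value = sensor_response(1.0, 3.0, sensor)
        assert value == pytest.approx(1.0 / 27.0 - 1.0 / 5832.0, rel=1e-6)
        assert value == pytest.approx(0.036866, abs=5e-7)

    def test_linear_in_mass(self):
        assert sensor_response(0.0, 2.0) == 0.0
        assert sensor_response(3.0, 2.0) == pytest.approx(
            3.0 * sensor_response(1.0, 2.0)
        )

    @pytest.mark.parametrize("p", [1.0, 3.0, 6.0])
    def test_strictly_decreasing_in_distance(self, p):
        sensor = SensorParams(exponent_p=p)
        d = np.linspace(1.0, 30.0, 50)
        resp = sensor_response(1.0, d, sensor)
        assert np.all(np.diff(resp) < 0)

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(ValueError):
            sensor_response(1.0, 0.0)


class TestSimulateRecording:
    def test_noiseless_signal_proportional_to_stomach_mass(self):
        params = liquid_like()
        stomach, _ = simulate_recording(params, noise=NOISELESS)
        traj = simulate_compartments(params, stomach.times)
        ratio = stomach.intensities / traj.stomach
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_same_seed_is_deterministic(self):
        noise = NoiseParams(sigma_fraction=0.02, seed=42)
        a = simulate_recording(liquid_like(), noise=noise)
        b = simulate_recording(liquid_like(), noise=noise)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.intensities, y.intensities)

    def test_crosstalk_matrix_adds_visible_compartments(self):
        params = liquid_like(n_compartments=2)
        # cecum sensor also sees the last SI compartment at 5 cm
        ct = np.full((2, 4), np.inf)
        ct[0, 0] = 2.0
        ct[1, 3] = 2.0
        ct[1, 2] = 5.0
        sensor = SensorParams(crosstalk_cm=ct)
        _, cecum_ct = simulate_recording(params, sensor, NOISELESS)
        _, cecum_plain = simulate_recording(params, SensorParams(), NOISELESS)
        assert np.all(cecum_ct.intensities >= cecum_plain.intensities)
        assert np.any(cecum_ct.intensities > cecum_plain.intensities)


class TestPopulationDraws:
    def test_zero_cv_returns_params_unchanged(self):
        rng = np.random.default_rng(0)
        params = solid_like()
        assert draw_animal_params(params, rng, 0.0) is params

    def test_lognormal_mean_is_preserved(self):
        rng = np.random.default_rng(1)
        params = liquid_like()
        draws = [draw_animal_params(params, rng, 0.15).k_e
                 for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(params.k_e, rel=0.02)
        cv = np.std(draws) / np.mean(draws)
        assert cv == pytest.approx(0.15, rel=0.1)


class TestValidationStudy:
    def test_default_study_has_18_records(self):
        records = simulate_validation_study(seed=0)
        assert len(records) == 18
        assert sorted({r.kill_time_min for r in records}) == [
            10, 20, 30, 40, 50, 60
        ]

    def test_noiseless_homogeneous_distance_monotone_in_kill_time(self):
        records = simulate_validation_study(
            noise=NOISELESS, population_cv=0.0, n_per_timepoint=1, seed=0
        )
        distances = [r.distance_cm for r in records]
        assert distances == sorted(distances)

    def test_same_seed_is_deterministic(self):
        a = simulate_validation_study(seed=5)
        b = simulate_validation_study(seed=5)
        assert a == b

    def test_front_distance_thresholds(self):
        # nothing in the SI -> 0; cecum loaded -> full length
        masses = np.array([0.9, 0.005, 0.0, 0.0, 0.0, 0.0])
        assert tracer_front_distance(masses, 4) == 0.0
        masses = np.array([0.2, 0.1, 0.02, 0.005, 0.0, 0.0])
        assert tracer_front_distance(masses, 4) == pytest.approx(50.0)
        masses = np.array([0.1, 0.1, 0.1, 0.1, 0.1, 0.5])
        assert tracer_front_distance(masses, 4) == pytest.approx(100.0)
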