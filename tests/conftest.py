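import numpy as np
import pytest

from gitransit import (
    ArrivalCurve,
    Meal,
    NoiseParams,
    RetentionCurve,
    SignalCurve,
    Site,
    liquid_like,
    simulate_recording,
)

NOISELESS = NoiseParams(sigma_fraction=0.0)


def exponential_retention(k=0.01, t_max=700.0, dt=10.0) -> RetentionCurve:
    t = np.arange(0.0, t_max + 1e-9, dt)
    return RetentionCurve(t, np.exp(-k * t))


def exponential_arrival(k=0.01, t_max=700.0, dt=10.0) -> ArrivalCurve:
    t = np.arange(0.0, t_max + 1e-9, dt)
    c = 1.0 - np.exp(-k * t)
    return ArrivalCurve(t, c / c.max())


def make_signal(times, values, site=Site.STOMACH, meal=Meal.LIQUID,
                animal_id="test") -> SignalCurve:
    return SignalCurve(np.asarray(times, float), np.asarray(values, float),
                       site, meal, animal_id)


@pytest.fixture(scope="session")
def noiseless_liquid_recording():
    """Noiseless default liquid simulation, shared across tests."""
    return simulate_recording(liquid_like(), noise=NOISELESS)


@pytest.fixture(scope="session")
def chain4_recording():
    """Noiseless liquid run of the slow 4-compartment chain, 700 min.

    k_e = 0.01, N = 4, k_t = 0.05: analytic means are MGET = 100,
    MCAT = 100 + 4/0.05 = 180.
    """
    params = liquid_like(n_compartments=4, k_t=0.05, duration_min=700.0)
    return params, simulate_recording(params, noise=NOISELESS)
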