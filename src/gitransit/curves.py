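"""Data model for two-site biomagnetic transit recordings.

A transit study records the magnetic signal intensity (mV) over the
gastric and cecal projections of the abdomen at regular 10-min intervals
after the animal ingests a magnetic test meal.  The raw mV traces carry
arbitrary gain and baseline; analysis works on dimensionless curves:

* the gastric **retention curve** R(t) — fraction of the meal still in the
  stomach, normalized so R = 1 at ingestion and R -> 0 once emptying
  completes;
* the cecal **arrival curve** C(t) — cumulative fraction of the meal that
  has reached the cecum, normalized by its plateau so C -> 1.

This module defines the containers and the baseline-correction /
normalization steps that produce those curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .exceptions import (
    BaselineWarning,
    DegenerateRecordingError,
    InvertedCurveError,
    NegativeTransitWarning,
    NoArrivalError,
)

__all__ = [
    "Site",
    "Meal",
    "SignalCurve",
    "RetentionCurve",
    "ArrivalCurve",
    "TransitTimes",
    "normalize_gastric",
    "normalize_cecal",
    "isotonic_regression",
]


class Site(str, Enum):
    """Abdominal projection over which the sensor is positioned."""

    STOMACH = "stomach"
    CECUM = "cecum"


class Meal(str, Enum):
    """Test-meal regime: liquid ferrofluid or solid ferrite pellet."""

    LIQUID = "liquid"
    SOLID = "solid"


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    return arr


@dataclass(frozen=True)
class SignalCurve:
    """One site's raw intensity-time recording.

    Parameters
    ----------
    times : array-like
        Minutes since meal ingestion; non-negative, strictly increasing,
        nominally on a uniform 10-min grid.
    intensities : array-like
        Magnetic signal in mV; finite reals.
    site : Site
        Which projection the sensor was over.
    meal : Meal
        Meal regime of the session.
    animal_id : str
        Opaque animal label.
    """

    times: np.ndarray
    intensities: np.ndarray
    site: Site
    meal: Meal
    animal_id: str = "unknown"

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        intensities = _as_float_array(self.intensities, "intensities")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "intensities", intensities)
        object.__setattr__(self, "site", Site(self.site))
        object.__setattr__(self, "meal", Meal(self.meal))
        if times.size != intensities.size:
            raise ValueError("times and intensities must have equal length")
        if times.size < 4:
            raise ValueError("a recording needs at least 4 samples")
        if times[0] < 0:
            raise ValueError("times must be non-negative")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(intensities)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class RetentionCurve:
    """Normalized gastric retention fraction R(t), R(t0) = 1."""

    times: np.ndarray
    fraction_remaining: np.ndarray
    animal_id: str = "unknown"
    meal: Meal = Meal.LIQUID

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        frac = _as_float_array(self.fraction_remaining, "fraction_remaining")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fraction_remaining", frac)
        object.__setattr__(self, "meal", Meal(self.meal))
        if times.size != frac.size:
            raise ValueError("times and fractions must have equal length")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if abs(frac[0] - 1.0) > 1e-9:
            raise ValueError(
                "retention curve must start at 1 (got %r); normalize first"
                % frac[0]
            )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class ArrivalCurve:
    """Normalized cumulative cecal arrival fraction C(t), max = 1."""

    times: np.ndarray
    fraction_arrived: np.ndarray
    animal_id: str = "unknown"
    meal: Meal = Meal.LIQUID

    def __post_init__(self):
        times = _as_float_array(self.times, "times")
        frac = _as_float_array(self.fraction_arrived, "fraction_arrived")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "fraction_arrived", frac)
        object.__setattr__(self, "meal", Meal(self.meal))
        if times.size != frac.size:
            raise ValueError("times and fractions must have equal length")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if abs(float(np.max(frac)) - 1.0) > 1e-9:
            raise ValueError("arrival curve must attain 1; normalize first")
        if np.min(frac) < -1e-9 or np.max(frac) > 1 + 1e-9:
            raise ValueError("arrival fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class TransitTimes:
    """Per-animal transit summary: MGET, MCAT and MSITT in minutes.

    MSITT is defined as MCAT - MGET and the identity is enforced exactly
    at construction.  A negative MSITT is representable (inconsistent
    curves can produce it) but emits :class:`NegativeTransitWarning`.
    """

    mget: float
    mcat: float
    msitt: float
    warnings: tuple[str, ...] = field(default=())

    def __post_init__(self):
        if not (np.isfinite(self.mget) and np.isfinite(self.mcat)):
            raise ValueError("MGET and MCAT must be finite")
        if self.mget <= 0 or self.mcat <= 0:
            raise ValueError("MGET and MCAT must be positive")
        if self.msitt != self.mcat - self.mget:
            raise ValueError("MSITT must equal MCAT - MGET exactly")

    @classmethod
    def from_mget_mcat(
        cls, mget: float, mcat: float, warnings_: tuple[str, ...] = ()
    ) -> "TransitTimes":
        msitt = mcat - mget
        if msitt < 0:
            warnings.warn(
                "MCAT < MGET: gastric and cecal curves are inconsistent",
                NegativeTransitWarning,
                stacklevel=2,
            )
        return cls(mget=float(mget), mcat=float(mcat), msitt=float(msitt),
                   warnings=warnings_)


def isotonic_regression(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators fit of a non-decreasing sequence to ``y``.

    Unit weights; returns the least-squares monotone sequence.  Used as an
    optional smoother for noisy cumulative arrival signals.
    """
    y = np.asarray(y, dtype=float)
    level = y.copy()
    weight = np.ones_like(level)
    # blocks stored compactly at the front of level/weight
    n_blocks = 0
    for value in y:
        level[n_blocks] = value
        weight[n_blocks] = 1.0
        n_blocks += 1
        while n_blocks > 1 and level[n_blocks - 2] > level[n_blocks - 1]:
            w = weight[n_blocks - 2] + weight[n_blocks - 1]
            level[n_blocks - 2] = (
                weight[n_blocks - 2] * level[n_blocks - 2]
                + weight[n_blocks - 1] * level[n_blocks - 1]
            ) / w
            weight[n_blocks - 2] = w
            n_blocks -= 1
    return np.repeat(level[:n_blocks], weight[:n_blocks].astype(int))


def normalize_gastric(
    curve: SignalCurve,
    baseline_mode: str = "tail",
    tail_samples: int = 3,
) -> RetentionCurve:
    """Turn a raw gastric signal into a retention curve.

    The baseline (residual signal once the stomach is empty) is estimated
    as the mean of the last ``tail_samples`` samples (``baseline_mode =
    "tail"``, the default — assumes emptying completed within the >=7-h
    record) or fixed at zero (``baseline_mode = "zero"``).  The curve is
    then rescaled affinely so the first sample maps to 1 and the baseline
    to 0:  R(t_i) = (S(t_i) - b) / (S(t_0) - b).

    Values below -0.1 after normalization indicate a bad baseline and emit
    :class:`BaselineWarning`; all values are floored at -0.1.
    """
    if curve.site is not Site.STOMACH:
        raise ValueError("normalize_gastric expects a stomach-site curve")
    s = curve.intensities
    if np.ptp(s) == 0:
        raise DegenerateRecordingError(
            "gastric signal has zero dynamic range (degenerate recording)"
        )
    if baseline_mode == "tail":
        b = float(np.mean(s[-tail_samples:]))
    elif baseline_mode == "zero":
        b = 0.0
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    if s[0] <= b:
        raise InvertedCurveError(
            "first gastric sample does not exceed the baseline "
            f"(S0={s[0]:g}, b={b:g}): inverted or empty curve"
        )
    r = (s - b) / (s[0] - b)
    if np.min(r) < -0.1:
        warnings.warn(
            "retention values below -0.1 after normalization: baseline "
            "estimate is likely wrong",
            BaselineWarning,
            stacklevel=2,
        )
    r = np.maximum(r, -0.1)
    r[0] = 1.0
    return RetentionCurve(curve.times, r, animal_id=curve.animal_id,
                          meal=curve.meal)


def normalize_cecal(
    curve: SignalCurve,
    baseline_mode: str = "head",
    head_samples: int = 2,
    isotonic: bool = False,
) -> ArrivalCurve:
    """Turn a raw cecal signal into a cumulative arrival curve.

    The pre-arrival baseline is the mean of the first ``head_samples``
    samples (``baseline_mode = "head"``, the default — no tracer can be at
    the cecum 5-10 min after ingestion) or zero.  The baseline-corrected
    signal is divided by its maximum C_max and clipped to [0, 1].  With
    ``isotonic=True`` a pool-adjacent-violators fit makes the curve
    monotone before normalization.
    """
    if curve.site is not Site.CECUM:
        raise ValueError("normalize_cecal expects a cecum-site curve")
    s = curve.intensities.astype(float)
    if baseline_mode == "head":
        b = float(np.mean(s[:head_samples]))
    elif baseline_mode == "zero":
        b = 0.0
    else:
        raise ValueError(f"unknown baseline_mode {baseline_mode!r}")
    corrected = s - b
    if isotonic:
        corrected = isotonic_regression(corrected)
    c_max = float(np.max(corrected))
    if c_max <= 0:
        raise NoArrivalError(
            "cecal signal never rises above baseline: no detectable arrival"
        )
    c = np.clip(corrected / c_max, 0.0, 1.0)
    return ArrivalCurve(curve.times, c, animal_id=curve.animal_id,
                        meal=curve.meal)
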