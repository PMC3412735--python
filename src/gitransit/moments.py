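"""Statistical-moment estimation of gastrointestinal transit times.

The transit summaries are the first moments of the underlying rate
distributions, computed as areas:

* ``MGET = ∫ R(t) dt`` — the mean gastric emptying time is the area under
  the normalized retention curve.  When emptying completes (R -> 0) this
  equals the mean of the emptying-rate distribution -dR/dt, i.e. the mean
  residence time of the meal in the stomach.
* ``MCAT = ∫ (1 - C(t)) dt`` — the mean cecum arrival time is the area
  between the normalized cumulative arrival curve and its plateau.
* ``MSITT = MCAT - MGET`` — the mean small-intestinal transit time.

Integration is trapezoidal on the native sample grid (nominally 10-min
spacing).  The meal is entirely gastric at ingestion, so R = 1 and C = 0
are assumed on [0, t_first] when the first sample is after t = 0.

The area form is exactly equivalent (summation by parts) to the
rate-weighted average ``Σ t_mid (R_i - R_{i+1}) / (R_0 - R_end)`` when the
curve decays fully; :func:`mget_rate_weighted` exposes that second form so
the identity can be checked independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .curves import ArrivalCurve, RetentionCurve, SignalCurve, TransitTimes
from .curves import normalize_cecal, normalize_gastric
from .exceptions import (
    CensoredPlateauWarning,
    IncompleteEmptyingError,
    IncompleteEmptyingWarning,
    QualityWarning,
)

__all__ = [
    "MomentConfig",
    "mean_gastric_emptying_time",
    "mean_cecum_arrival_time",
    "small_intestinal_transit_time",
    "mget_rate_weighted",
    "t50",
    "analyze_recording",
]

TAIL_POLICIES = ("truncate_warn", "exponential_extrapolate")


@dataclass(frozen=True)
class MomentConfig:
    """Knobs of the moment estimators.

    tail_policy
        What to do when the retention curve has not decayed to the plateau
        tolerance by the end of the record: ``"truncate_warn"`` (default)
        integrates what is there and warns; ``"exponential_extrapolate"``
        fits a mono-exponential to the last 5 samples and adds its
        analytic tail area (out to 5 time constants).
    plateau_epsilon
        Tolerance for "emptying complete" (final R <= eps) and "plateau
        reached" (final C >= 1 - eps).  Default 0.02.

    Integration is always trapezoidal on the sample grid.
    """

    tail_policy: str = "truncate_warn"
    plateau_epsilon: float = 0.02

    def __post_init__(self):
        if self.tail_policy not in TAIL_POLICIES:
            raise ValueError(
                f"tail_policy must be one of {TAIL_POLICIES}, "
                f"got {self.tail_policy!r}"
            )
        if not 0 < self.plateau_epsilon < 0.5:
            raise ValueError("plateau_epsilon must be in (0, 0.5)")


def _with_origin(times: np.ndarray, values: np.ndarray,
                 origin_value: float) -> tuple[np.ndarray, np.ndarray]:
    """Prepend (0, origin_value) when the first sample is after t=0."""
    if times[0] > 0:
        times = np.concatenate(([0.0], times))
        values = np.concatenate(([origin_value], values))
    return times, values


def _exponential_tail_area(times: np.ndarray, values: np.ndarray,
                           n_fit: int = 5) -> float:
    """Area of a mono-exponential tail fitted to the last ``n_fit`` samples.

    Log-linear least squares on the strictly positive tail samples;
    returns the analytic area from t_end out to 5 time constants,
    anchored at the last observed value for continuity.  Returns 0.0 (with
    a warning) when the tail is not usable (non-positive or non-decaying).
    """
    t = times[-n_fit:]
    v = values[-n_fit:]
    mask = v > 0
    if mask.sum() < 2:
        warnings.warn(
            "tail extrapolation skipped: too few positive tail samples",
            IncompleteEmptyingWarning, stacklevel=3,
        )
        return 0.0
    slope, _ = np.polyfit(t[mask], np.log(v[mask]), 1)
    if slope >= 0:
        warnings.warn(
            "tail extrapolation skipped: tail is not decaying",
            IncompleteEmptyingWarning, stacklevel=3,
        )
        return 0.0
    lam = -slope
    # ∫_{t_end}^{t_end + 5/λ} v_end e^{-λ(t - t_end)} dt
    return float(values[-1] / lam * (1.0 - np.exp(-5.0)))


def mean_gastric_emptying_time(
    retention: RetentionCurve, config: MomentConfig | None = None
) -> float:
    """MGET in minutes: area under the retention curve.

    Negative excursions (noise around the empty-stomach baseline) are
    floored at zero for integration.  If the final retention exceeds
    ``plateau_epsilon`` the record is incomplete: the default policy
    truncates and warns, the alternative adds a fitted exponential tail.
    """
    config = config or MomentConfig()
    t, r = _with_origin(retention.times, retention.fraction_remaining, 1.0)
    r = np.clip(r, 0.0, None)
    area = float(np.trapezoid(r, t))
    if retention.fraction_remaining[-1] > config.plateau_epsilon:
        if config.tail_policy == "exponential_extrapolate":
            area += _exponential_tail_area(t, r)
        else:
            warnings.warn(
                "emptying incomplete at end of record "
                f"(final retention {retention.fraction_remaining[-1]:.3f} > "
                f"{config.plateau_epsilon}); MGET is truncated",
                IncompleteEmptyingWarning, stacklevel=2,
            )
    return area


def mget_rate_weighted(retention: RetentionCurve) -> float:
    """MGET as the interval-midpoint average weighted by emptied fraction.

    ``Σ t_mid,i (R_i - R_{i+1}) / (R_0 - R_end)``, the discrete first
    moment of the emptying-rate distribution.  Algebraically identical to
    the trapezoidal area when the curve decays fully (R_end = 0); exposed
    for testing the duality, not used by the pipeline.
    """
    t, r = _with_origin(retention.times, retention.fraction_remaining, 1.0)
    drops = r[:-1] - r[1:]
    mids = 0.5 * (t[:-1] + t[1:])
    total = r[0] - r[-1]
    if total == 0:
        raise ZeroDivisionError("flat retention curve has no emptied mass")
    return float(np.sum(mids * drops) / total)


def mean_cecum_arrival_time(
    arrival: ArrivalCurve, config: MomentConfig | None = None
) -> float:
    """MCAT in minutes: area between the arrival curve and its plateau.

    Equals the first moment of the arrival-rate distribution once the
    plateau is reached.  If the final value is below ``1 -
    plateau_epsilon`` the arrival is right-censored: the estimate is
    returned but is biased low, and :class:`CensoredPlateauWarning` says so.
    """
    config = config or MomentConfig()
    t, c = _with_origin(arrival.times, arrival.fraction_arrived, 0.0)
    if arrival.fraction_arrived[-1] < 1.0 - config.plateau_epsilon:
        warnings.warn(
            "arrival plateau not reached (final value "
            f"{arrival.fraction_arrived[-1]:.3f} < "
            f"{1 - config.plateau_epsilon:.3f}); MCAT is right-censored "
            "and biased low",
            CensoredPlateauWarning, stacklevel=2,
        )
    return float(np.trapezoid(1.0 - c, t))


def small_intestinal_transit_time(mget: float, mcat: float) -> float:
    """MSITT = MCAT - MGET, in minutes.

    May come out negative when the two curves are inconsistent; that is
    reported (with a warning at :class:`TransitTimes` construction), not
    hidden.
    """
    if not (np.isfinite(mget) and np.isfinite(mcat)):
        raise ValueError("MGET and MCAT must be finite")
    return float(mcat - mget)


def t50(retention: RetentionCurve) -> float:
    """Half-emptying time: first crossing of R = 0.5, linearly interpolated.

    A legacy summary tied to the pure-exponential emptying model; provided
    for comparison with the moment-based MGET, which uses the whole curve.
    """
    t = retention.times
    r = retention.fraction_remaining
    below = np.nonzero(r <= 0.5)[0]
    if below.size == 0:
        raise IncompleteEmptyingError(
            "retention never falls to 0.5: incomplete emptying for t50"
        )
    i = int(below[0])
    if r[i] == 0.5 or i == 0:
        return float(t[i])
    # linear interpolation between the bracketing samples
    frac = (r[i - 1] - 0.5) / (r[i - 1] - r[i])
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def analyze_recording(
    stomach: SignalCurve,
    cecum: SignalCurve,
    config: MomentConfig | None = None,
    gastric_baseline_mode: str = "tail",
    cecal_baseline_mode: str = "head",
    isotonic: bool = False,
) -> TransitTimes:
    """Full moment analysis of one animal/meal recording pair.

    Normalizes both site signals, integrates the moments and returns
    :class:`TransitTimes` with any quality warnings attached as strings.
    """
    config = config or MomentConfig()
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", QualityWarning)
        retention = normalize_gastric(stomach, baseline_mode=gastric_baseline_mode)
        arrival = normalize_cecal(cecum, baseline_mode=cecal_baseline_mode,
                                  isotonic=isotonic)
        mget = mean_gastric_emptying_time(retention, config)
        mcat = mean_cecum_arrival_time(arrival, config)
        result = TransitTimes.from_mget_mcat(mget, mcat)
        quality = [(w.category, str(w.message)) for w in caught
                   if issubclass(w.category, QualityWarning)]
    for category, message in quality:  # re-emit for callers' filters
        warnings.warn(message, category, stacklevel=2)
    return TransitTimes(result.mget, result.mcat, result.msitt,
                        warnings=tuple(m for _, m in quality))
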