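"""Study-level modelling interface.

:class:`TransitStudy` collects the two-site recordings of a cohort (read
from CSV, passed in directly, or simulated) and ``fit()`` runs the
statistical-moment analysis on every recording, returning a
:class:`TransitStudyResults` that carries the per-animal transit times,
group summaries, paired liquid-vs-solid contrasts and a printable
summary table.

Example
-------
>>> from gitransit import TransitStudy
>>> study = TransitStudy.from_simulation(n_animals=6, seed=7)
>>> res = study.fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import Meal, SignalCurve
from .exceptions import IncompleteEmptyingError
from .moments import MomentConfig, analyze_recording, normalize_gastric, t50
from .simulator import (
    NoiseParams,
    SensorParams,
    TransitModelParams,
    liquid_like,
    simulate_cohort,
    solid_like,
)
from .stats import GroupSummary, PairedTestResult, paired_t_test, summarize

__all__ = ["TransitStudy", "TransitStudyResults"]

RESULT_COLUMNS = ["animal_id", "meal", "mget_min", "mcat_min", "msitt_min",
                  "t50_min", "warnings"]


class TransitStudy:
    """A cohort of two-site transit recordings ready for moment analysis.

    Parameters
    ----------
    recordings : sequence of (SignalCurve, SignalCurve)
        (stomach, cecum) pairs, one per animal/meal session.
    config : MomentConfig, optional
        Moment-estimator settings shared by all recordings.
    """

    def __init__(self, recordings, config: MomentConfig | None = None,
                 isotonic: bool = False):
        recordings = list(recordings)
        if not recordings:
            raise ValueError("a study needs at least one recording")
        for stomach, cecum in recordings:
            if not isinstance(stomach, SignalCurve) or not isinstance(
                    cecum, SignalCurve):
                raise TypeError("recordings must be SignalCurve pairs")
        self.recordings = recordings
        self.config = config or MomentConfig()
        self.isotonic = isotonic

    @classmethod
    def from_csv(cls, paths, config: MomentConfig | None = None,
                 isotonic: bool = False) -> "TransitStudy":
        """Build a study from recording CSV files (one per session)."""
        from .io import read_recording

        return cls([read_recording(p) for p in paths], config=config,
                   isotonic=isotonic)

    @classmethod
    def from_simulation(
        cls,
        n_animals: int = 6,
        meals=(Meal.LIQUID, Meal.SOLID),
        liquid_params: TransitModelParams | None = None,
        solid_params: TransitModelParams | None = None,
        sensor: SensorParams | None = None,
        noise: NoiseParams | None = None,
        population_cv: float = 0.15,
        seed: int | None = None,
        config: MomentConfig | None = None,
    ) -> "TransitStudy":
        """Simulate a paired-design cohort (each animal, both meals).

        A single seeded generator drives parameter draws and noise, so
        the study is reproducible from ``seed`` alone.
        """
        liquid_params = liquid_params or liquid_like()
        solid_params = solid_params or solid_like()
        rng = np.random.default_rng(seed)
        recordings = []
        for meal in meals:
            meal = Meal(meal)
            params = liquid_params if meal is Meal.LIQUID else solid_params
            recordings.extend(simulate_cohort(
                n_animals, params, sensor=sensor, noise=noise,
                population_cv=population_cv,
                seed=int(rng.integers(0, 2 ** 31 - 1)),
            ))
        return cls(recordings, config=config)

    def fit(self) -> "TransitStudyResults":
        """Run the moment analysis on every recording."""
        rows = []
        for stomach, cecum in self.recordings:
            times = analyze_recording(
                stomach, cecum, self.config, isotonic=self.isotonic,
            )
            try:
                half = t50(normalize_gastric(stomach))
            except IncompleteEmptyingError:
                half = np.nan
            rows.append({
                "animal_id": stomach.animal_id,
                "meal": stomach.meal.value,
                "mget_min": times.mget,
                "mcat_min": times.mcat,
                "msitt_min": times.msitt,
                "t50_min": half,
                "warnings": "; ".join(times.warnings),
            })
        table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
        return TransitStudyResults(study=self, transit_table=table)


@dataclass
class TransitStudyResults:
    """Fitted transit times and the group statistics derived from them."""

    study: TransitStudy
    transit_table: pd.DataFrame

    _METRICS = ("mget_min", "mcat_min", "msitt_min")

    def group_summary(self, meal, metric: str = "mget_min") -> GroupSummary:
        """Mean ± SD of one metric within one meal group."""
        meal = Meal(meal).value
        values = self.transit_table.loc[
            self.transit_table["meal"] == meal, metric
        ].to_numpy()
        return summarize(values)

    def paired_test(self, metric: str = "mget_min") -> PairedTestResult:
        """Paired liquid-vs-solid t-test on one metric.

        Pairs rows by animal_id; every animal must appear once under each
        meal.
        """
        if metric not in self._METRICS:
            raise ValueError(f"metric must be one of {self._METRICS}")
        wide = self.transit_table.pivot(index="animal_id", columns="meal",
                                        values=metric)
        if wide.isna().any().any() or set(wide.columns) != {"liquid",
                                                            "solid"}:
            raise ValueError(
                "paired test needs every animal recorded under both meals"
            )
        return paired_t_test(wide["liquid"].to_numpy(),
                             wide["solid"].to_numpy())

    def summary(self) -> str:
        """Printable study report: per-animal table, group rows, contrasts."""
        lines = ["Gastrointestinal transit — statistical-moment analysis",
                 "=" * 55, ""]
        with pd.option_context("display.width", 100):
            lines.append(self.transit_table.to_string(index=False,
                                                      float_format="%.1f"))
        lines.append("")
        meals = sorted(self.transit_table["meal"].unique())
        for meal in meals:
            parts = []
            for metric in self._METRICS:
                values = self.transit_table.loc[
                    self.transit_table["meal"] == meal, metric
                ]
                if len(values) >= 2:
                    s = summarize(values.to_numpy())
                    parts.append(f"{metric[:-4].upper()} {s.mean:.1f} ± "
                                 f"{s.sd:.1f}")
            if parts:
                lines.append(f"{meal:>7}: " + "   ".join(parts) +
                             f"   (n={int((self.transit_table['meal'] == meal).sum())})")
        if set(meals) == {"liquid", "solid"}:
            try:
                lines.append("")
                lines.append("Paired liquid vs solid (two-sided):")
                for metric in self._METRICS:
                    res = self.paired_test(metric)
                    star = " *" if res.significant else ""
                    lines.append(
                        f"  {metric[:-4].upper():<6} t = {res.t_statistic:+.3f}, "
                        f"df = {res.df}, p = {res.p_value:.4f}{star}"
                    )
            except ValueError:
                lines.pop()  # unpaired design: drop the header again
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        """Write the per-animal results table as CSV."""
        self.transit_table.to_csv(path, index=False)

    def plot_curves(self, ax=None):
        """Plot normalized retention and arrival curves of the cohort.

        Requires matplotlib (the ``plot`` extra).
        """
        import matplotlib.pyplot as plt

        from .moments import normalize_cecal

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        for stomach, cecum in self.study.recordings:
            style = "-" if stomach.meal is Meal.LIQUID else "--"
            r = normalize_gastric(stomach)
            c = normalize_cecal(cecum)
            ax.plot(r.times, r.fraction_remaining, style, color="tab:blue",
                    alpha=0.5)
            ax.plot(c.times, c.fraction_arrived, style, color="tab:orange",
                    alpha=0.5)
        ax.set_xlabel("time since ingestion (min)")
        ax.set_ylabel("fraction")
        ax.set_title("gastric retention (blue) and cecal arrival (orange)")
        return ax
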