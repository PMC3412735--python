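"""Reading and writing recording and result files.

Recording CSV dialect (one file per animal/meal session)::

    # animal_id: rat1
    # meal: liquid
    time_min,stomach_mv,cecum_mv
    0,5.125,0.012
    10,4.871,0.031
    ...

Metadata lines are optional, ``#``-prefixed and above the header; columns
are comma-separated with decimal points, UTF-8.  Parse errors name the
offending 1-based line number.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np

from .curves import Meal, SignalCurve, Site
from .exceptions import RecordingParseError

__all__ = ["read_recording", "write_recording", "write_validation_records"]

_HEADER = ["time_min", "stomach_mv", "cecum_mv"]


def read_recording(path) -> tuple[SignalCurve, SignalCurve]:
    """Read one recording CSV into (stomach, cecum) signal curves."""
    path = Path(path)
    meta = {"animal_id": path.stem, "meal": "liquid"}
    times, stomach, cecum = [], [], []
    header_seen = False
    with path.open(newline="", encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if header_seen:
                    raise RecordingParseError(
                        "metadata lines must precede the header", lineno
                    )
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    meta[key.strip()] = value.strip()
                continue
            cells = next(csv.reader([line]))
            if not header_seen:
                if [c.strip() for c in cells] != _HEADER:
                    raise RecordingParseError(
                        f"expected header {','.join(_HEADER)!r}, got {line!r}",
                        lineno,
                    )
                header_seen = True
                continue
            if len(cells) != 3:
                raise RecordingParseError(
                    f"expected 3 columns, got {len(cells)}", lineno
                )
            try:
                row = [float(c) for c in cells]
            except ValueError:
                raise RecordingParseError(
                    f"non-numeric cell in {line!r}", lineno
                ) from None
            if times and row[0] <= times[-1]:
                raise RecordingParseError(
                    f"time {row[0]:g} does not increase past {times[-1]:g}",
                    lineno,
                )
            times.append(row[0])
            stomach.append(row[1])
            cecum.append(row[2])
    if not header_seen:
        raise RecordingParseError("no header line found")
    if len(times) < 4:
        raise RecordingParseError("recording has fewer than 4 samples")
    try:
        meal = Meal(meta["meal"])
    except ValueError:
        raise RecordingParseError(f"unknown meal {meta['meal']!r}") from None
    animal_id = meta["animal_id"]
    t = np.asarray(times)
    return (
        SignalCurve(t, np.asarray(stomach), Site.STOMACH, meal, animal_id),
        SignalCurve(t, np.asarray(cecum), Site.CECUM, meal, animal_id),
    )


def write_recording(path, stomach: SignalCurve, cecum: SignalCurve) -> None:
    """Write a (stomach, cecum) pair to the recording CSV dialect.

    Floats are written with repr-roundtrip precision so write -> read ->
    write is byte-identical.
    """
    if not np.array_equal(stomach.times, cecum.times):
        raise ValueError("stomach and cecum curves must share a time grid")
    if stomach.animal_id != cecum.animal_id or stomach.meal != cecum.meal:
        raise ValueError("curves must come from the same animal and meal")
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        handle.write(f"# animal_id: {stomach.animal_id}\n")
        handle.write(f"# meal: {stomach.meal.value}\n")
        handle.write(",".join(_HEADER) + "\n")
        for t, s, c in zip(stomach.times, stomach.intensities,
                           cecum.intensities):
            handle.write(f"{float(t)!r},{float(s)!r},{float(c)!r}\n")


def write_validation_records(path, records) -> None:
    """Write kill-and-measure records to CSV."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["animal_id", "kill_time_min", "gastric_intensity_mv",
                         "initial_intensity_mv", "distance_cm"])
        for rec in records:
            writer.writerow([rec.animal_id, rec.kill_time_min,
                             repr(rec.gastric_intensity_mv),
                             repr(rec.initial_intensity_mv),
                             rec.distance_cm])
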