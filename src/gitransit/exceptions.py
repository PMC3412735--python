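"""Errors and quality warnings raised across the package.

Errors signal inputs that cannot be analysed at all (degenerate or
malformed recordings); :class:`QualityWarning` subclasses flag recordings
that *can* be analysed but whose numbers a physiologist should treat with
suspicion (incomplete emptying, censored arrival plateau, suspicious
baseline). Warnings are collected into result tables rather than silenced.
"""


class TransitError(Exception):
    """Base class for all gitransit errors."""


class DegenerateRecordingError(TransitError):
    """Signal has zero dynamic range (all intensities equal)."""


class InvertedCurveError(TransitError):
    """First gastric sample does not exceed the estimated baseline."""


class NoArrivalError(TransitError):
    """Cecal signal never rises above its pre-arrival baseline."""


class NotNormalizedError(TransitError):
    """A curve handed to a moment estimator is not properly normalized."""


class IncompleteEmptyingError(TransitError):
    """Retention never crosses the level required by the estimator (t50)."""


class IntegrationError(TransitError):
    """The compartmental ODE integration produced non-finite state."""


class RecordingParseError(TransitError):
    """A recording CSV violates the expected dialect.

    Carries the 1-based line number of the offending line when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigError(TransitError):
    """A run configuration contains unknown keys or invalid values."""


class QualityWarning(UserWarning):
    """Base class for data-quality warnings attached to results."""


class IncompleteEmptyingWarning(QualityWarning):
    """Final retention above the plateau tolerance: MGET is truncated."""


class CensoredPlateauWarning(QualityWarning):
    """Arrival curve has not plateaued: MCAT is right-censored (biased low)."""


class BaselineWarning(QualityWarning):
    """Normalized values far below zero: the baseline estimate looks wrong."""


class NegativeTransitWarning(QualityWarning):
    """MCAT < MGET: the two sites give mutually inconsistent curves."""
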