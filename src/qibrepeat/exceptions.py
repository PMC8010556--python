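"""Exception hierarchy.

All package errors derive from :class:`QibrepeatError`; most are also
``ValueError`` subclasses so callers using generic handling keep working.
"""


class QibrepeatError(Exception):
    """Base class for all qibrepeat errors."""


class ConfigurationError(QibrepeatError, ValueError):
    """An invalid study/simulation configuration; the message names the field."""


class CompletenessError(QibrepeatError, ValueError):
    """A measurement table is missing required records; names the subjects."""


class GeometryError(QibrepeatError, ValueError):
    """A lesion does not fit inside the phantom grid."""


class DegenerateContourError(QibrepeatError, ValueError):
    """A simulated contour perturbation would produce an empty ROI."""


class EmptyRoiError(QibrepeatError, ValueError):
    """An ROI mask is empty or contains no valid pixels."""


class SampleSizeError(QibrepeatError, ValueError):
    """Too few subjects/observations for the requested statistic."""


class DegenerateDataError(QibrepeatError, ValueError):
    """Data without variability where a variance-based statistic is undefined."""
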