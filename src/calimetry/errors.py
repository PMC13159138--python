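"""Exception hierarchy for calimetry.

All library-specific failures derive from :class:`CalimetryError` so callers
can catch one base class at pipeline boundaries.
"""


class CalimetryError(Exception):
    """Base class for all calimetry errors."""


class FormatError(CalimetryError):
    """An on-disk array or mask is missing, ill-shaped, or unreadable."""


class LayoutError(CalimetryError):
    """The experiment layout (well naming, FOV discovery) is inconsistent."""


class ConfigError(CalimetryError):
    """A configuration file or plate map is invalid."""


class DataError(CalimetryError):
    """Input data contain non-finite or otherwise invalid values."""


class BaselineError(CalimetryError):
    """The fluorescence baseline is too low for a meaningful dF/F0."""


class EstimationError(CalimetryError):
    """A statistical estimate (noise, AR coefficient) cannot be formed."""


class EpochError(CalimetryError):
    """Too few frames selected for an epoch-restricted computation."""


class FitError(CalimetryError):
    """A model fit is underdetermined or degenerate."""


class GenerationError(CalimetryError):
    """Synthetic-data generation could not satisfy its constraints."""
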