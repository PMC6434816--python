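"""Exception hierarchy for the pearldecon pipeline.

Every stage raises a subclass of :class:`PearldeconError`, so callers (the
CLI in particular) can distinguish pipeline failures from programming errors
and report the failing stage.
"""


class PearldeconError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PearldeconError):
    """An invalid simulation or pipeline configuration value; names the field."""


class MetadataError(PearldeconError):
    """Sample metadata missing, inconsistent, or not matching the data."""


class VCFParseError(PearldeconError):
    """A variant file could not be parsed."""


class EstimationError(PearldeconError):
    """A rate or contamination estimate is undefined (e.g. zero reference depth)."""


class SelectionError(PearldeconError):
    """Gene-panel selection produced an empty result."""
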