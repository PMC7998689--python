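"""Exception hierarchy for surftens.

All user-facing errors derive from :class:`SurftensError` so callers (and the
CLI) can catch one base class and print an actionable message instead of a
traceback.
"""


class SurftensError(Exception):
    """Base class for all surftens errors."""


class SchemaError(SurftensError):
    """A tabular input is missing a required column or has a bad header."""


class ValidationError(SurftensError):
    """A row or record violates a physical invariant (e.g. T >= Tc)."""


class ParseError(SurftensError):
    """A field that should be numeric could not be parsed."""


class ConfigurationError(SurftensError):
    """Inconsistent run configuration (e.g. split fractions not summing to 1)."""


class DegenerateRangeError(SurftensError):
    """Normalization requested over a constant sequence."""


class CapabilityError(SurftensError):
    """A fluid lacks an input property a correlation requires."""


class TrainingError(SurftensError):
    """All optimizer restarts failed."""


class ModelFileError(SurftensError):
    """A serialized network file is malformed or has the wrong schema."""
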