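"""Exception hierarchy.

All package errors derive from :class:`RRSelError` so callers (and the CLI)
can distinguish anticipated analysis failures from genuine bugs.
"""


class RRSelError(Exception):
    """Base class for all rrsel errors."""

    category = "error"


class SchemaError(RRSelError):
    """Column-role mapping is inconsistent with the input file."""

    category = "schema"


class DataError(RRSelError):
    """Input values violate a data contract (e.g. negative fitness)."""

    category = "data"


class InsufficientDataError(DataError):
    """Too few complete rows (or datasets) to fit the requested model."""

    category = "insufficient-data"


class DegenerateFitnessError(DataError):
    """Mean absolute fitness is zero; relative fitness is undefined."""

    category = "degenerate-fitness"


class ConfigError(RRSelError):
    """Invalid model, simulation or cross-validation configuration."""

    category = "config"


class ShapeError(RRSelError):
    """Mismatched dimensions or column names between fitted and new data."""

    category = "shape"


class NumericalError(RRSelError):
    """The sampler reached a non-finite state."""

    category = "numerical"


class NotApplicableError(RRSelError):
    """Operation requires model components that this fit does not have."""

    category = "not-applicable"
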