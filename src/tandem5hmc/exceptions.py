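"""Exception hierarchy for the tandem BS/OxBS pipeline."""


class Tandem5hmcError(Exception):
    """Base class for all package errors."""


class ConfigurationError(Tandem5hmcError):
    """A configuration value is invalid; the message names the field."""


class StructuralError(Tandem5hmcError):
    """Matrices or tables are mis-aligned (shape, index or column mismatch)."""


class IngestError(Tandem5hmcError):
    """Input values violate the data contract (range, missingness, parse)."""


class DegenerateDataError(Tandem5hmcError):
    """The requested computation is undefined on these data (zero events,
    zero variance, empty complement, ...)."""
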