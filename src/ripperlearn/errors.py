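"""Exception hierarchy shared across the package."""


class RipperLearnError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RipperLearnError):
    """Dataset or rule refers to columns/attributes inconsistent with a schema."""


class DataParseError(RipperLearnError):
    """A data file could not be parsed; message is row/column addressed."""


class RuleParseError(RipperLearnError):
    """Rule text could not be parsed; message carries the offending line number."""


class ValidationError(RipperLearnError):
    """A record or parameter bundle failed validation; message names the field."""
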