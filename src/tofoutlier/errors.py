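"""Exception types shared across the package."""


class TofOutlierError(Exception):
    """Base class for package errors."""


class ValidationError(TofOutlierError, ValueError):
    """Invalid configuration or input values."""


class DegenerateInputError(TofOutlierError, ValueError):
    """Input too short/empty for the requested operation."""


class SchemaError(TofOutlierError, ValueError):
    """A table or file does not match the documented schema."""


class ParseError(TofOutlierError, ValueError):
    """A recording file could not be parsed; carries a location."""
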