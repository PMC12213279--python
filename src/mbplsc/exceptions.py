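"""Exception hierarchy for mbplsc."""


class MbplscError(Exception):
    """Base class for all package errors."""


class SchemaError(MbplscError):
    """A column-role schema does not match the input table."""


class ParseError(MbplscError):
    """A cell of an input table could not be parsed as required."""


class ValidationError(MbplscError):
    """A dataset violates an invariant (duplicates, missing values, ...)."""


class ConfigError(MbplscError):
    """An analysis or simulation configuration is invalid."""


class ZeroVarianceError(MbplscError):
    """A column has zero variance, so correlations are undefined."""

    def __init__(self, column: str, context: str = ""):
        self.column = column
        msg = f"zero-variance column: {column!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class AlignmentError(MbplscError):
    """Variable names or group labels of two objects cannot be aligned."""
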