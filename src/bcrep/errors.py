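"""Exception types shared across the package."""


class BcrepError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(BcrepError):
    """A mandatory column could not be resolved in an input table."""


class EmptyInputError(BcrepError):
    """An operation received an empty table or collection."""


class ParameterError(BcrepError):
    """A parameter is outside its documented domain."""


class DegenerateInputError(BcrepError):
    """Input is formally valid but carries no usable signal (e.g. all-constant features)."""
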