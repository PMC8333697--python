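"""Exception hierarchy shared across the pipeline."""


class NetdcError(Exception):
    """Base class for all package errors."""


class ConfigurationError(NetdcError, ValueError):
    """A configuration / specification field is invalid."""


class InputError(NetdcError, ValueError):
    """Runtime input violates an operation's preconditions."""


class GridMismatchError(InputError):
    """Two volumes do not share a grid (shape and/or affine)."""


class FormatError(NetdcError, IOError):
    """An on-disk file could not be parsed in the expected format."""
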