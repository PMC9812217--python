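"""Exception hierarchy shared across the toolkit."""


class GridScreenError(Exception):
    """Base class for all gridscreen errors."""


class UnsupportedFormatError(GridScreenError, ValueError):
    """Image file extension (or forced format) is not one we read/write."""


class ImageParseError(GridScreenError, ValueError):
    """File exists but its header or payload could not be parsed."""


class ConfigurationError(GridScreenError):
    """A spec/config object is internally inconsistent or infeasible.

    Deliberately not a ValueError: pydantic validators re-wrap ValueError
    into ValidationError, and configuration problems should surface as
    themselves.
    """


class SchemaValidationError(GridScreenError, ValueError):
    """A target list or settings file failed schema validation."""


class NoLatticeError(GridScreenError, RuntimeError):
    """No periodic hole structure could be found in an image."""


class FocusPlacementError(GridScreenError, RuntimeError):
    """Focus target could not be placed between lattice points."""
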