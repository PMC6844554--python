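"""Exception types shared across the package."""


class LipidHCAError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(LipidHCAError, ValueError):
    """A configuration value or function argument violates its contract."""


class FlatImageError(LipidHCAError, ValueError):
    """An operation that needs intensity contrast received a constant image."""


class DegenerateStructuringElementError(LipidHCAError, ValueError):
    """The morphological structuring element does not fit inside the image."""


class ShapeMismatchError(LipidHCAError, ValueError):
    """Two rasters that must share a shape do not."""


class ConsistencyError(LipidHCAError, ValueError):
    """Label masks that must agree (e.g. nuclei within cells) do not."""


class PlacementError(LipidHCAError, RuntimeError):
    """The simulator could not place the requested objects in the field."""


class ConstantInputError(LipidHCAError, ValueError):
    """A correlation was requested on a constant vector."""
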