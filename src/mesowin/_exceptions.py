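"""Exception hierarchy shared across the package."""


class MesowinError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MesowinError, ValueError):
    """A file could not be parsed as the expected image/table/config format."""


class ParamError(MesowinError, ValueError):
    """A parameter set violates its documented invariants."""


class GeometryError(MesowinError, ValueError):
    """A landmark, polygon or midline lies outside the image or is degenerate."""


class DegenerateInputError(MesowinError, ValueError):
    """Input carries no usable signal (e.g. constant region passed to Otsu)."""


class InsufficientFramesError(MesowinError, ValueError):
    """A movie is too short for the requested discard/block layout."""


class PlacementError(MesowinError, RuntimeError):
    """Synthetic objects could not be placed without overlap."""
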