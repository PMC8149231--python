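"""Exception hierarchy shared across the package."""


class ImmunoTextureError(Exception):
    """Base class for all package errors."""


class DimensionError(ImmunoTextureError, ValueError):
    """Input array has the wrong number of dimensions or channels."""


class ParameterError(ImmunoTextureError, ValueError):
    """A numeric parameter is outside its admissible range."""


class GeometryError(ImmunoTextureError, ValueError):
    """A rectangle or window does not fit the image it refers to."""


class DegenerateInputError(ImmunoTextureError, ValueError):
    """The input is degenerate for the requested operation (e.g. constant image)."""


class StateError(ImmunoTextureError, RuntimeError):
    """An object is used before a required prior step (e.g. unevaluated antibody)."""
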