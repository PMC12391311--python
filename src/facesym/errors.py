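"""Exception hierarchy shared across the pipeline."""


class FaceSymError(Exception):
    """Base class for all package-specific failures."""


class NoFaceDetectedError(FaceSymError):
    """The landmark provider found no face in the image."""


class ProviderContractError(FaceSymError):
    """A landmark provider violated the 478-point contract."""


class DegenerateGeometryError(FaceSymError):
    """Landmark geometry is degenerate (coincident points, zero extent)."""


class ZeroValidPairsError(FaceSymError):
    """No valid mirrored pixel pairs exist; the symmetry score is undefined."""


class ConfigError(FaceSymError):
    """Invalid configuration value (e.g. an even blur kernel)."""


class UndefinedCorrelationError(FaceSymError):
    """Rank correlation undefined (constant vector or too few points)."""
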