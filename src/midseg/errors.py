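"""Exception hierarchy shared by all pipeline stages.

Every stage failure carries enough context (structure label, stage name) for
the orchestrator to report which nucleus failed where.
"""


class MidsegError(Exception):
    """Base class for all package errors."""


class FormatError(MidsegError):
    """Unreadable or unsupported file format."""


class DimensionError(MidsegError):
    """Input volume has the wrong dimensionality."""


class GeometryError(MidsegError):
    """Invalid geometry (self-intersecting polygon, contour at border, ...)."""


class DegenerateError(MidsegError):
    """Degenerate statistical input (e.g. constant array fed to Otsu)."""


class ConfigurationError(MidsegError):
    """Missing or inconsistent configuration/ROIs."""


class CollapseError(MidsegError):
    """A structure vanished (area below minimum) during thresholding/refinement."""

    def __init__(self, message: str, structure: str | None = None, stage: str | None = None):
        super().__init__(message)
        self.structure = structure
        self.stage = stage


class LocalizationError(MidsegError):
    """Midbrain crop could not be anchored inside the volume."""


class RegistrationError(MidsegError):
    """Registration backend diverged or produced an unusable transform."""


class TransformError(MidsegError):
    """Spatial transform not invertible where required."""


class InfeasibleError(MidsegError):
    """Dynamic program has no finite-cost cyclic path."""
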