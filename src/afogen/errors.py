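"""Exception hierarchy for the AFO design pipeline.

Every error raised by the package derives from :class:`AfogenError` so
callers (and the CLI) can map failures onto exit codes: validation errors
(bad parameters or inputs), geometry errors (a pipeline stage failed on
valid-looking input), and I/O errors (missing or unreadable files).
"""


class AfogenError(Exception):
    """Base class for all package errors."""


class InputValidationError(AfogenError):
    """Invalid parameter values or malformed in-memory inputs."""


class ParameterError(InputValidationError):
    """A numeric design parameter is out of its allowed range."""


class LandmarkError(InputValidationError):
    """A landmark file or landmark set is incomplete or malformed."""


class DegenerateLandmarkError(InputValidationError):
    """Two landmarks coincide, making an anatomical axis zero-length."""


class DegeneratePlaneError(InputValidationError):
    """The plantar landmarks are collinear; no plantar plane exists."""


class ProjectionDegenerateError(InputValidationError):
    """An axis projects to (near) zero length in a measurement plane."""


class PoseError(InputValidationError):
    """Landmarks are not in the neutralized pose an operation requires."""


class ImplausibleDeformityError(InputValidationError):
    """Measured deformity exceeds the sanity bound (likely bad landmarks)."""


class GeometryError(AfogenError):
    """A geometric pipeline stage failed."""


class EmptyShellError(GeometryError):
    """Template trimming removed every face."""


class NothingToSealError(GeometryError):
    """thicken_and_seal was given a closed mesh with no boundary to stitch."""


class StageError(GeometryError):
    """Wraps an exception raised inside a named design_afo stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {cause}")


class MeshIOError(AfogenError):
    """File-level I/O problems (unreadable, truncated, unsupported)."""


class MeshFormatError(MeshIOError):
    """File exists but cannot be parsed as a surface mesh."""


class EmptyMeshError(MeshIOError):
    """File parsed but contains zero faces."""
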