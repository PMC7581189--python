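"""Package-wide exception types."""


class GazeContextError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(GazeContextError, ValueError):
    """Object placement with impossible geometry (e.g. non-positive radius)."""


class ConstraintViolationError(GazeContextError, ValueError):
    """A scene or schedule violates its balance constraints."""


class DesignDegeneracyError(GazeContextError, ValueError):
    """Rank-deficient design matrix; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; collinear columns: {self.columns}")


class InvalidContrastError(GazeContextError, ValueError):
    """Contrast weights that define no comparison (all zero, wrong length)."""


class InsufficientSampleError(GazeContextError, ValueError):
    """Group-level statistics need at least two subjects."""


class EmptyROIError(GazeContextError, ValueError):
    """A region of interest with no member voxels on the given grid."""


class NormalizationError(GazeContextError, ValueError):
    """Baseline or trace normalization against a zero mean."""


class InvalidWindowError(GazeContextError, ValueError):
    """An analysis window outside the span of the data."""


class FoldConstructionError(GazeContextError, ValueError):
    """Cross-validation folds cannot be built (condition missing in a run)."""


class StageError(GazeContextError, RuntimeError):
    """A pipeline stage failed; names the stage and the offending input."""

    def __init__(self, stage, detail):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {detail}")
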