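"""Exception hierarchy for colonyqc.

Validation problems (bad parameters, unknown designs) and data problems
(degenerate inputs, untrainable configurations) are distinguished so the
CLI can map them to distinct exit codes.
"""


class ColonyQCError(Exception):
    """Base class for all package errors."""


class ValidationError(ColonyQCError):
    """Invalid parameters or configuration."""


class DataError(ColonyQCError):
    """Input data cannot support the requested computation."""


# --- validation-type errors -------------------------------------------------

class InvalidClassCountError(ValidationError):
    """Number of classes below the minimum (2) for a coding design."""


class UnsupportedDesignError(ValidationError):
    """Coding design name not recognised."""


class MissingParameterError(ValidationError):
    """A required parameter (scale vector, decoding weights, ...) is absent."""


# --- data-type errors -------------------------------------------------------

class InsufficientDataError(DataError):
    """Too few rows for the requested fit (e.g. k > n)."""


class InsufficientRowsError(DataError):
    """Table too small to preprocess (n < 2)."""


class DegenerateVectorError(DataError):
    """Zero-variance / zero-norm vector under a correlation-type distance."""


class DegenerateScaleError(DataError):
    """Zero-variance feature under the standardized Euclidean distance."""


class CovarianceNotPositiveDefiniteError(DataError):
    """Covariance matrix is singular or not positive definite.

    Raised by the plain linear/quadratic discriminant variants; the
    pseudo_* variants avoid it via pseudoinverses.
    """


class ZeroVarianceError(DataError):
    """A per-class per-feature variance is zero where a density needs it."""


class UntrainableColumnError(DataError):
    """A coding-matrix column's included classes have only one polarity."""

    def __init__(self, column: int, message: str | None = None):
        self.column = column
        super().__init__(message or f"column {column} is untrainable")


class UntrainableFoldError(DataError):
    """Removing a row empties one of the classes in a cross-validation fold."""

    def __init__(self, row: int, message: str | None = None):
        self.row = row
        super().__init__(message or f"leaving out row {row} empties a class")


class UnknownLabelError(DataError):
    """A label outside the declared class order."""


class NoKeypointsError(DataError):
    """The keypoint detector found nothing in an image."""

    def __init__(self, image_id: str = "<unnamed>", message: str | None = None):
        self.image_id = image_id
        super().__init__(message or f"no keypoints detected in image {image_id!r}")


class EmptyInputError(DataError):
    """An operation received an empty collection."""


class TooSmallImageError(ValidationError):
    """Requested image dimensions below the renderer's minimum (32 x 32)."""
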