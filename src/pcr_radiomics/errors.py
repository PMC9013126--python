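"""Exception hierarchy shared across the pipeline stages."""


class PcrRadiomicsError(Exception):
    """Base class for all package errors."""


class FormatError(PcrRadiomicsError):
    """File is not in a supported image format."""


class MetadataError(PcrRadiomicsError):
    """Image header carries invalid metadata (e.g. non-positive spacing)."""


class AlignmentError(PcrRadiomicsError):
    """Mask and volume do not share grid shape/spacing."""


class EmptyROIError(PcrRadiomicsError):
    """Region of interest contains no foreground voxels."""


class SmallROIError(PcrRadiomicsError):
    """Region of interest is below the minimum voxel count for stable features."""


class CohortValidationError(PcrRadiomicsError):
    """Cohort table rows violate the categorical coding contract."""

    def __init__(self, message: str, bad_rows=None):
        super().__init__(message)
        self.bad_rows = list(bad_rows) if bad_rows is not None else []


class DegenerateDistributionError(PcrRadiomicsError):
    """Statistic undefined for a zero-variance intensity sample."""


class MissingDataError(PcrRadiomicsError):
    """A model covariate is absent or non-finite."""

    def __init__(self, field: str):
        super().__init__(f"missing or non-finite covariate: {field!r}")
        self.field = field


class SchemaError(PcrRadiomicsError):
    """Serialised model specification misses a required field."""


class DegenerateCohortError(PcrRadiomicsError):
    """ROC statistics need both outcome classes present."""


class InvalidTableError(PcrRadiomicsError):
    """Contingency table unusable (zero expected counts)."""


class ReconstructionError(PcrRadiomicsError):
    """Confusion-matrix reconstruction from printed metrics failed or is ambiguous."""

    def __init__(self, message: str, candidates=None):
        super().__init__(message)
        self.candidates = list(candidates) if candidates is not None else []


class UndefinedKappaError(PcrRadiomicsError):
    """Cohen's kappa undefined (expected agreement equals 1)."""


class PhantomSpecError(PcrRadiomicsError):
    """Phantom geometry is inconsistent with the grid."""
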