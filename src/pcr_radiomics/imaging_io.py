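"""Image, mask and table I/O.

Volumes are held as 3-D arrays indexed ``(x, y, z)`` with voxel spacing
``(dx, dy, dz)`` in millimetres; ``z`` is the slice axis.  Orientation
matrices beyond spacing are deliberately ignored: all downstream features
are orientation-invariant.  On-disk formats are NIfTI (``.nii``,
``.nii.gz``) and NRRD (``.nrrd``); intensities are never rescaled or
normalised on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .errors import (
    AlignmentError,
    CohortValidationError,
    EmptyROIError,
    FormatError,
    MetadataError,
)

logger = logging.getLogger(__name__)

SUPPORTED_SUFFIXES = (".nii", ".nii.gz", ".nrrd")
SPACING_ATOL_MM = 1e-4

VALID_CT = (2, 3, 4)
VALID_CN = (0, 1, 2)
VALID_FIELD_STRENGTH = (1.5, 3.0)

FEATURE_TABLE_COLUMNS = [
    "id",
    "cT",
    "cN",
    "field_strength",
    "skewness",
    "entropy",
    "score",
    "pcr_label",
]


@dataclass
class ImageVolume:
    """3-D scalar intensity grid with anisotropic voxel spacing in mm."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise MetadataError(f"expected a 3-D volume, got ndim={self.voxels.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacing must be three positive lengths, got {self.spacing}")
        if not np.all(np.isfinite(self.voxels)):
            raise MetadataError("volume contains non-finite intensities")
        self.meta.setdefault("axis_order", "xyz")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass
class ROIMask:
    """Binary mask on the same grid as its paired :class:`ImageVolume`."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels) != 0
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.voxels.ndim != 3:
            raise MetadataError(f"expected a 3-D mask, got ndim={self.voxels.ndim}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MetadataError(f"spacing must be three positive lengths, got {self.spacing}")

    @property
    def n_foreground(self) -> int:
        return int(self.voxels.sum())


def check_aligned(volume: ImageVolume, mask: ROIMask) -> None:
    """Raise :class:`AlignmentError` unless mask and volume share the grid."""
    if mask.voxels.shape != volume.voxels.shape:
        raise AlignmentError(
            f"mask shape {mask.voxels.shape} != volume shape {volume.voxels.shape}"
        )
    if not np.allclose(mask.spacing, volume.spacing, atol=SPACING_ATOL_MM, rtol=0.0):
        raise AlignmentError(f"mask spacing {mask.spacing} != volume spacing {volume.spacing}")


def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in SUPPORTED_SUFFIXES):
        raise FormatError(
            f"unsupported image format for {path.name!r}; expected one of {SUPPORTED_SUFFIXES}"
        )


def read_volume(path) -> ImageVolume:
    """Read a NIfTI or NRRD volume, taking spacing from the file header.

    Intensities are returned exactly as stored; no rescaling is applied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - ITK error text varies
        raise FormatError(f"could not read {path}: {exc}") from exc
    spacing = img.GetSpacing()  # (x, y, z) in ITK convention
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise MetadataError(f"invalid header spacing {spacing} in {path.name}")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    voxels = np.ascontiguousarray(arr.transpose(2, 1, 0))
    return ImageVolume(voxels=voxels, spacing=tuple(spacing), meta={"source": str(path)})


def write_volume(volume: ImageVolume, path) -> None:
    """Write a volume to NIfTI or NRRD, preserving spacing and dtype."""
    path = Path(path)
    _check_suffix(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.voxels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    sitk.WriteImage(img, str(path))


def write_mask(mask: ROIMask, path) -> None:
    """Write a binary mask as an 8-bit volume."""
    write_volume(
        ImageVolume(mask.voxels.astype(np.uint8), mask.spacing), path
    )


def read_mask(path, reference: ImageVolume) -> ROIMask:
    """Read a mask and align it to the reference grid.

    Any nonzero voxel is foreground.  Raises :class:`AlignmentError` on a
    shape/spacing mismatch and :class:`EmptyROIError` for all-zero masks.
    """
    vol = read_volume(path)
    mask = ROIMask(voxels=vol.voxels, spacing=vol.spacing)
    check_aligned(reference, mask)
    if mask.n_foreground == 0:
        raise EmptyROIError(f"mask {Path(path).name!r} has no foreground voxels")
    return mask


# ---------------------------------------------------------------------------
# tabular I/O


def _validate_cohort_frame(df: pd.DataFrame, require_label: bool = True) -> pd.DataFrame:
    required = ["id", "cT", "cN", "field_strength"]
    if require_label:
        required.append("pcr_label")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortValidationError(f"cohort table misses columns {missing}")
    bad = []
    for idx, row in df.iterrows():
        problems = []
        if int(row["cT"]) not in VALID_CT:
            problems.append(f"cT={row['cT']}")
        if int(row["cN"]) not in VALID_CN:
            problems.append(f"cN={row['cN']}")
        if float(row["field_strength"]) not in VALID_FIELD_STRENGTH:
            problems.append(f"field_strength={row['field_strength']}")
        if require_label and int(row["pcr_label"]) not in (0, 1):
            problems.append(f"pcr_label={row['pcr_label']}")
        if problems:
            bad.append((idx, ", ".join(problems)))
    if bad:
        listing = "; ".join(f"row {i}: {p}" for i, p in bad)
        raise CohortValidationError(f"invalid cohort rows: {listing}", bad_rows=bad)
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise CohortValidationError(f"duplicate patient ids: {dups}")
    out = df.copy()
    out["cT"] = out["cT"].astype(int)
    out["cN"] = out["cN"].astype(int)
    out["field_strength"] = out["field_strength"].astype(float)
    if require_label:
        out["pcr_label"] = out["pcr_label"].astype(int)
    return out


@dataclass
class CohortTable:
    """Validated per-patient clinical table (cT, cN, field strength, pCR)."""

    df: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def n_positive(self) -> int:
        return int(self.df["pcr_label"].sum())

    @property
    def prevalence(self) -> float:
        return self.n_positive / self.n


def read_cohort_table(path) -> CohortTable:
    """Read and validate a cohort CSV; logs the pCR prevalence on load."""
    df = pd.read_csv(path)
    df = _validate_cohort_frame(df)
    table = CohortTable(df)
    logger.info(
        "cohort %s: %d patients, %d pCR (prevalence %.1f%%)",
        Path(path).name,
        table.n,
        table.n_positive,
        100.0 * table.prevalence,
    )
    return table


def write_cohort_table(table: CohortTable, path) -> None:
    table.df.to_csv(path, index=False)


def write_feature_table(records, path) -> None:
    """Write one CSV row per patient: id, covariates, features, score, label.

    ``records`` may be a DataFrame or an iterable of dicts / PatientRecord-like
    objects exposing the feature-table fields.
    """
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = []
        for r in records:
            if hasattr(r, "to_row"):
                rows.append(r.to_row())
            else:
                rows.append(dict(r))
        df = pd.DataFrame(rows)
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"feature table misses columns {missing}")
    df[FEATURE_TABLE_COLUMNS].to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"feature table misses columns {missing}")
    _validate_cohort_frame(df.drop(columns=["skewness", "entropy", "score"]),
                           require_label=True)
    return df
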