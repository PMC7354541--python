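"""CT slices, ROI masks, and their NIfTI round-trip.

The unit of analysis is a single 2-D axial CT slice in Hounsfield units (HU)
with physical pixel spacing in mm, tagged with its acquisition phase
(``pre`` = unenhanced, ``eq`` = equilibrium contrast phase).  ROI masks are
boolean grids on exactly the same lattice.  Registration between the two
phases is *assumed*, never computed: masks drawn on one phase may be copied
to the other only when the grids match, mirroring the clinical workflow in
which equilibrium-phase ROIs are copied onto the matching pre-contrast
sections.

Coordinate convention: 0-based, row-major ``(row, col)``; ``spacing_mm`` is
``(row_mm, col_mm)``.  The canonical interchange format is NIfTI; masks are
stored as uint8 0/1 volumes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import DataError, GeometryError, InputError

HU_MIN = -1024.0
HU_MAX = 3071.0

PHASES = ("pre", "eq")
REGIONS = ("whole_liver", "segment7", "aorta")

#: spacing agreement tolerance (mm) for treating two lattices as registered
SPACING_TOL_MM = 1e-6

CLINICAL_COLUMNS = ("patient_id", "haematocrit", "cpa_percent", "elf", "ishak")


@dataclass
class CTSlice:
    """A 2-D CT slice in HU with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray
        2-D float array of HU values; validated to be finite and within
        the representable CT range [-1024, 3071].  Out-of-range values are
        an error, never clipped silently.
    spacing_mm : (float, float)
        mm per pixel along (row, col); both strictly positive.
    phase : {"pre", "eq"}
    patient_id, slice_label : str
        Free-text identifiers (e.g. ``slice_label="hepatic_porta"``).
    thickness_mm : float, optional
        Reconstructed section thickness; carried as metadata only, it does
        not enter any computation.
    """

    pixels: np.ndarray
    spacing_mm: tuple[float, float]
    phase: str
    patient_id: str = ""
    slice_label: str = ""
    thickness_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.pixels = np.ascontiguousarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise GeometryError("pixels must be a non-empty 2-D grid")
        self.spacing_mm = (float(self.spacing_mm[0]), float(self.spacing_mm[1]))
        if not all(s > 0 and np.isfinite(s) for s in self.spacing_mm):
            raise GeometryError(f"pixel spacing must be positive, got {self.spacing_mm}")
        if self.phase not in PHASES:
            raise InputError(f"phase must be one of {PHASES}, got {self.phase!r}")
        if not np.all(np.isfinite(self.pixels)):
            raise DataError("pixels contain non-finite values")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise DataError(
                f"HU values [{lo:.1f}, {hi:.1f}] outside valid range "
                f"[{HU_MIN:.0f}, {HU_MAX:.0f}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class ROIMask:
    """Boolean region-of-interest on the lattice of a reference slice."""

    mask: np.ndarray
    region: str
    ref_shape: tuple[int, int]
    ref_spacing_mm: tuple[float, float]

    def __post_init__(self) -> None:
        self.mask = np.ascontiguousarray(self.mask).astype(bool)
        if self.region not in REGIONS:
            raise InputError(f"region must be one of {REGIONS}, got {self.region!r}")
        self.ref_shape = (int(self.ref_shape[0]), int(self.ref_shape[1]))
        self.ref_spacing_mm = (float(self.ref_spacing_mm[0]), float(self.ref_spacing_mm[1]))
        if self.mask.ndim != 2 or self.mask.shape != self.ref_shape:
            raise GeometryError(
                f"mask shape {self.mask.shape} does not match reference {self.ref_shape}"
            )
        if not self.mask.any():
            raise GeometryError(f"mask {self.region!r} has no true pixels")

    @classmethod
    def from_slice(cls, mask: np.ndarray, region: str, ref: CTSlice) -> "ROIMask":
        return cls(mask=mask, region=region, ref_shape=ref.shape, ref_spacing_mm=ref.spacing_mm)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def area_cm2(self) -> float:
        """Physical ROI area in cm^2 (pixel count x pixel area)."""
        return self.n_pixels * self.ref_spacing_mm[0] * self.ref_spacing_mm[1] / 100.0


def _lattices_match(
    shape_a: tuple[int, int],
    spacing_a: tuple[float, float],
    shape_b: tuple[int, int],
    spacing_b: tuple[float, float],
) -> bool:
    return shape_a == shape_b and all(
        abs(sa - sb) <= SPACING_TOL_MM for sa, sb in zip(spacing_a, spacing_b)
    )


def check_registration(a: CTSlice, b: CTSlice) -> bool:
    """True iff the two slices share a lattice (same shape, spacing to 1e-6 mm).

    Registration is a precondition for copying ROIs between phases; it is a
    pure predicate — mis-registered inputs are rejected downstream, never
    resampled.
    """
    return _lattices_match(a.shape, a.spacing_mm, b.shape, b.spacing_mm)


def copy_roi(mask: ROIMask, target: CTSlice) -> ROIMask:
    """Copy an ROI drawn on one phase onto a registered slice of the other.

    Raises
    ------
    GeometryError
        If the mask's reference lattice does not match ``target``.
    """
    if not _lattices_match(mask.ref_shape, mask.ref_spacing_mm, target.shape, target.spacing_mm):
        raise GeometryError(
            f"cannot copy ROI {mask.region!r}: lattice mismatch "
            f"({mask.ref_shape}@{mask.ref_spacing_mm} vs {target.shape}@{target.spacing_mm})"
        )
    return ROIMask.from_slice(mask.mask.copy(), mask.region, target)


def masks_disjoint(a: ROIMask, b: ROIMask) -> bool:
    """True iff two masks on the same lattice share no pixel (aorta vs liver)."""
    if a.ref_shape != b.ref_shape:
        raise GeometryError("masks live on different lattices")
    return not np.any(a.mask & b.mask)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(spacing_mm: tuple[float, float]) -> np.ndarray:
    return np.diag([spacing_mm[0], spacing_mm[1], 1.0, 1.0])


def write_slice(slc: CTSlice, path: str | Path) -> Path:
    """Write a CTSlice as a 2-D float64 NIfTI; spacing goes into pixdim."""
    path = Path(path)
    img = nib.Nifti1Image(slc.pixels, _affine(slc.spacing_mm))
    img.header.set_data_dtype(np.float64)
    img.header.set_zooms(slc.spacing_mm)
    nib.save(img, path)
    return path


def read_slice(
    path: str | Path,
    phase: str,
    patient_id: str = "",
    slice_label: str = "",
    spacing_override: Optional[tuple[float, float]] = None,
) -> CTSlice:
    """Read a 2-D (or single-slice 3-D) NIfTI as a validated CTSlice.

    Spacing is taken from the file header unless ``spacing_override`` is
    given.  Missing or non-positive header spacing with no override is a
    geometry error; non-finite pixels are a data error.
    """
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    data = np.squeeze(data)
    if data.ndim != 2:
        raise GeometryError(f"{path}: expected a 2-D or single-slice 3-D image, got shape {data.shape}")
    if spacing_override is not None:
        spacing = (float(spacing_override[0]), float(spacing_override[1]))
    else:
        zooms = img.header.get_zooms()[:2]
        spacing = (float(zooms[0]), float(zooms[1]))
        if not all(s > 0 and np.isfinite(s) for s in spacing):
            raise GeometryError(f"{path}: header spacing {spacing} invalid and no override given")
    return CTSlice(pixels=data, spacing_mm=spacing, phase=phase,
                   patient_id=patient_id, slice_label=slice_label)


def write_mask(mask: ROIMask, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.mask.astype(np.uint8), _affine(mask.ref_spacing_mm))
    img.header.set_data_dtype(np.uint8)
    img.header.set_zooms(mask.ref_spacing_mm)
    nib.save(img, path)
    return path


def read_mask(
    path: str | Path,
    region: str,
    reference: CTSlice,
) -> ROIMask:
    """Read a uint8 0/1 NIfTI mask and bind it to ``reference``'s lattice."""
    img = nib.load(str(path))
    data = np.squeeze(np.asarray(img.dataobj))
    if data.ndim != 2:
        raise GeometryError(f"{path}: expected 2-D mask, got shape {data.shape}")
    bad = set(np.unique(data)) - {0, 1}
    if bad:
        raise DataError(f"{path}: mask contains values other than 0/1: {sorted(bad)}")
    return ROIMask.from_slice(data.astype(bool), region, reference)


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the clinical CSV (patient_id, haematocrit, cpa_percent, elf, ishak).

    Markers may be missing (NaN); Ishak stages, where present, must lie in
    0..6.  Duplicate patient ids are rejected.
    """
    df = pd.read_csv(path, dtype={"patient_id": str})
    missing = set(CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"clinical table missing columns: {sorted(missing)}")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise InputError(f"duplicate patient_id in clinical table: {dupes}")
    ishak = df["ishak"].dropna()
    if ((ishak < 0) | (ishak > 6)).any():
        raise InputError("ishak stage outside 0..6")
    if (df["cpa_percent"].dropna() < 0).any():
        raise InputError("cpa_percent must be >= 0")
    return df


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    return path
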