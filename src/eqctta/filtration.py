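"""Laplacian-of-Gaussian band-pass filtration (the "filtration" step).

The filtration-histogram technique first convolves the slice with a
band-pass filter parameterised by a *spatial scale filter* (SSF) value in
mm, producing a derived texture map that selectively enhances image
features of approximately that size; histogram statistics are then read
off the map inside an ROI.  Scales follow the conventional banding:
fine = 2 mm, medium = 3-5 mm, coarse = 6 mm, and SSF = 0 means no
filtration (the raw-HU control).

Kernel construction
-------------------
The kernel is the *negated, scale-normalised* Laplacian of Gaussian:

    K(x, y) = -(sigma_r^2 d^2/dr^2 + sigma_c^2 d^2/dc^2) G(r, c)

with per-axis sigma_pixels = SSF / (2*sqrt(2) * spacing_mm).  Under this
mapping the zero-crossing ring of the LoG has diameter 2*sqrt(2)*sigma =
SSF, i.e. "SSF in mm" equals the diameter of the bright object the filter
highlights most strongly.  Negation makes bright blobs give *positive*
responses, so MPP and skewness increase with the prevalence of bright
features.  The sigma^2 scale normalisation (Lindeberg's convention) makes
the peak response across scales land at the matching object size, which
is what gives the SSF its "feature size" interpretation.  The kernel is
truncated at 4*sigma and mean-subtracted so its entries sum to exactly
zero (zero DC gain: a constant image yields an identically zero map).

The exact kernel used by commercial texture packages is proprietary; this
construction is an open, documented interpretation with the same stated
behaviour, and every choice (sigma mapping, truncation, boundary mode) is
explicit and configurable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
import numpy as np
from scipy import ndimage

from .errors import DataError, GeometryError, InputError, ResolutionWarning
from .image_io import CTSlice, ROIMask

#: SSF values used by default, in mm; 0 is the unfiltered control.
DEFAULT_SSF_MM = (0.0, 2.0, 3.0, 4.0, 5.0, 6.0)

#: mm-diameter -> sigma conversion: zero-crossing diameter 2*sqrt(2)*sigma = SSF
SSF_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0))

#: kernel truncation radius in units of sigma
TRUNCATE_SIGMAS = 4.0


@dataclass(frozen=True)
class SSFValue:
    """A spatial scale filter value in mm (>= 0; 0 = no filtration)."""

    ssf_mm: float

    def __post_init__(self) -> None:
        if not (self.ssf_mm >= 0 and np.isfinite(self.ssf_mm)):
            raise InputError(f"ssf_mm must be finite and >= 0, got {self.ssf_mm}")

    @property
    def scale_class(self) -> str:
        """Reporting band: none (0), fine (<3), medium (3-5), coarse (>5)."""
        if self.ssf_mm == 0:
            return "none"
        if self.ssf_mm < 3:
            return "fine"
        if self.ssf_mm <= 5:
            return "medium"
        return "coarse"

    def sigma_mm(self) -> float:
        return self.ssf_mm * SSF_TO_SIGMA

    def sigma_pixels(self, spacing_mm: tuple[float, float]) -> tuple[float, float]:
        return (self.sigma_mm() / spacing_mm[0], self.sigma_mm() / spacing_mm[1])


@dataclass
class FilteredMap:
    """Filter response map on the lattice of its source slice."""

    pixels: np.ndarray
    source: CTSlice
    ssf: SSFValue

    def __post_init__(self) -> None:
        self.pixels = np.ascontiguousarray(self.pixels, dtype=np.float64)
        if self.pixels.shape != self.source.shape:
            raise GeometryError("filtered map shape differs from source slice")
        if not np.all(np.isfinite(self.pixels)):
            raise DataError("filtered map contains non-finite values")

    @property
    def spacing_mm(self) -> tuple[float, float]:
        return self.source.spacing_mm


def log_kernel(ssf: SSFValue | float, spacing_mm: tuple[float, float]) -> np.ndarray:
    """Sampled negated scale-normalised LoG kernel for one SSF and spacing.

    Anisotropic spacing is handled per axis (separate sigma along rows and
    columns).  Entries sum to exactly 0.  Requesting a kernel for SSF = 0
    is an error — that scale means "bypass the filter".  A sigma below
    half a pixel triggers a :class:`ResolutionWarning`: the scale is at or
    under the sampling limit and responses are dominated by discretisation.
    """
    if not isinstance(ssf, SSFValue):
        ssf = SSFValue(float(ssf))
    if ssf.ssf_mm == 0:
        raise InputError("SSF = 0 is the filter bypass; no kernel exists")
    if not all(s > 0 for s in spacing_mm):
        raise GeometryError(f"spacing must be positive, got {spacing_mm}")
    sr, sc = ssf.sigma_pixels(spacing_mm)
    if min(sr, sc) < 0.5:
        warnings.warn(
            f"SSF {ssf.ssf_mm} mm gives sigma {min(sr, sc):.3f} px (< 0.5): "
            "scale is below the sampling resolution",
            ResolutionWarning,
            stacklevel=2,
        )
    rr = int(math.ceil(TRUNCATE_SIGMAS * sr))
    rc = int(math.ceil(TRUNCATE_SIGMAS * sc))
    r = np.arange(-rr, rr + 1, dtype=np.float64)[:, None]
    c = np.arange(-rc, rc + 1, dtype=np.float64)[None, :]
    g = np.exp(-(r**2 / (2 * sr**2) + c**2 / (2 * sc**2))) / (2 * math.pi * sr * sc)
    # scale-normalised Laplacian: sigma^2 * d2/dx2 terms reduce to (x^2/sigma^2 - 1)
    kernel = -((r**2 / sr**2) + (c**2 / sc**2) - 2.0) * g
    kernel -= kernel.mean()
    return kernel


def filter_slice(slc: CTSlice, ssf: SSFValue | float) -> FilteredMap:
    """Apply the band-pass filter at one SSF to a whole slice.

    The full image is filtered (mirror boundary handling); masking happens
    only afterwards, at statistic-sampling time, so that ROI edges never
    inject spurious responses into the map.  SSF = 0 returns the raw HU
    image unchanged.
    """
    if not isinstance(ssf, SSFValue):
        ssf = SSFValue(float(ssf))
    if not np.all(np.isfinite(slc.pixels)):
        raise DataError("slice contains non-finite pixels")
    if ssf.ssf_mm == 0:
        return FilteredMap(pixels=slc.pixels.copy(), source=slc, ssf=ssf)
    kernel = log_kernel(ssf, slc.spacing_mm)
    response = ndimage.convolve(slc.pixels, kernel, mode="mirror")
    return FilteredMap(pixels=response, source=slc, ssf=ssf)


def erosion_radius_px(ssf: SSFValue | float, spacing_mm: tuple[float, float]) -> tuple[int, int]:
    """Per-axis mask erosion radius ceil(2*sigma) used before sampling."""
    if not isinstance(ssf, SSFValue):
        ssf = SSFValue(float(ssf))
    if ssf.ssf_mm == 0:
        return (0, 0)
    sr, sc = ssf.sigma_pixels(spacing_mm)
    return (int(math.ceil(2 * sr)), int(math.ceil(2 * sc)))


def erode_mask(mask: ROIMask, ssf: SSFValue | float) -> np.ndarray:
    """Erode an ROI by ceil(2*sigma) pixels to suppress edge ring artefacts.

    Filtering responds strongly to intensity steps; the pixels nearest the
    ROI boundary carry ring artefacts from structure just outside, so they
    are dropped before histogram statistics are computed.  Returns the
    eroded boolean array (possibly empty — callers must check).
    """
    rr, rc = erosion_radius_px(ssf, mask.ref_spacing_mm)
    if rr == 0 and rc == 0:
        return mask.mask.copy()
    structure = np.ones((2 * rr + 1, 2 * rc + 1), dtype=bool)
    return ndimage.binary_erosion(mask.mask, structure=structure)


def export_filtered_map(fmap: FilteredMap, path: str | Path) -> Path:
    """Write a filtered map as NIfTI for visual inspection.

    The map is written via the slice writer with HU validation bypassed
    (filter responses are HU-derived, not HU, and may exceed the CT range).
    """
    import nibabel as nib

    path = Path(path)
    img = nib.Nifti1Image(fmap.pixels, np.diag([*fmap.spacing_mm, 1.0, 1.0]))
    img.header.set_data_dtype(np.float64)
    img.header.set_zooms(fmap.spacing_mm)
    nib.save(img, path)
    return path
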