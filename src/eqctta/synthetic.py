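"""Synthetic liver-CT phantoms with known fibrosis severity.

Each phantom is a pre-contrast / equilibrium-phase slice pair plus ROI
masks and clinical markers, generated from a single severity parameter
``s`` in [0, 1] that stands in for fibrotic burden.  The anatomy is a
fixed idealisation (elliptical liver, wedge-shaped segment VII whose
outer edge lies on the liver margin, aortic disc, a few vessels); the
severity expresses itself through five channels:

* **Fibrotic features** — bright Gaussian blobs of a characteristic
  mm-scale diameter whose areal density rises linearly with ``s``.  The
  blob "diameter" is its 1/e full width, 2*sqrt(2)*sigma_blob, the same
  convention the filter uses for SSF, so a blob of diameter d mm is
  maximally enhanced at SSF = d.
* **Equilibrium enhancement** — at equilibrium the liver gains a mean
  attenuation of ecv_true * dHU_blood / (1 - haematocrit) over the
  whole-liver ROI, with ecv_true = ecv0 + ecv_gain * s, so the ECV
  partition relation holds by construction and the pipeline can recover
  ecv_true from ROI means.  Vessels and the aorta enhance by the full
  blood delta.
* **Interstitial (feature-bound) enhancement** — each fibrotic blob
  brightens by a fixed multiple of its own pre-contrast amplitude
  (contrast pooling in the expanded interstitium of each feature); the
  spatially uniform remainder of the liver enhancement is adjusted so
  the whole-liver mean delta stays exactly on the ECV target.  With no
  features the enhancement is uniform.
* **Septal rim** — fibrosis in progressing disease is septal: a band of
  collagen-rich, high-ECV tissue runs along the watershed boundary of
  the affected segment.  The generator paints an equilibrium-only
  enhancement band (default 4 mm wide, centred ~6 mm inside the segment
  VII boundary) whose amplitude scales with ``s``.  This is the planted
  equilibrium-specific, segment-localised texture signal: it produces a
  positive medium-scale difference (EQ minus pre) response confined to
  the segment VII ROI, while leaving whole-liver means and the ECV
  relation untouched.
* **Markers** — noisy monotone links ELF = 8 + 4 s, CPA = 2 + 25 s (%),
  Ishak = round(6 s), plus Gaussian noise; haematocrit is a truncated
  normal around 0.42.  Default scales put a mid-severity cohort in
  clinically plausible ranges (ECV ~0.22-0.37, ELF 8-12, CPA 2-27).

**Hepatocyte-loss mode** (off by default) adds a coarse background
texture to the parenchyma whose amplitude *decreases* with ``s`` — a
modelling hypothesis for why pre-contrast SD/entropy/MPP can fall as
fibrosis replaces textured hepatocellular tissue.  It exists so a
planted *negative* texture-vs-CPA association can be simulated, and is
a hypothesis of this generator, not a measured fact.

The ECV measurement emulates the clinical protocol of averaging ROI
means over three contiguous sections: each phantom carries
``n_ecv_sections`` noise realisations per phase (same anatomy and
enhancement, independent pixel noise); texture analysis always uses the
first (designated porta-level) section only.

All randomness flows from an explicit seed; equal seeds give bitwise
equal phantoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InputError
from .image_io import (
    CTSlice,
    ROIMask,
    write_clinical_table,
    write_mask,
    write_slice,
)
from .pipeline import PatientRecord

DIAMETER_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0))  # same convention as SSF -> sigma


@dataclass(frozen=True)
class PhantomParams:
    """Generator settings; the defaults define the standard study conditions."""

    shape: tuple[int, int] = (128, 128)
    spacing_mm: tuple[float, float] = (1.0, 1.0)
    severity: float = 0.5                     # s in [0, 1]

    # fibrotic features
    feature_diameter_mm: float = 4.0          # 1/e full width of a blob
    feature_density_base: float = 1.0         # blobs per cm^2 at s = 0
    feature_density_gain: float = 6.0         # additional blobs per cm^2 at s = 1
    blob_amplitude_hu: float = 12.0
    blob_amplitude_jitter: float = 0.2        # lognormal sigma of per-blob amplitude

    # parenchyma and noise
    parenchyma_mu_hu: float = 55.0
    noise_sd_hu: float = 10.0
    tissue_hu: float = 30.0                   # non-liver soft tissue
    tissue_enhancement_hu: float = 5.0

    # equilibrium enhancement / ECV truth
    ecv0: float = 0.22
    ecv_gain: float = 0.15                    # ecv_true = ecv0 + ecv_gain * s
    delta_hu_blood: float = 40.0
    blob_enhancement_gain: float = 1.5        # equilibrium gain per unit blob amplitude

    # septal rim along the segment VII watershed (equilibrium only)
    rim_amplitude_hu: float = 14.0            # local excess enhancement at s = 1
    rim_width_mm: float = 4.0
    rim_offset_mm: float = 4.0                # distance of band's inner edge from boundary
    rim_smooth_mm: float = 1.0

    # haematocrit draw (truncated normal)
    hct_mean: float = 0.42
    hct_sd: float = 0.03
    hct_bounds: tuple[float, float] = (0.25, 0.55)

    # vessels
    vessel_count: int = 3
    vessel_radius_mm: float = 2.0
    vessel_hu: float = 45.0                   # pre-contrast blood
    vessel_margin_px: int = 2                 # mask exclusion dilation

    # marker links (monotone in s by construction)
    elf_base: float = 8.0
    elf_gain: float = 4.0
    elf_noise_sd: float = 0.4
    cpa_base: float = 2.0
    cpa_gain: float = 25.0
    cpa_noise_sd: float = 2.0
    ishak_noise_sd: float = 0.5

    # hepatocyte-loss mode: declining background texture
    hepatocyte_loss: bool = False
    bg_texture_amp_hu: float = 12.0           # amplitude at s = 0 when mode is on
    bg_texture_scale_mm: float = 6.0
    hepatocyte_loss_gain: float = 0.7         # amp = amp0 * (1 - gain * s)

    # contiguous sections used for the ECV ROI means
    n_ecv_sections: int = 3

    def __post_init__(self) -> None:
        if not (0.0 <= self.severity <= 1.0):
            raise InputError(f"severity must lie in [0, 1], got {self.severity}")
        ecv_true = self.ecv0 + self.ecv_gain * self.severity
        if not (0.0 < ecv_true < 1.0):
            raise InputError(f"ecv_true {ecv_true:.3f} outside (0, 1)")
        for name in ("feature_density_base", "feature_density_gain", "blob_amplitude_hu",
                     "noise_sd_hu", "delta_hu_blood", "bg_texture_amp_hu",
                     "rim_amplitude_hu", "blob_enhancement_gain"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.n_ecv_sections < 1:
            raise InputError("n_ecv_sections must be >= 1")

    @property
    def ecv_true(self) -> float:
        return self.ecv0 + self.ecv_gain * self.severity


@dataclass
class Phantom:
    """One simulated patient: slice pair, masks, clinical record, truth.

    ``pre`` / ``eq`` are the designated texture-analysis sections;
    ``pre_sections`` / ``eq_sections`` additionally hold the contiguous
    sections (including the first) used for the ECV ROI means.
    """

    pre: CTSlice
    eq: Optional[CTSlice]
    masks: dict[str, ROIMask]
    record: PatientRecord
    truth: dict[str, float]
    pre_sections: list[CTSlice] = field(default_factory=list)
    eq_sections: list[CTSlice] = field(default_factory=list)


# ---------------------------------------------------------------------------
# geometry (fixed anatomy shared by every phantom)
# ---------------------------------------------------------------------------

def _geometry(shape: tuple[int, int]):
    nr, nc = shape
    rr, cc = np.mgrid[0:nr, 0:nc].astype(np.float64)
    liver_centre = (0.45 * nr, 0.5 * nc)
    liver_axes = (0.345 * nr, 0.42 * nc)
    u = (rr - liver_centre[0]) / liver_axes[0]
    v = (cc - liver_centre[1]) / liver_axes[1]
    rho = np.hypot(u, v)
    theta = np.arctan2(v, u)
    liver = rho <= 1.0
    # peripherally based wedge whose outer edge lies on the liver margin
    wedge = liver & (rho >= 0.45) & (theta >= -2.4) & (theta <= -0.9)
    aorta_centre = (0.875 * nr, 0.5 * nc)
    aorta_r_px = 0.055 * nr
    aorta = (rr - aorta_centre[0]) ** 2 + (cc - aorta_centre[1]) ** 2 <= aorta_r_px**2
    return liver, wedge, aorta, rho


def _paint_blobs(
    shape: tuple[int, int],
    spacing: tuple[float, float],
    liver: np.ndarray,
    rng: np.random.Generator,
    params: PhantomParams,
) -> tuple[np.ndarray, int]:
    """Additive field of Gaussian blobs with centres uniform in the liver."""
    area_cm2 = liver.sum() * spacing[0] * spacing[1] / 100.0
    density = params.feature_density_base + params.feature_density_gain * params.severity
    n_blobs = int(rng.poisson(density * area_cm2))
    fieldmap = np.zeros(shape, dtype=np.float64)
    if n_blobs == 0:
        return fieldmap, 0
    idx_r, idx_c = np.nonzero(liver)
    pick = rng.integers(0, idx_r.size, size=n_blobs)
    # sub-pixel jitter keeps blob centres off the lattice
    centres_r = idx_r[pick] + rng.uniform(-0.5, 0.5, n_blobs)
    centres_c = idx_c[pick] + rng.uniform(-0.5, 0.5, n_blobs)
    amps = params.blob_amplitude_hu * np.exp(
        rng.normal(0.0, params.blob_amplitude_jitter, n_blobs)
    )
    sig_r = params.feature_diameter_mm * DIAMETER_TO_SIGMA / spacing[0]
    sig_c = params.feature_diameter_mm * DIAMETER_TO_SIGMA / spacing[1]
    ext_r, ext_c = int(math.ceil(4 * sig_r)), int(math.ceil(4 * sig_c))
    nr, nc = shape
    for cr, cc_, amp in zip(centres_r, centres_c, amps):
        r0, r1 = max(0, int(cr) - ext_r), min(nr, int(cr) + ext_r + 1)
        c0, c1 = max(0, int(cc_) - ext_c), min(nc, int(cc_) + ext_c + 1)
        rloc = np.arange(r0, r1, dtype=np.float64)[:, None] - cr
        cloc = np.arange(c0, c1, dtype=np.float64)[None, :] - cc_
        fieldmap[r0:r1, c0:c1] += amp * np.exp(
            -(rloc**2 / (2 * sig_r**2) + cloc**2 / (2 * sig_c**2))
        )
    return fieldmap, n_blobs


def _septal_rim(
    wedge: np.ndarray,
    spacing: tuple[float, float],
    params: PhantomParams,
) -> np.ndarray:
    """Band of unit intensity inside the wedge along its boundary, smoothed."""
    dist = ndimage.distance_transform_edt(wedge, sampling=spacing)
    band = (dist > params.rim_offset_mm) & (
        dist <= params.rim_offset_mm + params.rim_width_mm
    )
    sig = (params.rim_smooth_mm / spacing[0], params.rim_smooth_mm / spacing[1])
    return ndimage.gaussian_filter(band.astype(np.float64), sigma=sig, mode="mirror")


def _bg_texture(
    shape: tuple[int, int],
    spacing: tuple[float, float],
    rng: np.random.Generator,
    params: PhantomParams,
) -> np.ndarray:
    """Unit-SD smoothed noise field at the background-texture scale."""
    raw = rng.normal(0.0, 1.0, shape)
    sig = (
        params.bg_texture_scale_mm * DIAMETER_TO_SIGMA / spacing[0],
        params.bg_texture_scale_mm * DIAMETER_TO_SIGMA / spacing[1],
    )
    smooth = ndimage.gaussian_filter(raw, sigma=sig, mode="mirror")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _place_vessels(
    liver_rho: np.ndarray,
    shape: tuple[int, int],
    spacing: tuple[float, float],
    rng: np.random.Generator,
    params: PhantomParams,
) -> np.ndarray:
    vessels = np.zeros(shape, dtype=bool)
    if params.vessel_count == 0:
        return vessels
    interior = liver_rho <= 0.75
    idx_r, idx_c = np.nonzero(interior)
    pick = rng.integers(0, idx_r.size, size=params.vessel_count)
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
    for cr, cc_ in zip(idx_r[pick], idx_c[pick]):
        dist2 = ((rr - cr) * spacing[0]) ** 2 + ((cc - cc_) * spacing[1]) ** 2
        vessels |= dist2 <= params.vessel_radius_mm**2
    return vessels


# ---------------------------------------------------------------------------
# single phantom
# ---------------------------------------------------------------------------

def generate_phantom(
    params: PhantomParams,
    seed: int | np.random.SeedSequence,
    patient_id: str = "p000",
    with_eq: bool = True,
) -> Phantom:
    """Generate one pre/equilibrium phantom with masks, markers and truth."""
    rng = np.random.default_rng(seed)
    shape, spacing = params.shape, params.spacing_mm
    s = params.severity

    liver, wedge, aorta, rho = _geometry(shape)
    vessels = _place_vessels(rho, shape, spacing, rng, params)
    vessels &= liver
    blobfield, n_blobs = _paint_blobs(shape, spacing, liver, rng, params)

    clean = np.full(shape, params.tissue_hu, dtype=np.float64)
    clean[liver] = params.parenchyma_mu_hu
    if params.hepatocyte_loss:
        amp = params.bg_texture_amp_hu * max(0.0, 1.0 - params.hepatocyte_loss_gain * s)
        if amp > 0:
            clean[liver] += amp * _bg_texture(shape, spacing, rng, params)[liver]
    else:
        # keep the RNG stream aligned across modes so cohorts differ only
        # in the background-texture term itself
        _ = _bg_texture(shape, spacing, rng, params)
    clean += blobfield
    clean[vessels] = params.vessel_hu
    clean[aorta] = params.vessel_hu - 5.0  # aortic blood, pre-contrast

    # masks exclude vessels with a safety margin
    if vessels.any():
        excl = ndimage.binary_dilation(vessels, iterations=params.vessel_margin_px)
    else:
        excl = vessels
    masks_arr = {
        "whole_liver": liver & ~excl,
        "segment7": wedge & ~excl,
        "aorta": aorta,
    }

    haematocrit = float(np.clip(rng.normal(params.hct_mean, params.hct_sd), *params.hct_bounds))
    ecv_true = params.ecv_true
    delta_liver_target = ecv_true * params.delta_hu_blood / (1.0 - haematocrit)

    # enhancement: uniform base + feature-bound + septal rim inside the
    # liver, constructed so the whole-liver ROI mean equals the target
    rimfield = _septal_rim(wedge, spacing, params)
    wl = masks_arr["whole_liver"]
    blob_mean = float(blobfield[wl].mean())
    rim_mean = float(rimfield[wl].mean())
    uniform = (
        delta_liver_target
        - params.blob_enhancement_gain * blob_mean
        - s * params.rim_amplitude_hu * rim_mean
    )
    if uniform < 0:
        raise InputError(
            f"enhancement base {uniform:.2f} HU < 0: feature/rim enhancement "
            "exceeds the ECV target; lower blob_enhancement_gain or rim_amplitude_hu"
        )
    enh = np.full(shape, params.tissue_enhancement_hu, dtype=np.float64)
    parenchyma = liver & ~vessels
    enh[parenchyma] = (
        uniform
        + params.blob_enhancement_gain * blobfield[parenchyma]
        + s * params.rim_amplitude_hu * rimfield[parenchyma]
    )
    enh[vessels] = params.delta_hu_blood
    enh[aorta] = params.delta_hu_blood

    def _noisy(base: np.ndarray) -> np.ndarray:
        if params.noise_sd_hu > 0:
            return base + rng.normal(0.0, params.noise_sd_hu, shape)
        return base.copy()

    pre_sections = [
        CTSlice(_noisy(clean), spacing, "pre", patient_id, f"section{i + 1}")
        for i in range(params.n_ecv_sections)
    ]
    eq_sections = [
        CTSlice(_noisy(clean + enh), spacing, "eq", patient_id, f"section{i + 1}")
        for i in range(params.n_ecv_sections)
    ] if with_eq else []
    pre = pre_sections[0]
    eq = eq_sections[0] if with_eq else None

    ref = eq if eq is not None else pre
    masks = {name: ROIMask.from_slice(arr, name, ref) for name, arr in masks_arr.items()}

    record = PatientRecord(
        patient_id=patient_id,
        haematocrit=haematocrit,
        cpa=float(max(0.0, params.cpa_base + params.cpa_gain * s
                      + rng.normal(0.0, params.cpa_noise_sd))),
        elf=float(params.elf_base + params.elf_gain * s + rng.normal(0.0, params.elf_noise_sd)),
        ishak=int(np.clip(round(6 * s + rng.normal(0.0, params.ishak_noise_sd)), 0, 6)),
    )
    truth = {
        "severity": s,
        "ecv_true": ecv_true,
        "delta_hu_liver": delta_liver_target,
        "delta_hu_blood": params.delta_hu_blood,
        "n_blobs": float(n_blobs),
    }
    return Phantom(
        pre=pre, eq=eq, masks=masks, record=record, truth=truth,
        pre_sections=pre_sections, eq_sections=eq_sections,
    )


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def uniform_severity(rng: np.random.Generator, n: int) -> np.ndarray:
    """Default severity sampler: iid Uniform(0, 1)."""
    return rng.uniform(0.0, 1.0, n)


def simulate_cohort(
    n: int,
    seed: int,
    params: PhantomParams = PhantomParams(),
    severity_sampler: Callable[[np.random.Generator, int], np.ndarray] = uniform_severity,
    eq_missing_fraction: float = 0.0,
    out_dir: Optional[str | Path] = None,
) -> list[Phantom]:
    """Simulate an ``n``-patient cohort; optionally write it to disk.

    Exactly ``round(n * eq_missing_fraction)`` patients lack equilibrium
    imaging (assignment drawn deterministically from the master seed), so
    n = 29 with fraction 8/29 yields exactly 21 equilibrium datasets.
    Per-patient seeds are spawned from the master seed; the same master
    seed reproduces the cohort bitwise.

    With ``out_dir`` set, writes NIfTI images and masks plus
    ``manifest.csv`` and ``clinical.csv`` in the layout the extraction
    pipeline consumes.
    """
    if n < 2:
        raise InputError("cohort needs n >= 2")
    if not (0.0 <= eq_missing_fraction < 1.0):
        raise InputError("eq_missing_fraction must lie in [0, 1)")
    master = np.random.SeedSequence(seed)
    children = master.spawn(n + 1)
    rng = np.random.default_rng(children[0])
    severities = np.asarray(severity_sampler(rng, n), dtype=np.float64)
    if severities.shape != (n,):
        raise InputError("severity sampler must return n values")
    n_missing = int(round(n * eq_missing_fraction))
    missing = np.zeros(n, dtype=bool)
    missing[rng.permutation(n)[:n_missing]] = True

    return [
        generate_phantom(
            replace(params, severity=float(np.clip(severities[i], 0.0, 1.0))),
            seed=children[i + 1],
            patient_id=f"p{i + 1:03d}",
            with_eq=not missing[i],
        )
        for i in range(n)
    ] if out_dir is None else _simulate_and_write(
        n, children, severities, missing, params, out_dir
    )


def _simulate_and_write(n, children, severities, missing, params, out_dir):
    cohort = [
        generate_phantom(
            replace(params, severity=float(np.clip(severities[i], 0.0, 1.0))),
            seed=children[i + 1],
            patient_id=f"p{i + 1:03d}",
            with_eq=not missing[i],
        )
        for i in range(n)
    ]
    write_cohort(cohort, out_dir)
    return cohort


def write_cohort(cohort: Sequence[Phantom], out_dir: str | Path) -> Path:
    """Write images, masks, manifest.csv and clinical.csv for a cohort.

    Contiguous extra sections (for the ECV means) are written alongside
    the main slices and referenced from the manifest's ``pre_extra_paths``
    / ``eq_extra_paths`` columns as ';'-joined lists.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_rows, clinical_rows = [], []
    for ph in cohort:
        pid = ph.record.patient_id
        pre_path = out / f"{pid}_pre.nii.gz"
        write_slice(ph.pre, pre_path)
        pre_extra = []
        for i, s in enumerate(ph.pre_sections[1:], start=2):
            p = out / f"{pid}_pre_s{i}.nii.gz"
            write_slice(s, p)
            pre_extra.append(str(p))
        eq_path, eq_extra = "", []
        if ph.eq is not None:
            eq_path = str(out / f"{pid}_eq.nii.gz")
            write_slice(ph.eq, eq_path)
            for i, s in enumerate(ph.eq_sections[1:], start=2):
                p = out / f"{pid}_eq_s{i}.nii.gz"
                write_slice(s, p)
                eq_extra.append(str(p))
        mask_paths = {}
        for region, mask in ph.masks.items():
            p = out / f"{pid}_mask_{region}.nii.gz"
            write_mask(mask, p)
            mask_paths[region] = str(p)
        manifest_rows.append(
            {
                "patient_id": pid,
                "pre_path": str(pre_path),
                "eq_path": eq_path,
                "whole_liver_path": mask_paths["whole_liver"],
                "segment7_path": mask_paths["segment7"],
                "aorta_path": mask_paths["aorta"],
                "pre_extra_paths": ";".join(pre_extra),
                "eq_extra_paths": ";".join(eq_extra),
            }
        )
        rec = ph.record
        clinical_rows.append(
            {
                "patient_id": pid,
                "haematocrit": rec.haematocrit,
                "cpa_percent": rec.cpa,
                "elf": rec.elf,
                "ishak": rec.ishak,
            }
        )
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    write_clinical_table(pd.DataFrame(clinical_rows), out / "clinical.csv")
    return out
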