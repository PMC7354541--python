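"""Histogram statistics of a filtered map inside an ROI.

Six statistics per (ROI, phase, SSF): mean, standard deviation, entropy,
mean of the positive pixels (MPP), skewness and kurtosis.  Conventions
(all configurable, defaults documented in docs/methods.md):

* moments use the population divisor ``n``;
* skewness is Fisher-Pearson g1 = m3 / m2^1.5, kurtosis is *excess*
  g2 = m4 / m2^2 - 3 (Gaussian -> 0);
* entropy is Shannon entropy in bits of the 256-bin equal-width histogram
  spanning the observed [min, max] of the sampled values, with
  0*log(0) := 0; a constant region has entropy 0;
* MPP averages strictly positive values (v > 0); if none exist the value
  is 0 and the vector is flagged ``no_positive_pixels`` so feature tables
  stay rectangular;
* a zero-variance region gets skewness = kurtosis = 0 with a
  ``zero_variance`` flag rather than NaN.

The per-phase vectors subtract metric-wise (equilibrium minus
pre-contrast) to form the ``diff`` phase, the subtracted-enhancement
texture signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import GeometryError, PairingError, SamplingError
from .filtration import FilteredMap, erode_mask
from .image_io import ROIMask

METRIC_ORDER = ("mean", "sd", "entropy", "mpp", "skewness", "kurtosis")

DEFAULT_BINS = 256
DEFAULT_MIN_PIXELS = 50


@dataclass(frozen=True)
class TextureVector:
    """The six histogram statistics at one (region, phase, SSF)."""

    ssf_mm: float
    region: str
    phase: str  # pre | eq | diff
    mean: float
    sd: float
    entropy: float
    mpp: float
    skewness: float
    kurtosis: float
    n_pixels: int
    flags: frozenset = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in METRIC_ORDER}


def _entropy_bits(values: np.ndarray, bins: int) -> float:
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        return 0.0
    counts, _ = np.histogram(values, bins=bins, range=(lo, hi))
    p = counts[counts > 0] / values.size
    return float(-(p * np.log2(p)).sum())


def compute_metrics(
    fmap: FilteredMap,
    mask: ROIMask,
    *,
    bins: int = DEFAULT_BINS,
    min_pixels: int = DEFAULT_MIN_PIXELS,
    excess_kurtosis: bool = True,
    erode: bool = True,
    population: bool = True,
) -> TextureVector:
    """Compute the six statistics over the masked filter responses.

    With ``erode=True`` (default) the mask is first shrunk by
    ceil(2*sigma) pixels (see :func:`eqctta.filtration.erode_mask`); at
    SSF = 0 no erosion happens.  ``population=False`` switches SD,
    skewness and kurtosis to the sample-corrected estimators (ddof-1 SD,
    adjusted Fisher-Pearson G1/G2); the population convention is the
    default because ROIs hold thousands of pixels and the uncorrected
    moments match the plain histogram definitions.  Raises
    :class:`GeometryError` if the mask is empty after erosion and
    :class:`SamplingError` if fewer than ``min_pixels`` pixels remain.
    """
    if mask.ref_shape != fmap.pixels.shape:
        raise GeometryError("mask lattice does not match filtered map")
    sampled = erode_mask(mask, fmap.ssf) if erode else mask.mask
    n = int(sampled.sum())
    if n == 0:
        raise GeometryError(f"mask {mask.region!r} empty after erosion at SSF {fmap.ssf.ssf_mm} mm")
    if n < min_pixels:
        raise SamplingError(
            f"only {n} pixels in {mask.region!r} at SSF {fmap.ssf.ssf_mm} mm "
            f"(minimum {min_pixels})"
        )
    v = fmap.pixels[sampled]
    flags: set[str] = set()

    mean = float(v.mean())
    centred = v - mean
    m2 = float(np.mean(centred**2))
    sd = float(np.sqrt(m2))

    if m2 == 0.0:
        flags.add("zero_variance")
        skew = kurt = 0.0
        entropy = 0.0
    else:
        m3 = float(np.mean(centred**3))
        m4 = float(np.mean(centred**4))
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - (3.0 if excess_kurtosis else 0.0)
        if not population:
            sd = float(np.sqrt(m2 * n / (n - 1)))
            skew = skew * math.sqrt(n * (n - 1)) / (n - 2)
            g2 = m4 / m2**2 - 3.0
            G2 = ((n - 1) / ((n - 2) * (n - 3))) * ((n + 1) * g2 + 6.0)
            kurt = G2 + (0.0 if excess_kurtosis else 3.0)
        entropy = _entropy_bits(v, bins)

    pos = v[v > 0]
    if pos.size == 0:
        flags.add("no_positive_pixels")
        mpp = 0.0
    else:
        mpp = float(pos.mean())

    return TextureVector(
        ssf_mm=fmap.ssf.ssf_mm,
        region=mask.region,
        phase=fmap.source.phase,
        mean=mean,
        sd=sd,
        entropy=entropy,
        mpp=mpp,
        skewness=skew,
        kurtosis=kurt,
        n_pixels=n,
        flags=frozenset(flags),
    )


def subtract_features(eq: TextureVector, pre: TextureVector) -> TextureVector:
    """Metric-wise difference (equilibrium minus pre-contrast).

    Both vectors must refer to the same SSF and region with phases ``eq``
    and ``pre``; the result carries phase ``diff`` and the union of the
    operand flags.  Antisymmetric by construction.
    """
    if eq.ssf_mm != pre.ssf_mm or eq.region != pre.region:
        raise PairingError(
            f"cannot pair ({eq.region}, SSF {eq.ssf_mm}) with ({pre.region}, SSF {pre.ssf_mm})"
        )
    if eq.phase != "eq" or pre.phase != "pre":
        raise PairingError(f"expected phases (eq, pre), got ({eq.phase}, {pre.phase})")
    return TextureVector(
        ssf_mm=eq.ssf_mm,
        region=eq.region,
        phase="diff",
        mean=eq.mean - pre.mean,
        sd=eq.sd - pre.sd,
        entropy=eq.entropy - pre.entropy,
        mpp=eq.mpp - pre.mpp,
        skewness=eq.skewness - pre.skewness,
        kurtosis=eq.kurtosis - pre.kurtosis,
        n_pixels=min(eq.n_pixels, pre.n_pixels),
        flags=eq.flags | pre.flags,
    )


def to_long_rows(vectors: Iterable[TextureVector], patient_id: str) -> list[dict]:
    """Serialize texture vectors to long-format feature rows."""
    rows = []
    for tv in vectors:
        for metric in METRIC_ORDER:
            rows.append(
                {
                    "patient_id": patient_id,
                    "region": tv.region,
                    "phase": tv.phase,
                    "ssf_mm": tv.ssf_mm,
                    "metric": metric,
                    "value": getattr(tv, metric),
                    "flags": "|".join(sorted(tv.flags)),
                }
            )
    return rows
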