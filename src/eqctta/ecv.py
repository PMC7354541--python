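"""Extracellular volume fraction (ECV) from equilibrium contrast CT.

Iodinated contrast distributes in the extracellular, extravascular space.
At contrast steady state the ratio of attenuation change in tissue to the
change in blood is the partition coefficient; multiplying by the plasma
fraction (1 - haematocrit) converts it to the tissue extracellular volume
fraction:

    ECV_liver = (1 - haematocrit) * (dHU_liver / dHU_blood)

where each dHU is (equilibrium - pre-contrast) mean ROI attenuation, the
liver dHU from a parenchymal ROI and the blood dHU from an aortic ROI.
ECV expands with fibrosis, making it an imaging biomarker of fibrotic
burden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EnhancementError, GeometryError, InputError
from .image_io import CTSlice, ROIMask

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ECVResult:
    """ECV for one patient with the quantities that produced it."""

    ecv: float
    delta_hu_liver: float
    delta_hu_blood: float
    haematocrit: float
    patient_id: str = ""
    flags: frozenset = frozenset()


def roi_mean_hu(slc: CTSlice, mask: ROIMask) -> float:
    """Mean HU over the ROI, with no erosion.

    This mirrors the clinical mean-attenuation measurement, which uses
    the drawn ROI as-is; erosion is a texture-sampling concern only.
    """
    if mask.ref_shape != slc.shape:
        raise GeometryError("mask lattice does not match slice")
    return float(slc.pixels[mask.mask].mean())


def multi_slice_mean_hu(slices: Sequence[CTSlice], mask: ROIMask) -> float:
    """Average of per-slice ROI means across contiguous sections.

    When several contiguous sections are provided per phase, per-section
    ROI means are averaged (unweighted) before the ECV formula.
    """
    if len(slices) == 0:
        raise InputError("no slices provided")
    return float(np.mean([roi_mean_hu(s, mask) for s in slices]))


def _normalise_haematocrit(haematocrit: float) -> float:
    if not np.isfinite(haematocrit):
        raise InputError("haematocrit is not finite")
    if 1.0 <= haematocrit <= 100.0:
        logger.info("haematocrit %.3g interpreted as percent -> %.3g", haematocrit, haematocrit / 100)
        haematocrit = haematocrit / 100.0
    if not (0.0 < haematocrit < 1.0):
        raise InputError(f"haematocrit must lie in (0, 1), got {haematocrit}")
    return haematocrit


def compute_ecv(
    pre_liver: float,
    eq_liver: float,
    pre_blood: float,
    eq_blood: float,
    haematocrit: float,
    patient_id: str = "",
) -> ECVResult:
    """ECV = (1 - haematocrit) * dHU_liver / dHU_blood.

    Deltas are (equilibrium - pre-contrast).  A non-positive blood delta
    means the blood pool did not enhance — failed equilibrium or swapped
    ROIs — and raises :class:`EnhancementError`.  A result outside [0, 1]
    is physiologically impossible and is returned with an
    ``ecv_out_of_range`` flag, never clipped.  Haematocrit given in
    percent (values in [1, 100]) is converted to a fraction with a logged
    note.
    """
    haematocrit = _normalise_haematocrit(haematocrit)
    delta_liver = eq_liver - pre_liver
    delta_blood = eq_blood - pre_blood
    if delta_blood <= 0:
        raise EnhancementError(
            f"blood delta-HU {delta_blood:.2f} <= 0: equilibrium enhancement failed "
            "or liver/aorta ROIs are swapped"
        )
    ecv = (1.0 - haematocrit) * delta_liver / delta_blood
    flags: set[str] = set()
    if not (0.0 <= ecv <= 1.0):
        flags.add("ecv_out_of_range")
        logger.warning("patient %s: ECV %.3f outside [0, 1]", patient_id or "?", ecv)
    return ECVResult(
        ecv=ecv,
        delta_hu_liver=delta_liver,
        delta_hu_blood=delta_blood,
        haematocrit=haematocrit,
        patient_id=patient_id,
        flags=frozenset(flags),
    )
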