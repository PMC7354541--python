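"""Per-patient extraction and cohort feature-table assembly.

For each patient the pipeline computes texture vectors for every
available combination of ROI (whole liver, segment VII), phase
(pre-contrast, equilibrium, and their metric-wise difference) and SSF,
plus the ECV when both phases, an aortic ROI and a haematocrit are
available.  Partial data is first-class: a patient with only a
pre-contrast slice contributes pre-phase features and missing values in
the difference/ECV columns — the clinical reality this mirrors is a
cohort with pre-contrast imaging for all patients but equilibrium-phase
imaging for only a subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .ecv import ECVResult, compute_ecv, multi_slice_mean_hu
from .errors import InputError
from .filtration import DEFAULT_SSF_MM, filter_slice
from .image_io import CTSlice, ROIMask, check_registration, copy_roi, masks_disjoint
from .metrics import (
    METRIC_ORDER,
    TextureVector,
    compute_metrics,
    subtract_features,
    to_long_rows,
)

logger = logging.getLogger(__name__)

TEXTURE_REGIONS = ("whole_liver", "segment7")
PHASE_ORDER = ("pre", "eq", "diff")

MARKER_COLUMNS = ("haematocrit", "cpa_percent", "elf", "ishak", "ecv")


@dataclass
class PatientRecord:
    """One row of the clinical table; ecv is derived by the pipeline."""

    patient_id: str
    haematocrit: Optional[float] = None  # fraction in (0, 1)
    cpa: Optional[float] = None          # collagen proportionate area, %
    elf: Optional[float] = None          # enhanced liver fibrosis score
    ishak: Optional[int] = None          # histological stage 0..6
    ecv: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ishak is not None and not (0 <= self.ishak <= 6):
            raise InputError(f"ishak stage {self.ishak} outside 0..6")
        if self.cpa is not None and self.cpa < 0:
            raise InputError(f"cpa {self.cpa} must be >= 0")


@dataclass
class PatientFeatures:
    """Extraction output for one patient."""

    record: PatientRecord
    textures: list[TextureVector] = field(default_factory=list)
    ecv_result: Optional[ECVResult] = None
    skipped: list[str] = field(default_factory=list)


def _mask_on(mask: ROIMask, slc: CTSlice) -> Optional[ROIMask]:
    try:
        return copy_roi(mask, slc)
    except Exception:
        return None


def extract_patient(
    pre: CTSlice,
    eq: Optional[CTSlice],
    masks: dict[str, ROIMask],
    record: PatientRecord,
    ssf_list: Sequence[float] = DEFAULT_SSF_MM,
    *,
    bins: int = 256,
    min_pixels: int = 50,
    erode: bool = True,
    excess_kurtosis: bool = True,
    pre_sections: Optional[Sequence[CTSlice]] = None,
    eq_sections: Optional[Sequence[CTSlice]] = None,
) -> PatientFeatures:
    """Run filtration + histogram statistics for one patient.

    ``masks`` maps region name to an ROIMask drawn on either phase (the
    clinical convention is to draw on the equilibrium images and copy to
    pre-contrast; any mask whose lattice matches both phases works).
    Registration failure between phases downgrades the patient to
    single-phase features with a logged skip — it never aborts the
    cohort.

    ``pre_sections`` / ``eq_sections`` optionally supply the contiguous
    sections used for the ECV ROI means (per-section means are
    averaged, mirroring the clinical multi-section measurement); texture
    always uses the designated single slices ``pre`` / ``eq``.
    """
    out = PatientFeatures(record=record)

    registered = eq is not None and check_registration(pre, eq)
    if eq is not None and not registered:
        msg = f"{record.patient_id}: pre/eq not registered; diff and ECV skipped"
        logger.warning(msg)
        out.skipped.append(msg)

    if "aorta" in masks and "whole_liver" in masks:
        wl = masks["whole_liver"]
        ao = masks["aorta"]
        if wl.ref_shape == ao.ref_shape and not masks_disjoint(wl, ao):
            raise InputError(f"{record.patient_id}: aorta and liver ROIs overlap")

    phases: list[CTSlice] = [pre] + ([eq] if eq is not None else [])
    by_phase: dict[tuple[str, str, float], TextureVector] = {}
    for region in TEXTURE_REGIONS:
        if region not in masks:
            continue
        for slc in phases:
            mask = _mask_on(masks[region], slc)
            if mask is None:
                msg = f"{record.patient_id}: mask {region} does not fit {slc.phase} lattice; skipped"
                logger.warning(msg)
                out.skipped.append(msg)
                continue
            for ssf in ssf_list:
                fmap = filter_slice(slc, ssf)
                tv = compute_metrics(
                    fmap, mask, bins=bins, min_pixels=min_pixels,
                    erode=erode, excess_kurtosis=excess_kurtosis,
                )
                by_phase[(region, slc.phase, float(ssf))] = tv
                out.textures.append(tv)

    if registered:
        for (region, phase, ssf), tv in list(by_phase.items()):
            if phase != "eq":
                continue
            pre_tv = by_phase.get((region, "pre", ssf))
            if pre_tv is not None:
                out.textures.append(subtract_features(tv, pre_tv))

    # ECV needs both phases, liver + aorta ROIs on each, and haematocrit
    if registered and record.haematocrit is not None and \
            "whole_liver" in masks and "aorta" in masks:
        wl_pre, wl_eq = _mask_on(masks["whole_liver"], pre), _mask_on(masks["whole_liver"], eq)
        ao_pre, ao_eq = _mask_on(masks["aorta"], pre), _mask_on(masks["aorta"], eq)
        if None not in (wl_pre, wl_eq, ao_pre, ao_eq):
            pre_secs = list(pre_sections) if pre_sections else [pre]
            eq_secs = list(eq_sections) if eq_sections else [eq]
            if not all(check_registration(s, pre) for s in pre_secs) or not all(
                check_registration(s, eq) for s in eq_secs
            ):
                raise InputError(f"{record.patient_id}: extra ECV sections not registered")
            out.ecv_result = compute_ecv(
                pre_liver=multi_slice_mean_hu(pre_secs, wl_pre),
                eq_liver=multi_slice_mean_hu(eq_secs, wl_eq),
                pre_blood=multi_slice_mean_hu(pre_secs, ao_pre),
                eq_blood=multi_slice_mean_hu(eq_secs, ao_eq),
                haematocrit=record.haematocrit,
                patient_id=record.patient_id,
            )
            record.ecv = out.ecv_result.ecv
    elif record.haematocrit is None and registered:
        msg = f"{record.patient_id}: no haematocrit; ECV skipped"
        logger.warning(msg)
        out.skipped.append(msg)

    return out


def feature_column(region: str, phase: str, ssf_mm: float, metric: str) -> str:
    return f"{region}_{phase}_ssf{ssf_mm:g}_{metric}"


def parse_feature_column(name: str) -> Optional[tuple[str, str, float, str]]:
    """Invert :func:`feature_column`; None if the column is not a feature."""
    parts = name.split("_")
    # region may itself contain "_" (whole_liver); scan for the phase token
    for i in range(1, len(parts) - 2):
        if parts[i] in PHASE_ORDER and parts[i + 1].startswith("ssf"):
            region = "_".join(parts[:i])
            phase = parts[i]
            try:
                ssf = float(parts[i + 1][3:])
            except ValueError:
                return None
            metric = "_".join(parts[i + 2:])
            if metric in METRIC_ORDER:
                return region, phase, ssf, metric
    return None


def build_feature_table(patients: Sequence[PatientFeatures]) -> pd.DataFrame:
    """Assemble the rectangular cohort feature table.

    One row per patient (sorted by id), one column per
    (region, phase, SSF, metric) in deterministic order — region, then
    phase (pre, eq, diff), then SSF ascending, then metric in the
    conventional order mean/SD/entropy/MPP/skewness/kurtosis — followed
    by the clinical marker columns.  Missing combinations (e.g. diff
    features for a patient without equilibrium imaging) are NaN.
    """
    if len(patients) < 2:
        raise InputError("need at least 2 patients to build a cohort table")
    ids = [p.record.patient_id for p in patients]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise InputError(f"duplicate patient_id: {dupes}")

    rows: dict[str, dict[str, float]] = {}
    seen: set[tuple[str, str, float]] = set()
    for p in patients:
        row: dict[str, float] = {}
        for tv in p.textures:
            seen.add((tv.region, tv.phase, tv.ssf_mm))
            for metric in METRIC_ORDER:
                row[feature_column(tv.region, tv.phase, tv.ssf_mm, metric)] = getattr(tv, metric)
        rec = p.record
        row["haematocrit"] = np.nan if rec.haematocrit is None else rec.haematocrit
        row["cpa_percent"] = np.nan if rec.cpa is None else rec.cpa
        row["elf"] = np.nan if rec.elf is None else rec.elf
        row["ishak"] = np.nan if rec.ishak is None else rec.ishak
        row["ecv"] = rec.ecv if rec.ecv is not None else np.nan
        rows[rec.patient_id] = row

    regions = [r for r in TEXTURE_REGIONS if any(k[0] == r for k in seen)]
    ssfs = sorted({k[2] for k in seen})
    columns = [
        feature_column(region, phase, ssf, metric)
        for region in regions
        for phase in PHASE_ORDER
        for ssf in ssfs
        for metric in METRIC_ORDER
        if (region, phase, ssf) in seen
    ]
    columns += list(MARKER_COLUMNS)

    table = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=columns)
    table.index.name = "patient_id"
    return table.sort_index()


def features_long_table(patients: Sequence[PatientFeatures]) -> pd.DataFrame:
    """Long-format serialization of every texture vector in the cohort."""
    rows: list[dict] = []
    for p in sorted(patients, key=lambda q: q.record.patient_id):
        rows.extend(to_long_rows(p.textures, p.record.patient_id))
    return pd.DataFrame(
        rows, columns=["patient_id", "region", "phase", "ssf_mm", "metric", "value", "flags"]
    )


def ecv_table(patients: Sequence[PatientFeatures]) -> pd.DataFrame:
    """Per-patient ECV results (patients without ECV are NaN rows)."""
    rows = []
    for p in sorted(patients, key=lambda q: q.record.patient_id):
        r = p.ecv_result
        rows.append(
            {
                "patient_id": p.record.patient_id,
                "ecv": r.ecv if r else np.nan,
                "delta_hu_liver": r.delta_hu_liver if r else np.nan,
                "delta_hu_blood": r.delta_hu_blood if r else np.nan,
                "haematocrit": r.haematocrit if r else (p.record.haematocrit or np.nan),
                "flags": "|".join(sorted(r.flags)) if r else "",
            }
        )
    return pd.DataFrame(rows)
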