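"""End-to-end workflow: load or simulate a cohort, extract, correlate, report.

``run_pipeline`` produces, under the configured output directory:

* ``features.csv`` — wide cohort feature table (one row per patient),
* ``features_long.csv`` — long-format texture vectors,
* ``ecv.csv`` — per-patient ECV with its components,
* ``correlations_long.csv`` / ``correlations_wide.csv`` — Spearman
  association tables (the wide layout mirrors the conventional
  SSF-block x metric report),
* ``summary.txt`` — human-readable digest of significant associations,
* ``run.log`` — provenance: package version, config echo + hash, seeds,
  per-patient skips.

Any stage failure aborts the run and removes partial outputs, so an
output directory either holds a complete, reproducible report bundle or
nothing.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .config import RunConfig
from .errors import InputError
from .image_io import read_clinical_table, read_mask, read_slice
from .pipeline import (
    PatientFeatures,
    PatientRecord,
    build_feature_table,
    ecv_table,
    extract_patient,
    features_long_table,
)
from .stats import correlate_features, correlations_wide
from .synthetic import Phantom, PhantomParams, simulate_cohort

logger = logging.getLogger(__name__)

REPORT_FILES = (
    "features.csv",
    "features_long.csv",
    "ecv.csv",
    "correlations_long.csv",
    "correlations_wide.csv",
    "summary.txt",
)


def _opt(v) -> Optional[float]:
    try:
        v = float(v)
    except (TypeError, ValueError):
        return None
    return None if pd.isna(v) else v


def load_cohort(manifest_path: str | Path, clinical_path: str | Path):
    """Read a manifest + clinical CSV pair into per-patient inputs.

    Yields ``(record, pre, eq, masks, pre_sections, eq_sections)``
    tuples ready for :func:`eqctta.pipeline.extract_patient`.
    """
    manifest = pd.read_csv(manifest_path, dtype=str).fillna("")
    clinical = read_clinical_table(clinical_path).set_index("patient_id")
    for _, row in manifest.iterrows():
        pid = str(row["patient_id"])
        if pid not in clinical.index:
            raise InputError(f"manifest patient {pid} missing from clinical table")
        crow = clinical.loc[pid]
        ishak = _opt(crow["ishak"])
        record = PatientRecord(
            patient_id=pid,
            haematocrit=_opt(crow["haematocrit"]),
            cpa=_opt(crow["cpa_percent"]),
            elf=_opt(crow["elf"]),
            ishak=None if ishak is None else int(ishak),
        )
        pre = read_slice(row["pre_path"], "pre", patient_id=pid)
        eq = read_slice(row["eq_path"], "eq", patient_id=pid) if row.get("eq_path") else None
        ref = eq if eq is not None else pre
        masks = {
            region: read_mask(row[f"{region}_path"], region, ref)
            for region in ("whole_liver", "segment7", "aorta")
            if row.get(f"{region}_path")
        }
        pre_secs = [pre] + [
            read_slice(p, "pre", patient_id=pid)
            for p in str(row.get("pre_extra_paths", "")).split(";") if p
        ]
        eq_secs = ([eq] + [
            read_slice(p, "eq", patient_id=pid)
            for p in str(row.get("eq_extra_paths", "")).split(";") if p
        ]) if eq is not None else []
        yield record, pre, eq, masks, pre_secs, eq_secs


def extract_cohort(
    cohort_inputs,
    config: RunConfig,
) -> list[PatientFeatures]:
    """Run per-patient extraction over loaded or simulated inputs."""
    out = []
    for record, pre, eq, masks, pre_secs, eq_secs in cohort_inputs:
        out.append(
            extract_patient(
                pre, eq, masks, record, config.ssf_list,
                bins=config.entropy_bins,
                min_pixels=config.min_pixels,
                erode=config.erosion,
                excess_kurtosis=config.excess_kurtosis,
                pre_sections=pre_secs or None,
                eq_sections=eq_secs or None,
            )
        )
    return out


def phantoms_as_inputs(cohort: Sequence[Phantom]):
    for ph in cohort:
        yield ph.record, ph.pre, ph.eq, ph.masks, ph.pre_sections, ph.eq_sections


def render_summary(corr_long: pd.DataFrame, alpha: float) -> str:
    """Digest of significant feature-marker associations, strongest first."""
    lines = [
        "Significant Spearman associations (p <= %.3g, no multiplicity correction)" % alpha,
        "=" * 74,
    ]
    sig = corr_long[corr_long["significant"]].copy()
    if sig.empty:
        lines.append("(none)")
    else:
        sig = sig.reindex(sig["r_s"].abs().sort_values(ascending=False).index)
        for _, r in sig.iterrows():
            lines.append(
                f"{r['region']:<12} {r['phase']:<5} SSF {r['ssf_mm']:>3g} mm "
                f"{r['metric']:<9} vs {r['marker']:<11} "
                f"r_s = {r['r_s']:+.3f}  p = {r['p_value']:.4g}  (n = {r['n']})"
            )
    lines.append("")
    lines.append(f"{len(sig)} of {len(corr_long)} feature-marker pairs significant.")
    return "\n".join(lines)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full workflow; returns the paths of the report bundle."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_path = out_dir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("eqctta")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    written: list[Path] = []
    try:
        logger.info("eqctta %s | config %s", __version__, config.digest())
        for key, val in sorted(config.to_dict().items()):
            logger.info("config %s = %r", key, val)

        if config.manifest:
            if not config.clinical:
                raise InputError("manifest given without clinical table")
            inputs = list(load_cohort(config.manifest, config.clinical))
            logger.info("loaded cohort of %d patients from %s", len(inputs), config.manifest)
        else:
            params = PhantomParams(hepatocyte_loss=config.hepatocyte_loss)
            cohort = simulate_cohort(
                config.n_patients, config.seed, params=params,
                eq_missing_fraction=config.eq_missing_fraction,
            )
            inputs = list(phantoms_as_inputs(cohort))
            logger.info(
                "simulated cohort: n=%d seed=%d eq_missing=%.3f",
                config.n_patients, config.seed, config.eq_missing_fraction,
            )

        patients = extract_cohort(inputs, config)
        for p in patients:
            for msg in p.skipped:
                logger.warning("skip: %s", msg)

        table = build_feature_table(patients)
        corr = correlate_features(
            table, markers=config.markers, alpha=config.alpha,
            benjamini_hochberg=config.benjamini_hochberg,
        )
        paths = {
            "features": out_dir / "features.csv",
            "features_long": out_dir / "features_long.csv",
            "ecv": out_dir / "ecv.csv",
            "correlations_long": out_dir / "correlations_long.csv",
            "correlations_wide": out_dir / "correlations_wide.csv",
            "summary": out_dir / "summary.txt",
            "log": log_path,
        }
        table.to_csv(paths["features"])
        written.append(paths["features"])
        features_long_table(patients).to_csv(paths["features_long"], index=False)
        written.append(paths["features_long"])
        ecv_table(patients).to_csv(paths["ecv"], index=False)
        written.append(paths["ecv"])
        corr.to_csv(paths["correlations_long"], index=False)
        written.append(paths["correlations_long"])
        correlations_wide(corr).to_csv(paths["correlations_wide"])
        written.append(paths["correlations_wide"])
        summary = render_summary(corr, config.alpha)
        paths["summary"].write_text(summary + "\n")
        written.append(paths["summary"])
        logger.info("report bundle complete in %s", out_dir)
        return paths
    except Exception:
        for p in written:  # leave no partial bundle behind
            try:
                p.unlink()
            except OSError:
                pass
        logger.exception("pipeline failed; partial outputs removed")
        raise
    finally:
        root.removeHandler(handler)
        handler.close()
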