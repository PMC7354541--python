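"""Spearman rank-correlation of texture features against fibrosis markers.

Every feature column of the cohort table — (region, phase, SSF, metric) —
is correlated against each clinical marker (CPA, ECV, ELF, Ishak) with
Spearman's r_s on pairwise-complete cases, and an association is flagged
significant at p <= alpha (default 0.05).  *No* multiple-testing
correction is applied by default: the filter scales are strongly
dependent, so independence-assuming corrections such as Bonferroni are
deliberately not used; an optional Benjamini-Hochberg column can be
switched on for sensitivity checks.

The p-value uses the t-distribution approximation
t = r_s * sqrt((n-2)/(1-r_s^2)) with n-2 degrees of freedom (two-sided),
adequate at the cohort sizes involved (n <= ~30); an exact permutation
option exists for tiny n.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, UndefinedCorrelationError
from .pipeline import parse_feature_column

logger = logging.getLogger(__name__)

DEFAULT_MARKERS = ("cpa_percent", "ecv", "elf", "ishak")
DEFAULT_ALPHA = 0.05
MIN_PAIRS = 3


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average-rank ties and a t-approx p.

    Returns ``(r_s, p_value)``.  For a perfectly monotone sample
    (|r_s| = 1) the t statistic diverges; the p-value reported is the
    two-sided permutation bound 2/n! (floored at the smallest positive
    float).  Zero variance in either vector leaves the correlation
    undefined and raises :class:`UndefinedCorrelationError`.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise InputError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < MIN_PAIRS:
        raise InputError(f"need at least {MIN_PAIRS} pairs, got {n}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise InputError("inputs must be finite (drop missing pairs first)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance: ranks are all tied")
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) >= 1.0 - 1e-14:
        r = math.copysign(1.0, r)
        if n <= 170:
            p = max(2.0 / math.factorial(n), np.finfo(float).tiny)
        else:
            p = float(np.finfo(float).tiny)
        return r, p
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 2))
    return r, min(1.0, p)


def spearman_exact(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Exact permutation p-value (n <= 10); r_s as in :func:`spearman`."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    if n > 10:
        raise InputError("exact permutation p only supported for n <= 10")
    r_obs, _ = spearman(x, y)
    rx = sps.rankdata(x, method="average")
    ry = sps.rankdata(y, method="average")
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        count += abs(r) >= abs(r_obs) - 1e-12
        total += 1
    return r_obs, count / total


def correlate_features(
    table: pd.DataFrame,
    markers: Sequence[str] = DEFAULT_MARKERS,
    alpha: float = DEFAULT_ALPHA,
    benjamini_hochberg: bool = False,
) -> pd.DataFrame:
    """Correlate every feature column against every marker.

    ``table`` is the wide cohort feature table (patients x columns).
    Missing values are handled pairwise-complete per (feature, marker)
    pair, so the effective n differs between e.g. pre-contrast features
    (all patients) and difference features (equilibrium subset only).
    Pairs with fewer than 3 complete cases or a constant feature are
    skipped with a log entry.

    Returns the long-format table with columns region, phase, ssf_mm,
    metric, marker, r_s, p_value, n, significant (and q_value when
    ``benjamini_hochberg`` is on — provided for sensitivity analysis;
    the ``significant`` flag always refers to the uncorrected p).
    """
    if not (0.0 < alpha < 1.0):
        raise InputError(f"alpha must lie in (0, 1), got {alpha}")
    feature_cols = [(c, parse_feature_column(c)) for c in table.columns]
    feature_cols = [(c, meta) for c, meta in feature_cols if meta is not None]
    if not feature_cols:
        raise InputError("table contains no feature columns")
    rows = []
    for (col, (region, phase, ssf, metric)) in feature_cols:
        for marker in markers:
            if marker not in table.columns:
                continue
            pair = table[[col, marker]].dropna()
            n = len(pair)
            if n < MIN_PAIRS:
                logger.info("skipping %s vs %s: only %d complete pairs", col, marker, n)
                continue
            try:
                r, p = spearman(pair[col].to_numpy(), pair[marker].to_numpy())
            except UndefinedCorrelationError:
                logger.info("skipping %s vs %s: zero variance", col, marker)
                continue
            rows.append(
                {
                    "region": region,
                    "phase": phase,
                    "ssf_mm": ssf,
                    "metric": metric,
                    "marker": marker,
                    "r_s": r,
                    "p_value": p,
                    "n": n,
                    "significant": p <= alpha,
                }
            )
    result = pd.DataFrame(
        rows,
        columns=["region", "phase", "ssf_mm", "metric", "marker",
                 "r_s", "p_value", "n", "significant"],
    )
    if benjamini_hochberg and len(result):
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests(result["p_value"].to_numpy(), method="fdr_bh")
        result["q_value"] = q
    return result


def correlations_wide(corr_long: pd.DataFrame, value: str = "r_s") -> pd.DataFrame:
    """Pivot the long correlation table into the report layout.

    Rows are (SSF block, marker); columns are (region, phase, metric) —
    the shape of the published summary tables, one cell per association.
    """
    if corr_long.empty:
        return pd.DataFrame()
    wide = corr_long.pivot_table(
        index=["ssf_mm", "marker"],
        columns=["region", "phase", "metric"],
        values=value,
        aggfunc="first",
        sort=True,
    )
    wide = wide.sort_index(ascending=[False, True])
    wide.columns = ["_".join(map(str, c)) for c in wide.columns]
    return wide
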