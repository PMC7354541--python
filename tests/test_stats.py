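import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from eqctta import (
    InputError,
    UndefinedCorrelationError,
    correlate_features,
    correlations_wide,
    spearman,
    spearman_exact,
)


def oracle_spearman_r(x, y):
    """Brute-force average-rank Spearman, coded from the raw definition."""
    def avg_ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            r = (i + j) / 2.0 + 1.0  # average of 1-based positions
            for k in range(i, j + 1):
                ranks[order[k]] = r
            i = j + 1
        return ranks

    rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


class TestSpearman:
    def test_monotone_gives_plus_one(self):
        r, p = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert r == 1.0
        assert p == pytest.approx(2 / math.factorial(5))

    def test_antitone_gives_minus_one(self):
        r, p = spearman([1, 2, 3], [3, 2, 1])
        assert r == -1.0
        assert p == pytest.approx(2 / math.factorial(3))

    def test_tied_data_matches_bruteforce_oracle(self):
        x = [1, 1, 2, 3]
        y = [2, 1, 4, 4]
        r, _ = spearman(x, y)
        assert r == pytest.approx(oracle_spearman_r(x, y), rel=1e-12)

    def test_random_tied_vectors_match_oracle_and_scipy(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 6, n).astype(float)
            y = x + rng.integers(-2, 3, n)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r, p = spearman(x, y)
            assert r == pytest.approx(oracle_spearman_r(x, y), rel=1e-12, abs=1e-12)
            r_sp, p_sp = sps.spearmanr(x, y)
            assert r == pytest.approx(r_sp, rel=1e-10, abs=1e-12)
            if abs(r) < 1:  # scipy uses the same t-approximation
                assert p == pytest.approx(p_sp, rel=1e-8)

    @given(
        st.lists(st.integers(-1000, 1000), min_size=5, max_size=20, unique=True),
        st.sampled_from(["exp", "cube", "affine"]),
    )
    def test_invariance_under_monotone_transforms(self, xs, fname):
        # integer supports keep the transforms injective in float arithmetic
        rng = np.random.default_rng(len(xs))
        y = rng.normal(size=len(xs))
        if np.ptp(y) == 0:
            return
        f = {
            "exp": lambda v: math.exp(v / 100.0),
            "cube": lambda v: float(v) ** 3,
            "affine": lambda v: 2.5 * v + 7,
        }[fname]
        r0, p0 = spearman(xs, y)
        r1, p1 = spearman([f(v) for v in xs], y)
        assert r1 == pytest.approx(r0, abs=1e-12)
        assert p1 == pytest.approx(p0, abs=1e-12)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])

    def test_too_short(self):
        with pytest.raises(InputError):
            spearman([1, 2], [2, 1])

    def test_exact_permutation_small_n(self):
        x = [1, 2, 3, 4, 5]
        y = [1, 3, 2, 5, 4]
        r, p_exact = spearman_exact(x, y)
        assert 0 < p_exact <= 1
        # perfectly monotone: exact two-sided p is 2/n!
        _, p_perfect = spearman_exact(x, sorted(y))
        assert p_perfect == pytest.approx(2 / math.factorial(5))


def _toy_table(rng, n=20):
    marker = rng.normal(size=n)
    df = pd.DataFrame(
        {
            "whole_liver_pre_ssf0_mean": marker.copy(),   # identical to marker
            "whole_liver_pre_ssf4_sd": rng.normal(size=n),
            "segment7_diff_ssf4_mean": np.where(np.arange(n) < 14, rng.normal(size=n), np.nan),
            "whole_liver_eq_ssf6_entropy": np.full(n, 3.0),  # constant -> skipped
            "elf": marker,
            "cpa_percent": rng.normal(size=n),
            "ecv": rng.normal(size=n),
            "ishak": rng.integers(0, 7, n),
        },
        index=[f"p{i:03d}" for i in range(n)],
    )
    df.index.name = "patient_id"
    return df


class TestCorrelateFeatures:
    def test_feature_equal_to_marker_gives_unity(self, rng):
        corr = correlate_features(_toy_table(rng))
        row = corr[
            (corr["metric"] == "mean")
            & (corr["phase"] == "pre")
            & (corr["ssf_mm"] == 0)
            & (corr["marker"] == "elf")
        ]
        assert row["r_s"].iloc[0] == 1.0
        assert bool(row["significant"].iloc[0])

    def test_constant_feature_skipped(self, rng):
        corr = correlate_features(_toy_table(rng))
        assert not (corr["metric"] == "entropy").any()

    def test_pairwise_complete_n(self, rng):
        corr = correlate_features(_toy_table(rng))
        diff = corr[corr["phase"] == "diff"]
        assert (diff["n"] == 14).all()
        pre = corr[(corr["phase"] == "pre") & (corr["metric"] == "sd")]
        assert (pre["n"] == 20).all()

    def test_alpha_monotonicity(self, rng):
        t = _toy_table(rng)
        strict = correlate_features(t, alpha=0.01)["significant"].sum()
        loose = correlate_features(t, alpha=0.05)["significant"].sum()
        assert strict <= loose

    def test_benjamini_hochberg_optional_column(self, rng):
        t = _toy_table(rng)
        plain = correlate_features(t)
        with_q = correlate_features(t, benjamini_hochberg=True)
        assert "q_value" not in plain.columns
        assert (with_q["q_value"] >= with_q["p_value"] - 1e-12).all()

    def test_wide_layout_counts(self, rng):
        corr = correlate_features(_toy_table(rng))
        wide = correlations_wide(corr)
        # rows: one per (ssf, marker) present; columns: one per feature cell
        assert wide.shape[0] == len(corr.groupby(["ssf_mm", "marker"]))
        assert wide.shape[1] == len(corr.groupby(["region", "phase", "metric"]))

    def test_invalid_alpha(self, rng):
        with pytest.raises(InputError):
            correlate_features(_toy_table(rng), alpha=1.5)
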