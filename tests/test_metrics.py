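import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from eqctta import (
    CTSlice,
    GeometryError,
    PairingError,
    ROIMask,
    SamplingError,
    compute_metrics,
    filter_slice,
    subtract_features,
)
from eqctta.filtration import FilteredMap, SSFValue
from eqctta.metrics import TextureVector


# ---------------------------------------------------------------------------
# independent brute-force oracle (raw definitions, no shared code)
# ---------------------------------------------------------------------------

def oracle_metrics(values, bins=256):
    v = [float(x) for x in values]
    n = len(v)
    mean = math.fsum(v) / n
    m2 = math.fsum((x - mean) ** 2 for x in v) / n
    m3 = math.fsum((x - mean) ** 3 for x in v) / n
    m4 = math.fsum((x - mean) ** 4 for x in v) / n
    sd = math.sqrt(m2)
    if m2 == 0:
        skew = kurt = 0.0
        entropy = 0.0
    else:
        skew = m3 / m2**1.5
        kurt = m4 / m2**2 - 3.0
        lo, hi = min(v), max(v)
        counts = [0] * bins
        for x in v:
            idx = min(int((x - lo) / (hi - lo) * bins), bins - 1)
            counts[idx] += 1
        entropy = -math.fsum(
            (c / n) * math.log2(c / n) for c in counts if c > 0
        )
    pos = [x for x in v if x > 0]
    mpp = math.fsum(pos) / len(pos) if pos else 0.0
    return dict(mean=mean, sd=sd, entropy=entropy, mpp=mpp, skewness=skew, kurtosis=kurt)


def _vector_from_values(values, spacing=(1.0, 1.0), **kw):
    n = len(values)
    side = int(math.ceil(math.sqrt(n)))
    img = np.zeros((max(side, 10), max(side, 10)))
    mask = np.zeros_like(img, dtype=bool)
    img.flat[:n] = values
    mask.flat[:n] = True
    slc = CTSlice(np.zeros_like(img), spacing, "pre")
    fmap = FilteredMap(img, slc, SSFValue(0.0))
    roi = ROIMask.from_slice(mask, "whole_liver", slc)
    return compute_metrics(fmap, roi, **kw)


class TestAgainstOracle:
    def test_hundred_random_regions_match_to_1e12(self, rng):
        for _ in range(100):
            n = int(rng.integers(60, 400))
            values = rng.normal(rng.uniform(-20, 20), rng.uniform(0.5, 30), n)
            tv = _vector_from_values(values)
            expect = oracle_metrics(values)
            for name, ref in expect.items():
                got = getattr(tv, name)
                assert got == pytest.approx(ref, rel=1e-12, abs=1e-12), name

    def test_large_normal_sample_has_gaussian_shape(self, rng):
        values = rng.standard_normal(10_000)
        tv = _vector_from_values(values)
        assert abs(tv.skewness) < 0.1
        assert abs(tv.kurtosis) < 0.1


class TestDegenerateCases:
    def test_constant_region(self):
        tv = _vector_from_values([5.0] * 100)
        assert tv.mean == 5.0
        assert tv.sd == 0.0
        assert tv.entropy == 0.0
        assert tv.mpp == 5.0
        assert tv.skewness == 0.0 and tv.kurtosis == 0.0
        assert "zero_variance" in tv.flags

    def test_no_positive_pixels_flagged_zero(self):
        tv = _vector_from_values([-3.0, -1.0] * 50)
        assert tv.mpp == 0.0
        assert "no_positive_pixels" in tv.flags

    def test_symmetric_two_point_region(self):
        tv = _vector_from_values([-1.0, 1.0] * 50)
        assert tv.mean == pytest.approx(0.0)
        assert tv.sd == pytest.approx(1.0)
        assert tv.mpp == pytest.approx(1.0)

    def test_too_few_pixels_raises(self):
        with pytest.raises(SamplingError):
            _vector_from_values([1.0] * 10)

    def test_empty_after_erosion_raises(self, rng):
        img = rng.normal(0, 1, (40, 40)) * 0.01
        slc = CTSlice(img, (1.0, 1.0), "pre")
        fmap = filter_slice(slc, 6.0)
        thin = np.zeros((40, 40), dtype=bool)
        thin[20, 5:35] = True  # 1-px line vanishes under erosion
        roi = ROIMask.from_slice(thin, "segment7", slc)
        with pytest.raises(GeometryError):
            compute_metrics(fmap, roi)


class TestInvariances:
    def test_positive_shift_equivariance(self, rng):
        base = rng.uniform(5.0, 50.0, 500)  # all positive, stays positive
        c = 7.0
        tv0 = _vector_from_values(base)
        tv1 = _vector_from_values(base + c)
        assert tv1.mean == pytest.approx(tv0.mean + c, rel=1e-12)
        assert tv1.mpp == pytest.approx(tv0.mpp + c, rel=1e-12)
        for name in ("sd", "skewness", "kurtosis", "entropy"):
            assert getattr(tv1, name) == pytest.approx(getattr(tv0, name), abs=1e-9)

    def test_positive_scaling(self, rng):
        base = rng.normal(0, 10, 500)
        a = 3.5
        tv0 = _vector_from_values(base)
        tv1 = _vector_from_values(a * base)
        assert tv1.sd == pytest.approx(a * tv0.sd, rel=1e-12)
        assert tv1.skewness == pytest.approx(tv0.skewness, abs=1e-9)
        assert tv1.kurtosis == pytest.approx(tv0.kurtosis, abs=1e-9)

    def test_entropy_bounded_by_log_bins(self, rng):
        tv = _vector_from_values(rng.normal(0, 1, 5000), bins=64)
        assert 0.0 <= tv.entropy <= math.log2(64)

    def test_sample_moment_convention(self, rng):
        from scipy import stats as sps

        values = rng.normal(0, 5, 301)
        tv = _vector_from_values(values, population=False)
        assert tv.sd == pytest.approx(np.std(values, ddof=1), rel=1e-12)
        assert tv.skewness == pytest.approx(sps.skew(values, bias=False), rel=1e-9)
        assert tv.kurtosis == pytest.approx(
            sps.kurtosis(values, fisher=True, bias=False), rel=1e-9
        )


def _tv(phase, ssf=4.0, region="segment7", **over):
    base = dict(mean=1.0, sd=2.0, entropy=3.0, mpp=4.0, skewness=0.5, kurtosis=-0.5)
    base.update(over)
    return TextureVector(ssf_mm=ssf, region=region, phase=phase, n_pixels=100, **base)


class TestSubtractFeatures:
    def test_metricwise_difference(self):
        eq = _tv("eq", mean=12.0)
        pre = _tv("pre", mean=10.5)
        diff = subtract_features(eq, pre)
        assert diff.phase == "diff"
        assert diff.mean == pytest.approx(1.5)
        assert diff.sd == 0.0 and diff.entropy == 0.0

    def test_self_subtraction_is_zero(self):
        d = subtract_features(_tv("eq"), _tv("pre"))
        assert all(getattr(d, m) == 0.0 for m in ("mean", "sd", "entropy", "mpp", "skewness", "kurtosis"))

    @given(st.lists(st.floats(-50, 50), min_size=6, max_size=6))
    def test_antisymmetry(self, vals):
        keys = ("mean", "sd", "entropy", "mpp", "skewness", "kurtosis")
        a = _tv("eq", **dict(zip(keys, vals)))
        b = _tv("pre")
        fwd = subtract_features(a, b)
        # swapped-phase counterpart of the same vectors
        rev = subtract_features(_tv("eq"), _tv("pre", **dict(zip(keys, vals))))
        for k in keys:
            assert getattr(fwd, k) == pytest.approx(-getattr(rev, k), abs=1e-12)

    def test_mismatched_ssf_or_region_rejected(self):
        with pytest.raises(PairingError):
            subtract_features(_tv("eq", ssf=4.0), _tv("pre", ssf=5.0))
        with pytest.raises(PairingError):
            subtract_features(_tv("eq", region="whole_liver"), _tv("pre"))
        with pytest.raises(PairingError):
            subtract_features(_tv("pre"), _tv("pre"))

    def test_flags_union(self):
        eq = TextureVector(4.0, "segment7", "eq", 0, 0, 0, 0, 0, 0, 100,
                           frozenset({"zero_variance"}))
        pre = TextureVector(4.0, "segment7", "pre", 0, 0, 0, 0, 0, 0, 90,
                            frozenset({"no_positive_pixels"}))
        d = subtract_features(eq, pre)
        assert d.flags == {"zero_variance", "no_positive_pixels"}
        assert d.n_pixels == 90
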