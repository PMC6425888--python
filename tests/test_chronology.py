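"""Detrending, prewhitening, robust means and descriptive statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dendroprov.chronology import (Chronology, DetrendingError, RWISeries,
                                   build_chronology, chronology_stats,
                                   detrend_to_rwi, fit_growth_spline, glk,
                                   interseries_rbar, mean_sensitivity,
                                   prewhiten_ar1, tukey_biweight_mean)
from dendroprov.io import RingWidthSeries


def _series(values, first_year=1950, sid="S", **kw):
    return RingWidthSeries(sid, first_year, tuple(values), **kw)


def _rwi(values, first_year=1950, sid="S", **kw):
    return RWISeries(sid, first_year, tuple(values), **kw)


def _sinusoid_response(period, n=150):
    t = np.arange(n, dtype=float)
    y = 2.0 + np.sin(2 * np.pi * t / period)
    curve = fit_growth_spline(_series(y))
    X = np.column_stack([np.ones(n), np.sin(2 * np.pi * t / period),
                         np.cos(2 * np.pi * t / period)])
    coef, *_ = np.linalg.lstsq(X, curve, rcond=None)
    return float(np.hypot(coef[1], coef[2]))


class TestGrowthSpline:
    def test_fifty_percent_response_at_cutoff(self):
        assert _sinusoid_response(30) == pytest.approx(0.5, abs=0.05)

    def test_low_frequency_passband(self):
        assert _sinusoid_response(100) >= 0.9

    def test_high_frequency_stopband(self):
        assert _sinusoid_response(5) <= 0.1

    def test_linear_ramp_tracked(self):
        n = 120
        y = np.linspace(1.0, 4.0, n)
        curve = fit_growth_spline(_series(y))
        interior = slice(15, n - 15)
        rel = np.abs(curve[interior] - y[interior]) / y[interior]
        assert rel.max() < 0.02

    def test_period2_alternation_rejected(self):
        n = 100
        y = 2.0 + 0.5 * (-1.0) ** np.arange(n)
        curve = fit_growth_spline(_series(y))
        assert np.abs(curve[10:-10] - 2.0).max() < 0.04

    def test_short_series_rejected(self):
        with pytest.raises(DetrendingError):
            fit_growth_spline(_series([1.0] * 9))


class TestDetrend:
    def test_identity_when_widths_equal_curve(self):
        y = np.linspace(2, 3, 40)
        r = detrend_to_rwi(_series(y), y)
        assert np.allclose(r.values(), 1.0)

    def test_scaling(self):
        y = np.linspace(2, 3, 40)
        r = detrend_to_rwi(_series(2 * y), y)
        assert np.allclose(r.values(), 2.0)

    def test_missing_ring_yields_zero_index(self):
        y = np.ones(20)
        w = y.copy()
        w[5] = 0.0
        r = detrend_to_rwi(_series(w), y)
        assert r.values()[5] == 0.0 and len(r.index) == 20

    def test_nonpositive_curve_names_year(self):
        y = np.ones(20)
        curve = y.copy()
        curve[7] = 0.0
        with pytest.raises(DetrendingError, match="1957"):
            detrend_to_rwi(_series(y, first_year=1950), curve)

    def test_mean_index_near_one_for_simulated_growth(self, rng):
        t = np.arange(60.0)
        y = 3 * np.exp(-0.03 * t) + 0.5 + rng.normal(0, 0.1, 60)
        r = detrend_to_rwi(_series(y), fit_growth_spline(_series(y)))
        assert r.values().mean() == pytest.approx(1.0, abs=0.05)


class TestPrewhiten:
    def test_removes_ar1_autocorrelation(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            x = np.empty(200)
            x[0] = 0.0
            eps = rng.normal(0, 0.1, 200)
            for t in range(1, 200):
                x[t] = 0.7 * x[t - 1] + eps[t]
            out = prewhiten_ar1(_rwi(1.0 + x)).values()
            r1 = np.corrcoef(out[:-1], out[1:])[0, 1]
            assert abs(r1) < 0.1

    def test_output_one_shorter_and_mean_one(self, rng):
        x = 1.0 + rng.normal(0, 0.1, 40)
        out = prewhiten_ar1(_rwi(x))
        assert len(out.index) == 39
        assert out.first_year == 1951
        assert out.values().mean() == pytest.approx(1.0, abs=1e-12)
        assert out.prewhitened

    def test_white_noise_passthrough(self, rng):
        x = 1.0 + rng.normal(0, 0.1, 500)
        out = prewhiten_ar1(_rwi(x)).values()
        # φ ≈ 0: output ≈ recentred input minus first year
        assert np.corrcoef(out, x[1:])[0, 1] > 0.99

    def test_constant_input_rejected(self):
        with pytest.raises(DetrendingError):
            prewhiten_ar1(_rwi([1.0] * 20))


class TestBiweight:
    def test_constant(self):
        assert tukey_biweight_mean([5, 5, 5]) == 5

    def test_symmetric(self):
        assert tukey_biweight_mean([1, 2, 3]) == pytest.approx(2.0)

    def test_outlier_downweighted(self):
        m = tukey_biweight_mean([1, 1, 1, 10])
        assert m == pytest.approx(1.0, abs=0.05)
        assert m < 3.25

    def test_matches_mean_for_clean_symmetric_data(self, rng):
        x = rng.normal(10, 1, 200)
        assert tukey_biweight_mean(x) == pytest.approx(x.mean(), abs=0.05)

    def test_bounded_influence(self, rng):
        x = list(rng.normal(0, 1, 30))
        base = tukey_biweight_mean(x)
        for bad in (1e3, 1e6, 1e9):
            assert abs(tukey_biweight_mean(x + [bad]) - base) < 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            tukey_biweight_mean([])

    def test_independent_irls_oracle(self):
        """Frozen value from an independent weighted-iteration implementation."""
        x = np.array([0.8, 0.9, 1.0, 1.1, 1.2, 3.0])
        med = np.median(x)
        s = 9 * np.median(np.abs(x - med))
        m = med
        for _ in range(200):
            u = (x - m) / s
            w = np.where(np.abs(u) < 1, (1 - u ** 2) ** 2, 0)
            m = float((w * x).sum() / w.sum())
        assert tukey_biweight_mean(x) == pytest.approx(m, abs=1e-8)


class TestChronology:
    def test_identical_series_reproduced_with_depth(self):
        rwis = [_rwi([1.0, 1.2, 0.8], sid=f"T{i}") for i in range(15)]
        c = build_chronology(rwis, "P", "S")
        assert np.allclose(c.values(), [1.0, 1.2, 0.8])
        assert c.depth == (15, 15, 15)

    def test_single_series_chronology(self):
        c = build_chronology([_rwi([1.0, 1.1])])
        assert np.allclose(c.values(), [1.0, 1.1]) and c.depth == (1, 1)

    def test_robust_to_single_outlier_year(self):
        rwis = [_rwi([1.0, 1.0]) for _ in range(14)] + [_rwi([1.0, 3.0])]
        c = build_chronology(rwis)
        arith = (14 * 1.0 + 3.0) / 15
        assert abs(c.values()[1] - 1.0) < abs(c.values()[1] - arith)

    def test_staggered_series_depth(self):
        rwis = [_rwi([1.0] * 5, first_year=1950),
                _rwi([1.0] * 5, first_year=1952)]
        c = build_chronology(rwis)
        assert c.first_year == 1950
        assert c.depth == (1, 1, 2, 2, 2, 1, 1)


class TestGlk:
    def test_hand_counted_example(self):
        assert glk([1, 2, 1, 3], [2, 3, 2, 2]) == pytest.approx(5 / 6)

    def test_self_agreement(self, rng):
        x = rng.normal(1, 0.2, 50)
        assert glk(x, x) == 1.0

    def test_perfect_opposition(self):
        a = np.array([1, 2, 1, 2, 1], dtype=float)
        assert glk(a, -a) == 0.0

    def test_symmetry_and_affine_invariance(self, rng):
        a, b = rng.normal(1, 0.2, 40), rng.normal(1, 0.2, 40)
        assert glk(a, b) == glk(b, a)
        assert glk(2.5 * a + 7, b) == glk(a, b)

    def test_overlap_required(self):
        with pytest.raises(ValueError):
            glk([1.0], [2.0])


class TestMeanSensitivity:
    def test_constant_is_zero(self):
        assert mean_sensitivity([2.0] * 10) == 0.0

    @pytest.mark.parametrize("x, expected", [
        ([1.0, 3.0], 1.0),
        ([1.0, 3.0, 1.0], 1.0),
    ])
    def test_direct_formula(self, x, expected):
        assert mean_sensitivity(x) == pytest.approx(expected)

    def test_zero_sum_pair_skipped(self):
        # (0,0) pair contributes nothing; remaining pairs count
        assert mean_sensitivity([0.0, 0.0, 1.0]) == pytest.approx(2.0)


class TestRbar:
    def test_identical_series(self):
        rwis = [_rwi(np.sin(np.arange(30.0)) + 1) for _ in range(3)]
        assert interseries_rbar(rwis) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        rwis = [_rwi(1 + rng.normal(0, 0.1, 200), sid=f"T{i}")
                for i in range(15)]
        assert abs(interseries_rbar(rwis)) < 0.05

    def test_two_series_equals_pearson(self, rng):
        a, b = 1 + rng.normal(0, 0.1, 50), 1 + rng.normal(0, 0.1, 50)
        expected = np.corrcoef(a, b)[0, 1]
        assert interseries_rbar([_rwi(a), _rwi(b)]) == pytest.approx(expected)

    def test_insufficient_overlap_rejected(self):
        rwis = [_rwi([1.0, 2.0] * 3, first_year=1950),
                _rwi([1.0, 2.0] * 3, first_year=1990)]
        with pytest.raises(ValueError):
            interseries_rbar(rwis)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    a=st.lists(st.floats(0.1, 10.0), min_size=3, max_size=40),
    b=st.lists(st.floats(0.1, 10.0), min_size=3, max_size=40),
    scale=st.floats(0.1, 50.0),
    shift=st.floats(-5.0, 5.0),
)
def test_glk_symmetry_and_positive_affine_invariance(a, b, scale, shift):
    a, b = np.asarray(a), np.asarray(b)
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    assert glk(a, b) == glk(b, a)
    assert glk(scale * a + shift, b) == glk(a, b)


def test_chronology_stats_fields(rng):
    raw = [_series(3 * np.exp(-0.02 * np.arange(40.0))
                   + rng.normal(0, 0.2, 40) + 1, sid=f"T{i}",
                   provenance="BA", site="KN") for i in range(5)]
    from dendroprov.chronology import detrend_collection
    rwis = detrend_collection(raw)
    st = chronology_stats(raw, rwis)
    assert st.n_trees == 5
    assert 0 <= st.glk <= 1
    assert st.ms >= 0
    assert -1 <= st.rbar <= 1
    assert st.provenance == "BA" and st.site == "KN"
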