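import numpy as np
import pytest

from kneenorm import (
    EstimatorError,
    Spectrum,
    UndefinedStatisticError,
    compare_spectra,
    linear_concordance,
    match_peaks,
    passing_bablok,
)
from kneenorm.concordance import PairedIntensities
from oracles import passing_bablok_brute


def _pairs(x, y):
    return PairedIntensities(np.asarray(x, float), np.asarray(y, float), 0, 0)


def _spectrum(mz, intensity, **kw):
    return Spectrum.from_arrays(mz, intensity, **kw)


class TestMatchPeaks:
    def test_identical_grids_match_fully(self):
        mz = np.linspace(100, 200, 50)
        a = _spectrum(mz, np.arange(1.0, 51.0))
        b = _spectrum(mz, np.arange(51.0, 101.0))
        p = match_peaks(a, b, tol=0.5)
        assert p.n_matched == 50
        assert p.n_unmatched_x == p.n_unmatched_y == 0

    def test_shift_beyond_tolerance_matches_nothing(self):
        mz = np.linspace(100, 200, 20)
        a = _spectrum(mz, np.ones(20))
        b = _spectrum(mz + 0.1, np.ones(20))
        assert match_peaks(a, b, tol=0.05).n_matched == 0

    def test_zero_tolerance_requires_exact_equality(self):
        a = _spectrum([100.0, 150.0], [1.0, 2.0])
        b = _spectrum([100.0, 150.0 + 1e-9], [3.0, 4.0])
        p = match_peaks(a, b, tol=0.0)
        assert p.n_matched == 1

    def test_matching_is_symmetric(self):
        rng = np.random.default_rng(11)
        a = _spectrum(np.sort(rng.uniform(100, 200, 80)), rng.uniform(1, 10, 80))
        b = _spectrum(np.sort(rng.uniform(100, 200, 90)), rng.uniform(1, 10, 90))
        ab = match_peaks(a, b, tol=0.5)
        ba = match_peaks(b, a, tol=0.5)
        assert ab.n_matched == ba.n_matched
        assert sorted(zip(ab.x, ab.y)) == sorted(zip(ba.y, ba.x))


class TestLinearConcordance:
    def test_identity_line(self):
        x = np.arange(1.0, 21.0)
        slope, intercept, r2, r, rho = linear_concordance(_pairs(x, x))
        assert (slope, intercept, r2, r, rho) == pytest.approx((1, 0, 1, 1, 1))

    def test_negative_association(self):
        x = np.arange(1.0, 21.0)
        slope, intercept, r2, r, rho = linear_concordance(_pairs(x, -x))
        assert r == pytest.approx(-1.0)
        assert r2 == pytest.approx(1.0)
        assert rho == pytest.approx(-1.0)

    def test_matches_closed_form_least_squares(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(1, 100, 20)
        y = 3.0 * x + 7.0 + rng.normal(0, 5, 20)
        slope, intercept, r2, r, _ = linear_concordance(_pairs(x, y))
        # independent closed-form normal equations
        sxx = np.sum((x - x.mean()) ** 2)
        sxy = np.sum((x - x.mean()) * (y - y.mean()))
        syy = np.sum((y - y.mean()) ** 2)
        assert slope == pytest.approx(sxy / sxx)
        assert intercept == pytest.approx(y.mean() - (sxy / sxx) * x.mean())
        assert r2 == pytest.approx(sxy**2 / (sxx * syy))
        assert r == pytest.approx(sxy / np.sqrt(sxx * syy))

    def test_zero_variance_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            linear_concordance(_pairs(np.ones(10), np.arange(10.0)))

    def test_spearman_invariant_under_monotone_transforms(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(1, 100, 40)
        y = rng.uniform(1, 100, 40)
        _, _, _, _, rho = linear_concordance(_pairs(x, y))
        _, _, _, _, rho_t = linear_concordance(_pairs(np.exp(x / 20.0), y**3))
        assert rho_t == pytest.approx(rho)


class TestPassingBablok:
    def test_identity_line_exact(self):
        x = np.linspace(1.0, 50.0, 50)
        slope, intercept, slope_ci, _ = passing_bablok(_pairs(x, x))
        assert slope == 1.0
        assert intercept == 0.0
        assert slope_ci == (1.0, 1.0)

    def test_exact_linear_data(self):
        x = np.linspace(1.0, 50.0, 50)
        slope, intercept, _, _ = passing_bablok(_pairs(x, 2.0 * x + 3.0))
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(3.0)

    def test_matches_bruteforce_oracle_on_random_pairs(self):
        rng = np.random.default_rng(17)
        x = rng.uniform(1, 100, 200)
        y = 1.3 * x + rng.normal(0, 10, 200)
        slope, intercept, _, _ = passing_bablok(_pairs(x, y))
        oslope, ointercept = passing_bablok_brute(x, y)
        assert slope == oslope
        assert intercept == ointercept

    def test_swap_maps_slope_to_reciprocal(self):
        x = np.linspace(1.0, 30.0, 30)
        y = 2.0 * x + 3.0
        slope_xy, _, _, _ = passing_bablok(_pairs(x, y))
        slope_yx, _, _, _ = passing_bablok(_pairs(y, x))
        assert slope_yx == pytest.approx(1.0 / slope_xy)

    def test_too_few_pairs_rejected(self):
        x = np.arange(1.0, 6.0)
        with pytest.raises(EstimatorError):
            passing_bablok(_pairs(x, x))

    def test_large_sets_subsample_deterministically(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 100, 6000)
        y = x * 1.1 + rng.normal(0, 1, 6000)
        a = passing_bablok(_pairs(x, y))
        b = passing_bablok(_pairs(x, y))
        assert a == b
        assert a[0] == pytest.approx(1.1, abs=0.01)


class TestCompareSpectra:
    def test_self_comparison(self):
        rng = np.random.default_rng(2)
        s = _spectrum(
            np.sort(rng.uniform(100, 200, 60)),
            rng.uniform(1, 100, 60),
            scale="standardized",
        )
        result = compare_spectra(s, s)
        assert result.pb_slope == 1.0
        assert result.pb_intercept == 0.0
        assert result.spearman_rho == pytest.approx(1.0)
        assert result.n_matched == 60

    def test_warns_on_raw_scale(self, caplog):
        rng = np.random.default_rng(2)
        s = _spectrum(np.sort(rng.uniform(100, 200, 60)), rng.uniform(1, 100, 60))
        with caplog.at_level("WARNING"):
            compare_spectra(s, s)
        assert any("standardized" in r.message for r in caplog.records)
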