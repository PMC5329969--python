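import numpy as np
import pytest

from kneenorm import (
    DistortionSpec,
    add_biological_noise,
    apply_distortion,
    distortion_factors,
    knee_stability_experiment,
    simulate_plasma_spectrum,
)
from kneenorm.simulate import NoiseModel, SimSpec


class TestSimulatePlasmaSpectrum:
    def test_seeded_determinism_is_bitwise(self):
        spec = SimSpec(n_peaks=5000, mz_range=(225.0, 425.0), seed=1)
        a, b = simulate_plasma_spectrum(spec), simulate_plasma_spectrum(spec)
        np.testing.assert_array_equal(a.mz, b.mz)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_counts_and_range_respected(self, default_spectrum):
        assert len(default_spectrum) == 5000
        lo, hi = default_spectrum.mz_range
        assert lo >= 225.0 and hi <= 425.0

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n_peaks=50), dict(mz_range=(400.0, 300.0)), dict(tail_exponent=-1.0)],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimSpec(**kwargs)


class TestBiologicalNoise:
    def test_cv_zero_is_identity(self, default_spectrum):
        out = add_biological_noise(default_spectrum, NoiseModel(cv=0.0, seed=1))
        np.testing.assert_array_equal(out.intensity, default_spectrum.intensity)

    def test_same_seed_same_output(self, default_spectrum):
        noise = NoiseModel(cv=0.46, seed=7)
        a = add_biological_noise(default_spectrum, noise)
        b = add_biological_noise(default_spectrum, noise)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_empirical_cv_matches_target(self):
        """Replicating one peak 200 times yields ~46% intensity CV."""
        from kneenorm import Spectrum

        one = Spectrum.from_arrays([100.0], [1000.0])
        values = np.array([
            add_biological_noise(one, NoiseModel(cv=0.46, seed=s)).intensity[0]
            for s in range(200)
        ])
        cv = values.std(ddof=1) / values.mean()
        assert cv == pytest.approx(0.46, abs=0.05)

    def test_noise_is_unbiased(self):
        """The mean over many replicates converges to the original."""
        from kneenorm import Spectrum

        s = Spectrum.from_arrays([100.0, 200.0, 300.0], [10.0, 1000.0, 5.0])
        stack = np.stack([
            add_biological_noise(s, NoiseModel(cv=0.46, seed=seed)).intensity
            for seed in range(3000)
        ])
        np.testing.assert_allclose(stack.mean(axis=0), s.intensity, rtol=0.02)


class TestDistortions:
    def test_uniform_is_exact_multiplication(self, default_spectrum):
        out = apply_distortion(default_spectrum, DistortionSpec.uniform(10.0))
        np.testing.assert_array_equal(out.intensity, default_spectrum.intensity * 10.0)

    def test_ramp_endpoints_and_midpoint(self, default_spectrum):
        d = DistortionSpec.ramp(1.0, 10.0)
        f = distortion_factors(default_spectrum, d)
        lo, hi = default_spectrum.mz_range
        assert f[0] == pytest.approx(1.0)
        assert f[-1] == pytest.approx(10.0)
        mid_idx = np.argmin(np.abs(default_spectrum.mz - 0.5 * (lo + hi)))
        assert f[mid_idx] == pytest.approx(5.5, abs=0.05)

    def test_gaussian_center_boost_edge_suppression(self, default_spectrum):
        d = DistortionSpec.gaussian(0.25, 4.0)
        f = distortion_factors(default_spectrum, d)
        lo, hi = default_spectrum.mz_range
        mid_idx = np.argmin(np.abs(default_spectrum.mz - 0.5 * (lo + hi)))
        assert f[mid_idx] == pytest.approx(4.0, abs=0.01)
        assert f[0] == pytest.approx(0.25, abs=0.05)
        assert f[-1] == pytest.approx(0.25, abs=0.05)

    @pytest.mark.parametrize(
        "d",
        [DistortionSpec.uniform(), DistortionSpec.ramp(), DistortionSpec.gaussian()],
        ids=["uniform", "ramp", "gaussian"],
    )
    def test_distortion_is_exactly_invertible(self, default_spectrum, d):
        out = apply_distortion(default_spectrum, d)
        restored = out.intensity / distortion_factors(default_spectrum, d)
        np.testing.assert_allclose(restored, default_spectrum.intensity, rtol=1e-12)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            DistortionSpec("uniform", (-1.0,))
        with pytest.raises(ValueError):
            DistortionSpec("wiggle", (1.0,))


class TestKneeStabilityExperiment:
    def test_zero_noise_gives_zero_cv(self, default_spectrum):
        r = knee_stability_experiment(
            default_spectrum, NoiseModel(cv=0.0, seed=1), iterations=3
        )
        assert r.cv == 0.0

    def test_seed_stream_prefix_is_stable(self, default_spectrum):
        noise = NoiseModel(cv=0.46, seed=4)
        short = knee_stability_experiment(default_spectrum, noise, iterations=10)
        long = knee_stability_experiment(default_spectrum, noise, iterations=20)
        assert long.values[:10] == short.values

    def test_knee_cv_far_below_intensity_cv(self, default_spectrum):
        """Across noise seeds the knee varies ~an order less than the peaks."""
        for seed in range(3):
            r = knee_stability_experiment(
                default_spectrum,
                NoiseModel(cv=0.46, seed=seed),
                iterations=10,
                window=(250.0, 50.0),
            )
            assert r.cv < 0.25 * 0.46
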