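"""Synthetic plasma-like spectra, biological noise, distortions, experiments.

Blood plasma direct-infusion spectra contain thousands of peaks whose
concentrations span several orders of magnitude; within any m/z window the
rank-ordered intensities decay like a power law.  The generator emulates
this with m/z values uniform over the configured range and intensities
drawn from a Pareto-like law  I = A * u**(-gamma) + base,  u ~ Uniform(0,1),
whose window order statistics follow  y(k) ~ A * (k/n)**(-gamma) + base.

Biological variation is modelled as an independent multiplicative Gaussian
factor per peak (mean 1, sd = CV), matching the reported average
between-sample CV of 46% for plasma metabolites.  Three distortion models
emulate instrument-dependent intensity corruption: a uniform gain, a linear
ramp across the m/z axis, and a Gaussian bump (suppressed edges, boosted
center).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ExperimentError
from .kneefinder import DEFAULT_MIN_OCCUPANCY, window_normalization_value
from .peaks_io import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "SimSpec",
    "NoiseModel",
    "DistortionSpec",
    "KneeStabilityResult",
    "simulate_plasma_spectrum",
    "add_biological_noise",
    "apply_distortion",
    "distortion_factors",
    "knee_stability_experiment",
]


@dataclass(frozen=True)
class SimSpec:
    """Parameters of the plasma-like spectrum generator.

    Intensities follow a truncated Pareto-like law
    ``I = (amplitude * u**(-tail_exponent) + baseline) * exp(jitter)``
    where ``u`` is an abundance quantile in (0, 1].  Quantiles are laid out
    along the m/z-ordered peaks by a golden-ratio (low-discrepancy)
    recurrence, so every wide m/z window samples the whole abundance
    hierarchy evenly — the homogeneity that makes real plasma windows fit a
    power law with r2 ~ 1.  The quantile is smoothly floored at
    ``quantile_floor`` (default: half the mean quantile spacing of a 50-Th
    window) so the dominant peak of a window is set by the assemblage, not
    by a lucky draw.  ``jitter_sd`` is the sd of the per-peak lognormal
    abundance jitter.
    """

    n_peaks: int = 5000
    mz_range: tuple[float, float] = (225.0, 425.0)
    amplitude: float = 1000.0
    tail_exponent: float = 0.5
    baseline: float = 1.0
    jitter_sd: float = 0.05
    quantile_floor: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_peaks < 100:
            raise ValueError("n_peaks must be >= 100")
        lo, hi = self.mz_range
        if not lo < hi:
            raise ValueError("mz_range must satisfy lo < hi")
        if self.tail_exponent <= 0:
            raise ValueError("tail_exponent must be > 0")
        if self.amplitude <= 0 or self.baseline < 0:
            raise ValueError("amplitude must be > 0 and baseline >= 0")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        if self.quantile_floor is not None and not 0 < self.quantile_floor < 1:
            raise ValueError("quantile_floor must be in (0, 1)")

    @property
    def effective_quantile_floor(self) -> float:
        if self.quantile_floor is not None:
            return self.quantile_floor
        lo, hi = self.mz_range
        # half the mean quantile spacing of a 50-Th window
        return (hi - lo) / (100.0 * self.n_peaks)


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian intensity noise.

    ``cv`` is the target per-peak coefficient of variation (0.46 emulates
    the biological variation of plasma metabolites).  The Gaussian factor is
    truncated below at ``floor`` (fraction of the original intensity) since
    at CV 46% about 1.5% of draws would otherwise be negative.
    """

    cv: float = 0.46
    seed: int = 0
    floor: float = 0.01

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if not 0 < self.floor < 1:
            raise ValueError("floor must be in (0, 1)")


@dataclass(frozen=True)
class DistortionSpec:
    """One of the three distortion models.

    kind='uniform': params=(factor,) — every intensity multiplied by factor.
    kind='ramp':    params=(f_lo, f_hi) — factor linear in m/z from f_lo at
                    the first peak to f_hi at the last.
    kind='gaussian':params=(f_edge, f_center[, width_fraction]) — factor
                    f_edge + (f_center - f_edge) * exp(-(mz-mid)^2/(2 s^2))
                    with s = width_fraction * span (default 1/6, so the
                    factor has essentially relaxed to f_edge at the edges).
    """

    kind: str
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        expected = {"uniform": (1, 1), "ramp": (2, 2), "gaussian": (2, 3)}
        if self.kind not in expected:
            raise ValueError(f"unknown distortion kind: {self.kind!r}")
        lo, hi = expected[self.kind]
        if not lo <= len(self.params) <= hi:
            raise ValueError(
                f"{self.kind} distortion takes {lo}-{hi} parameters, "
                f"got {len(self.params)}"
            )
        if any(p <= 0 for p in self.params):
            raise ValueError("all distortion factors must be > 0")

    @classmethod
    def uniform(cls, factor: float = 10.0) -> "DistortionSpec":
        return cls("uniform", (factor,))

    @classmethod
    def ramp(cls, f_lo: float = 1.0, f_hi: float = 10.0) -> "DistortionSpec":
        return cls("ramp", (f_lo, f_hi))

    @classmethod
    def gaussian(
        cls,
        f_edge: float = 0.25,
        f_center: float = 4.0,
        width_fraction: float = 1.0 / 6.0,
    ) -> "DistortionSpec":
        return cls("gaussian", (f_edge, f_center, width_fraction))


_GOLDEN = (np.sqrt(5.0) - 1.0) / 2.0


def simulate_plasma_spectrum(spec: SimSpec = SimSpec()) -> Spectrum:
    """Generate a plasma-like synthetic spectrum (deterministic per seed).

    m/z values are uniform over ``mz_range``.  Abundance quantiles follow a
    randomly-phased golden-ratio recurrence over the m/z-ordered peaks and
    are smoothly floored (``u -> sqrt(u**2 + floor**2)``) before entering
    the Pareto-like intensity law; see :class:`SimSpec`.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.mz_range
    n = spec.n_peaks
    mz = np.sort(rng.uniform(lo, hi, size=n))
    u = np.mod(rng.uniform() + _GOLDEN * np.arange(n), 1.0)
    floor = spec.effective_quantile_floor
    u = np.sqrt(u * u + floor * floor)
    intensity = spec.amplitude * u ** (-spec.tail_exponent) + spec.baseline
    if spec.jitter_sd > 0:
        intensity = intensity * np.exp(rng.normal(0.0, spec.jitter_sd, size=n))
    return Spectrum.from_arrays(mz, intensity, label=f"sim(seed={spec.seed})")


def add_biological_noise(spectrum: Spectrum, noise: NoiseModel) -> Spectrum:
    """Fluctuate each intensity by an independent Gaussian factor.

    The factor has mean 1 and standard deviation ``noise.cv`` and is
    truncated below at ``noise.floor``.  ``cv=0`` returns the input
    unchanged.
    """
    if noise.cv == 0:
        return spectrum
    rng = np.random.default_rng(noise.seed)
    factors = rng.normal(1.0, noise.cv, size=len(spectrum))
    factors = np.maximum(factors, noise.floor)
    return spectrum.with_intensity(spectrum.intensity * factors)


def distortion_factors(spectrum: Spectrum, d: DistortionSpec) -> np.ndarray:
    """Per-peak multiplicative factor of a distortion (exactly invertible)."""
    mz = spectrum.mz
    if d.kind == "uniform":
        return np.full(mz.size, d.params[0])
    lo, hi = spectrum.mz_range
    span = hi - lo
    if d.kind == "ramp":
        f_lo, f_hi = d.params
        frac = (mz - lo) / span if span > 0 else np.zeros_like(mz)
        return f_lo + (f_hi - f_lo) * frac
    f_edge, f_center = d.params[0], d.params[1]
    width_fraction = d.params[2] if len(d.params) > 2 else 1.0 / 6.0
    mid = 0.5 * (lo + hi)
    sigma = width_fraction * span
    return f_edge + (f_center - f_edge) * np.exp(
        -((mz - mid) ** 2) / (2.0 * sigma**2)
    )


def apply_distortion(spectrum: Spectrum, d: DistortionSpec) -> Spectrum:
    """Multiply intensities by the distortion's m/z-dependent factor."""
    return spectrum.with_intensity(
        spectrum.intensity * distortion_factors(spectrum, d)
    )


@dataclass(frozen=True)
class KneeStabilityResult:
    """Outcome of the knee-stability experiment."""

    cv: float  # sd/mean of the knee value across replicates (fraction)
    values: tuple[float, ...]  # per-replicate knee values
    n_failed: int  # replicates whose window failed to fit


def knee_stability_experiment(
    spectrum: Spectrum,
    noise: NoiseModel,
    iterations: int = 10,
    window: tuple[float, float] | None = None,
    min_occupancy: int = DEFAULT_MIN_OCCUPANCY,
) -> KneeStabilityResult:
    """Measure the CV of one window's knee value under intensity noise.

    For each of ``iterations`` replicates the window's peak intensities are
    independently fluctuated per ``noise`` and the knee value re-extracted;
    the result is sd/mean of the replicate knee values.  Replicate noise
    streams are spawned from ``noise.seed`` so extending ``iterations``
    preserves the earlier replicates.

    The default window is centered at the spectrum midpoint with width 50.
    """
    if iterations < 2:
        raise ValueError("need at least 2 iterations")
    lo, hi = spectrum.mz_range
    if window is None:
        window = (0.5 * (lo + hi), 50.0)
    center, width = window
    base = window_normalization_value(
        spectrum, center, width, min_occupancy=min_occupancy
    )
    if base is None:
        raise ExperimentError(
            f"window ({center:g}, width {width:g}) is not viable on the "
            "base spectrum"
        )
    mask_lo, mask_hi = center - width / 2.0, center + width / 2.0
    i0 = int(np.searchsorted(spectrum.mz, mask_lo, side="left"))
    i1 = int(np.searchsorted(spectrum.mz, mask_hi, side="left"))
    sub = Spectrum(
        mz=spectrum.mz[i0:i1],
        intensity=spectrum.intensity[i0:i1],
        label=spectrum.label,
        scale=spectrum.scale,
    )
    children = np.random.SeedSequence(noise.seed).spawn(iterations)
    values: list[float] = []
    n_failed = 0
    for child in children:
        if noise.cv == 0:
            noisy = sub
        else:
            rng = np.random.default_rng(child)
            factors = np.maximum(
                rng.normal(1.0, noise.cv, size=len(sub)), noise.floor
            )
            noisy = sub.with_intensity(sub.intensity * factors)
        result = window_normalization_value(
            noisy, center, width, min_occupancy=min_occupancy
        )
        if result is None:
            n_failed += 1
        else:
            values.append(result[1])
    if n_failed > 0.2 * iterations:
        raise ExperimentError(
            f"{n_failed}/{iterations} replicates failed to yield a knee"
        )
    arr = np.array(values)
    cv = float(np.std(arr, ddof=1) / np.mean(arr))
    return KneeStabilityResult(cv=cv, values=tuple(values), n_failed=n_failed)
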