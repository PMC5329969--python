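"""Sliding-window normalization curve and spectrum standardization.

A window of fixed m/z width (default 50 Th) slides across the spectrum in
steps of m/z 1; each viable window contributes a normalization point
(window center, knee value).  A smoothing spline through these points is
the normalization curve.  Dividing every peak intensity by the curve value
at the peak's m/z converts the spectrum to a dimensionless,
instrument-independent scale in which the knee level is ~1 everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline, make_interp_spline, make_smoothing_spline

from .errors import StandardizationError
from .kneefinder import (
    DEFAULT_MIN_OCCUPANCY,
    WindowResult,
    analyze_window,
)
from .peaks_io import Scale, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_WIDTH",
    "DEFAULT_STEP",
    "NormalizationPoint",
    "NormalizationCurve",
    "compute_normalization_points",
    "fit_normalization_curve",
    "standardize_spectrum",
    "standardize",
]

DEFAULT_WIDTH = 50.0
DEFAULT_STEP = 1.0

#: Residual bound for the smoothing spline: the standard deviation of
#: (spline - points) must not exceed this fraction of the points' median.
MAX_RESIDUAL_FRACTION = 0.15


@dataclass(frozen=True)
class NormalizationPoint:
    center_mz: float
    value: float  # knee intensity, > 0


@dataclass(frozen=True)
class NormalizationCurve:
    """Smoothing spline through normalization points with guarded extrapolation.

    Peaks within half a window width of the spectrum edges have no window of
    their own, so the curve must be evaluated outside its support.  Cubic
    spline extrapolation is unstable there; instead the curve is continued
    by its endpoint tangent (``extrapolation="linear"``, the default, which
    keeps following a trend such as a linear gain ramp) or by the constant
    endpoint value (``extrapolation="clamp"``).  Either way the result is
    floored at 1% of the endpoint value so division stays positive.
    """

    support: tuple[NormalizationPoint, ...]
    spline: BSpline
    lam: float | None  # smoothing parameter actually used (None = interpolating)
    extrapolation: str = "linear"

    @property
    def centers(self) -> np.ndarray:
        return np.array([p.center_mz for p in self.support])

    @property
    def values(self) -> np.ndarray:
        return np.array([p.value for p in self.support])

    def __call__(self, mz) -> np.ndarray:
        mz = np.atleast_1d(np.asarray(mz, dtype=float))
        lo, hi = self.support[0].center_mz, self.support[-1].center_mz
        out = self.spline(np.clip(mz, lo, hi))
        if self.extrapolation == "linear":
            # secant slope over the outer stretch of support: far more stable
            # than the endpoint tangent of a smoothing spline
            h = min(25.0, 0.25 * (hi - lo))
            below, above = mz < lo, mz > hi
            if np.any(below):
                v = float(self.spline(lo))
                s = (float(self.spline(lo + h)) - v) / h
                ext = v + s * (mz[below] - lo)
                out[below] = np.clip(ext, 0.1 * v, 10.0 * v)
            if np.any(above):
                v = float(self.spline(hi))
                s = (v - float(self.spline(hi - h))) / h
                ext = v + s * (mz[above] - hi)
                out[above] = np.clip(ext, 0.1 * v, 10.0 * v)
        return out


def compute_normalization_points(
    spectrum: Spectrum,
    width: float = DEFAULT_WIDTH,
    step: float = DEFAULT_STEP,
    min_occupancy: int = DEFAULT_MIN_OCCUPANCY,
    edge_windows: bool = True,
    return_diagnostics: bool = False,
):
    """Slide the window across the spectrum and collect knee values.

    Full-width centers start at ``mz_min + width/2`` and advance by ``step``
    while the window still fits inside the spectrum.  Windows that fail
    occupancy or fitting are omitted (gaps are bridged by the spline later).

    With ``edge_windows=True`` (the default) additional windows, truncated
    at the spectrum boundaries, are analyzed so the normalization curve has
    support inside the half-window edge zones; a truncated window's knee
    value is keyed to the mean m/z of its peaks rather than the nominal
    center, since its content is one-sided.  Without edge windows, peaks in
    the edge zones rely entirely on extrapolation of the curve, which cannot
    follow an intensity distortion that keeps changing there.

    Returns the list of :class:`NormalizationPoint`; with
    ``return_diagnostics=True`` also the per-window :class:`WindowResult`
    records (full-width windows only).
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be > 0")
    lo, hi = spectrum.mz_range
    if hi - lo < width:
        raise StandardizationError(
            f"spectrum m/z span {hi - lo:.3f} is smaller than the window "
            f"width {width:g}; standardization is not applicable"
        )
    n_centers = int(np.floor((hi - lo - width) / step + 1e-9)) + 1
    centers = lo + width / 2.0 + step * np.arange(n_centers)
    points: list[NormalizationPoint] = []
    diagnostics: list[WindowResult] = []
    for center in centers:
        result = analyze_window(spectrum, float(center), width, min_occupancy)
        diagnostics.append(result)
        if result.knee is not None:
            points.append(NormalizationPoint(float(center), result.knee.value))
        else:
            logger.debug(
                "no normalization point at m/z %.3f (%s)", center, result.reason
            )

    if edge_windows:
        half = width / 2.0
        edge_centers = np.concatenate([
            np.arange(lo - half + step, lo + half, step),
            np.arange(hi + half - step, hi - half, -step)[::-1],
        ])
        for center in edge_centers:
            result = analyze_window(spectrum, float(center), width, min_occupancy)
            if result.knee is None:
                continue
            w_lo = max(center - half, lo)
            w_hi = min(center + half, hi + 1e-12)
            i0 = int(np.searchsorted(spectrum.mz, w_lo, side="left"))
            i1 = int(np.searchsorted(spectrum.mz, w_hi, side="left"))
            key_mz = float(np.mean(spectrum.mz[i0:i1]))
            points.append(NormalizationPoint(key_mz, result.knee.value))
        points.sort(key=lambda p: p.center_mz)
        # drop support points closer than step/4 to their neighbor
        kept: list[NormalizationPoint] = []
        for p in points:
            if kept and p.center_mz - kept[-1].center_mz < step / 4.0:
                continue
            kept.append(p)
        points = kept

    if len(points) < 4:
        raise StandardizationError(
            f"only {len(points)} viable normalization points (need >= 4); "
            "spectrum too sparse for standardization"
        )
    if return_diagnostics:
        return points, diagnostics
    return points


def _spline_at(x: np.ndarray, y: np.ndarray, lam: float | None) -> BSpline:
    if lam == 0.0:
        return make_interp_spline(x, y, k=3)
    return make_smoothing_spline(x, y, lam=lam)


def fit_normalization_curve(
    points,
    lam: float | None = None,
    max_residual_fraction: float = MAX_RESIDUAL_FRACTION,
    extrapolation: str = "linear",
) -> NormalizationCurve:
    """Fit a smoothing spline through normalization points.

    The smoothing parameter defaults to generalized cross-validation; if the
    GCV curve is too stiff (residual standard deviation above
    ``max_residual_fraction`` of the median point value) the penalty is
    tightened until the bound holds.  Point values are rescaled by their
    median before fitting (and the spline rescaled back), so the curve is
    equivariant under intensity scaling; the rescaled values are rounded to
    12 significant digits so that spectra differing only by a uniform factor
    select bitwise-identical spline shapes.
    """
    points = [
        p if isinstance(p, NormalizationPoint) else NormalizationPoint(*p)
        for p in points
    ]
    if len(points) < 4:
        raise StandardizationError("need >= 4 normalization points for a spline")
    x = np.array([p.center_mz for p in points])
    y = np.array([p.value for p in points])
    if np.any(np.diff(x) <= 0):
        raise StandardizationError("normalization point centers must be increasing")
    if np.any(y <= 0):
        raise StandardizationError("normalization values must be > 0")

    med = float(np.median(y))
    yn = np.array([float(f"{v:.12g}") for v in y / med])

    if len(points) == 4:
        # below the smoothing-spline minimum; interpolate
        lam_used: float | None = 0.0
        spline_n = _spline_at(x, yn, 0.0)
    elif lam is not None:
        lam_used = float(lam)
        spline_n = _spline_at(x, yn, lam_used)
    else:
        spline_n = make_smoothing_spline(x, yn)  # GCV choice
        # recover the implied penalty only to drive the tightening loop
        lam_used = None
        bound = max_residual_fraction * float(np.median(yn))
        resid_sd = float(np.std(spline_n(x) - yn))
        if resid_sd > bound:
            trial = 1.0
            for _ in range(80):
                candidate = make_smoothing_spline(x, yn, lam=trial)
                if float(np.std(candidate(x) - yn)) <= bound:
                    spline_n, lam_used = candidate, trial
                    break
                trial *= 0.25
            else:
                raise StandardizationError(
                    "smoothing spline cannot satisfy the residual bound"
                )

    fine = np.linspace(x[0], x[-1], 2001)
    if np.any(spline_n(fine) <= 0):
        raise StandardizationError(
            "normalization curve dips to <= 0 on its support; increase the "
            "smoothing parameter (lam)"
        )
    if extrapolation not in ("linear", "clamp"):
        raise ValueError("extrapolation must be 'linear' or 'clamp'")
    # rescale the spline back to intensity units
    spline = BSpline(spline_n.t, spline_n.c * med, spline_n.k)
    return NormalizationCurve(
        support=tuple(points), spline=spline, lam=lam_used,
        extrapolation=extrapolation,
    )


def standardize_spectrum(spectrum: Spectrum, curve: NormalizationCurve) -> Spectrum:
    """Divide every peak intensity by the normalization curve at its m/z."""
    divisor = curve(spectrum.mz)
    if np.any(divisor <= 0) or not np.all(np.isfinite(divisor)):
        raise StandardizationError(
            "normalization curve evaluated non-positive or non-finite"
        )
    return spectrum.with_intensity(
        spectrum.intensity / divisor, scale=Scale.standardized
    )


def standardize(
    spectrum: Spectrum,
    width: float = DEFAULT_WIDTH,
    step: float = DEFAULT_STEP,
    min_occupancy: int = DEFAULT_MIN_OCCUPANCY,
    lam: float | None = None,
) -> tuple[Spectrum, NormalizationCurve]:
    """End-to-end standardization: points -> curve -> division.

    Returns the standardized spectrum and the normalization curve used.
    """
    points = compute_normalization_points(
        spectrum, width=width, step=step, min_occupancy=min_occupancy
    )
    curve = fit_normalization_curve(points, lam=lam)
    return standardize_spectrum(spectrum, curve), curve
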