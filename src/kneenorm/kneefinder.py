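"""Power-law fit of rank-ordered window intensities and knee-point detection.

Within a sliding m/z window the peak intensities, arranged in descending
order, follow a power law y = a*x**b + c in the rank x (a > 0, b < 0,
c >= 0).  The knee — the point of maximum curvature of that fitted curve —
is remarkably stable under per-peak concentration fluctuations because its
position is set by the whole assemblage of substances in the window, not by
any individual peak.  The knee intensity therefore serves as a label-free
internal standard for the window.

Curvature is evaluated on the axis-normalized curve (rank rescaled to [0, 1]
by the window size n, intensity rescaled to [0, 1] by its range over
[1, n]).  Raw-axis curvature would move with any rescaling of the intensity
axis; normalizing the axes makes the knee rank invariant and the knee value
exactly equivariant under intensity scaling, which is what lets the
standardization cancel a uniform distortion exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import (
    DegenerateWindowError,
    FitError,
    KneeNotFoundError,
    OccupancyError,
)
from .peaks_io import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_MIN_OCCUPANCY",
    "RankedIntensities",
    "PowerFit",
    "KneePoint",
    "WindowResult",
    "rank_window",
    "fit_power",
    "find_knee",
    "analyze_window",
    "window_normalization_value",
]

#: A 3-parameter nonlinear fit plus curvature maximization is unstable on
#: very small windows; windows below this occupancy are skipped.
DEFAULT_MIN_OCCUPANCY = 20

_B_BOUNDS = (-10.0, -1e-9)
_FIT_TOL = 1e-8
_MAX_ITER = 1000


@dataclass(frozen=True)
class RankedIntensities:
    """Window intensities in descending order with ranks 1..n."""

    ranks: np.ndarray
    intensities: np.ndarray

    @property
    def n(self) -> int:
        return int(self.intensities.size)


@dataclass(frozen=True)
class PowerFit:
    """Least-squares parameters of y = a*x**b + c on ranked intensities."""

    a: float
    b: float
    c: float
    r2: float
    n: int

    def __call__(self, x) -> np.ndarray:
        return self.a * np.asarray(x, dtype=float) ** self.b + self.c


@dataclass(frozen=True)
class KneePoint:
    """Maximum-curvature point of the axis-normalized fitted curve."""

    rank: float  # continuous position in (1, n)
    value: float  # fitted (un-normalized) intensity a*rank**b + c


@dataclass(frozen=True)
class WindowResult:
    """Diagnostic record for one window of the sliding-window pass."""

    center_mz: float
    n: int
    fit: PowerFit | None
    knee: KneePoint | None
    reason: str | None  # None on success; why the window was skipped otherwise


def rank_window(
    intensities, min_occupancy: int = DEFAULT_MIN_OCCUPANCY
) -> RankedIntensities:
    """Arrange window intensities in descending order.

    Ties are broken by input position (stable sort); callers passing
    intensities in m/z order therefore get a deterministic
    (intensity descending, m/z ascending) ordering.
    """
    values = np.asarray(intensities, dtype=float).ravel()
    if values.size < min_occupancy:
        raise OccupancyError(
            f"window holds {values.size} peaks, fewer than the minimum "
            f"occupancy {min_occupancy}"
        )
    if np.any(values <= 0) or not np.all(np.isfinite(values)):
        raise ValueError("window intensities must be positive and finite")
    order = np.argsort(-values, kind="stable")
    ranked = values[order]
    return RankedIntensities(
        ranks=np.arange(1, values.size + 1), intensities=ranked
    )


def fit_power(ranked: RankedIntensities) -> PowerFit:
    """Fit y = a*x**b + c (a > 0, b < 0, c >= 0) to ranked intensities.

    The fit runs on intensities normalized by their maximum for numerical
    conditioning (window intensities span orders of magnitude); parameters
    are rescaled back afterwards, which also makes the fit equivariant under
    intensity scaling to floating-point accuracy.
    """
    y = ranked.intensities
    x = ranked.ranks.astype(float)
    ymax = float(y[0])
    spread = (y[0] - y[-1]) / ymax if ymax > 0 else 0.0
    if spread < 1e-9:
        raise DegenerateWindowError(
            "window intensities are near-constant; power fit is degenerate"
        )
    yn = y / ymax
    # endpoint-based initialization: a0 from the dynamic range, c0 from the tail
    p0 = (float(yn[0] - yn[-1]), -1.0, float(yn[-1]))
    lower = (1e-12, _B_BOUNDS[0], 0.0)
    upper = (np.inf, _B_BOUNDS[1], np.inf)
    try:
        popt, _ = optimize.curve_fit(
            lambda xx, a, b, c: a * xx**b + c,
            x,
            yn,
            p0=p0,
            bounds=(lower, upper),
            ftol=_FIT_TOL,
            xtol=_FIT_TOL,
            gtol=_FIT_TOL,
            maxfev=_MAX_ITER,
        )
    except RuntimeError as exc:
        raise FitError(f"power fit did not converge: {exc}") from exc
    a, b, c = float(popt[0]), float(popt[1]), float(popt[2])
    resid = yn - (a * x**b + c)
    ss_res = float(np.dot(resid, resid))
    ss_tot = float(np.sum((yn - yn.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return PowerFit(a=a * ymax, b=b, c=c * ymax, r2=r2, n=ranked.n)


def _curvature_terms(u: np.ndarray, b: float, q: float, n: int):
    """First three derivatives of the normalized curve Y(u), u = rank/n."""
    t = u * n
    yp = q * t ** (b - 1.0)
    ypp = q * (b - 1.0) * n * t ** (b - 2.0)
    yppp = q * (b - 1.0) * (b - 2.0) * n * n * t ** (b - 3.0)
    return yp, ypp, yppp


def find_knee(
    fit: PowerFit, n: int, min_occupancy: int = DEFAULT_MIN_OCCUPANCY
) -> KneePoint:
    """Locate the maximum of the plane-curve curvature of the fitted curve.

    The curve is axis-normalized (rank / n on the abscissa, intensity
    rescaled by its range over [1, n] on the ordinate) and the curvature
    kappa = |Y''| / (1 + Y'^2)^(3/2) is maximized on the interior of
    (1/n, 1).  The stationarity condition
    Y'''*(1 + Y'^2) - 3*Y'*Y''^2 = 0 is solved by bracketed root finding
    seeded from a 1000-point grid, so the knee rank is resolved essentially
    to machine precision.  The returned value is the un-normalized fitted
    intensity at the knee rank.
    """
    if n < min_occupancy:
        raise OccupancyError(
            f"window size {n} below minimum occupancy {min_occupancy}"
        )
    a, b, c = fit.a, fit.b, fit.c
    if not (a > 0 and b < 0):
        raise KneeNotFoundError("power fit must have a > 0 and b < 0")
    yrange = a * (1.0 - float(n) ** b)  # y(1) - y(n), positive
    q = n * a * b / yrange  # slope prefactor of the normalized curve

    def stationarity(u):
        yp, ypp, yppp = _curvature_terms(np.asarray(u, dtype=float), b, q, n)
        return yppp * (1.0 + yp * yp) - 3.0 * yp * ypp * ypp

    u_lo, u_hi = 1.0 / n, 1.0
    grid = np.linspace(u_lo, u_hi, 1000)
    h = stationarity(grid)
    sign_change = np.flatnonzero(np.sign(h[:-1]) * np.sign(h[1:]) < 0)

    if sign_change.size:
        # pick the sign change at the largest curvature (there is normally one)
        def kappa(u):
            yp, ypp, _ = _curvature_terms(np.asarray(u, dtype=float), b, q, n)
            return np.abs(ypp) / (1.0 + yp * yp) ** 1.5

        best = max(
            sign_change,
            key=lambda i: float(kappa(0.5 * (grid[i] + grid[i + 1]))),
        )
        u_star = float(
            optimize.brentq(
                stationarity, grid[best], grid[best + 1], xtol=1e-15, rtol=8.9e-16
            )
        )
    else:
        # fallback: direct bounded maximization of the curvature
        def neg_kappa(u):
            yp, ypp, _ = _curvature_terms(np.asarray(u, dtype=float), b, q, n)
            return -np.abs(ypp) / (1.0 + yp * yp) ** 1.5

        res = optimize.minimize_scalar(
            neg_kappa,
            bounds=(u_lo, u_hi),
            method="bounded",
            options={"xatol": 1e-10},
        )
        u_star = float(res.x)
        if u_star <= u_lo + 1e-8 or u_star >= u_hi - 1e-8:
            raise KneeNotFoundError(
                "curvature has no interior maximum on the window"
            )

    rank = u_star * n
    if not (1.0 < rank < n):
        raise KneeNotFoundError(
            f"knee rank {rank:.3f} is not interior to (1, {n})"
        )
    return KneePoint(rank=rank, value=float(a * rank**b + c))


def analyze_window(
    spectrum: Spectrum,
    center_mz: float,
    width: float = 50.0,
    min_occupancy: int = DEFAULT_MIN_OCCUPANCY,
) -> WindowResult:
    """Rank, fit and knee-find one window; failures become a skip reason.

    Window membership uses the half-open interval
    [center - width/2, center + width/2) so every peak belongs to exactly
    one window for a given center grid.
    """
    if width <= 0:
        raise ValueError("window width must be > 0")
    values = spectrum.slice_mz(center_mz - width / 2.0, center_mz + width / 2.0)
    n = int(values.size)
    try:
        ranked = rank_window(values, min_occupancy=min_occupancy)
    except OccupancyError:
        return WindowResult(center_mz, n, None, None, "occupancy")
    try:
        fit = fit_power(ranked)
    except DegenerateWindowError:
        return WindowResult(center_mz, n, None, None, "degenerate")
    except FitError:
        return WindowResult(center_mz, n, None, None, "fit")
    try:
        knee = find_knee(fit, ranked.n, min_occupancy=min_occupancy)
    except KneeNotFoundError:
        return WindowResult(center_mz, n, fit, None, "knee")
    return WindowResult(center_mz, n, fit, knee, None)


def window_normalization_value(
    spectrum: Spectrum,
    center_mz: float,
    width: float = 50.0,
    min_occupancy: int = DEFAULT_MIN_OCCUPANCY,
) -> tuple[float, float] | None:
    """Knee value of the window centered at ``center_mz``, or None.

    Returns ``(center_mz, knee value)``; a window that fails occupancy or
    fitting yields None (logged with the reason) rather than an error, since
    gaps are expected and are bridged later by the normalization curve.
    """
    result = analyze_window(spectrum, center_mz, width, min_occupancy)
    if result.knee is None:
        logger.debug(
            "window at m/z %.3f skipped (%s, n=%d)",
            center_mz,
            result.reason,
            result.n,
        )
        return None
    return (center_mz, result.knee.value)
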