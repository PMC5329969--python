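"""Pairwise spectrum comparison statistics.

After standardization, spectra of the same sample acquired on different
instruments (or with different settings) should agree peak-for-peak.  This
module pairs peaks between two spectra by m/z proximity and quantifies the
agreement with an ordinary least-squares line (slope, intercept, R^2),
Pearson and Spearman correlations, and Passing-Bablok regression — the
nonparametric method-comparison estimator whose slope 1 / intercept 0
indicates interchangeable measurement scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import EstimatorError, UndefinedStatisticError
from .peaks_io import Scale, Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_MATCH_TOL",
    "PairedIntensities",
    "ConcordanceResult",
    "match_peaks",
    "linear_concordance",
    "passing_bablok",
    "compare_spectra",
]

#: Default absolute m/z matching tolerance in Thomson.
DEFAULT_MATCH_TOL = 0.005

#: Above this many matched pairs, Passing-Bablok subsamples (fixed seed) to
#: cap the O(n^2) pairwise-slope enumeration.
PB_MAX_PAIRS = 5000
_PB_SUBSAMPLE_SEED = 20170228


@dataclass(frozen=True)
class PairedIntensities:
    """Matched peak intensities of two spectra."""

    x: np.ndarray
    y: np.ndarray
    n_unmatched_x: int
    n_unmatched_y: int

    @property
    def n_matched(self) -> int:
        return int(self.x.size)


@dataclass(frozen=True)
class ConcordanceResult:
    slope: float
    intercept: float
    r2: float
    pearson_r: float
    spearman_rho: float
    pb_slope: float
    pb_intercept: float
    pb_slope_ci: tuple[float, float]
    pb_intercept_ci: tuple[float, float]
    n_matched: int

    def as_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r2": self.r2,
            "pearson_r": self.pearson_r,
            "spearman_rho": self.spearman_rho,
            "pb_slope": self.pb_slope,
            "pb_intercept": self.pb_intercept,
            "pb_slope_ci": list(self.pb_slope_ci),
            "pb_intercept_ci": list(self.pb_intercept_ci),
            "n_matched": self.n_matched,
        }


def match_peaks(
    a: Spectrum, b: Spectrum, tol: float = DEFAULT_MATCH_TOL
) -> PairedIntensities:
    """Pair peaks of two spectra by m/z proximity.

    Greedy one-to-one matching resolved globally by ascending |delta m/z|
    (ties broken by m/z), so match(a, b) mirrors match(b, a).  A tolerance
    of 0 matches only exact m/z equality.  Zero matches is a valid empty
    result.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    amz, bmz = a.mz, b.mz
    cand_i: list[int] = []
    cand_j: list[int] = []
    for i, m in enumerate(amz):
        j0 = int(np.searchsorted(bmz, m - tol, side="left"))
        j1 = int(np.searchsorted(bmz, m + tol, side="right"))
        for j in range(j0, j1):
            if abs(bmz[j] - m) <= tol:
                cand_i.append(i)
                cand_j.append(j)
    if not cand_i:
        return PairedIntensities(
            np.empty(0), np.empty(0), len(a), len(b)
        )
    ci = np.array(cand_i)
    cj = np.array(cand_j)
    dist = np.abs(bmz[cj] - amz[ci])
    order = np.lexsort((cj, ci, dist))
    used_a = np.zeros(len(a), dtype=bool)
    used_b = np.zeros(len(b), dtype=bool)
    xs: list[float] = []
    ys: list[float] = []
    for k in order:
        i, j = int(ci[k]), int(cj[k])
        if used_a[i] or used_b[j]:
            continue
        used_a[i] = used_b[j] = True
        xs.append(a.intensity[i])
        ys.append(b.intensity[j])
    return PairedIntensities(
        np.array(xs),
        np.array(ys),
        int(np.count_nonzero(~used_a)),
        int(np.count_nonzero(~used_b)),
    )


def linear_concordance(p: PairedIntensities):
    """OLS line of y on x plus Pearson and Spearman correlations.

    Returns ``(slope, intercept, r2, pearson_r, spearman_rho)``.
    """
    if p.n_matched < 3:
        raise UndefinedStatisticError(
            f"need >= 3 matched pairs, have {p.n_matched}"
        )
    if np.ptp(p.x) == 0 or np.ptp(p.y) == 0:
        raise UndefinedStatisticError("zero variance in x or y")
    fit = stats.linregress(p.x, p.y)
    rho = stats.spearmanr(p.x, p.y).statistic
    return (
        float(fit.slope),
        float(fit.intercept),
        float(fit.rvalue**2),
        float(fit.rvalue),
        float(rho),
    )


def _pairwise_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    n = x.size
    ii, jj = np.triu_indices(n, k=1)
    dx = x[jj] - x[ii]
    dy = y[jj] - y[ii]
    slopes = np.empty(dx.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = dy / dx
    vertical = dx == 0
    slopes[vertical] = np.where(dy[vertical] > 0, np.inf, -np.inf)
    keep = ~(vertical & (dy == 0))  # identical points carry no slope
    keep &= slopes != -1.0  # slopes of exactly -1 are disregarded
    return slopes[keep]


def passing_bablok(p: PairedIntensities, subsample: int = PB_MAX_PAIRS):
    """Passing-Bablok regression with 95% confidence intervals.

    The slope is the shifted median of all pairwise slopes S_ij (i<j):
    slopes equal to exactly -1 are discarded, K = #{S_ij < -1}, and the
    estimate is the K-offset median of the sorted slopes; the intercept is
    median(y - slope*x).  Confidence bounds use the rank-based normal
    approximation with C = 1.96*sqrt(n(n-1)(2n+5)/18).

    Beyond ``subsample`` pairs the computation runs on a fixed-seed subsample
    to cap the O(n^2) slope enumeration.

    Returns ``(slope, intercept, slope_ci, intercept_ci)``.
    """
    x, y = p.x, p.y
    n = x.size
    if n < 10:
        raise EstimatorError(f"need >= 10 matched pairs, have {n}")
    if np.ptp(x) == 0:
        raise EstimatorError("all x values equal; slope undefined")
    if n > subsample:
        rng = np.random.default_rng(_PB_SUBSAMPLE_SEED)
        idx = np.sort(rng.choice(n, size=subsample, replace=False))
        x, y = x[idx], y[idx]
        n = subsample
        logger.info("Passing-Bablok subsampled %d of %d pairs", subsample, p.n_matched)

    slopes = np.sort(_pairwise_slopes(x, y))
    big_n = slopes.size
    if big_n == 0:
        raise EstimatorError("no finite pairwise slopes")
    k_off = int(np.count_nonzero(slopes < -1.0))

    def shifted(idx1: int) -> float:
        # 1-based index into the K-shifted sorted slopes, clipped to range
        return float(slopes[np.clip(idx1 - 1 + k_off, 0, big_n - 1)])

    if big_n % 2:
        slope = shifted((big_n + 1) // 2)
    else:
        slope = 0.5 * (shifted(big_n // 2) + shifted(big_n // 2 + 1))
    intercept = float(np.median(y - slope * x))

    c_crit = 1.96 * np.sqrt(n * (n - 1) * (2 * n + 5) / 18.0)
    m1 = int(round((big_n - c_crit) / 2.0))
    m2 = big_n - m1 + 1
    slope_lo, slope_hi = shifted(m1), shifted(m2)
    intercept_lo = float(np.median(y - slope_hi * x))
    intercept_hi = float(np.median(y - slope_lo * x))
    return (
        slope,
        intercept,
        (slope_lo, slope_hi),
        (intercept_lo, intercept_hi),
    )


def compare_spectra(
    a: Spectrum, b: Spectrum, tol: float = DEFAULT_MATCH_TOL
) -> ConcordanceResult:
    """Full comparison report: matching + linear + Passing-Bablok."""
    if a.scale is not Scale.standardized or b.scale is not Scale.standardized:
        logger.warning(
            "comparing spectra that are not both standardized "
            "(scales: %s, %s)", a.scale.value, b.scale.value
        )
    p = match_peaks(a, b, tol)
    slope, intercept, r2, pearson_r, rho = linear_concordance(p)
    pb_slope, pb_intercept, slope_ci, intercept_ci = passing_bablok(p)
    return ConcordanceResult(
        slope=slope,
        intercept=intercept,
        r2=r2,
        pearson_r=pearson_r,
        spearman_rho=rho,
        pb_slope=pb_slope,
        pb_intercept=pb_intercept,
        pb_slope_ci=slope_ci,
        pb_intercept_ci=intercept_ci,
        n_matched=p.n_matched,
    )
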