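"""Largest-patch time-series diagnostics.

Near a fragmentation threshold the largest forest patch develops a
filamentary structure, so small losses produce large fluctuations in its
size.  The early-warning indicators computed here are:

* the largest-patch proportion series RS_max(t) = S_max(t) / sum_i S_i(t),
* the centred fluctuation series dRS_max(t) = RS_max(t) - <RS_max>
  (and the absolute analogue dS_max),
* the tail family of the fluctuation distribution (heavy vs exponential),
* the trend in fluctuation variance via 10%/90% quantile regression, and
* the sample skewness of the fluctuations (negative before fragmentation:
  drops below the mean dominate).

Quantile regression slopes are exact pinball-loss minimisers (the optimal
line for a single regressor interpolates two observations, so the solver
enumerates candidate lines); their significance comes from a seeded
moving-block bootstrap, which respects the short-range autocorrelation of
a yearly series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import fitting
from .dip import DipResult, dip_statistic, dip_test  # re-exported  # noqa: F401
from .raster import PatchCensus

__all__ = [
    "LargestPatchSeries",
    "TrendResult",
    "DipResult",
    "build_series",
    "fit_fluctuations",
    "skewness",
    "quantile_slope",
    "variance_trend",
    "dip_test",
    "dip_statistic",
]

FLUCTUATION_MODELS = ("powerlaw", "lognormal", "exponential")


@dataclass(frozen=True)
class LargestPatchSeries:
    """Aligned yearly series of largest-patch statistics for one threshold."""

    years: np.ndarray
    s_max: np.ndarray
    total_forest: np.ndarray
    threshold: float = float("nan")
    region_id: str = "region"

    def __post_init__(self) -> None:
        for name in ("years", "s_max", "total_forest"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.years.size == self.s_max.size == self.total_forest.size):
            raise ValueError("series fields must be aligned on years")

    @property
    def rs_max(self) -> np.ndarray:
        return self.s_max / self.total_forest

    @property
    def delta_s_max(self) -> np.ndarray:
        return self.s_max - self.s_max.mean()

    @property
    def delta_rs_max(self) -> np.ndarray:
        r = self.rs_max
        return r - r.mean()

    @property
    def n_years(self) -> int:
        return int(self.years.size)


@dataclass(frozen=True)
class TrendResult:
    """Quantile-regression slope of a fluctuation series on year.

    ``ci_lower``/``ci_upper`` are the percentile bootstrap confidence bounds
    for the slope; it is significant when the interval excludes zero.
    """

    quantile: float
    slope: float
    significant: bool
    ci_lower: float
    ci_upper: float
    series: str = "delta_rs_max"


def build_series(censuses: Sequence[PatchCensus]) -> LargestPatchSeries:
    """Assemble the yearly largest-patch series from per-year censuses."""
    if len(censuses) < 3:
        raise ValueError("need at least 3 yearly censuses")
    region = censuses[0].region_id
    thr = censuses[0].threshold
    for c in censuses:
        if c.region_id != region or not _thr_eq(c.threshold, thr):
            raise ValueError("censuses must share region and threshold")
        if c.is_empty:
            raise ValueError(f"empty census for year {c.year}")
    order = np.argsort([c.year for c in censuses])
    cs = [censuses[i] for i in order]
    return LargestPatchSeries(
        years=[c.year for c in cs],
        s_max=[c.s_max for c in cs],
        total_forest=[c.total_forest for c in cs],
        threshold=thr,
        region_id=region,
    )


def _thr_eq(a: float, b: float) -> bool:
    return (np.isnan(a) and np.isnan(b)) or a == b


def skewness(series: LargestPatchSeries | np.ndarray) -> float:
    """Sample skewness g1 = m3 / m2^(3/2) of the relative fluctuations.

    Shift-invariant, so identical for RS_max and dRS_max.
    """
    x = series.delta_rs_max if isinstance(series, LargestPatchSeries) else np.asarray(series, float)
    if x.size < 3:
        raise ValueError("skewness requires >= 3 values")
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 == 0:
        raise ValueError("skewness undefined: zero variance")
    return float(np.mean(d**3) / m2**1.5)


def fit_fluctuations(
    series: LargestPatchSeries,
    which: str = "delta_rs_max",
    min_tail: int = 4,
) -> fitting.ModelSelection:
    """Fit power-law / log-normal / exponential models to |fluctuations|.

    Fluctuations are signed; the heavy-vs-exponential tail question concerns
    their magnitudes, so the three models are fitted to |d| > 0 with the
    smallest magnitude as the shared lower bound.  With a short yearly
    series the likelihood-ratio tests are usually inconclusive: when no
    test reaches p < 0.05 the best model is reported as "undetermined".
    """
    d = np.abs(getattr(series, which))
    d = d[d > 0]
    if d.size < 8:
        raise ValueError(f"need >= 8 non-zero fluctuations, got {d.size}")
    if np.allclose(d, d[0]):
        raise ValueError("degenerate fluctuation series (all magnitudes equal)")
    x_min = d.min()
    fits = fitting.fit_all(d, x_min=x_min, models=FLUCTUATION_MODELS, min_tail=min_tail)
    sel = fitting.select_model(fits, sizes=d)
    best = sel.best_model
    # the AICc winner counts only if the likelihood-ratio test separates it
    # from every competitor; otherwise the short series cannot decide
    tail_sorted = np.sort(d[d >= x_min])
    l_best = fitting._pointwise_loglik(sel.fits[best], tail_sorted)
    lrt = dict(sel.lrt)
    decided = True
    for m, f in sel.fits.items():
        if m == best:
            continue
        z, p = fitting._vuong(l_best, fitting._pointwise_loglik(f, tail_sorted))
        lrt[f"{best}_vs_{m}"] = (z, p)
        decided &= p < 0.05
    if not decided:
        best = "undetermined"
    return fitting.ModelSelection(
        aicc=sel.aicc, weights=sel.weights, lrt=lrt, best_model=best, fits=sel.fits
    )


# ---------------------------------------------------------------------------
# quantile regression
# ---------------------------------------------------------------------------

def _pinball(u: np.ndarray, tau: float) -> np.ndarray:
    return u * (tau - (u < 0))


#: above this length the exact O(n^3) line enumeration hands over to the
#: interior-point solver in statsmodels
_EXACT_QR_MAX_N = 48


def quantile_slope(t, y, tau: float) -> tuple[float, float]:
    """Pinball-loss linear quantile regression (slope, intercept).

    For short series (the 16-year use case) the solution is exact: the
    optimal line interpolates two observations, so all O(n^2) candidate
    lines are scored directly, ties in loss resolving to the smallest
    |slope|.  Longer series use the iterative solver in statsmodels.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    n = t.size
    if n < 2:
        raise ValueError("need >= 2 points")
    if n > _EXACT_QR_MAX_N:
        return _statsmodels_quantile_slope(t, y, tau)
    ii, jj = np.triu_indices(n, k=1)
    dt = t[jj] - t[ii]
    ok = dt != 0
    ii, jj, dt = ii[ok], jj[ok], dt[ok]
    slopes = (y[jj] - y[ii]) / dt
    inters = y[ii] - slopes * t[ii]
    resid = y[None, :] - (inters[:, None] + slopes[:, None] * t[None, :])
    loss = _pinball(resid, tau).sum(axis=1)
    best = np.flatnonzero(loss <= loss.min() + 1e-12)
    k = best[np.argmin(np.abs(slopes[best]))]
    return float(slopes[k]), float(inters[k])


def _statsmodels_quantile_slope(t: np.ndarray, y: np.ndarray, tau: float) -> tuple[float, float]:
    import statsmodels.api as sm

    X = np.column_stack([np.ones_like(t), t])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.QuantReg(y, X).fit(q=tau)
    return float(res.params[1]), float(res.params[0])


def _batched_quantile_slopes(T: np.ndarray, Y: np.ndarray, tau: float) -> np.ndarray:
    """Exact quantile-regression slopes for each row of (T, Y) (vectorised).

    Pairs with coincident times (possible in a resample) are excluded from
    the candidate-line set for that row.
    """
    B, n = Y.shape
    ii, jj = np.triu_indices(n, k=1)
    dt = T[:, jj] - T[:, ii]  # (B, P)
    with np.errstate(divide="ignore", invalid="ignore"):
        slopes = (Y[:, jj] - Y[:, ii]) / dt
    inters = Y[:, ii] - slopes * T[:, ii]
    resid = Y[:, None, :] - (inters[:, :, None] + slopes[:, :, None] * T[:, None, :])
    loss = _pinball(resid, tau).sum(axis=2)
    loss[dt == 0] = np.inf
    return slopes[np.arange(B), np.argmin(loss, axis=1)]


def _block_bootstrap_slopes(
    t: np.ndarray,
    y: np.ndarray,
    tau: float,
    n_boot: int,
    block: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Moving-block (circular) bootstrap of (year, value) pairs; refit slope."""
    n = t.size
    n_blocks = int(np.ceil(n / block))
    starts = rng.integers(0, n, size=(n_boot, n_blocks))
    offs = np.arange(block)
    idx = (starts[:, :, None] + offs[None, None, :]).reshape(n_boot, -1)[:, :n] % n
    if n <= _EXACT_QR_MAX_N:
        return _batched_quantile_slopes(t[idx], y[idx], tau)
    return np.array(
        [_statsmodels_quantile_slope(t[row], y[row], tau)[0] for row in idx]
    )


def variance_trend(
    series: LargestPatchSeries,
    quantiles: Sequence[float] = (0.10, 0.90),
    which: str = "delta_rs_max",
    n_boot: int = 1000,
    block: int = 4,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[list[TrendResult], str]:
    """Quantile-regression variance trend of the fluctuation series.

    For each quantile tau the slope of the fluctuations on year is fitted by
    pinball-loss minimisation; a slope is significant when the percentile
    interval from a moving-block bootstrap of (year, value) pairs excludes
    zero.  Direction of the variance:
    ``increase`` if the upper-quantile slope is significantly positive or
    the lower-quantile slope significantly negative (the envelope widens),
    ``decrease`` for the reverse, ``NS`` when nothing is significant.
    Conflicting significant signals classify by the larger |slope|.
    """
    y_all = getattr(series, which)
    t = series.years.astype(float)
    n = t.size
    if n < 8:
        raise ValueError(f"need >= 8 time points, got {n}")
    if n < 2 * len(quantiles):
        raise ValueError("fewer points than 2 per quantile")
    rng = np.random.default_rng(seed)
    results: list[TrendResult] = []
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    for tau in quantiles:
        slope, inter = quantile_slope(t, y_all, tau)
        # uncertainty by moving-block bootstrap of (year, value) pairs:
        # resampling whole blocks keeps short-range autocorrelation, and
        # resampling pairs (rather than residuals around the fitted line)
        # keeps the interval calibrated on a 16-point series
        if np.allclose(y_all - (inter + slope * t), 0):
            ci = (slope, slope)
            sig = slope != 0
        else:
            boot = _block_bootstrap_slopes(t, y_all, tau, n_boot, block, rng)
            ci = (float(np.quantile(boot, lo_q)), float(np.quantile(boot, hi_q)))
            sig = ci[0] > 0 or ci[1] < 0
        results.append(
            TrendResult(
                quantile=float(tau),
                slope=slope,
                significant=bool(sig),
                ci_lower=ci[0],
                ci_upper=ci[1],
                series=which,
            )
        )
    direction = _classify_direction(results)
    return results, direction


def _classify_direction(results: Sequence[TrendResult]) -> str:
    """Combine per-quantile slope signs into a variance direction."""
    votes: list[tuple[str, float]] = []
    for r in results:
        if not r.significant:
            continue
        widen = (r.quantile >= 0.5 and r.slope > 0) or (r.quantile < 0.5 and r.slope < 0)
        votes.append(("increase" if widen else "decrease", abs(r.slope)))
    if not votes:
        return "NS"
    dirs = {v[0] for v in votes}
    if len(dirs) == 1:
        return votes[0][0]
    return max(votes, key=lambda v: v[1])[0]
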