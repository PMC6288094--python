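"""Hartigan's dip statistic for departures from unimodality.

The dip of a sample is the smallest sup-norm distance between its empirical
CDF and any unimodal CDF (convex below the mode, concave above it).  It is
computed with the classical Hartigan & Hartigan algorithm: alternating
greatest-convex-minorant / least-concave-majorant constructions on a
shrinking modal interval, in ECDF-count units, halved and normalised at the
end (so the minimum attainable dip is 1/(2n)).

The p-value is calibrated by Monte-Carlo against the uniform null — the
standard reference distribution for the dip — at the observed sample size.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = ["DipResult", "dip_statistic", "dip_test"]


@dataclass(frozen=True)
class DipResult:
    statistic: float
    p_value: float
    n: int
    n_boot: int = 0
    seed: int | None = None


def dip_statistic(values) -> float:
    """Hartigan's dip: sup-norm distance from the ECDF to unimodality."""
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n < 1:
        raise ValueError("dip requires at least one observation")
    if n < 2 or x[0] == x[-1]:
        return 0.5 / n if n else 0.0

    # 1-based arrays to follow the classical formulation
    xx = np.empty(n + 1)
    xx[1:] = x
    mn = np.zeros(n + 1, dtype=np.int64)  # gcm predecessor chains
    mj = np.zeros(n + 1, dtype=np.int64)  # lcm successor chains

    mn[1] = 1
    for j in range(2, n + 1):
        mn[j] = j - 1
        while True:
            mnj = mn[j]
            mnmnj = mn[mnj]
            if mnj == 1 or (xx[j] - xx[mnj]) * (mnj - mnmnj) < (
                xx[mnj] - xx[mnmnj]
            ) * (j - mnj):
                break
            mn[j] = mnmnj

    mj[n] = n
    for k in range(n - 1, 0, -1):
        mj[k] = k + 1
        while True:
            mjk = mj[k]
            mjmjk = mj[mjk]
            if mjk == n or (xx[k] - xx[mjk]) * (mjk - mjmjk) < (
                xx[mjk] - xx[mjmjk]
            ) * (k - mjk):
                break
            mj[k] = mjmjk

    low, high = 1, n
    dip = 1.0  # in ECDF-count units; normalised by 2n on return
    gcm = np.zeros(n + 2, dtype=np.int64)
    lcm = np.zeros(n + 2, dtype=np.int64)

    while True:
        # change points of the gcm (high -> low) and lcm (low -> high)
        ic = 1
        gcm[1] = high
        while gcm[ic] > low:
            gcm[ic + 1] = mn[gcm[ic]]
            ic += 1
        ig = l_gcm = ic
        ix = ig - 1

        ic = 1
        lcm[1] = low
        while lcm[ic] < high:
            lcm[ic + 1] = mj[lcm[ic]]
            ic += 1
        ih = l_lcm = ic
        iv = 2

        # largest distance between the gcm and lcm curves on [low, high]
        d = 0.0
        if l_gcm != 2 or l_lcm != 2:
            while True:
                gcmix = gcm[ix]
                lcmiv = lcm[iv]
                if gcmix > lcmiv:
                    gcmi1 = gcm[ix + 1]
                    dx = (lcmiv - gcmi1 + 1) - (xx[lcmiv] - xx[gcmi1]) * (
                        gcmix - gcmi1
                    ) / (xx[gcmix] - xx[gcmi1])
                    iv += 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv - 1
                else:
                    lcmiv1 = lcm[iv - 1]
                    dx = (xx[gcmix] - xx[lcmiv1]) * (lcmiv - lcmiv1) / (
                        xx[lcmiv] - xx[lcmiv1]
                    ) - (gcmix - lcmiv1 - 1)
                    ix -= 1
                    if dx >= d:
                        d = dx
                        ig = ix + 1
                        ih = iv
                if ix < 1:
                    ix = 1
                if iv > l_lcm:
                    iv = l_lcm
                if gcm[ix] == lcm[iv]:
                    break
        else:
            d = 1.0

        if d < dip:
            break

        # maximal ECDF deviation from the gcm over [low, gcm[ig]]
        dip_l = 0.0
        for j in range(ig, l_gcm):
            lo_i, hi_i = gcm[j + 1], gcm[j]
            max_t = 1.0
            if hi_i - lo_i > 1 and xx[hi_i] != xx[lo_i]:
                c = (hi_i - lo_i) / (xx[hi_i] - xx[lo_i])
                jj = np.arange(lo_i, hi_i + 1)
                t = (jj - lo_i + 1) - (xx[jj] - xx[lo_i]) * c
                max_t = max(max_t, float(t.max()))
            dip_l = max(dip_l, max_t)

        # maximal ECDF deviation from the lcm over [lcm[ih], high]
        dip_u = 0.0
        for j in range(ih, l_lcm):
            lo_i, hi_i = lcm[j], lcm[j + 1]
            max_t = 1.0
            if hi_i - lo_i > 1 and xx[hi_i] != xx[lo_i]:
                c = (hi_i - lo_i) / (xx[hi_i] - xx[lo_i])
                jj = np.arange(lo_i, hi_i + 1)
                t = (xx[jj] - xx[lo_i]) * c - (jj - lo_i - 1)
                max_t = max(max_t, float(t.max()))
            dip_u = max(dip_u, max_t)

        dip = max(dip, dip_l, dip_u)
        new_low, new_high = gcm[ig], lcm[ih]
        if new_low == low and new_high == high:  # no shrinkage -> done
            break
        low, high = new_low, new_high

    return float(dip / (2.0 * n))


@lru_cache(maxsize=32)
def _null_dips(n: int, reps: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    return np.array([dip_statistic(rng.random(n)) for _ in range(reps)])


def dip_test(values, n_boot: int = 2000, seed: int = 0) -> DipResult:
    """Dip statistic with a Monte-Carlo p-value under the uniform null.

    ``p = (1 + #{D_null >= D_obs}) / (1 + n_boot)``; deterministic for a
    given seed (the null table is cached per (n, n_boot, seed)).
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"dip test requires n >= 4, got {n}")
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    d = dip_statistic(x)
    null = _null_dips(n, n_boot, seed)
    p = (1.0 + np.sum(null >= d)) / (1.0 + n_boot)
    return DipResult(statistic=d, p_value=float(p), n=n, n_boot=n_boot, seed=seed)
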