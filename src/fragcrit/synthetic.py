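"""Synthetic landscapes: percolation lattices, contact-process dynamics and
multi-year region fixtures.

These generators provide percolation-theory ground truth for the pipeline.
Random site percolation with the Moore neighbourhood is the reference model:
at the critical occupancy p_c the patch-size distribution is a power law
with the isotropic-percolation universality-class exponent (alpha = 2.05495
in 2D), below p_c the landscape is fragmented, and above it a patch
containing most of the forest spans the lattice.  The critical occupancy is
located empirically by a spanning-probability scan rather than hard-coded.

The contact process adds simple forest dynamics (colonisation from occupied
Moore neighbours at rate lambda per neighbour fraction, extinction at unit
rate) with an absorbing empty state; it illustrates how a dynamical model
crosses the same kind of fragmentation threshold.

Region fixtures emulate a 16-year series of percent-cover rasters.  Cell
cover is drawn as ``100 * (1 - u)**gamma`` with u uniform, so a single
occupancy parameter at the focal 30% threshold maps monotonically to every
threshold in the 20-40% sweep: lower thresholds see a denser forest, higher
ones a sparser one, exactly as with real percent-cover data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .raster import (
    DEFAULT_THRESHOLDS,
    BinaryLandscape,
    CoverRaster,
    PatchCensus,
    census_sweep,
    label_patches,
)

__all__ = [
    "PercolationParams",
    "ContactProcessParams",
    "ScenarioSpec",
    "percolation_lattice",
    "spanning_probability",
    "find_critical_occupancy",
    "periodic_patch_sizes",
    "critical_cluster_sizes",
    "contact_process",
    "powerlaw_sample",
    "cover_from_occupancy",
    "region_fixture",
    "region_cover_series",
]

_MOORE = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PercolationParams:
    L: int
    p: float
    seed: int = 0
    boundary: Literal["open", "periodic"] = "open"

    def __post_init__(self) -> None:
        if self.L < 2:
            raise ValueError("lattice side L must be >= 2")
        if not 0 <= self.p <= 1:
            raise ValueError("occupancy p must be in [0, 1]")


@dataclass(frozen=True)
class ContactProcessParams:
    """Asynchronous contact process on an L x L lattice.

    One time step ("year") is L^2 update attempts.  An occupied site goes
    extinct with probability 1/(1+lam) per attempt; an empty site is
    colonised with probability lam/(1+lam) * (occupied Moore neighbours)/8.
    """

    L: int
    lam: float
    steps: int = 16
    initial_density: float = 0.5
    seed: int = 0
    boundary: Literal["open", "periodic"] = "periodic"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("colonisation rate must be >= 0")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


@dataclass(frozen=True)
class ScenarioSpec:
    """A 16-year regional scenario in a chosen percolation regime.

    ``regime`` fixes the trajectory of the occupancy at the focal 30%
    threshold: ``subcritical`` (~0.30, fragmented), ``supercritical``
    (~0.55, connected, no trend), ``near_critical`` (hovering just above
    the critical occupancy), ``transition`` (supercritical plateau ramping
    down towards the critical occupancy — the early-warning scenario).
    """

    regime: Literal["subcritical", "near_critical", "supercritical", "transition"]
    years: int = 16
    L: int = 256
    start_year: int = 2000
    drift: float | None = None
    noise: float = 0.006
    seed: int = 0
    region_id: str | None = None

    def __post_init__(self) -> None:
        if self.years < 3:
            raise ValueError("need >= 3 years")


# critical occupancy of Moore-neighbourhood site percolation; this module
# locates it by scan (find_critical_occupancy), generators take it as input
_P_SUPER = 0.55
_P_SUB = 0.30


def percolation_lattice(params: PercolationParams) -> BinaryLandscape:
    """I.i.d. Bernoulli(p) occupancy lattice, deterministic given the seed."""
    rng = np.random.default_rng(params.seed)
    mask = rng.random((params.L, params.L)) < params.p
    return BinaryLandscape(mask=mask, threshold=float("nan"), region_id=f"perc_p{params.p}")


def _spans(mask: np.ndarray) -> bool:
    """True when one Moore-connected cluster crosses left to right.

    A fixed crossing direction is used because Moore site percolation and
    von-Neumann site percolation form a matching pair: an occupied Moore
    crossing in one direction excludes a vacant von-Neumann crossing in the
    other, so at criticality the fixed-direction crossing probability tends
    to 1/2 — the scan's level-crossing target is then asymptotically
    unbiased.
    """
    labels, n = ndimage.label(mask, structure=_MOORE)
    if n == 0:
        return False
    lr = np.intersect1d(labels[:, 0], labels[:, -1])
    return bool(np.any(lr > 0))


def spanning_probability(L: int, p: float, reps: int, seed: int = 0) -> float:
    """Fraction of seeded replicates with a left-right spanning cluster."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(reps):
        mask = rng.random((L, L)) < p
        hits += _spans(mask)
    return hits / reps


def find_critical_occupancy(
    sizes: Sequence[int] = (256, 512, 1024),
    reps: Sequence[int] | int = (16, 32, 64),
    bracket: tuple[float, float] = (0.30, 0.55),
    seed: int = 0,
) -> float:
    """Locate p_c by a spanning-probability scan.

    For each lattice size the bracket is scanned on a 7-point grid and the
    crossing of spanning probability 1/2 is estimated — by linear
    interpolation on the wide first-round grid, then by a least-squares
    line through the pooled grid probabilities once the window is narrow —
    and the window zooms onto the crossing between rounds.  The returned
    estimate averages the two largest lattice sizes (the finite-size shift
    of the 1/2-crossing decays as L^(-1/nu)).
    """
    rng = np.random.default_rng(seed)
    if isinstance(reps, int):
        reps = [reps] * 3
    estimates = []
    for L in sizes:
        lo, hi = bracket
        est = 0.5 * (lo + hi)
        for r, n_rep in enumerate(reps):
            grid = np.linspace(lo, hi, 7)
            probs = np.array(
                [
                    spanning_probability(L, p, n_rep, seed=int(rng.integers(2**31)))
                    for p in grid
                ]
            )
            if r == 0:
                est = _cross_half(grid, probs)
            else:
                slope, inter = np.polyfit(grid, probs, 1)
                if slope > 0:
                    est = float(np.clip((0.5 - inter) / slope, lo, hi))
                else:
                    est = _cross_half(grid, probs)
            width = (hi - lo) / 3
            lo, hi = max(est - width / 2, 0.0), min(est + width / 2, 1.0)
        estimates.append(est)
    return float(np.mean(estimates[-2:])) if len(estimates) > 1 else float(estimates[0])


def periodic_patch_sizes(mask: np.ndarray) -> np.ndarray:
    """Moore-connected cluster sizes on the torus (periodic boundaries).

    Components are labelled with open boundaries and then merged across the
    wrap-around seams with a union-find pass.
    """
    lab, n = ndimage.label(mask, structure=_MOORE)
    if n == 0:
        return np.empty(0)
    parent = np.arange(n + 1)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for shift in (-1, 0, 1):
        for a, b in (
            (lab[:, -1], np.roll(lab[:, 0], shift)),
            (lab[-1, :], np.roll(lab[0, :], shift)),
        ):
            for x, y in zip(a.tolist(), b.tolist()):
                if x and y:
                    rx, ry = find(x), find(y)
                    if rx != ry:
                        parent[ry] = rx
    roots = np.array([find(i) for i in range(n + 1)])
    sizes = np.bincount(lab.ravel(), minlength=n + 1)
    merged = np.zeros(n + 1, dtype=np.int64)
    np.add.at(merged, roots, sizes)
    out = merged[1:]
    return np.sort(out[out > 0])[::-1].astype(float)


def critical_cluster_sizes(params: PercolationParams, exclude_incipient: bool = True) -> np.ndarray:
    """Finite-cluster census for universality-exponent estimation.

    Generates a Bernoulli lattice, labels clusters on the torus when the
    boundary is periodic, and (by default) drops the single largest
    cluster: at the critical occupancy it is the incipient percolating
    cluster, which scales as L^(d_f) and does not belong to the finite-
    cluster distribution n_s ∝ s^(-alpha).
    """
    rng = np.random.default_rng(params.seed)
    mask = rng.random((params.L, params.L)) < params.p
    if params.boundary == "periodic":
        sizes = periodic_patch_sizes(mask)
    else:
        lab, n = ndimage.label(mask, structure=_MOORE)
        sizes = np.sort(np.bincount(lab.ravel())[1:])[::-1].astype(float)
    if exclude_incipient and sizes.size > 1:
        sizes = sizes[1:]
    return sizes


def _cross_half(grid: np.ndarray, probs: np.ndarray) -> float:
    """First linear-interpolation crossing of 0.5 on a monotone-ish scan."""
    above = np.flatnonzero(probs >= 0.5)
    if above.size == 0:
        return float(grid[-1])
    j = above[0]
    if j == 0:
        return float(grid[0])
    p0, p1 = probs[j - 1], probs[j]
    if p1 == p0:
        return float(grid[j])
    w = (0.5 - p0) / (p1 - p0)
    return float(grid[j - 1] + w * (grid[j] - grid[j - 1]))


# ---------------------------------------------------------------------------
# contact process
# ---------------------------------------------------------------------------

def contact_process(params: ContactProcessParams) -> list[BinaryLandscape]:
    """Simulate the contact process; one landscape per step (year)."""
    rng = np.random.default_rng(params.seed)
    L = params.L
    lam = params.lam
    grid = rng.random((L, L)) < params.initial_density
    periodic = params.boundary == "periodic"
    p_ext = 1.0 / (1.0 + lam)
    out: list[BinaryLandscape] = []
    n_attempts = L * L
    for step in range(params.steps):
        rows = rng.integers(0, L, size=n_attempts)
        cols = rng.integers(0, L, size=n_attempts)
        u = rng.random(n_attempts)
        for r, c, uu in zip(rows, cols, u):
            if grid[r, c]:
                if uu < p_ext:
                    grid[r, c] = False
            else:
                occ = _moore_occupied(grid, r, c, L, periodic)
                if uu < (1.0 - p_ext) * occ / 8.0:
                    grid[r, c] = True
        out.append(
            BinaryLandscape(
                mask=grid.copy(),
                threshold=float("nan"),
                region_id=f"cp_lam{lam}",
                year=step,
            )
        )
    return out


def _moore_occupied(grid: np.ndarray, r: int, c: int, L: int, periodic: bool) -> int:
    total = 0
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            rr, cc = r + dr, c + dc
            if periodic:
                total += grid[rr % L, cc % L]
            elif 0 <= rr < L and 0 <= cc < L:
                total += grid[rr, cc]
    return total


# ---------------------------------------------------------------------------
# samplers and fixtures
# ---------------------------------------------------------------------------

def powerlaw_sample(
    alpha: float, x_min: float = 1.0, n: int = 1, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Inverse-CDF draws from the continuous power law on [x_min, inf)."""
    if alpha <= 1:
        raise ValueError("power-law exponent must exceed 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = rng.random(n)
    return x_min * (1.0 - u) ** (-1.0 / (alpha - 1.0))


#: cover = 100 * (1-u)^GAMMA puts occupancy p30 at the 30% threshold while
#: spreading occupancies monotonically over the 20-40% sweep
_GAMMA_FOCAL_THRESHOLD = 30.0


def _gamma_for(p_focal: float, threshold: float = _GAMMA_FOCAL_THRESHOLD) -> float:
    # P(cover >= t) = 1 - (t/100)^(1/gamma); solve for gamma at the focal t
    frac = threshold / 100.0
    return float(np.log(frac) / np.log(1.0 - p_focal))


def cover_from_occupancy(
    p_focal: float,
    L: int,
    rng: np.random.Generator,
    region_id: str = "synthetic",
    year: int = 0,
) -> CoverRaster:
    """Percent-cover raster whose occupancy at the 30% threshold is p_focal."""
    if not 0 < p_focal < 1:
        raise ValueError("focal occupancy must be in (0, 1)")
    gamma = _gamma_for(p_focal)
    u = rng.random((L, L))
    cover = 100.0 * (1.0 - u) ** gamma
    return CoverRaster(values=cover, region_id=region_id, year=year)


def _occupancy_path(spec: ScenarioSpec, p_c: float, rng: np.random.Generator) -> np.ndarray:
    y = spec.years
    if spec.regime == "supercritical":
        base = np.full(y, _P_SUPER)
    elif spec.regime == "subcritical":
        base = np.full(y, _P_SUB)
    elif spec.regime == "near_critical":
        base = np.full(y, p_c + 0.01)
    else:  # transition: plateau then ramp down towards p_c
        plateau = np.full(y // 2, p_c + 0.06)
        ramp = np.linspace(p_c + 0.06, p_c + 0.002, y - y // 2)
        base = np.concatenate([plateau, ramp])
        if spec.drift is not None:
            base = base + spec.drift * np.arange(y)
    noise = rng.normal(0.0, spec.noise, size=y)
    return np.clip(base + noise, 0.02, 0.98)


def region_cover_series(spec: ScenarioSpec, p_c: float = 0.4072) -> list[CoverRaster]:
    """Yearly percent-cover rasters for a scenario regime."""
    rng = np.random.default_rng(spec.seed)
    region = spec.region_id or f"{spec.regime}_{spec.seed}"
    path = _occupancy_path(spec, p_c, rng)
    return [
        cover_from_occupancy(p, spec.L, rng, region_id=region, year=spec.start_year + i)
        for i, p in enumerate(path)
    ]


def region_fixture(
    spec: ScenarioSpec,
    p_c: float = 0.4072,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> dict[float, list[PatchCensus]]:
    """Yearly patch censuses per threshold for a scenario regime."""
    covers = region_cover_series(spec, p_c=p_c)
    out: dict[float, list[PatchCensus]] = {float(t): [] for t in thresholds}
    for cov in covers:
        for census in census_sweep(cov, thresholds):
            out[float(census.threshold)].append(census)
    return out
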