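"""Combined near-criticality verdict for a region.

A region is flagged as near a critical fragmentation threshold when, for at
least one forest-definition threshold simultaneously: the patch-size
distribution is best described by a power law, the variance of the
largest-patch fluctuations is increasing in time, and the skewness of those
fluctuations is negative.  The fragmentation *state* is read from RS_max at
the most conservative (40%) threshold: above 0.6 the largest patch holds
most of the forest (unfragmented), below 0.3 it does not (fragmented).

The tail family of the fluctuation distribution is computed and reported
but does not gate the verdict: with a short (16-year) series the
likelihood-ratio tests cannot reliably separate heavy from exponential
tails, so that criterion is recorded as evidence only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import dynamics, fitting
from .raster import PatchCensus

__all__ = [
    "ThresholdCriteria",
    "CriterionSet",
    "CriticalityVerdict",
    "classify_state",
    "assess_region",
    "criteria_from_censuses",
]

RS_MAX_UNFRAGMENTED = 0.6
RS_MAX_FRAGMENTED = 0.3
STATE_THRESHOLD = 40.0


@dataclass(frozen=True)
class ThresholdCriteria:
    """Per-threshold booleans entering the combined verdict."""

    threshold: float
    powerlaw_best: bool | None
    variance_direction: str  # increase / decrease / NS
    skewness: float | None
    fluctuation_tail: str = "undetermined"  # heavy / exponential / undetermined
    mean_rs_max: float = float("nan")

    @property
    def variance_increasing(self) -> bool | None:
        return None if self.variance_direction == "error" else self.variance_direction == "increase"

    @property
    def skewness_negative(self) -> bool | None:
        return None if self.skewness is None else self.skewness < 0

    @property
    def complete(self) -> bool:
        return (
            self.powerlaw_best is not None
            and self.variance_direction != "error"
            and self.skewness is not None
        )


@dataclass(frozen=True)
class CriterionSet:
    """All criteria for one region: per-threshold entries plus RS_max at 40%."""

    region_id: str
    thresholds: tuple[ThresholdCriteria, ...]
    rs_max_at_40: float = float("nan")

    def at(self, threshold: float) -> ThresholdCriteria:
        for tc in self.thresholds:
            if tc.threshold == threshold:
                return tc
        raise KeyError(threshold)


@dataclass(frozen=True)
class CriticalityVerdict:
    region_id: str
    near_critical: bool
    qualifying_thresholds: tuple[float, ...]
    state: str  # fragmented / intermediate / unfragmented / unknown
    indeterminate: bool = False


def classify_state(rs_max_at_40: float) -> str:
    """Fragmentation state from RS_max at the 40% threshold (0.3/0.6 bounds)."""
    if not np.isfinite(rs_max_at_40) or not 0 < rs_max_at_40 <= 1:
        raise ValueError(f"RS_max must be in (0, 1], got {rs_max_at_40}")
    if rs_max_at_40 > RS_MAX_UNFRAGMENTED:
        return "unfragmented"
    if rs_max_at_40 < RS_MAX_FRAGMENTED:
        return "fragmented"
    return "intermediate"


def assess_region(criteria: CriterionSet) -> CriticalityVerdict:
    """OR over thresholds of (power law AND increasing variance AND negative skew)."""
    if not criteria.thresholds:
        raise ValueError("criteria computed for no threshold")
    qualifying = []
    any_complete = False
    for tc in criteria.thresholds:
        if not tc.complete:
            continue
        any_complete = True
        if tc.powerlaw_best and tc.variance_increasing and tc.skewness_negative:
            qualifying.append(tc.threshold)
    try:
        state = classify_state(criteria.rs_max_at_40)
    except ValueError:
        state = "unknown"
    return CriticalityVerdict(
        region_id=criteria.region_id,
        near_critical=bool(qualifying),
        qualifying_thresholds=tuple(qualifying),
        state=state,
        indeterminate=not any_complete,
    )


def criteria_from_censuses(
    censuses_by_threshold: Mapping[float, Sequence[PatchCensus]],
    seed: int = 0,
    n_boot: int = 1000,
    min_tail: int = fitting.MIN_TAIL_SIZE,
) -> CriterionSet:
    """Compute the full criterion set from yearly censuses per threshold.

    Per threshold and year the four candidate models are compared on the
    patch sizes (power law wins a year when it takes the top Akaike
    weight); the threshold-level boolean requires a power-law win in at
    least half of the years.  The variance trend and skewness come from the
    largest-patch fluctuation series, the tail family from the
    three-model comparison on fluctuation magnitudes.
    """
    region = None
    entries: list[ThresholdCriteria] = []
    rs40 = float("nan")
    for k, (thr, censuses) in enumerate(sorted(censuses_by_threshold.items())):
        if not censuses:
            continue
        region = censuses[0].region_id
        pl_wins, pl_total = 0, 0
        for c in censuses:
            if c.n_patches < min_tail:
                continue
            try:
                fits = fitting.fit_all(c.sizes, min_tail=min_tail)
                sel = fitting.select_model(fits, sizes=c.sizes)
            except (ValueError, fitting.InsufficientDataError, fitting.DegenerateSampleError):
                continue
            pl_total += 1
            pl_wins += sel.best_model == "powerlaw"
        powerlaw_best = (pl_wins >= pl_total / 2.0) if pl_total else None

        try:
            series = dynamics.build_series(list(censuses))
        except ValueError:
            entries.append(
                ThresholdCriteria(
                    threshold=float(thr),
                    powerlaw_best=powerlaw_best,
                    variance_direction="error",
                    skewness=None,
                )
            )
            continue
        if float(thr) == STATE_THRESHOLD:
            rs40 = float(series.rs_max.mean())
        try:
            _, direction = dynamics.variance_trend(series, n_boot=n_boot, seed=seed + k)
        except ValueError:
            direction = "error"
        try:
            skew = dynamics.skewness(series)
        except ValueError:
            skew = None
        try:
            tail_sel = dynamics.fit_fluctuations(series)
            tail = {
                "powerlaw": "heavy",
                "lognormal": "heavy",
                "exponential": "exponential",
            }.get(tail_sel.best_model, "undetermined")
        except ValueError:
            tail = "undetermined"
        entries.append(
            ThresholdCriteria(
                threshold=float(thr),
                powerlaw_best=powerlaw_best,
                variance_direction=direction,
                skewness=skew,
                fluctuation_tail=tail,
                mean_rs_max=float(series.rs_max.mean()),
            )
        )
    if region is None:
        raise ValueError("no censuses provided")
    return CriterionSet(region_id=region, thresholds=tuple(entries), rs_max_at_40=rs40)
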