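"""Cross-sectional mean day-specific curves and percentile-bootstrap bands.

After registration every cycle contributes one value per grid day; the
cohort summary is the per-day arithmetic mean across cycles, optionally on
per-cycle standardized (z-scored) values

    z(t) = (x(t) - mean_cycle) / sd_cycle,

with the sample SD (denominator n-1 by default).  Uncertainty bands are
nonparametric percentile-bootstrap intervals in which the resampling unit
is the whole cycle — cycles, not days, are the exchangeable units when each
day holds only a handful of observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateSDError, InsufficientDataError, ParameterError

__all__ = [
    "StandardizedCycle",
    "SummaryCurve",
    "standardize",
    "standardize_cycle",
    "cross_sectional_mean",
    "bootstrap_ci",
]


@dataclass
class StandardizedCycle:
    """Per-cycle z-scored hormone values on the analysis grid."""

    cycle_id: str
    day_index: np.ndarray
    z: dict  # hormone -> z-values
    cycle_mean: dict  # hormone -> mean over grid days
    cycle_sd: dict  # hormone -> SD over grid days


@dataclass
class SummaryCurve:
    """Cross-sectional (standardized) mean day-specific curve with CI band."""

    hormone: str
    day_index: np.ndarray
    mean: np.ndarray
    ci_lower: np.ndarray | None = None
    ci_upper: np.ndarray | None = None
    n_cycles: np.ndarray | None = None
    standardized: bool = False
    dropped_days: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def value_at(self, day: int) -> float:
        pos = np.where(self.day_index == day)[0]
        if pos.size == 0:
            return np.nan
        return float(self.mean[pos[0]])


def standardize(
    values: np.ndarray, ddof: int = 1
) -> tuple[np.ndarray, float, float]:
    """z-score a series; returns (z, mean, sd).

    Uses the sample SD (``ddof=1``) by default.  Raises
    :class:`DegenerateSDError` for a constant series.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("standardize needs >= 2 values")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=ddof))
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateSDError(
            "cannot standardize a constant (zero-variance) series"
        )
    return (x - mean) / sd, mean, sd


def standardize_cycle(
    cycle_id: str,
    day_index: np.ndarray,
    values_by_hormone: dict,
    ddof: int = 1,
) -> StandardizedCycle:
    """Standardize every hormone of one cycle over its grid days."""
    z, means, sds = {}, {}, {}
    for hormone, vals in values_by_hormone.items():
        try:
            z[hormone], means[hormone], sds[hormone] = standardize(vals, ddof)
        except DegenerateSDError as exc:
            raise DegenerateSDError(f"cycle {cycle_id}, {hormone}: {exc}")
    return StandardizedCycle(
        cycle_id=cycle_id,
        day_index=np.asarray(day_index, dtype=int),
        z=z,
        cycle_mean=means,
        cycle_sd=sds,
    )


def _per_day_counts(values: np.ndarray) -> np.ndarray:
    return (~np.isnan(values)).sum(axis=0)


def cross_sectional_mean(
    values: np.ndarray,
    day_index: np.ndarray,
    hormone: str = "",
    standardized: bool = False,
    min_cycles: int = 2,
) -> SummaryCurve:
    """Per-day arithmetic mean across cycles.

    ``values`` is (n_cycles, n_days); NaN marks a cycle that does not cover
    a day.  Days observed in fewer than ``min_cycles`` cycles are dropped
    and reported in ``dropped_days``.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] == 0:
        raise InsufficientDataError("need a (n_cycles, n_days) value matrix")
    day_index = np.asarray(day_index, dtype=int)
    counts = _per_day_counts(values)
    keep = counts >= min_cycles
    dropped = [int(d) for d in day_index[~keep]]
    with np.errstate(invalid="ignore"):
        means = np.nanmean(values[:, keep], axis=0)
    return SummaryCurve(
        hormone=hormone,
        day_index=day_index[keep],
        mean=means,
        n_cycles=counts[keep],
        standardized=standardized,
        dropped_days=dropped,
    )


def bootstrap_ci(
    values: np.ndarray,
    day_index: np.ndarray,
    hormone: str = "",
    standardized: bool = False,
    level: float = 0.95,
    n_boot: int = 10_000,
    seed: int = 0,
    min_cycles: int = 2,
) -> SummaryCurve:
    """Percentile-bootstrap confidence band for the per-day mean curve.

    Whole cycles (rows) are resampled with replacement, preserving the day
    alignment within each cycle; per-day bounds are the (1-level)/2 and
    1-(1-level)/2 quantiles of the bootstrap distribution of per-day means.
    Deterministic for a fixed ``seed``.
    """
    if not (0.0 < level < 1.0):
        raise ParameterError(f"ci level must be in (0, 1), got {level}")
    if n_boot < 100:
        raise ParameterError(f"n_boot must be >= 100, got {n_boot}")
    curve = cross_sectional_mean(
        values, day_index, hormone, standardized, min_cycles
    )
    values = np.asarray(values, dtype=float)
    keep = np.isin(np.asarray(day_index, int), curve.day_index)
    kept = values[:, keep]
    n_cycles = values.shape[0]
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n_cycles, size=(n_boot, n_cycles))
    with np.errstate(invalid="ignore"):
        boot_means = np.nanmean(kept[idx], axis=1)  # (n_boot, n_days)
    alpha = (1.0 - level) / 2.0
    curve.ci_lower = np.nanquantile(boot_means, alpha, axis=0)
    curve.ci_upper = np.nanquantile(boot_means, 1.0 - alpha, axis=0)
    curve.meta = {"level": level, "n_boot": n_boot, "seed": seed}
    return curve
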