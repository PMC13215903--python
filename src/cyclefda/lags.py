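"""Curve-translation (lag) correlation analysis of summary curves.

The hypothesis of a delayed feedback loop — FSH up-regulating inhibin B and
inhibin B suppressing FSH, each with a ~1-day latency — is probed by
translating one standardized mean day-specific curve forward by k days
against the other and correlating the overlap:

    pair set  { (leader(t), follower(t + k)) : t in window, both present }

i.e. the leader's value k days *earlier* is paired with the follower's
response.  Window bounds index the leader's day t, so a window "day -13 to
day +9" keeps 22 lag-1 pairs on a -13..+9 grid (t = -13..8 after clipping
to follower availability) and the early-follicular window "day -13 to -8"
keeps 6.  Pearson, Kendall τ-b and Spearman ρ are reported
with two-sided p-values; rank statistics use exact small-sample null
distributions where feasible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import (
    DegeneracyError,
    InsufficientDataError,
    InvariantError,
    ParameterError,
)
from .summaries import SummaryCurve

__all__ = [
    "LagSpec",
    "CorrelationResult",
    "LagScanResult",
    "METHODS",
    "lagged_pairs",
    "correlate",
    "lag_scan",
    "holm_adjust",
]

METHODS = ("pearson", "kendall", "spearman")

#: largest n for which the exact permutation null of Spearman's rho is
#: enumerated (n! grows too fast beyond this)
SPEARMAN_EXACT_MAX_N = 8
KENDALL_EXACT_MAX_N = 10


@dataclass
class LagSpec:
    """A forward translation of the ``leader`` curve by ``lag_days``.

    ``window`` is the inclusive day-index range, quoted on the leader's
    time axis t in the pair set (leader(t), follower(t + lag_days)).
    """

    leader: str
    lag_days: int
    window: tuple[int, int]

    def __post_init__(self) -> None:
        if self.lag_days < 1:
            raise InvariantError("lag_days must be >= 1")
        lo, hi = self.window
        if lo > hi:
            raise InvariantError(f"empty window [{lo}, {hi}]")


@dataclass
class CorrelationResult:
    leader: str
    lag: int
    window: tuple[int, int]
    method: str
    coefficient: float
    p_value: float
    n_pairs: int

    def to_record(self) -> dict:
        return {
            "leader": self.leader,
            "lag": self.lag,
            "window": [int(self.window[0]), int(self.window[1])],
            "method": self.method,
            "coefficient": self.coefficient,
            "p_value": self.p_value,
            "n_pairs": self.n_pairs,
        }


@dataclass
class LagScanResult:
    results: list  # CorrelationResult, one per lag
    best_positive_lag: int = 0
    most_negative_lag: int = 0

    @property
    def coefficients(self) -> dict:
        return {r.lag: r.coefficient for r in self.results}


def lagged_pairs(
    leader: SummaryCurve,
    follower: SummaryCurve,
    lag: int,
    window: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Values paired under a forward translation of the leader by ``lag``.

    Returns (leader values at t, follower values at t+lag, the days t).
    Raises :class:`InsufficientDataError` below 3 pairs.
    """
    lo, hi = int(window[0]), int(window[1])
    ld = {int(d): float(v) for d, v in zip(leader.day_index, leader.mean)}
    fd = {int(d): float(v) for d, v in zip(follower.day_index, follower.mean)}
    ts, lv, fv = [], [], []
    for t in range(lo, hi + 1):
        if t in ld and (t + lag) in fd:
            ts.append(t)
            lv.append(ld[t])
            fv.append(fd[t + lag])
    if len(ts) < 3:
        raise InsufficientDataError(
            f"only {len(ts)} pairs in window [{lo}, {hi}] at lag {lag} "
            "(need >= 3)"
        )
    return np.array(lv), np.array(fv), np.array(ts)


def _has_ties(x: np.ndarray) -> bool:
    return np.unique(x).size < x.size


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p-value for Spearman's rho.

    Enumerates all pairings of the rank vectors (feasible for small n);
    average ranks handle ties, making the null the permutation null of the
    observed rank patterns.
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    n = rx.size
    count = 0
    total = math.factorial(n)
    ry_c = ry - ry.mean()
    denom = np.sqrt(((rx - rx.mean()) ** 2).sum() * (ry_c**2).sum())
    rx_c = rx - rx.mean()
    for perm in itertools.permutations(range(n)):
        r = abs(float(np.dot(rx_c[list(perm)], ry_c)) / denom)
        if r >= obs - 1e-12:
            count += 1
    return count / total


def correlate(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "pearson",
    leader: str = "",
    lag: int = 0,
    window: tuple[int, int] = (0, 0),
) -> CorrelationResult:
    """Correlation coefficient with a two-sided p-value.

    Pearson uses the t-distribution on n-2 df; Kendall τ-b uses the exact
    null for n <= 10 without ties (normal approximation otherwise);
    Spearman is Pearson on average ranks, with an exact permutation null
    for n <= 8 and the t-approximation above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3 or y.size != n:
        raise InsufficientDataError(f"need >= 3 paired values, got {n}")
    if method not in METHODS:
        raise ParameterError(f"unknown method {method!r} (use {METHODS})")
    if method in ("pearson", "spearman"):
        for name, v in (("x", x), ("y", y)):
            if np.ptp(v) == 0:
                raise DegeneracyError(
                    f"zero variance in coordinate {name} for {method}"
                )

    if method == "pearson":
        res = stats.pearsonr(x, y)
        coef, p = float(res.statistic), float(res.pvalue)
    elif method == "kendall":
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise DegeneracyError(
                "zero variance in coordinate "
                f"{'x' if np.ptp(x) == 0 else 'y'} for kendall"
            )
        exact_ok = (
            n <= KENDALL_EXACT_MAX_N and not _has_ties(x) and not _has_ties(y)
        )
        res = stats.kendalltau(
            x, y, variant="b", method="exact" if exact_ok else "asymptotic"
        )
        coef, p = float(res.statistic), float(res.pvalue)
    else:
        res = stats.spearmanr(x, y)
        coef = float(res.statistic)
        if n <= SPEARMAN_EXACT_MAX_N:
            p = _spearman_exact_p(x, y)
        else:
            p = float(res.pvalue)
    p = min(max(p, np.finfo(float).tiny), 1.0)
    return CorrelationResult(
        leader=leader,
        lag=lag,
        window=(int(window[0]), int(window[1])),
        method=method,
        coefficient=coef,
        p_value=p,
        n_pairs=n,
    )


def correlate_curves(
    leader: SummaryCurve,
    follower: SummaryCurve,
    spec: LagSpec,
    methods: tuple[str, ...] = METHODS,
) -> list[CorrelationResult]:
    """All requested correlation methods for one lag specification."""
    lv, fv, _ = lagged_pairs(leader, follower, spec.lag_days, spec.window)
    return [
        correlate(
            lv, fv, method, leader=spec.leader, lag=spec.lag_days,
            window=spec.window,
        )
        for method in methods
    ]


def holm_adjust(results: list) -> list:
    """Holm step-down adjusted copies of a family of correlation results.

    Off by default everywhere (raw p-values are reported as-is); apply
    explicitly when several lag/window/method combinations form one
    hypothesis family.
    """
    m = len(results)
    order = sorted(range(m), key=lambda i: results[i].p_value)
    adjusted = [None] * m
    running = 0.0
    for rank, i in enumerate(order):
        p = min(1.0, (m - rank) * results[i].p_value)
        running = max(running, p)
        r = results[i]
        adjusted[i] = CorrelationResult(
            r.leader, r.lag, r.window, r.method, r.coefficient,
            running, r.n_pairs,
        )
    return adjusted


def lag_scan(
    leader: SummaryCurve,
    follower: SummaryCurve,
    lags,
    window: tuple[int, int],
    method: str = "pearson",
    leader_name: str = "",
) -> LagScanResult:
    """Correlations across a set of integer lags, with argmax/argmin lags.

    Coefficient ties break to the smallest ``|lag|``.
    """
    results = []
    for lag in sorted(set(int(k) for k in lags)):
        lv, fv, _ = lagged_pairs(leader, follower, lag, window)
        results.append(
            correlate(
                lv, fv, method,
                leader=leader_name or leader.hormone,
                lag=lag, window=window,
            )
        )
    # smallest |lag| wins ties (sort key: coefficient, then -|lag|)
    best = max(results, key=lambda r: (r.coefficient, -abs(r.lag)))
    worst = min(results, key=lambda r: (r.coefficient, abs(r.lag)))
    return LagScanResult(
        results=results,
        best_positive_lag=best.lag,
        most_negative_lag=worst.lag,
    )
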