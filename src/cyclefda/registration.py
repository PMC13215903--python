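"""Elastic registration of hormone curves under the Fisher–Rao metric.

Curves sampled daily are viewed as functions on [0, 1].  Each curve f is
represented by its square-root velocity function (SRVF)

    q(s) = sign(f'(s)) * sqrt(|f'(s)|),

under which the Fisher–Rao distance between curves becomes the ordinary
L2 distance between SRVFs, and time-warping f -> f∘γ acts as
q -> (q∘γ)·sqrt(γ').  Pairwise alignment minimises

    ∫ ( q_target(s) - q_moving(γ(s))·sqrt(γ'(s)) )² ds

over boundary-fixed monotone warps γ by dynamic programming on a lattice of
monotone paths with a fixed local step set.  Group alignment iterates a
Karcher-mean template: average the SRVFs, align every curve to the average,
re-centre the warps so their mean is the identity, repeat until the summed
elastic distance stabilises.

Daily series (~23 points) are linearly up-sampled to a working resolution
(default 101 points) before registration; warps are mapped back to integer
days for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .exceptions import ConvergenceWarning, GridError, InvariantError

__all__ = [
    "NormalizedCurve",
    "SRVFCurve",
    "WarpingFunction",
    "AlignedCohort",
    "DEFAULT_STEPS",
    "to_srvf",
    "warp_curve",
    "invert_warp",
    "dp_align",
    "elastic_distance",
    "karcher_align",
]

#: Local DP steps (di, dj): slopes 1/3..3, strictly monotone in both axes.
#: The (1, 1) step is listed first so that cost ties resolve to the
#: identity-like path (degenerate all-zero SRVFs then yield γ = identity).
DEFAULT_STEPS: tuple[tuple[int, int], ...] = (
    (1, 1),
    (1, 2),
    (2, 1),
    (1, 3),
    (3, 1),
    (2, 3),
    (3, 2),
)


@dataclass
class NormalizedCurve:
    """A curve on the normalized abscissa [0, 1].

    ``day_range`` retains the source day-index span for back-mapping.
    """

    grid: np.ndarray
    values: np.ndarray
    day_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise InvariantError("grid and values lengths differ")
        if self.grid.size < 2:
            raise InvariantError("curve needs at least 2 samples")
        if not (self.grid[0] == 0.0 and self.grid[-1] == 1.0):
            raise InvariantError("grid must span [0, 1]")
        if np.any(np.diff(self.grid) <= 0):
            raise InvariantError("grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvariantError("curve values must be finite")

    def resample(self, n: int) -> "NormalizedCurve":
        s = np.linspace(0.0, 1.0, n)
        return NormalizedCurve(
            s, np.interp(s, self.grid, self.values), self.day_range
        )


@dataclass
class SRVFCurve:
    """Square-root velocity representation q of a curve."""

    grid: np.ndarray
    q: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        if self.grid.shape != self.q.shape:
            raise InvariantError("grid and q lengths differ")
        if not np.all(np.isfinite(self.q)):
            raise InvariantError("q must be finite")


@dataclass
class WarpingFunction:
    """Boundary-fixed monotone time deformation γ: [0,1] -> [0,1].

    ``objective`` holds the DP alignment cost when the warp came from
    :func:`dp_align`.
    """

    grid: np.ndarray
    gamma: np.ndarray
    objective: float | None = None

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        if self.grid.shape != self.gamma.shape:
            raise InvariantError("grid and gamma lengths differ")
        if not (
            abs(self.gamma[0]) < 1e-12 and abs(self.gamma[-1] - 1.0) < 1e-12
        ):
            raise InvariantError("warp must fix the boundary: γ(0)=0, γ(1)=1")
        if np.any(np.diff(self.gamma) < -1e-12):
            raise InvariantError("warp must be non-decreasing")
        self.gamma = np.clip(self.gamma, 0.0, 1.0)

    @classmethod
    def identity(cls, n: int) -> "WarpingFunction":
        s = np.linspace(0.0, 1.0, n)
        return cls(s, s.copy())

    def __call__(self, s: np.ndarray) -> np.ndarray:
        return np.interp(s, self.grid, self.gamma)


@dataclass
class AlignedCohort:
    """Result of group registration: aligned curves, warps, template, trace."""

    aligned: list
    warps: list
    template: NormalizedCurve
    trace: list = field(default_factory=list)
    converged: bool = True
    n_iterations: int = 0


def to_srvf(curve: NormalizedCurve) -> SRVFCurve:
    """SRVF transform with central-difference derivatives.

    A constant curve maps to q ≡ 0.
    """
    if curve.grid.size < 3:
        raise InvariantError("SRVF needs at least 3 samples")
    deriv = np.gradient(curve.values, curve.grid)
    # suppress cancellation noise so constant curves map to exactly q = 0
    tol = 1e-10 * max(1.0, float(np.abs(curve.values).max()))
    deriv[np.abs(deriv) < tol] = 0.0
    return SRVFCurve(curve.grid, np.sign(deriv) * np.sqrt(np.abs(deriv)))


def srvf_to_curve(
    q: SRVFCurve, anchor: float = 0.0
) -> NormalizedCurve:
    """Integrate q·|q| back to a curve, anchored at f(0) = anchor."""
    f = anchor + cumulative_trapezoid(q.q * np.abs(q.q), q.grid, initial=0.0)
    return NormalizedCurve(q.grid, f)


def warp_curve(
    curve: NormalizedCurve, gamma: WarpingFunction
) -> NormalizedCurve:
    """Compose f∘γ, sampled on the curve's own grid."""
    warped_s = gamma(curve.grid)
    return NormalizedCurve(
        curve.grid,
        np.interp(warped_s, curve.grid, curve.values),
        curve.day_range,
    )


def invert_warp(gamma: WarpingFunction) -> WarpingFunction:
    """Numeric inverse of γ (reflection about the diagonal)."""
    return WarpingFunction(
        gamma.grid, np.interp(gamma.grid, gamma.gamma, gamma.grid)
    )


def _segment_cost_tables(
    q1: np.ndarray,
    q2: np.ndarray,
    steps: tuple[tuple[int, int], ...],
    penalty: float,
) -> dict[tuple[int, int], np.ndarray]:
    """Cost of each DP segment, per step, for all end nodes.

    The segment from (i-di, j-dj) to (i, j) models γ locally linear with
    slope m = dj/di and accrues the right-endpoint Riemann cost

        h · Σ_{k=1..di} ( q1[i-di+k] - sqrt(m)·q2(s_{j-dj} + k·m·h) )²

    plus the roughness term ``penalty · <q1²> · (sqrt(m)-1)² · di·h`` where
    <q1²> is the mean square of the target SRVF, making ``penalty`` a
    dimensionless slope-roughness weight independent of the data's units.
    Tables are indexed [i, j] and are valid for i >= di, j >= dj (others
    hold +inf).
    """
    n = q1.size
    s = np.linspace(0.0, 1.0, n)
    h = 1.0 / (n - 1)
    pen_scale = penalty * max(float(np.mean(q1**2)), 1e-12)
    tables: dict[tuple[int, int], np.ndarray] = {}
    for di, dj in steps:
        if di >= n or dj >= n:
            continue
        m = dj / di
        sqm = np.sqrt(m)
        cost = np.zeros((n - di, n - dj))
        for k in range(1, di + 1):
            # q2 sampled at s_j - (dj - k·m)·h  for every column j
            offset = (dj - k * m) * h
            q2k = np.interp(s - offset, s, q2)
            a = q1[k : n - di + k]  # q1[i-di+k] for i = di..n-1
            cost += (a[:, None] - sqm * q2k[None, dj:]) ** 2
        cost *= h
        cost += pen_scale * (sqm - 1.0) ** 2 * di * h
        table = np.full((n, n), np.inf)
        table[di:, dj:] = cost
        tables[(di, dj)] = table
    return tables


def dp_align(
    q_target: SRVFCurve,
    q_moving: SRVFCurve,
    penalty: float = 0.0,
    steps: tuple[tuple[int, int], ...] = DEFAULT_STEPS,
) -> WarpingFunction:
    """Optimal warp of ``q_moving`` onto ``q_target`` by dynamic programming.

    Minimises ``∫ (q_target(s) - q_moving(γ(s))·sqrt(γ'(s)))² ds`` over the
    lattice of boundary-fixed monotone paths with local steps ``steps``.
    Ties resolve to the earlier-listed step, so identical (including
    degenerate all-zero) SRVFs yield the identity warp.  The returned warp
    carries the attained objective in ``.objective``.
    """
    if penalty < 0:
        raise InvariantError("dp penalty must be >= 0")
    q1, q2 = np.asarray(q_target.q, float), np.asarray(q_moving.q, float)
    if q1.size != q2.size:
        n = max(q1.size, q2.size)
        s = np.linspace(0.0, 1.0, n)
        q1 = np.interp(s, q_target.grid, q1)
        q2 = np.interp(s, q_moving.grid, q2)
    n = q1.size
    tables = _segment_cost_tables(q1, q2, steps, penalty)

    D = np.full((n, n), np.inf)
    D[0, 0] = 0.0
    # predecessor step index per node (-1 = none)
    P = np.full((n, n), -1, dtype=np.int8)
    step_list = [st for st in steps if st in tables]
    for i in range(1, n):
        row = D[i]
        for s_idx, (di, dj) in enumerate(step_list):
            if i < di:
                continue
            cand = D[i - di, : n - dj] + tables[(di, dj)][i, dj:]
            better = cand < row[dj:]
            if better.any():
                row[dj:][better] = cand[better]
                P[i, dj:][better] = s_idx

    if not np.isfinite(D[-1, -1]):
        raise GridError("no monotone DP path reaches (1, 1)")

    # backtrack the optimal path
    path_i, path_j = [n - 1], [n - 1]
    i = j = n - 1
    while i > 0 or j > 0:
        di, dj = step_list[P[i, j]]
        i, j = i - di, j - dj
        path_i.append(i)
        path_j.append(j)
    path_i.reverse()
    path_j.reverse()

    s = np.linspace(0.0, 1.0, n)
    gamma = np.interp(s, s[path_i], s[path_j])
    warp = WarpingFunction(s, gamma)
    warp.objective = float(D[-1, -1])
    return warp


def elastic_distance(
    f: NormalizedCurve, g: NormalizedCurve, resolution: int = 101
) -> float:
    """Fisher–Rao (phase-optimised) distance between two curves."""
    qf = to_srvf(f.resample(resolution))
    qg = to_srvf(g.resample(resolution))
    return float(np.sqrt(dp_align(qf, qg).objective))


def _l2sq(grid: np.ndarray, values: np.ndarray) -> float:
    return float(np.trapezoid(values**2, grid))


def _unit_q(q: np.ndarray, s: np.ndarray) -> np.ndarray:
    norm = np.sqrt(np.trapezoid(q**2, s))
    return q / norm if norm > 0 else q


def karcher_align(
    curves: list[NormalizedCurve],
    max_iter: int = 20,
    tol: float = 1e-6,
    resolution: int | None = 101,
    penalty: float = 0.0,
    steps: tuple[tuple[int, int], ...] = DEFAULT_STEPS,
    scale: bool = True,
) -> AlignedCohort:
    """Group alignment to an iterated Karcher-mean SRVF template.

    Each iteration (i) averages the SRVFs of the currently aligned curves,
    (ii) re-aligns every *original* curve to that template by
    :func:`dp_align`, (iii) re-centres the warps so their mean is the
    identity (fixing the phase gauge), then evaluates the objective
    Σ_i ||q(f_i∘γ_i) − mean q||².  The trace of objective values is
    non-increasing by construction: an iteration that would increase it is
    discarded and the previous iterate kept.

    With ``scale=True`` (default) warps are estimated on unit-L2-norm
    SRVFs, making phase estimation invariant to each curve's amplitude
    scale — cohorts here span several-fold peak heights, and without the
    normalisation the DP's sqrt(γ') factor partly chases amplitude rather
    than phase ("pinching").  The curves themselves keep their amplitudes.

    The template is mapped back to a curve anchored at the mean of the
    aligned curves' left endpoint values.
    """
    if len(curves) < 2:
        raise GridError("karcher_align needs at least 2 curves")
    n0 = curves[0].grid.size
    for c in curves[1:]:
        if c.grid.size != n0 or not np.allclose(c.grid, curves[0].grid):
            raise GridError("curves must share a common grid")
    if resolution is not None:
        work = [c.resample(resolution) for c in curves]
    else:
        work = [NormalizedCurve(c.grid, c.values, c.day_range) for c in curves]
    n = work[0].grid.size
    s = work[0].grid

    orig_q = [to_srvf(c) for c in work]
    if scale:
        est_q = [SRVFCurve(s, _unit_q(q.q, s)) for q in orig_q]
    else:
        est_q = orig_q
    aligned = [NormalizedCurve(s, c.values.copy(), c.day_range) for c in work]
    warps = [WarpingFunction.identity(n) for _ in work]

    def objective(curr_aligned: list[NormalizedCurve]) -> float:
        qs = np.array([to_srvf(c).q for c in curr_aligned])
        if scale:
            qs = np.array([_unit_q(q, s) for q in qs])
        mu = qs.mean(axis=0)
        return float(sum(_l2sq(s, q - mu) for q in qs))

    trace = [objective(aligned)]
    converged = False
    n_done = 0
    for _ in range(max_iter):
        qs = np.array([to_srvf(c).q for c in aligned])
        if scale:
            qs = np.array([_unit_q(q, s) for q in qs])
        template_q = SRVFCurve(s, qs.mean(axis=0))

        new_warps = [
            dp_align(template_q, q, penalty=penalty, steps=steps)
            for q in est_q
        ]
        # gauge fix: mean warp -> identity
        mean_gamma = np.mean([w.gamma for w in new_warps], axis=0)
        inv_mean = np.interp(s, mean_gamma, s)
        centred = []
        for w in new_warps:
            g = np.interp(inv_mean, s, w.gamma)
            g[0], g[-1] = 0.0, 1.0
            centred.append(WarpingFunction(s, np.maximum.accumulate(g)))
        new_aligned = [warp_curve(c, w) for c, w in zip(work, centred)]

        obj = objective(new_aligned)
        if obj > trace[-1] + 1e-12:
            converged = True  # finite-resolution floor reached
            break
        aligned, warps = new_aligned, centred
        n_done += 1
        rel = (trace[-1] - obj) / max(abs(trace[-1]), 1e-30)
        trace.append(obj)
        if rel < tol:
            converged = True
            break
    else:
        warnings.warn(
            f"karcher_align: no convergence in {max_iter} iterations",
            ConvergenceWarning,
        )

    qs = np.array([to_srvf(c).q for c in aligned])
    anchor = float(np.mean([c.values[0] for c in aligned]))
    template = srvf_to_curve(SRVFCurve(s, qs.mean(axis=0)), anchor=anchor)
    template.day_range = work[0].day_range
    return AlignedCohort(
        aligned=aligned,
        warps=warps,
        template=template,
        trace=trace,
        converged=converged,
        n_iterations=n_done,
    )
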