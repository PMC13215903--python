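"""Synthetic ovulatory-cycle cohorts with a delayed FSH↔inhibin-B feedback.

The generator is phenomenological: it reproduces the statistical structure
the analysis pipeline assumes rather than follicle-population mechanics.

Early follicular phase (menses to ``regime_change_day``): a coupled linear
map with a one-day (configurable) latency,

    B(t+d)   = b_B + g1·(FSH(t) - b_F) + noise
    FSH(t+d) = b_F - g2·(B(t)  - b_B) + noise,

whose linearisation has spectral radius sqrt(g1·g2): below 1 the map gives
a damped saw-tooth oscillation with a 4·d-day period, the "saw-tooth
scatter" visible in daily early-follicular hormone series.

Peri-ovulatory phase (``regime_change_day``..0): inhibin B declines to a
nadir at day -2 then rises to an ovulatory peak at day 0; FSH rises to a
pre-ovulatory peak at day -1.  Peak heights are drawn per cycle from the
observed serum ranges (inhibin B 66.6–398.9 pg/ml, FSH 6.6–9.3 mIU/ml) and
the whole cycle's amplitude scales with the draw, emulating the several-fold
between-cycle amplitude heterogeneity of a variable follicular wave
(~4–14 recruited follicles).

Luteal phase: both hormones low with mild noise.

Cycle-to-cycle phase variation enters as a smooth random warp of the
follicular segment (the same boundary-fixed family the registration step
estimates), measurement error as multiplicative lognormal noise, and missed
blood draws as randomly deleted sample days (never the peri-ovulatory days
-2..0, so the ground-truth day 0 stays defined).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .exceptions import ParameterError, StabilityError
from .io import RawCycle, write_cycles

__all__ = [
    "FeedbackParams",
    "CycleTruth",
    "SyntheticCohort",
    "paperlike_preset",
    "simulate_cycle",
    "simulate_cohort",
]

#: reference mid-range peaks used to normalise per-cycle amplitude factors
_B_PEAK_MID = 232.75  # pg/ml, midpoint of (66.6, 398.9)
_FSH_PEAK_MID = 7.95  # mIU/ml, midpoint of (6.6, 9.3)


@dataclass
class FeedbackParams:
    """Parameters of the delayed positive–negative feedback generator.

    Gains are entered as positive magnitudes; the suppression of FSH by
    inhibin B carries its negative sign inside the map.
    """

    baseline_fsh: float = 6.0  # mIU/ml, early-follicular FSH level
    baseline_b: float = 80.0  # pg/ml, early-follicular inhibin B level
    gain_fsh_to_b: float = 40.0  # pg/ml per mIU/ml (positive arm)
    gain_b_to_fsh: float = 0.02  # mIU/ml per pg/ml (negative arm, magnitude)
    feedback_delay: int = 1  # days
    regime_change_day: int = -8  # day index where the oscillation ends
    nadir_day: int = -2  # day index of the inhibin B minimum
    peak_b_range: tuple[float, float] = (66.6, 398.9)  # pg/ml at day 0
    peak_fsh_range: tuple[float, float] = (6.6, 9.3)  # mIU/ml at day -1
    osc_amp_fsh: float = 1.2  # mIU/ml, initial FSH deviation
    phase_jitter_sd: float = 0.6  # days, SD of the smooth follicular warp
    noise_cv: float = 0.08  # fractional lognormal assay CV
    cycle_length_range: tuple[int, int] = (25, 28)  # days
    luteal_length_range: tuple[int, int] = (9, 11)  # post-peak sampled days
    missing_rate: float = 0.02  # fraction of sample days deleted
    stability_bound: float = 1.0  # max allowed spectral radius
    seed: int = 0

    @property
    def spectral_radius(self) -> float:
        """|eigenvalue| of the linearised delayed map."""
        return float(np.sqrt(self.gain_fsh_to_b * self.gain_b_to_fsh))

    def validate(self) -> None:
        # zero gains are allowed (open loop: flat early phase at baseline)
        if self.gain_fsh_to_b < 0 or self.gain_b_to_fsh < 0:
            raise ParameterError("feedback gains must be >= 0")
        if self.feedback_delay < 1:
            raise ParameterError("feedback_delay must be >= 1")
        for name in ("peak_b_range", "peak_fsh_range", "cycle_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ParameterError(f"{name} must be ordered, got {lo}>{hi}")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")
        if not (0.0 <= self.missing_rate < 0.1):
            raise ParameterError("missing_rate must lie in [0, 0.1)")
        if self.nadir_day >= 0 or self.regime_change_day >= self.nadir_day:
            raise ParameterError(
                "need regime_change_day < nadir_day < 0"
            )
        if self.spectral_radius > self.stability_bound:
            raise StabilityError(
                "feedback map diverges: spectral radius "
                f"{self.spectral_radius:.3f} > bound {self.stability_bound}"
            )


def paperlike_preset() -> FeedbackParams:
    """Defaults reproducing the qualitative study-cohort phenomenology.

    Four-cycle cohorts of 25–28-day cycles; ovulatory inhibin B peaks in
    66.6–398.9 pg/ml at day 0 preceded by FSH peaks in 6.6–9.3 mIU/ml at
    day -1; an inhibin B nadir at day -2; a damped 4-day saw-tooth in the
    early follicular phase ending near day -6 to -8.
    """
    return FeedbackParams()


@dataclass
class CycleTruth:
    """Ground truth for one simulated cycle (for closed-loop tests)."""

    cycle_id: str
    day0_calendar_day: int
    cycle_length: int
    regime_change_day: int
    peak_b: float
    peak_fsh: float
    warp_coefficients: list
    deleted_calendar_days: list


@dataclass
class SyntheticCohort:
    cycles: list  # RawCycle
    truth: list  # CycleTruth
    params: FeedbackParams

    def write(self, cohort_path, truth_path=None) -> None:
        write_cycles(self.cycles, cohort_path)
        if truth_path is not None:
            payload = {
                "params": _params_dict(self.params),
                "cycles": [asdict(t) for t in self.truth],
            }
            with open(truth_path, "w") as fh:
                json.dump(payload, fh, indent=2)


def _params_dict(params: FeedbackParams) -> dict:
    d = asdict(params)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = list(v)
    return d


def _smooth_warp_coeffs(
    rng: np.random.Generator, sd_days: float, span_days: float
) -> np.ndarray:
    """Coefficients of a boundary-fixed sinusoidal warp displacement.

    d(u) = c1·sin(pi u) + c2·sin(2 pi u) on the unit interval; the typical
    peak displacement in days is ~``sd_days``.  Redraws until the warp is
    comfortably monotone.
    """
    if sd_days <= 0:
        return np.zeros(2)
    scale = sd_days / span_days
    for _ in range(100):
        c = rng.normal(0.0, scale, size=2) / np.array([1.0, 2.0])
        # slope of u + d(u) is 1 + pi c1 cos + 2 pi c2 cos2
        if np.pi * abs(c[0]) + 2 * np.pi * abs(c[1]) < 0.9:
            return c
    return np.zeros(2)


def _apply_follicular_warp(
    t: np.ndarray, values: np.ndarray, coeffs: np.ndarray
) -> np.ndarray:
    """Warp the follicular segment t in [t[0], 0] by the smooth family.

    Endpoints (menses start and the day-0 peak) are fixed; interior days
    are re-sampled from the linearly interpolated series at warped times.
    """
    if not np.any(coeffs):
        return values
    out = values.copy()
    fol = t <= 0
    tf = t[fol].astype(float)
    span = tf[-1] - tf[0]
    if span <= 0:
        return values
    u = (tf - tf[0]) / span
    warped_u = u + coeffs[0] * np.sin(np.pi * u) + coeffs[1] * np.sin(
        2 * np.pi * u
    )
    warped_t = tf[0] + np.maximum.accumulate(warped_u) * span
    out[fol] = np.interp(warped_t, tf, values[fol])
    return out


def _noise_free_cycle(
    params: FeedbackParams,
    cycle_length: int,
    day0_cd: int,
    peak_b: float,
    peak_fsh: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic skeleton of one cycle on its day-index axis."""
    t = np.arange(1 - day0_cd, cycle_length - day0_cd + 1)
    n = t.size
    fsh = np.empty(n)
    inhb = np.empty(n)

    ab = peak_b / _B_PEAK_MID
    af = peak_fsh / _FSH_PEAK_MID
    b_f = params.baseline_fsh * af
    b_b = params.baseline_b * ab
    # cross-gains rescaled so each hormone's deviations keep its own scale
    g1 = params.gain_fsh_to_b * ab / af
    g2 = params.gain_b_to_fsh * af / ab
    d = params.feedback_delay

    # --- early follicular phase: delayed positive-negative feedback map ---
    t_reg = params.regime_change_day
    early = t <= t_reg
    n_early = int(early.sum())
    x = np.zeros(n_early)  # FSH deviation
    y = np.zeros(n_early)  # inhibin B deviation
    if g1 > 0 and g2 > 0:
        # seed the loop with an early-follicular FSH excursion and the
        # post-menses inhibin B deficit it has already produced
        x[: min(d, n_early)] = params.osc_amp_fsh * af
        y[: min(d, n_early)] = -0.5 * params.osc_amp_fsh * g1 * af
    for i in range(d, n_early):
        x[i] = -g2 * y[i - d]
        y[i] = g1 * x[i - d]
    fsh[early] = b_f + x
    inhb[early] = b_b + y

    # --- peri-ovulatory phase: decline to nadir, rise to the day-0 peak ---
    i_reg = n_early - 1
    t_nad = params.nadir_day
    nadir_b = 0.35 * b_b
    trough_fsh = 0.75 * b_f
    mid = (t > t_reg) & (t <= 0)
    for i in np.where(mid)[0]:
        ti = t[i]
        if ti <= t_nad:  # linear decline to the nadir
            frac = (ti - t_reg) / (t_nad - t_reg)
            inhb[i] = inhb[i_reg] + frac * (nadir_b - inhb[i_reg])
        else:  # rise to the ovulatory peak at day 0
            frac = (ti - t_nad) / (0 - t_nad)
            inhb[i] = nadir_b + frac**1.5 * (peak_b - nadir_b)
        # FSH: decline to a trough at -4, peak at -1, fall-off at day 0
        if ti <= -4:
            frac = (ti - t_reg) / (-4 - t_reg)
            fsh[i] = fsh[i_reg] + frac * (trough_fsh - fsh[i_reg])
        elif ti <= -1:
            frac = (ti + 4) / 3.0
            fsh[i] = trough_fsh + frac * (peak_fsh - trough_fsh)
        else:  # day 0
            fsh[i] = 0.8 * peak_fsh

    # --- luteal phase: low levels ---
    late = t > 0
    n_late = int(late.sum())
    if n_late:
        frac = np.linspace(0.0, 1.0, n_late)
        inhb[late] = (0.35 - 0.15 * frac) * b_b
        fsh[late] = (0.55 + 0.25 * frac) * b_f
    return t, fsh, inhb


def simulate_cycle(
    params: FeedbackParams,
    rng: np.random.Generator,
    cycle_id: str = "C1",
) -> tuple[RawCycle, CycleTruth]:
    """Draw one cycle: skeleton, phase warp, noise, missed samples."""
    params.validate()
    lr = params.cycle_length_range
    cycle_length = int(rng.integers(lr[0], lr[1] + 1))
    pr = params.luteal_length_range
    post = int(rng.integers(pr[0], pr[1] + 1))
    day0_cd = max(cycle_length - post, 14)
    peak_b = float(rng.uniform(*params.peak_b_range))
    peak_fsh = float(rng.uniform(*params.peak_fsh_range))

    t, fsh, inhb = _noise_free_cycle(
        params, cycle_length, day0_cd, peak_b, peak_fsh
    )

    span = float(-t[0])
    coeffs = _smooth_warp_coeffs(rng, params.phase_jitter_sd, span)
    fsh = _apply_follicular_warp(t, fsh, coeffs)
    inhb = _apply_follicular_warp(t, inhb, coeffs)

    if params.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(params.noise_cv**2)))
        fsh = fsh * np.exp(rng.normal(0, sigma, t.size) - sigma**2 / 2)
        inhb = inhb * np.exp(rng.normal(0, sigma, t.size) - sigma**2 / 2)
        # the injected ovulatory peak must survive measurement noise for
        # the truth day 0 to stay defined
        i0 = int(np.where(t == 0)[0][0])
        others = np.delete(inhb, i0)
        if inhb[i0] <= others.max():
            inhb[i0] = others.max() * (1 + 1e-6)

    fsh = np.maximum(fsh, 1e-3)
    inhb = np.maximum(inhb, 1e-3)

    deletable = np.where((t < params.nadir_day) | (t > 0))[0]
    deleted = deletable[
        rng.random(deletable.size) < params.missing_rate
    ]
    # keep at least 15 sampled days
    max_del = max(t.size - 15, 0)
    deleted = deleted[:max_del]
    fsh_out, inhb_out = fsh.copy(), inhb.copy()
    fsh_out[deleted] = np.nan
    inhb_out[deleted] = np.nan

    cal = t + day0_cd
    cycle = RawCycle(cycle_id, cal, fsh_out, inhb_out)
    truth = CycleTruth(
        cycle_id=cycle_id,
        day0_calendar_day=int(day0_cd),
        cycle_length=cycle_length,
        regime_change_day=int(params.regime_change_day),
        peak_b=peak_b,
        peak_fsh=peak_fsh,
        warp_coefficients=[float(c) for c in coeffs],
        deleted_calendar_days=[int(cal[i]) for i in deleted],
    )
    return cycle, truth


def simulate_cohort(
    params: FeedbackParams | None = None,
    n_cycles: int = 4,
    seed: int | None = None,
) -> SyntheticCohort:
    """Independent cycles from per-cycle substreams of a seeded generator.

    Deterministic for fixed (params, n_cycles, seed); per-cycle spawned
    streams mean that adding cycles never reshuffles earlier draws.
    """
    if params is None:
        params = paperlike_preset()
    params.validate()
    if n_cycles < 2:
        raise ParameterError("n_cycles must be >= 2")
    if seed is None:
        seed = params.seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_cycles)
    cycles, truths = [], []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        cyc, truth = simulate_cycle(params, rng, cycle_id=f"S{i + 1}")
        cyc.validate()
        cycles.append(cyc)
        truths.append(truth)
    return SyntheticCohort(cycles=cycles, truth=truths, params=params)
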