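"""statsmodels-style model surface for the full cycle analysis.

:class:`HormoneFeedbackModel` wraps the whole procedure — ovulatory-peak
indexing, elastic registration per hormone, per-cycle standardization,
cross-sectional summary curves with percentile-bootstrap bands, and the
±k-day curve-translation correlations — behind a ``fit()`` that returns a
:class:`HormoneFeedbackResults` carrying estimates, uncertainty bands,
diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as cio
from . import lags as clags
from . import registration as reg
from . import summaries as csum
from .exceptions import GridError, ParameterError
from .simulate import FeedbackParams, simulate_cohort

__all__ = ["HormoneFeedbackModel", "HormoneFeedbackResults"]

HORMONES = ("fsh", "inhibin_b")
DEFAULT_EARLY_WINDOW = (-13, -8)
DEFAULT_SCAN_LAGS = (0, 1, 2, 3)


def _curves_to_normalized(
    series: list[cio.CycleSeries], hormone: str, grid: tuple[int, int]
) -> list[reg.NormalizedCurve]:
    lo, hi = grid
    days = np.arange(lo, hi + 1)
    s = (days - lo) / (hi - lo)
    s[0], s[-1] = 0.0, 1.0
    curves = []
    for cyc in series:
        sel = (cyc.day_index >= lo) & (cyc.day_index <= hi)
        curves.append(
            reg.NormalizedCurve(s, cyc.values(hormone)[sel], (lo, hi))
        )
    return curves


def _aligned_day_values(
    cohort: reg.AlignedCohort, grid: tuple[int, int]
) -> np.ndarray:
    """Sample aligned working-resolution curves back at integer days."""
    lo, hi = grid
    days = np.arange(lo, hi + 1)
    s_days = (days - lo) / (hi - lo)
    out = np.empty((len(cohort.aligned), days.size))
    for i, c in enumerate(cohort.aligned):
        out[i] = np.interp(s_days, c.grid, c.values)
    return out


class HormoneFeedbackModel:
    """Delayed FSH↔inhibin-B feedback analysis of a cycle cohort.

    Parameters
    ----------
    cycles
        Raw per-cycle daily records (see :class:`cyclefda.io.RawCycle`).
    grid
        Candidate day-index range before intersection across cycles.
    peak_window
        Calendar-day bounds for the inhibin B peak search (default: the
        central 50% of each cycle's sampled span).
    resolution, dp_penalty, max_iter, tol, shared_warps
        Registration settings.  By default the warps estimated on the
        inhibin B curves (whose ovulatory peak is the sharpest landmark)
        are applied to both hormones: the two hormones are measured in the
        same daily blood draw, so a cycle has one time deformation, and
        warping them independently would scramble the within-cycle
        cross-hormone lag structure the analysis measures.
        ``shared_warps=None`` registers each hormone independently;
        ``shared_warps="fsh"`` borrows FSH-derived warps instead.
    sd_ddof, ci_level, n_boot
        Standardization / bootstrap settings.
    early_window
        Day-index window of the early-follicular (oscillatory) segment.
    scan_lags
        Lags scanned for the leader-curve translation analysis.
    """

    def __init__(
        self,
        cycles: list[cio.RawCycle],
        *,
        grid: tuple[int, int] = (-20, 15),
        peak_window: tuple[int, int] | None = None,
        resolution: int = 101,
        dp_penalty: float = 0.0,
        max_iter: int = 20,
        tol: float = 1e-6,
        shared_warps: str | None = "inhibin_b",
        sd_ddof: int = 1,
        ci_level: float = 0.95,
        n_boot: int = 10_000,
        early_window: tuple[int, int] = DEFAULT_EARLY_WINDOW,
        scan_lags: tuple[int, ...] = DEFAULT_SCAN_LAGS,
        lag_specs: list | None = None,
    ) -> None:
        if len(cycles) < 2:
            raise GridError("need at least 2 cycles")
        if shared_warps not in (None, "fsh", "inhibin_b"):
            raise ParameterError(
                f"shared_warps must be None or a hormone, got {shared_warps}"
            )
        self.cycles = cycles
        self.grid = grid
        self.peak_window = peak_window
        self.resolution = resolution
        self.dp_penalty = dp_penalty
        self.max_iter = max_iter
        self.tol = tol
        self.shared_warps = shared_warps
        self.sd_ddof = sd_ddof
        self.ci_level = ci_level
        self.n_boot = n_boot
        self.early_window = early_window
        self.scan_lags = scan_lags
        self.lag_specs = lag_specs

    # ---------------------------------------------------------- constructors
    @classmethod
    def from_csv(cls, path, **kwargs) -> "HormoneFeedbackModel":
        return cls(cio.read_cycles(path), **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs):
        import io as _io

        buf = _io.StringIO()
        df.to_csv(buf, index=False, float_format="%.17g")
        buf.seek(0)
        return cls(cio.read_cycles(buf), **kwargs)

    @classmethod
    def from_simulation(
        cls,
        params: FeedbackParams | None = None,
        n_cycles: int = 4,
        seed: int = 0,
        **kwargs,
    ):
        cohort = simulate_cohort(params, n_cycles=n_cycles, seed=seed)
        model = cls(cohort.cycles, **kwargs)
        model.simulated_truth = cohort
        return model

    # ----------------------------------------------------------------- fit
    def fit(self, seed: int = 0) -> "HormoneFeedbackResults":
        """Run the full pipeline; ``seed`` drives the bootstrap only."""
        day0: dict[str, int] = {}
        series: list[cio.CycleSeries] = []
        for cyc in self.cycles:
            cyc.validate()
            d0 = (
                cyc.day0_override
                if cyc.day0_override is not None
                else cio.detect_day0(cyc, self.peak_window)
            )
            day0[cyc.cycle_id] = d0
            series.append(cio.reindex_to_day0(cyc, d0, self.grid))
        grid = cio.common_grid(series)

        aligned: dict[str, reg.AlignedCohort] = {}
        curves = {
            h: _curves_to_normalized(series, h, grid) for h in HORMONES
        }
        if self.shared_warps is None:
            for h in HORMONES:
                aligned[h] = reg.karcher_align(
                    curves[h],
                    max_iter=self.max_iter,
                    tol=self.tol,
                    resolution=self.resolution,
                    penalty=self.dp_penalty,
                )
        else:
            src = self.shared_warps
            aligned[src] = reg.karcher_align(
                curves[src],
                max_iter=self.max_iter,
                tol=self.tol,
                resolution=self.resolution,
                penalty=self.dp_penalty,
            )
            other = "fsh" if src == "inhibin_b" else "inhibin_b"
            res = self.resolution
            work = [c.resample(res) for c in curves[other]]
            borrowed = [
                reg.warp_curve(c, w)
                for c, w in zip(work, aligned[src].warps)
            ]
            qs = np.array([reg.to_srvf(c).q for c in borrowed])
            anchor = float(np.mean([c.values[0] for c in borrowed]))
            template = reg.srvf_to_curve(
                reg.SRVFCurve(borrowed[0].grid, qs.mean(axis=0)), anchor
            )
            aligned[other] = reg.AlignedCohort(
                aligned=borrowed,
                warps=aligned[src].warps,
                template=template,
                trace=[],
                converged=aligned[src].converged,
                n_iterations=aligned[src].n_iterations,
            )

        day_values = {h: _aligned_day_values(aligned[h], grid) for h in HORMONES}
        days = np.arange(grid[0], grid[1] + 1)

        standardized_cycles = []
        z_values = {h: np.empty_like(day_values[h]) for h in HORMONES}
        for i, cyc in enumerate(series):
            sc = csum.standardize_cycle(
                cyc.cycle_id,
                days,
                {h: day_values[h][i] for h in HORMONES},
                ddof=self.sd_ddof,
            )
            standardized_cycles.append(sc)
            for h in HORMONES:
                z_values[h][i] = sc.z[h]

        rng = np.random.SeedSequence(seed)
        boot_seeds = rng.generate_state(2 * len(HORMONES))
        summaries: dict[tuple[str, bool], csum.SummaryCurve] = {}
        k = 0
        for h in HORMONES:
            for std, mat in ((False, day_values[h]), (True, z_values[h])):
                summaries[(h, std)] = csum.bootstrap_ci(
                    mat,
                    days,
                    hormone=h,
                    standardized=std,
                    level=self.ci_level,
                    n_boot=self.n_boot,
                    seed=int(boot_seeds[k] % (2**31)),
                )
                k += 1

        fsh_curve = summaries[("fsh", True)]
        b_curve = summaries[("inhibin_b", True)]
        std_curve = {"fsh": fsh_curve, "inhibin_b": b_curve}
        full_window = grid
        early = self.early_window

        if self.lag_specs is None:
            specs = [
                clags.LagSpec("fsh", 1, full_window),
                clags.LagSpec("inhibin_b", 1, early),
            ]
        else:
            specs = [
                clags.LagSpec(
                    d["leader"],
                    d.get("lag_days", 1),
                    tuple(d["window"]) if d.get("window") else full_window,
                )
                for d in self.lag_specs
            ]
        correlations: list[clags.CorrelationResult] = []
        for spec in specs:
            leader = std_curve[spec.leader]
            follower = std_curve[
                "inhibin_b" if spec.leader == "fsh" else "fsh"
            ]
            correlations += clags.correlate_curves(leader, follower, spec)

        scans = {
            "fsh": clags.lag_scan(
                fsh_curve, b_curve, self.scan_lags, full_window,
                method="pearson", leader_name="fsh",
            ),
            "inhibin_b": clags.lag_scan(
                b_curve, fsh_curve, self.scan_lags, early,
                method="pearson", leader_name="inhibin_b",
            ),
        }

        return HormoneFeedbackResults(
            model=self,
            series=series,
            day0=day0,
            grid=grid,
            aligned=aligned,
            aligned_day_values=day_values,
            standardized_cycles=standardized_cycles,
            standardized_day_values=z_values,
            summaries=summaries,
            correlations=correlations,
            scans=scans,
            seed=seed,
        )


@dataclass
class HormoneFeedbackResults:
    """Fitted cohort analysis: estimates, bands, correlations, diagnostics."""

    model: HormoneFeedbackModel
    series: list
    day0: dict
    grid: tuple[int, int]
    aligned: dict
    aligned_day_values: dict
    standardized_cycles: list
    standardized_day_values: dict
    summaries: dict
    correlations: list
    scans: dict
    seed: int = 0
    warnings: list = field(default_factory=list)

    # ------------------------------------------------------------ accessors
    def summary_curve(
        self, hormone: str, standardized: bool = True
    ) -> csum.SummaryCurve:
        return self.summaries[(hormone, standardized)]

    def correlation(
        self, leader: str, method: str
    ) -> clags.CorrelationResult:
        for r in self.correlations:
            if r.leader == leader and r.method == method:
                return r
        raise KeyError((leader, method))

    @property
    def best_fsh_lead_lag(self) -> int:
        return self.scans["fsh"].best_positive_lag

    @property
    def converged(self) -> bool:
        return all(a.converged for a in self.aligned.values())

    # ------------------------------------------------------------- exports
    def correlations_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_record() for r in self.correlations])

    def summaries_frame(self) -> pd.DataFrame:
        rows = []
        for (h, std), c in self.summaries.items():
            for i, d in enumerate(c.day_index):
                rows.append(
                    {
                        "hormone": h,
                        "day_index": int(d),
                        "mean": c.mean[i],
                        "ci_lower": c.ci_lower[i],
                        "ci_upper": c.ci_upper[i],
                        "n_cycles": int(c.n_cycles[i]),
                        "standardized": std,
                    }
                )
        return pd.DataFrame(rows)

    def aligned_frame(self) -> pd.DataFrame:
        lo, hi = self.grid
        days = np.arange(lo, hi + 1)
        s_days = (days - lo) / (hi - lo)
        rows = []
        for h in HORMONES:
            cohort = self.aligned[h]
            for i, cyc in enumerate(self.series):
                sel = (cyc.day_index >= lo) & (cyc.day_index <= hi)
                raw = cyc.values(h)[sel]
                gamma = np.interp(
                    s_days, cohort.warps[i].grid, cohort.warps[i].gamma
                )
                for j, d in enumerate(days):
                    rows.append(
                        {
                            "cycle_id": cyc.cycle_id,
                            "day_index": int(d),
                            "hormone": h,
                            "raw_value": raw[j],
                            "aligned_value": self.aligned_day_values[h][i, j],
                            "warp_gamma": gamma[j],
                        }
                    )
        return pd.DataFrame(rows)

    def correlations_json(self) -> str:
        return json.dumps(
            [r.to_record() for r in self.correlations], indent=2
        )

    # -------------------------------------------------------------- summary
    def summary(self) -> str:
        """Human-readable fit summary (statsmodels flavour)."""
        lines = []
        lo, hi = self.grid
        lines.append("Hormone feedback cycle analysis")
        lines.append("=" * 64)
        lines.append(
            f"Cycles: {len(self.series)}    common day grid: [{lo}, {hi}]"
        )
        d0 = ", ".join(f"{k}: CD{v}" for k, v in self.day0.items())
        lines.append(f"Day 0 (ovulatory inhibin B peak) at {d0}")
        for h in HORMONES:
            a = self.aligned[h]
            tr = (
                f"objective {a.trace[0]:.4g} -> {a.trace[-1]:.4g}"
                if a.trace
                else "warps shared"
            )
            lines.append(
                f"Registration [{h}]: {a.n_iterations} iteration(s), "
                f"{tr}, converged={a.converged}"
            )
        lines.append("-" * 64)
        lines.append(
            f"{'leader':>10} {'lag':>4} {'window':>10} {'method':>9} "
            f"{'coef':>7} {'p':>9} {'n':>4}"
        )
        for r in self.correlations:
            lines.append(
                f"{r.leader:>10} {r.lag:>4} "
                f"{str(list(r.window)):>10} {r.method:>9} "
                f"{r.coefficient:>7.3f} {r.p_value:>9.3g} {r.n_pairs:>4}"
            )
        lines.append("-" * 64)
        lines.append(
            "FSH-leads lag scan (Pearson): "
            + ", ".join(
                f"k={r.lag}: {r.coefficient:.3f}"
                for r in self.scans["fsh"].results
            )
        )
        lines.append(
            f"Max positive FSH-leads correlation at lag "
            f"+{self.scans['fsh'].best_positive_lag}"
        )
        return "\n".join(lines)

    # ------------------------------------------------------------- plotting
    def plot_summary(self, hormone: str, standardized: bool = True, ax=None):
        from .plotting import plot_summary_curve

        return plot_summary_curve(
            self.summary_curve(hormone, standardized), ax=ax
        )

    def plot_lag_overlay(self, leader: str = "fsh", lag: int = 1, ax=None):
        from .plotting import plot_lag_overlay

        follower = "inhibin_b" if leader == "fsh" else "fsh"
        return plot_lag_overlay(
            self.summary_curve(leader, True),
            self.summary_curve(follower, True),
            lag=lag,
            ax=ax,
        )
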