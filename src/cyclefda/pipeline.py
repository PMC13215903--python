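"""End-to-end pipeline orchestration with a single config and a manifest.

``run_pipeline`` executes read → day-0 index → align → standardize →
summarize (+CI) → lag correlations, writes every stage's artifact, and
records a manifest (config echo, version, SHA-256 of each artifact,
timestamps, warnings) sufficient to verify a bit-identical re-run of the
deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from . import io as cio
from .model import HormoneFeedbackModel
from .simulate import paperlike_preset, simulate_cohort

__all__ = ["AnalysisConfig", "RunManifest", "validate_config", "run_pipeline"]

log = logging.getLogger("cyclefda")


@dataclass
class AnalysisConfig:
    """Flat, YAML-serialisable configuration of one pipeline run."""

    input: str | None = None  # cohort CSV; None -> simulate
    preset: str = "paperlike"
    n_cycles: int = 4
    seed: int = 0
    grid: tuple[int, int] = (-20, 15)
    peak_window: tuple[int, int] | None = None
    resolution: int = 101
    dp_penalty: float = 0.0
    max_iter: int = 20
    tol: float = 1e-6
    shared_warps: str | None = "inhibin_b"
    ci_level: float = 0.95
    n_boot: int = 10_000
    sd_denominator: int = 1  # ddof of the standardization SD
    early_window: tuple[int, int] = (-13, -8)
    scan_lags: tuple[int, ...] = (0, 1, 2, 3)
    lag_specs: list = field(
        default_factory=lambda: [
            {"leader": "fsh", "lag_days": 1, "window": None},
            {"leader": "inhibin_b", "lag_days": 1, "window": [-13, -8]},
        ]
    )
    outdir: str = "cyclefda_out"
    plots: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        for name in ("grid", "peak_window", "early_window", "scan_lags"):
            v = getattr(cfg, name)
            if isinstance(v, list):
                setattr(cfg, name, tuple(v))
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class RunManifest:
    config: dict
    version: str
    artifacts: dict  # name -> {path, sha256}
    started: str = ""
    finished: str = ""
    warnings: list = field(default_factory=list)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def validate_config(config: AnalysisConfig) -> list[str]:
    """Human-readable configuration problems; an empty list means valid."""
    problems: list[str] = []
    if config.input is not None and not Path(config.input).exists():
        problems.append(f"input file does not exist: {config.input}")
    if not (0.0 < config.ci_level < 1.0):
        problems.append(
            f"ci_level must lie in (0, 1), got {config.ci_level}"
        )
    if config.n_boot < 100:
        problems.append(f"n_boot must be >= 100, got {config.n_boot}")
    if config.resolution < 10:
        problems.append(f"resolution must be >= 10, got {config.resolution}")
    if config.grid[0] > config.grid[1]:
        problems.append(f"empty grid range {config.grid}")
    if config.shared_warps not in (None, "fsh", "inhibin_b"):
        problems.append(
            f"shared_warps must be null/fsh/inhibin_b, got "
            f"{config.shared_warps}"
        )
    for spec in config.lag_specs:
        if spec.get("lag_days", 1) < 1:
            problems.append("lag_days must be >= 1")
        if spec.get("leader") not in ("fsh", "inhibin_b"):
            problems.append(f"unknown leader {spec.get('leader')!r}")
    if config.input is None and config.n_cycles < 2:
        problems.append("n_cycles must be >= 2 when simulating")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


def run_pipeline(config: AnalysisConfig) -> RunManifest:
    """Run every stage and write all artifacts plus the run manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=config.to_dict(), version=__version__, artifacts={},
        started=_now(),
    )

    def register(name: str, path: Path) -> None:
        manifest.artifacts[name] = {
            "path": str(path), "sha256": _sha256(path)
        }

    if config.input is None:
        params = paperlike_preset()
        cohort = simulate_cohort(
            params, n_cycles=config.n_cycles, seed=config.seed
        )
        cohort_csv = outdir / "cohort.csv"
        cohort.write(cohort_csv, outdir / "truth.json")
        register("cohort", cohort_csv)
        register("truth", outdir / "truth.json")
        cycles = cohort.cycles
        log.info("simulate: %d cycles (preset %s)", len(cycles), config.preset)
    else:
        cycles = cio.read_cycles(config.input)
        log.info("read: %d cycles from %s", len(cycles), config.input)

    model = HormoneFeedbackModel(
        cycles,
        grid=config.grid,
        peak_window=config.peak_window,
        resolution=config.resolution,
        dp_penalty=config.dp_penalty,
        max_iter=config.max_iter,
        tol=config.tol,
        shared_warps=config.shared_warps,
        sd_ddof=config.sd_denominator,
        ci_level=config.ci_level,
        n_boot=config.n_boot,
        early_window=config.early_window,
        scan_lags=config.scan_lags,
        lag_specs=config.lag_specs,
    )
    results = model.fit(seed=config.seed)
    n_imp = sum(
        int(s.fsh_imputed.sum() + s.inhibin_b_imputed.sum())
        for s in results.series
    )
    log.info(
        "index: common grid %s, %d imputed values", results.grid, n_imp
    )
    for h, a in results.aligned.items():
        log.info(
            "align[%s]: %d iterations, converged=%s", h, a.n_iterations,
            a.converged,
        )
        if not a.converged:
            manifest.warnings.append(f"registration for {h} not converged")

    indexed_csv = outdir / "indexed.csv"
    cio.write_series(results.series, indexed_csv)
    register("indexed", indexed_csv)

    aligned_csv = outdir / "aligned.csv"
    results.aligned_frame().to_csv(aligned_csv, index=False)
    register("aligned", aligned_csv)

    sm = results.summaries_frame()
    for h in ("fsh", "inhibin_b"):
        path = outdir / f"summary_{h}.csv"
        sm[sm.hormone == h].to_csv(path, index=False)
        register(f"summary_{h}", path)

    corr_json = outdir / "correlations.json"
    corr_json.write_text(results.correlations_json())
    register("correlations", corr_json)
    corr_csv = outdir / "correlations.csv"
    results.correlations_frame().to_csv(corr_csv, index=False)
    register("correlations_csv", corr_csv)
    log.info(
        "correlate: %d results, best FSH-leads lag +%d",
        len(results.correlations), results.best_fsh_lead_lag,
    )

    if config.plots:
        import matplotlib

        matplotlib.use("Agg", force=True)
        import matplotlib.pyplot as plt

        for h in ("fsh", "inhibin_b"):
            ax = results.plot_summary(h, standardized=True)
            fig_path = outdir / f"summary_{h}.png"
            ax.figure.savefig(fig_path, dpi=120)
            plt.close(ax.figure)
            register(f"plot_{h}", fig_path)

    summary_txt = outdir / "summary.txt"
    summary_txt.write_text(results.summary() + "\n")
    register("summary_text", summary_txt)

    manifest.finished = _now()
    manifest.write(outdir / "manifest.json")
    return manifest
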