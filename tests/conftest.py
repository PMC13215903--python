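"""Shared fixtures and small generators for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from cyclefda.registration import NormalizedCurve, WarpingFunction


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_smooth_warp(rng: np.random.Generator, n: int,
                     scale: float = 0.08) -> WarpingFunction:
    """Random boundary-fixed monotone warp from a low-order sine family."""
    s = np.linspace(0.0, 1.0, n)
    while True:
        c = rng.normal(0.0, scale, 2) / np.array([1.0, 2.0])
        g = s + c[0] * np.sin(np.pi * s) + c[1] * np.sin(2 * np.pi * s)
        if np.all(np.diff(g) > 0):
            return WarpingFunction(s, g)


def bimodal_curve(n: int = 101) -> NormalizedCurve:
    """A two-bump test curve with identifiable phase structure."""
    s = np.linspace(0.0, 1.0, n)
    v = (
        np.exp(-(((s - 0.35) / 0.12) ** 2))
        + 0.7 * np.exp(-(((s - 0.75) / 0.10) ** 2))
    )
    return NormalizedCurve(s, v)


def mean_pairwise_corr(mats) -> float:
    n = len(mats)
    cs = [
        np.corrcoef(mats[i], mats[j])[0, 1]
        for i in range(n)
        for j in range(i + 1, n)
    ]
    return float(np.mean(cs))


@pytest.fixture
def cohort_csv(tmp_path):
    """Write a small 4-cycle paper-like cohort CSV; returns its path."""
    from cyclefda.simulate import paperlike_preset, simulate_cohort

    cohort = simulate_cohort(paperlike_preset(), n_cycles=4, seed=11)
    path = tmp_path / "cohort.csv"
    cohort.write(path)
    return path
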