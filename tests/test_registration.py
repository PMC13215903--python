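"""SRVF transform, DP warping and Karcher-mean alignment tests.

The dynamic-programming aligner is checked against an independent
brute-force enumeration of all monotone lattice paths (same step set and
segment-cost definition, written from the cost formula rather than shared
code), and against self-consistency: a curve warped by a known smooth γ*
must be re-aligned with γ ≈ γ*.
"""

import numpy as np
import pytest

from cyclefda.exceptions import GridError, InvariantError
from cyclefda.registration import (
    DEFAULT_STEPS,
    NormalizedCurve,
    SRVFCurve,
    WarpingFunction,
    dp_align,
    elastic_distance,
    invert_warp,
    karcher_align,
    to_srvf,
    warp_curve,
)

from conftest import bimodal_curve, make_smooth_warp, mean_pairwise_corr


# ----------------------------------------------------------- brute force
def brute_force_objective(q1, q2, steps=DEFAULT_STEPS, penalty=0.0):
    """Exhaustive minimum over all monotone lattice paths (oracle)."""
    n = len(q1)
    s = np.linspace(0, 1, n)
    h = 1.0 / (n - 1)
    pen = penalty * max(np.mean(np.asarray(q1) ** 2), 1e-12)

    def seg_cost(i0, j0, i1, j1):
        di, dj = i1 - i0, j1 - j0
        m = dj / di
        sqm = np.sqrt(m)
        c = 0.0
        for k in range(1, di + 1):
            q2v = np.interp(s[j0] + k * m * h, s, q2)
            c += h * (q1[i0 + k] - sqm * q2v) ** 2
        return c + pen * (sqm - 1) ** 2 * di * h

    best = [np.inf]

    def rec(i, j, acc):
        if i == n - 1 and j == n - 1:
            best[0] = min(best[0], acc)
            return
        for di, dj in steps:
            if i + di <= n - 1 and j + dj <= n - 1:
                rec(i + di, j + dj, acc + seg_cost(i, j, i + di, j + dj))

    rec(0, 0, 0.0)
    return best[0]


class TestToSRVF:
    def test_linear_curve_gives_unit_q(self):
        s = np.linspace(0, 1, 51)
        q = to_srvf(NormalizedCurve(s, s.copy()))
        assert np.allclose(q.q, 1.0)

    def test_constant_curve_gives_zero_q(self):
        s = np.linspace(0, 1, 51)
        q = to_srvf(NormalizedCurve(s, np.full(51, 3.7)))
        assert np.allclose(q.q, 0.0)

    def test_quadratic_matches_closed_form(self):
        """f(s)=s² has q(s)=√(2s) (finite differences, away from s=0)."""
        s = np.linspace(0, 1, 101)
        q = to_srvf(NormalizedCurve(s, s**2))
        expected = np.sqrt(2 * s)
        err = np.abs(q.q[5:] - expected[5:])
        assert err.max() <= 0.05

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvariantError):
            to_srvf(NormalizedCurve(np.array([0.0, 1.0]), np.array([0.0, 1.0])))


class TestWarpCurve:
    def test_identity_returns_curve(self):
        f = bimodal_curve(101)
        g = WarpingFunction.identity(101)
        assert np.allclose(warp_curve(f, g).values, f.values)

    def test_composition_with_square_warp(self):
        s = np.linspace(0, 1, 201)
        f = NormalizedCurve(s, s.copy())
        g = WarpingFunction(s, s**2)
        assert np.allclose(warp_curve(f, g).values, s**2, atol=1e-6)

    def test_warp_then_inverse_recovers_curve(self, rng):
        f = bimodal_curve(201)
        g = make_smooth_warp(rng, 201)
        round_trip = warp_curve(warp_curve(f, g), invert_warp(g))
        assert np.abs(round_trip.values - f.values).max() <= 2 / 200

    def test_non_monotone_warp_rejected(self):
        s = np.linspace(0, 1, 11)
        bad = s.copy()
        bad[5], bad[6] = bad[6], bad[5]
        with pytest.raises(InvariantError):
            WarpingFunction(s, bad)


class TestDPAlign:
    def test_self_alignment_is_identity_with_zero_objective(self):
        q = to_srvf(bimodal_curve(81))
        w = dp_align(q, q)
        assert np.allclose(w.gamma, w.grid)
        assert w.objective == pytest.approx(0.0, abs=1e-10)

    def test_degenerate_zero_srvfs_give_identity(self):
        s = np.linspace(0, 1, 21)
        z = SRVFCurve(s, np.zeros(21))
        w = dp_align(z, z)
        assert np.allclose(w.gamma, w.grid)

    def test_known_warp_recovered(self, rng):
        """Aligning f to f∘γ* recovers γ* within 2 grid spacings."""
        n = 50
        f = bimodal_curve(n)
        for _ in range(5):
            gam = make_smooth_warp(rng, n)
            target = to_srvf(warp_curve(f, gam))
            w = dp_align(target, to_srvf(f))
            assert np.abs(w.gamma - gam.gamma).max() <= 2 / (n - 1)

    @pytest.mark.parametrize("penalty", [0.0, 0.1])
    def test_matches_brute_force_on_tiny_grids(self, rng, penalty):
        for _ in range(40):
            n = int(rng.integers(3, 7))
            s = np.linspace(0, 1, n)
            q1, q2 = rng.normal(size=n), rng.normal(size=n)
            w = dp_align(SRVFCurve(s, q1), SRVFCurve(s, q2), penalty=penalty)
            oracle = brute_force_objective(q1, q2, penalty=penalty)
            assert w.objective == pytest.approx(oracle, abs=1e-12)

    def test_negative_penalty_rejected(self):
        q = to_srvf(bimodal_curve(21))
        with pytest.raises(InvariantError):
            dp_align(q, q, penalty=-1.0)


class TestElasticDistance:
    def test_warp_invariance(self, rng):
        """d(f, f∘γ) is small (DP slope-set discretization floor only).

        The lattice quantizes γ' to a finite slope set, so the distance to
        a re-parameterised copy is not exactly 0; it stays a small fraction
        of the curve's own SRVF norm and shrinks with resolution.
        """
        f = bimodal_curve(101)
        scale = np.sqrt(np.trapezoid(to_srvf(f).q ** 2, f.grid))
        for _ in range(3):
            g = make_smooth_warp(rng, 101)
            d = elastic_distance(f, warp_curve(f, g))
            assert d <= 0.1 * scale


class TestKarcherAlign:
    def test_identical_curves_all_identity(self):
        f = bimodal_curve(101)
        copies = [
            NormalizedCurve(f.grid, f.values.copy()) for _ in range(4)
        ]
        out = karcher_align(copies, tol=1e-6)
        for w in out.warps:
            assert np.abs(w.gamma - w.grid).max() <= 1e-6
        for c in out.aligned:
            assert np.allclose(c.values, f.values)

    def test_prewarped_copies_realign(self, rng):
        """Registration undoes random smooth warps of a common template."""
        f = bimodal_curve(100)
        warped = [
            warp_curve(f, make_smooth_warp(rng, 100)) for _ in range(4)
        ]
        pre = mean_pairwise_corr([c.values for c in warped])
        out = karcher_align(warped, resolution=100)
        post = mean_pairwise_corr([c.values for c in out.aligned])
        assert post >= pre
        assert post >= 0.99

    def test_two_curves_trace_non_increasing(self, rng):
        f = bimodal_curve(80)
        g = warp_curve(f, make_smooth_warp(rng, 80))
        out = karcher_align([f, g])
        assert np.all(np.diff(out.trace) <= 1e-9)

    def test_random_cohorts_trace_non_increasing(self, rng):
        for _ in range(5):
            s = np.linspace(0, 1, 60)
            curves = [
                NormalizedCurve(
                    s,
                    rng.normal(0, 0.2)
                    + np.sin(2 * np.pi * (s + rng.normal(0, 0.05)))
                    + rng.normal(0, 0.05, 60),
                )
                for _ in range(4)
            ]
            out = karcher_align(curves, resolution=60)
            assert np.all(np.diff(out.trace) <= 1e-9)

    def test_relabelling_permutes_warps(self, rng):
        f = bimodal_curve(60)
        curves = [warp_curve(f, make_smooth_warp(rng, 60)) for _ in range(3)]
        out1 = karcher_align(curves, resolution=60)
        out2 = karcher_align(curves[::-1], resolution=60)
        for w1, w2 in zip(out1.warps, out2.warps[::-1]):
            assert np.allclose(w1.gamma, w2.gamma)

    def test_mismatched_grids_rejected(self):
        f = bimodal_curve(50)
        g = bimodal_curve(60)
        with pytest.raises(GridError):
            karcher_align([f, g])

    def test_single_curve_rejected(self):
        with pytest.raises(GridError):
            karcher_align([bimodal_curve(50)])
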