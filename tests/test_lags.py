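"""Lagged-pair construction and correlation tests.

Kendall's tau is checked against an O(n²) concordant/discordant count
(tau-b with tie corrections) and Spearman's rho against the
Pearson-on-average-ranks definition, both written independently of the
implementation path.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from cyclefda.exceptions import (
    DegeneracyError,
    InsufficientDataError,
    InvariantError,
)
from cyclefda.lags import (
    LagSpec,
    correlate,
    lag_scan,
    lagged_pairs,
)
from cyclefda.summaries import SummaryCurve


def curve(days, values, hormone="h"):
    return SummaryCurve(
        hormone=hormone,
        day_index=np.asarray(days),
        mean=np.asarray(values, dtype=float),
        standardized=True,
    )


# ----------------------------------------------------------------- oracles
def kendall_tau_b_brute(x, y):
    """Direct pair counting with tie corrections."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx, dy = x[i] - x[j], y[i] - y[j]
            if dx == 0 and dy == 0:
                tx += 1
                ty += 1
            elif dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                conc += 1
            else:
                disc += 1
    n0 = n * (n - 1) / 2
    denom = np.sqrt((n0 - tx) * (n0 - ty))
    return (conc - disc) / denom if denom > 0 else np.nan


def spearman_brute(x, y):
    """Pearson correlation of average ranks."""
    rx, ry = stats.rankdata(x), stats.rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestLaggedPairs:
    def test_shifted_copy_gives_equal_coordinates(self):
        days = np.arange(-5, 6)
        lead = curve(days, np.sin(days / 2.0))
        # follower responds 1 day later with identical values
        foll = curve(days + 1, np.sin(days / 2.0))
        lv, fv, _ = lagged_pairs(lead, foll, 1, (-5, 5))
        assert np.allclose(lv, fv)

    def test_full_cycle_window_pair_count(self):
        days = np.arange(-13, 10)
        lead = curve(days, np.arange(23.0))
        foll = curve(days, np.arange(23.0) ** 2)
        lv, fv, ts = lagged_pairs(lead, foll, 1, (-13, 9))
        assert len(lv) == 22
        assert ts[0] == -13 and ts[-1] == 8

    def test_early_window_pair_count(self):
        days = np.arange(-13, 10)
        lead = curve(days, np.arange(23.0))
        foll = curve(days, np.arange(23.0) ** 2)
        lv, _, ts = lagged_pairs(lead, foll, 1, (-13, -8))
        assert len(lv) == 6
        assert list(ts) == [-13, -12, -11, -10, -9, -8]

    def test_insufficient_pairs_raise(self):
        days = np.arange(-2, 2)
        c = curve(days, np.ones(4))
        with pytest.raises(InsufficientDataError):
            lagged_pairs(c, c, 3, (-2, -2))

    def test_lag_spec_validation(self):
        with pytest.raises(InvariantError):
            LagSpec("fsh", 0, (-13, 9))
        with pytest.raises(InvariantError):
            LagSpec("fsh", 1, (5, -5))


class TestCorrelate:
    @pytest.mark.parametrize("method", ["pearson", "kendall", "spearman"])
    def test_perfect_positive(self, method):
        x = np.arange(10.0)
        r = correlate(x, x.copy(), method)
        assert r.coefficient == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["pearson", "kendall", "spearman"])
    def test_perfect_negative(self, method):
        x = np.arange(10.0)
        r = correlate(x, -x, method)
        assert r.coefficient == pytest.approx(-1.0)

    def test_kendall_matches_brute_force_small_n(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 8))
            x = rng.integers(0, 5, n).astype(float)  # ties likely
            y = rng.integers(0, 5, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            r = correlate(x, y, "kendall")
            assert r.coefficient == pytest.approx(
                kendall_tau_b_brute(x, y), abs=1e-12
            )

    def test_spearman_matches_rank_definition(self, rng):
        for _ in range(60):
            n = int(rng.integers(3, 12))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r = correlate(x, y, "spearman")
            assert r.coefficient == pytest.approx(
                spearman_brute(x, y), abs=1e-12
            )

    def test_spearman_exact_p_matches_enumeration_oracle(self):
        """Exact small-n p equals scipy's permutation test (full null)."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        y = np.array([2.0, 1.0, 4.0, 3.0, 6.0, 5.0])
        r = correlate(x, y, "spearman")

        def statistic(perm_y):
            return abs(spearman_brute(x, perm_y))

        ref = stats.permutation_test(
            (y,), statistic, permutation_type="pairings",
            n_resamples=np.inf, alternative="greater",
        )
        assert r.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False), min_size=4, max_size=12
        ).filter(lambda xs: max(xs) - min(xs) > 1e-3)
    )
    @pytest.mark.parametrize("method", ["pearson", "kendall", "spearman"])
    def test_antisymmetry(self, method, xs):
        x = np.array(xs)
        y = np.sin(x) + 0.1 * x  # non-degenerate companion
        if np.ptp(y) < 1e-9:
            return
        r1 = correlate(x, y, method)
        r2 = correlate(x, -y, method)
        assert r2.coefficient == pytest.approx(-r1.coefficient, abs=1e-12)
        assert r2.p_value == pytest.approx(r1.p_value, rel=1e-9)

    def test_rank_methods_invariant_to_monotone_transform(self, rng):
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        for method in ("kendall", "spearman"):
            r1 = correlate(x, y, method)
            r2 = correlate(np.exp(x), y**3 + 5 * y, method)
            assert r2.coefficient == pytest.approx(r1.coefficient, abs=1e-12)

    def test_zero_variance_names_coordinate(self):
        with pytest.raises(DegeneracyError, match="coordinate y"):
            correlate(np.arange(5.0), np.ones(5), "pearson")


class TestHolmAdjust:
    def test_step_down_monotone_and_bounded(self, rng):
        from cyclefda.lags import holm_adjust

        x = rng.normal(size=12)
        results = [
            correlate(x, x + rng.normal(0, s, 12), "pearson")
            for s in (0.1, 1.0, 5.0)
        ]
        adj = holm_adjust(results)
        raw = sorted(r.p_value for r in results)
        srt = sorted(a.p_value for a in adj)
        # smallest raw p multiplied by the family size, all capped at 1
        assert srt[0] == pytest.approx(min(raw[0] * 3, 1.0))
        assert all(a.p_value >= r.p_value for a, r in zip(adj, results))
        assert all(a.p_value <= 1.0 for a in adj)


class TestLagScan:
    def test_argmax_at_true_delay(self, rng):
        days = np.arange(-15, 15)
        base = np.sin(days / 3.0)
        lead = curve(days, base)
        delayed = curve(days, np.interp(days - 2, days, base)
                        + rng.normal(0, 0.01, days.size))
        scan = lag_scan(lead, delayed, (0, 1, 2, 3), (-12, 10))
        assert scan.best_positive_lag == 2

    @pytest.mark.parametrize("method", ["pearson", "kendall", "spearman"])
    def test_lag0_self_correlation_is_one(self, method):
        days = np.arange(-5, 6)
        c = curve(days, np.sin(days / 2.0))
        scan = lag_scan(c, c, (0,), (-5, 5), method=method)
        assert scan.results[0].coefficient == pytest.approx(1.0)

    def test_tie_breaks_to_smallest_abs_lag(self):
        days = np.arange(0, 20)
        c = curve(days, np.tile([1.0, 2.0], 10))  # period 2: lags 0,2 tie
        scan = lag_scan(c, c, (0, 2), (0, 17))
        assert scan.best_positive_lag == 0
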