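"""Per-cycle hormone series I/O, ovulatory-peak detection and day-0 indexing.

Cycles arrive as delimited text with one row per sampled calendar day
(``cycle_id, calendar_day, fsh, inhibin_b``; CD1 = first day of menses,
FSH in mIU/ml, inhibin B in pg/ml, missing = empty field or ``NA``).
Each cycle is re-indexed so that day 0 is the day of its mid-cycle
(ovulatory) inhibin B peak, which places all cycles of a cohort on a
comparable day grid for cross-sectional analysis.

Missing interior days are filled by linear interpolation and flagged; the
sampled span is never extrapolated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DetectionError,
    GridError,
    IntegrityError,
    ParseError,
    ReindexError,
)

__all__ = [
    "RawCycle",
    "CycleSeries",
    "read_cycles",
    "write_cycles",
    "write_series",
    "detect_day0",
    "default_peak_window",
    "reindex_to_day0",
    "common_grid",
]

REQUIRED_COLUMNS = ("cycle_id", "calendar_day", "fsh", "inhibin_b")
#: minimum number of sampled (non-missing) days for a usable cycle
MIN_SAMPLED_DAYS = 15


@dataclass
class RawCycle:
    """One cycle's daily hormone record on a contiguous calendar-day axis.

    ``calendar_day`` runs without gaps from the first to the last sampled
    day; days on which the blood draw was missed carry NaN in both hormone
    columns.  ``day0_override`` optionally pins day 0 to a given calendar
    day (used when peak detection is to be bypassed for a cycle).
    """

    cycle_id: str
    calendar_day: np.ndarray
    fsh: np.ndarray
    inhibin_b: np.ndarray
    day0_override: int | None = None

    def __post_init__(self) -> None:
        self.calendar_day = np.asarray(self.calendar_day, dtype=int)
        self.fsh = np.asarray(self.fsh, dtype=float)
        self.inhibin_b = np.asarray(self.inhibin_b, dtype=float)
        if not (len(self.calendar_day) == len(self.fsh) == len(self.inhibin_b)):
            raise IntegrityError(
                f"cycle {self.cycle_id}: column lengths differ"
            )
        if np.any(np.diff(self.calendar_day) <= 0):
            raise IntegrityError(
                f"cycle {self.cycle_id}: calendar days not strictly increasing"
            )
        for name, values in (("fsh", self.fsh), ("inhibin_b", self.inhibin_b)):
            bad = np.where(values < 0)[0]
            if bad.size:
                day = int(self.calendar_day[bad[0]])
                raise ParseError(
                    f"cycle {self.cycle_id}, calendar day {day}: "
                    f"negative {name} concentration {values[bad[0]]}"
                )

    @property
    def sampled_mask(self) -> np.ndarray:
        """Days with at least one hormone measured (missed draw = all-NaN)."""
        return ~(np.isnan(self.fsh) & np.isnan(self.inhibin_b))

    @property
    def n_sampled(self) -> int:
        return int(self.sampled_mask.sum())

    @property
    def gap_days(self) -> np.ndarray:
        """Calendar days inside the span on which the sample was missed."""
        return self.calendar_day[~self.sampled_mask]

    def validate(self) -> None:
        if self.n_sampled < MIN_SAMPLED_DAYS:
            raise IntegrityError(
                f"cycle {self.cycle_id}: only {self.n_sampled} sampled days "
                f"(need >= {MIN_SAMPLED_DAYS})"
            )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle_id": self.cycle_id,
                "calendar_day": self.calendar_day,
                "fsh": self.fsh,
                "inhibin_b": self.inhibin_b,
            }
        )


@dataclass
class CycleSeries:
    """A cycle on the day-index axis (day 0 = ovulatory inhibin B peak).

    ``day_index`` is contiguous; ``*_imputed`` flags mark exactly the days
    whose value was filled by linear interpolation because the sample was
    missing in the raw record.
    """

    cycle_id: str
    day_index: np.ndarray
    fsh: np.ndarray
    inhibin_b: np.ndarray
    fsh_imputed: np.ndarray
    inhibin_b_imputed: np.ndarray
    day0_calendar_day: int = 0

    def __post_init__(self) -> None:
        self.day_index = np.asarray(self.day_index, dtype=int)
        if self.day_index.size and np.any(np.diff(self.day_index) != 1):
            raise IntegrityError(
                f"cycle {self.cycle_id}: day_index not contiguous"
            )

    @property
    def day_range(self) -> tuple[int, int]:
        return int(self.day_index[0]), int(self.day_index[-1])

    def values(self, hormone: str) -> np.ndarray:
        return {"fsh": self.fsh, "inhibin_b": self.inhibin_b}[hormone]

    def imputed(self, hormone: str) -> np.ndarray:
        return {"fsh": self.fsh_imputed, "inhibin_b": self.inhibin_b_imputed}[
            hormone
        ]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cycle_id": self.cycle_id,
                "calendar_day": self.day_index + self.day0_calendar_day,
                "day_index": self.day_index,
                "fsh": self.fsh,
                "inhibin_b": self.inhibin_b,
                "fsh_imputed": self.fsh_imputed,
                "inhibin_b_imputed": self.inhibin_b_imputed,
            }
        )


def read_cycles(path) -> list[RawCycle]:
    """Read a cohort CSV into one :class:`RawCycle` per distinct cycle id.

    Rows are grouped by ``cycle_id`` and day-sorted; missing concentrations
    (empty field or ``NA``) are preserved as NaN; calendar days absent from
    the file inside a cycle's sampled span become all-NaN gap days.
    An optional ``day0_override`` column pins day 0 per cycle.
    """
    df = pd.read_csv(
        path,
        na_values=["NA"],
        keep_default_na=True,
        float_precision="round_trip",
    )
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ParseError(f"{path}: missing required column(s) {missing_cols}")
    try:
        df["calendar_day"] = df["calendar_day"].astype(int)
    except (ValueError, TypeError) as exc:
        raise ParseError(f"{path}: non-integer calendar_day ({exc})") from exc
    for col in ("fsh", "inhibin_b"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: non-numeric {col} ({exc})") from exc

    dup = df.duplicated(subset=["cycle_id", "calendar_day"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise IntegrityError(
            f"duplicate rows for cycle {row['cycle_id']}, "
            f"calendar day {int(row['calendar_day'])}"
        )

    cycles: list[RawCycle] = []
    for cid, grp in df.groupby("cycle_id", sort=False):
        grp = grp.sort_values("calendar_day")
        days = grp["calendar_day"].to_numpy()
        full = np.arange(days[0], days[-1] + 1)
        fsh = np.full(full.size, np.nan)
        inhb = np.full(full.size, np.nan)
        pos = days - days[0]
        fsh[pos] = grp["fsh"].to_numpy(dtype=float)
        inhb[pos] = grp["inhibin_b"].to_numpy(dtype=float)
        override = None
        if "day0_override" in grp.columns:
            vals = grp["day0_override"].dropna().unique()
            if vals.size == 1:
                override = int(vals[0])
            elif vals.size > 1:
                raise IntegrityError(
                    f"cycle {cid}: conflicting day0_override values {vals}"
                )
        cycles.append(
            RawCycle(str(cid), full, fsh, inhb, day0_override=override)
        )
    return cycles


def write_cycles(cycles: list[RawCycle], path) -> None:
    """Write a cohort in the same CSV dialect :func:`read_cycles` accepts.

    Gap days are written as rows with empty hormone fields, so a write/read
    round trip reproduces values bit-identically and preserves missingness.
    """
    frames = [c.to_frame() for c in cycles]
    # %.17g guarantees a float64 round-trips bit-identically through text
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def write_series(series: list[CycleSeries], path) -> None:
    """Write day-0-indexed series with imputation-flag columns."""
    frames = [s.to_frame() for s in series]
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.17g"
    )


def default_peak_window(cycle: RawCycle) -> tuple[int, int]:
    """Central 50% of the cycle's sampled calendar span (mid-cycle search)."""
    sampled = cycle.calendar_day[cycle.sampled_mask]
    lo, hi = int(sampled[0]), int(sampled[-1])
    span = hi - lo
    return lo + math.ceil(span * 0.25), lo + math.floor(span * 0.75)


def detect_day0(
    cycle: RawCycle, search_window: tuple[int, int] | None = None
) -> int:
    """Calendar day of the mid-cycle (ovulatory) inhibin B peak.

    The peak is the maximum inhibin B inside ``search_window`` (defaults to
    the central 50% of the sampled span); ties break to the earliest day.
    """
    if search_window is None:
        search_window = default_peak_window(cycle)
    lo, hi = int(search_window[0]), int(search_window[1])
    mask = (cycle.calendar_day >= lo) & (cycle.calendar_day <= hi)
    vals = cycle.inhibin_b[mask]
    days = cycle.calendar_day[mask]
    ok = ~np.isnan(vals)
    if ok.sum() < 3:
        raise DetectionError(
            f"cycle {cycle.cycle_id}: <3 inhibin B values in window "
            f"[{lo}, {hi}]"
        )
    vals, days = vals[ok], days[ok]
    # np.argmax returns the first maximum -> earliest-day tie break
    return int(days[np.argmax(vals)])


def _interp_fill(
    day: np.ndarray, values: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fill interior NaNs by linear interpolation; return (filled, flags)."""
    missing = np.isnan(values)
    if not missing.any():
        return values.copy(), missing
    present = ~missing
    filled = values.copy()
    filled[missing] = np.interp(
        day[missing], day[present], values[present]
    )
    return filled, missing


def reindex_to_day0(
    cycle: RawCycle, day0: int, grid: tuple[int, int] = (-20, 15)
) -> CycleSeries:
    """Shift a cycle onto the day-index axis ``t = calendar_day - day0``.

    Days inside ``grid`` but missed in sampling are linearly interpolated
    (and flagged); grid days outside the cycle's sampled span are dropped,
    never extrapolated.
    """
    sampled = cycle.calendar_day[cycle.sampled_mask]
    lo = max(int(grid[0]), int(sampled[0]) - day0)
    hi = min(int(grid[1]), int(sampled[-1]) - day0)
    if lo > hi:
        raise ReindexError(
            f"cycle {cycle.cycle_id}: grid {grid} does not intersect "
            f"sampled span [{sampled[0] - day0}, {sampled[-1] - day0}]"
        )
    sel = (cycle.calendar_day >= lo + day0) & (cycle.calendar_day <= hi + day0)
    days = cycle.calendar_day[sel]
    fsh, fsh_imp = _interp_fill(days, cycle.fsh[sel])
    inhb, inhb_imp = _interp_fill(days, cycle.inhibin_b[sel])
    return CycleSeries(
        cycle_id=cycle.cycle_id,
        day_index=days - day0,
        fsh=fsh,
        inhibin_b=inhb,
        fsh_imputed=fsh_imp,
        inhibin_b_imputed=inhb_imp,
        day0_calendar_day=int(day0),
    )


def common_grid(cohort: list[CycleSeries]) -> tuple[int, int]:
    """Inclusive day-index range shared by all cycles of a cohort."""
    if len(cohort) < 2:
        raise GridError("common grid needs at least 2 cycles")
    lo = max(s.day_range[0] for s in cohort)
    hi = min(s.day_range[1] for s in cohort)
    if lo > hi:
        raise GridError(
            f"cycle day ranges do not overlap (intersection [{lo}, {hi}])"
        )
    return lo, hi
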