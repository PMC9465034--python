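"""Pest-outbreak analysis and warning engine.

Daily trap counts are analyzed on a 7-day cycle (roughly one emergence period
for cotton bollworm and similar moths). Within the first cycle each day's
count is compared with a cardinal (baseline) count through the increasing
rate IR; from the second cycle onward the day-on-day rate DIR and the
cycle-on-cycle rate CIR (same weekday, previous cycle) are added. Every rate
has the same shape, (current - reference) / reference x 100%.

Outbreak severity is graded 1–5 from a pest-density band and a pest
increasing rate (PIR) band; daily warning colors escalate from blue
(any rate in 0–100%) through orange (100–300%) to red (>300%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Rate",
    "increasing_rate",
    "day_rate",
    "cycle_rate",
    "pest_increase_rate",
    "GradingTable",
    "grade",
    "warn",
    "WarningColor",
    "CycleSummary",
    "DayRecord",
    "WarningReport",
    "analyze",
    "CYCLE_DAYS",
]

CYCLE_DAYS = 7


# ---------------------------------------------------------------------------
# rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Rate:
    """A percentage rate that may be undefined (no reference count) or
    'new presence' (reference 0 but pests appeared — flagged, not infinite)."""

    value: float | None
    new_presence: bool = False

    @property
    def defined(self) -> bool:
        return self.value is not None


def _rate(current: float, reference: float) -> Rate:
    if reference > 0:
        return Rate(value=(current - reference) / reference * 100.0)
    if current > 0:
        return Rate(value=None, new_presence=True)
    return Rate(value=None)


def increasing_rate(current: float, base: float) -> Rate:
    """IR: change of today's count relative to the cardinal (baseline) count."""
    return _rate(current, base)


def day_rate(today: float, yesterday: float) -> Rate:
    """DIR: day-on-day increasing rate."""
    return _rate(today, yesterday)


def cycle_rate(today: float, same_day_prev_cycle: float) -> Rate:
    """CIR: rate against the same weekday of the previous 7-day cycle."""
    return _rate(today, same_day_prev_cycle)


def pest_increase_rate(n_level_count: float, level1_count: float) -> Rate:
    """PIR: growth of a cycle's count relative to the level-1 baseline cycle."""
    return _rate(n_level_count, level1_count)


# ---------------------------------------------------------------------------
# grading
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GradingTable:
    """Outbreak grading bands, right-closed (a band ``>5~10`` means
    ``5 < x <= 10``; density 5 itself is level 1).

    The published rate row lists ">300%" for both of the top levels; the
    level-5 rate band is read here as >500% so the bands partition the axis.
    Both rows are editable for agencies using different survey criteria.
    """

    density_edges: tuple[float, ...] = (5.0, 10.0, 20.0, 30.0)
    rate_edges: tuple[float, ...] = (0.0, 100.0, 300.0, 500.0)

    def density_level(self, density: float) -> int:
        if density < 0:
            raise ValueError("density must be nonnegative")
        return 1 + int(np.searchsorted(self.density_edges, density,
                                       side="left"))

    def rate_level(self, rate: float | Rate) -> int:
        if isinstance(rate, Rate):
            if not rate.defined:
                return 2 if rate.new_presence else 1
            rate = rate.value
        if rate <= 0:  # no growth: never escalates the grade
            return 1
        return 1 + int(np.searchsorted(self.rate_edges, rate, side="left"))


def grade(density: float, rate: float | Rate = 0.0,
          table: GradingTable = GradingTable()) -> int:
    """Outbreak level 1–5: the worse (max) of the density and rate bands."""
    return max(table.density_level(density), table.rate_level(rate))


# ---------------------------------------------------------------------------
# warning colors
# ---------------------------------------------------------------------------

class WarningColor:
    NONE = "none"
    BLUE = "blue"
    ORANGE = "orange"
    RED = "red"


def warn(rates: dict[str, Rate | float | None]) -> str:
    """Warning color from the defined rates among {IR, DIR, CIR}.

    Any rate in (0, 100]% shows at least blue, (100, 300]% orange, >300% red;
    a rate undefined because pests appeared over a zero baseline counts as
    orange (sudden new presence). All rates <= 0 (or absent) -> no warning.
    """
    best = WarningColor.NONE
    order = [WarningColor.NONE, WarningColor.BLUE, WarningColor.ORANGE,
             WarningColor.RED]

    def bump(color: str) -> None:
        nonlocal best
        if order.index(color) > order.index(best):
            best = color

    for r in rates.values():
        if r is None:
            continue
        if isinstance(r, (int, float)):
            r = Rate(value=float(r))
        if not r.defined:
            if r.new_presence:
                bump(WarningColor.ORANGE)
            continue
        if r.value > 300:
            bump(WarningColor.RED)
        elif r.value > 100:
            bump(WarningColor.ORANGE)
        elif r.value > 0:
            bump(WarningColor.BLUE)
    return best


# ---------------------------------------------------------------------------
# full series analysis
# ---------------------------------------------------------------------------

@dataclass
class DayRecord:
    date: str
    count: int
    cycle: int              # 1-based cycle index
    ir: Rate | None         # defined in cycle 1 only
    dir: Rate | None        # from cycle 2 onward
    cir: Rate | None        # from cycle 2 onward
    color: str


@dataclass
class CycleSummary:
    cycle: int
    density: float          # total trap count over the cycle
    pir: Rate
    level: int


@dataclass
class WarningReport:
    days: list[DayRecord]
    cycles: list[CycleSummary]
    cardinal: float

    def to_dict(self) -> dict:
        def rate_dict(r):
            if r is None:
                return None
            return {"value": r.value, "new_presence": r.new_presence}

        return {
            "cardinal": self.cardinal,
            "days": [{"date": d.date, "count": d.count, "cycle": d.cycle,
                      "IR": rate_dict(d.ir), "DIR": rate_dict(d.dir),
                      "CIR": rate_dict(d.cir), "color": d.color}
                     for d in self.days],
            "cycles": [{"cycle": c.cycle, "density": c.density,
                        "PIR": rate_dict(c.pir), "level": c.level}
                       for c in self.cycles],
        }


def analyze(counts, dates=None, cardinal: float | None = None,
            table: GradingTable = GradingTable()) -> WarningReport:
    """Analyze a daily count series into per-day rates/colors and per-cycle
    density, PIR and outbreak level.

    ``counts`` may be a sequence of daily counts or a DataFrame with ``date``
    and ``count`` columns; dates must be consecutive calendar days. The
    cardinal count defaults to day 1 of the first cycle but accepts a
    user-supplied historical baseline.
    """
    if isinstance(counts, pd.DataFrame):
        df = counts
        dates = pd.to_datetime(df["date"])
        counts = df["count"].to_numpy()
    counts = np.asarray(counts)
    if counts.ndim != 1 or len(counts) == 0:
        raise ValueError("need a 1-D, nonempty daily count series")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    if dates is not None:
        dates = pd.to_datetime(pd.Series(list(dates)))
        gaps = dates.diff().dropna()
        if len(gaps) and not (gaps == pd.Timedelta(days=1)).all():
            raise ValueError("counts must be daily with no gaps")
        date_strs = dates.dt.strftime("%Y-%m-%d").tolist()
    else:
        date_strs = [f"day{1 + i}" for i in range(len(counts))]

    if cardinal is None:
        cardinal = float(counts[0])

    days: list[DayRecord] = []
    for i, c in enumerate(counts):
        cyc = i // CYCLE_DAYS + 1
        ir = dir_ = cir = None
        if cyc == 1:
            ir = increasing_rate(float(c), cardinal)
        else:
            dir_ = day_rate(float(c), float(counts[i - 1]))
            cir = cycle_rate(float(c), float(counts[i - CYCLE_DAYS]))
        color = warn({"IR": ir, "DIR": dir_, "CIR": cir})
        days.append(DayRecord(date=date_strs[i], count=int(c), cycle=cyc,
                              ir=ir, dir=dir_, cir=cir, color=color))

    cycles: list[CycleSummary] = []
    totals = [float(counts[s:s + CYCLE_DAYS].sum())
              for s in range(0, len(counts), CYCLE_DAYS)]
    for j, density in enumerate(totals):
        pir = pest_increase_rate(density, totals[0]) if j else Rate(value=0.0)
        level = grade(density, pir, table)
        cycles.append(CycleSummary(cycle=j + 1, density=density, pir=pir,
                                   level=level))
    return WarningReport(days=days, cycles=cycles, cardinal=cardinal)
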