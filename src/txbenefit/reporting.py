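"""Table and figure-series generation.

Produces the standard summary table — one row per (mortality rate, waiting
time) cell with whole-percent no-benefit/harm/benefit columns and the
harm:benefit ratio — plus exportable survival-curve and relative-risk step
series for plotting.  Display rounding is half-away-from-zero: probabilities
to whole percent, times and life expectancies to one decimal, ratios to two
significant figures, matching how such tables are conventionally printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np
import pandas as pd

from .model import (
    RelativeRiskProfile,
    Scenario,
    life_expectancy,
    time_to_equal_survival,
    transplant_survival,
    waitlist_survival,
)
from .outcomes import adjust_profile, decompose, time_to_equal_life_years

__all__ = [
    "TableSpec",
    "generate_table",
    "survival_curve_series",
    "rr_step_series",
    "round_half_away",
    "round_sig",
]

TABLE_COLUMNS = [
    "mortality_rate",
    "life_expectancy",
    "wait_years",
    "no_benefit_pct",
    "harm_pct",
    "benefit_pct",
    "harm_benefit_ratio",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (as printed tables do), not banker's."""
    if not math.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures, ties away from zero."""
    if x == 0 or not math.isfinite(x):
        return x
    ndigits = sig - 1 - math.floor(math.log10(abs(x)))
    return round_half_away(x, ndigits)


@dataclass(frozen=True)
class TableSpec:
    """Layout of a harm-benefit summary table."""

    mr_grid: tuple[float, ...] = (15, 20, 25, 30, 35)
    wait_list: tuple[float, ...] = (2.0,)
    hold_fraction: float = 0.0
    hold_rr: float = 2.2
    preset_name: str = "table_matching"

    def __post_init__(self) -> None:
        if not self.mr_grid or not self.wait_list:
            raise ValueError("mr_grid and wait_list must be non-empty")
        if any(mr <= 0 for mr in self.mr_grid):
            raise ValueError("mortality rates must be positive")
        if any(w < 0 for w in self.wait_list):
            raise ValueError("waiting times must be >= 0")


def generate_table(spec: TableSpec, rounded: bool = True) -> pd.DataFrame:
    """One row per (MR, wait) cell of the harm-benefit decomposition.

    With ``rounded`` (the default), percentages are whole numbers, life
    expectancy has one decimal and the ratio two significant figures; pass
    ``rounded=False`` for full-precision values.
    """
    rows = []
    for mr in spec.mr_grid:
        for w in spec.wait_list:
            scenario = Scenario.from_rate(
                mr,
                wait_years=w,
                hold_fraction=spec.hold_fraction,
                hold_rr=spec.hold_rr,
                preset=spec.preset_name,
            )
            d = decompose(scenario)
            row = {
                "mortality_rate": mr,
                "life_expectancy": life_expectancy(mr),
                "wait_years": w,
                "no_benefit_pct": 100.0 * d.p_no_benefit,
                "harm_pct": 100.0 * d.p_harm,
                "benefit_pct": 100.0 * d.p_benefit,
                "harm_benefit_ratio": d.harm_benefit_ratio,
            }
            if rounded:
                row["life_expectancy"] = round_half_away(row["life_expectancy"], 1)
                for k in ("no_benefit_pct", "harm_pct", "benefit_pct"):
                    row[k] = round_half_away(row[k], 0)
                row["harm_benefit_ratio"] = round_sig(row["harm_benefit_ratio"], 2)
            rows.append(row)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def survival_curve_series(
    profile: RelativeRiskProfile,
    m: float,
    t_grid: Sequence[float],
) -> pd.DataFrame:
    """Exact survival curves sampled on a time grid.

    Returns a frame with columns ``t``, ``s_waitlist``, ``s_transplant``;
    the crossing time and the time of equal cumulative life years are
    attached as ``DataFrame.attrs['t_equal_survival']`` and
    ``attrs['t_equal_life_years']``.
    """
    t = np.asarray(list(t_grid), dtype=float)
    if t.size == 0:
        raise ValueError("t_grid must be non-empty")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be nonnegative and strictly increasing")
    df = pd.DataFrame(
        {
            "t": t,
            "s_waitlist": [waitlist_survival(m, ti) for ti in t],
            "s_transplant": [transplant_survival(profile, m, ti) for ti in t],
        }
    )
    df.attrs["t_equal_survival"] = time_to_equal_survival(profile)
    df.attrs["t_equal_life_years"] = time_to_equal_life_years(profile, m)
    return df


def rr_step_series(
    profile: RelativeRiskProfile, t_max: float | None = None
) -> pd.DataFrame:
    """Step-function series of the relative risk over time.

    Each segment contributes its start and end point (the final open-ended
    segment ends at ``t_max``, default one year past the last breakpoint),
    so plotting ``t`` against ``rr`` with straight lines draws the steps.
    """
    bps = profile.breakpoints
    if t_max is None:
        t_max = (bps[-1] if bps else 0.0) + 1.0
    rows = []
    for start, dur, rr in profile.iter_segments():
        end = min(start + dur, t_max)
        if end <= start:
            break
        rows.append({"t": start, "rr": rr})
        rows.append({"t": end, "rr": rr})
    return pd.DataFrame(rows)


def hold_adjusted_profile_for(spec: TableSpec) -> RelativeRiskProfile:
    """The spec's preset profile after its hold-status adjustment."""
    return adjust_profile(
        RelativeRiskProfile.preset(spec.preset_name),
        spec.hold_fraction,
        spec.hold_rr,
    )
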