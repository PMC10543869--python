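"""Extraction of policy-relevant optima from a simulated design grid.

Five criteria, mirroring the incentives in the global system of bed-net
standards and procurement:

* BL — baseline: every deployed AI at its standard solo loading (1.0),
  3-year redeployment;
* MC — unconstrained maximum of average control over the whole grid;
* CW — cheapest net passing the WHO prequalification requirement
  (> 80% cone-test mortality at 3 years of net age, fixed 3-year
  lifespan); equal-cost ties go to higher control;
* MW — maximum control within the same WHO requirement;
* UC — maximum control among designs achieving universal (100%)
  coverage.

All selection is exhaustive filter-and-sort over the grid table; an empty
feasible set is reported as "no solution", which is data rather than an
error (some net classes genuinely cannot pass the WHO filter).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenario_simulation import GridResult

__all__ = [
    "CRITERIA",
    "OptimalityCriterion",
    "OptimaTable",
    "ConfigurationError",
    "find_optimum",
    "summarize_optima",
]

CRITERIA = ("BL", "MC", "CW", "MW", "UC")

#: numeric slack for the strict "> 0.8" WHO inequality and the
#: "coverage == 1" universal-coverage requirement
NUMERIC_TOL = 1e-9


class ConfigurationError(ValueError):
    """The grid cannot support the requested criterion (e.g. no 3-year rows)."""


@dataclass(frozen=True)
class OptimalityCriterion:
    """One optimality criterion and its constraint constants."""

    code: str
    who_threshold: float = 0.8
    pq_lifespan: float = 3.0
    standard_loading: float = 1.0

    def __post_init__(self) -> None:
        if self.code not in CRITERIA:
            raise ValueError(f"unknown criterion code {self.code!r}")
        if not 0.0 < self.who_threshold <= 1.0:
            raise ValueError("WHO threshold must lie in (0, 1]")


@dataclass
class OptimaTable:
    """One row per criterion x usage; infeasible criteria are explicit rows
    with ``feasible = False`` and missing metrics."""

    table: pd.DataFrame


def _ordered(df: pd.DataFrame, keys: list[tuple[str, bool]]) -> pd.DataFrame:
    cols = [k for k, _ in keys]
    asc = [a for _, a in keys]
    return df.sort_values(cols, ascending=asc, kind="mergesort")


def find_optimum(
    grid: GridResult, criterion: OptimalityCriterion, usage: str = "joint"
) -> pd.Series | None:
    """Select the optimal grid row for one criterion and usage variant.

    Returns the selected row, or ``None`` when the feasible set is empty
    (possible for CW, MW and UC).  Ties are broken deterministically:
    higher control first (CW after price), then lower price, lower
    loadings, shorter lifespan.
    """
    df = grid.table[grid.table["usage"] == usage]
    if df.empty:
        raise ConfigurationError(f"grid contains no rows for usage {usage!r}")
    code = criterion.code

    if code in ("BL", "CW", "MW"):
        at_pq = df[np.isclose(df["lifespan"], criterion.pq_lifespan)]
        if at_pq.empty:
            raise ConfigurationError(
                f"{code} requires lifespan {criterion.pq_lifespan} in the grid"
            )

    if code == "BL":
        sel = at_pq
        std = criterion.standard_loading
        if usage != "solo_2":
            sel = sel[np.isclose(sel["c1"], std)]
        if usage != "solo_1":
            sel = sel[np.isclose(sel["c2"], std)]
        if sel.empty:
            raise ConfigurationError(
                f"BL requires the standard loading {std} in the loading grid"
            )
        return sel.iloc[0]

    if code == "MC":
        feasible = df
        keys = [("avg_control", False), ("price", True), ("c1", True), ("c2", True), ("lifespan", True)]
    elif code == "CW":
        feasible = at_pq[at_pq["start_bioefficacy"] > criterion.who_threshold - NUMERIC_TOL]
        keys = [("price", True), ("avg_control", False), ("c1", True), ("c2", True)]
    elif code == "MW":
        feasible = at_pq[at_pq["start_bioefficacy"] > criterion.who_threshold - NUMERIC_TOL]
        keys = [("avg_control", False), ("price", True), ("c1", True), ("c2", True)]
    else:  # UC
        feasible = df[df["coverage"] >= 1.0 - NUMERIC_TOL]
        keys = [("avg_control", False), ("price", True), ("c1", True), ("c2", True), ("lifespan", True)]

    if feasible.empty:
        return None
    return _ordered(feasible, keys).iloc[0]


def summarize_optima(
    grid: GridResult,
    criteria: list[OptimalityCriterion] | None = None,
    usages: tuple[str, ...] = ("joint", "solo_1", "solo_2"),
) -> OptimaTable:
    """Tabulate every criterion x usage, in fixed BL/MC/CW/MW/UC order."""
    if criteria is None:
        criteria = [OptimalityCriterion(code) for code in CRITERIA]
    metric_cols = [
        "c1",
        "c2",
        "lifespan",
        "price",
        "coverage",
        "avg_control",
        "start_bioefficacy",
        "relative_change",
    ]
    rows = []
    for crit in criteria:
        for usage in usages:
            if usage not in grid.table["usage"].values:
                continue
            row = find_optimum(grid, crit, usage)
            entry: dict = {"criterion": crit.code, "usage": usage}
            if row is None:
                entry["feasible"] = False
                entry.update({c: np.nan for c in metric_cols})
            else:
                entry["feasible"] = True
                entry.update({c: row[c] for c in metric_cols})
            rows.append(entry)
    columns = ["criterion", "usage", "feasible", *metric_cols]
    return OptimaTable(table=pd.DataFrame(rows, columns=columns))
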