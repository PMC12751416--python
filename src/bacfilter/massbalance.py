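"""Cell mass balance over a biofilter: net input, standing stock, budgets.

The filter is treated as a single control volume. Between two takedowns the
number of cells delivered by the water phase is the piecewise-constant
(left-hold) integral of ``(TCC_in - TCC_eff) * Q`` over the interval; the
cells resident on the GAC at a takedown (standing stock) are
``sum_f M_f * q_f`` over bed sections (wet mass x cells per gram). The
balance attributes the unexplained difference to biology:

    delta_cells = (stock_end - stock_start) - net_input

with positive delta meaning net growth and negative net decay, and the
transformation rate is delta divided by the interval length in days.
``eq1_literal=True`` flips the sign convention to the raw algebraic form
(net_input - stock change), kept for comparability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BedProfile, FlowSpec, TCCSeries

__all__ = [
    "CellBudget",
    "cumulative_net_input",
    "standing_stock",
    "cell_budget",
    "budget_series",
]


@dataclass(frozen=True)
class CellBudget:
    """Cell balance over one takedown interval.

    ``phase`` is ``growth`` if the rate exceeds ``+epsilon`` cells/day,
    ``decay`` below ``-epsilon`` and ``balanced`` within the band.
    """

    t_start: float
    t_end: float
    net_input: float
    stock_start: float
    stock_end: float
    delta_cells: float
    rate: float
    phase: str

    def as_dict(self) -> dict:
        return {
            "t_start": self.t_start,
            "t_end": self.t_end,
            "net_input": self.net_input,
            "stock_start": self.stock_start,
            "stock_end": self.stock_end,
            "delta_cells": self.delta_cells,
            "rate_cells_per_day": self.rate,
            "phase": self.phase,
        }


def _step_integral(days: np.ndarray, values: np.ndarray, t_a: float, t_b: float) -> float:
    """Left-hold integral of a step function over [t_a, t_b]."""
    # value at time t is values[i] for days[i] <= t < days[i+1]
    total = 0.0
    for i in range(len(days)):
        seg_start = days[i]
        seg_end = days[i + 1] if i + 1 < len(days) else np.inf
        lo = max(seg_start, t_a)
        hi = min(seg_end, t_b)
        if hi > lo:
            total += values[i] * (hi - lo)
    return total


def cumulative_net_input(
    influent: TCCSeries, effluent: TCCSeries, flow: FlowSpec, window: tuple[float, float]
) -> float:
    """Cells delivered minus cells exported over ``window`` (may be negative).

    Both TCC series are held constant between consecutive measurements
    (left-hold); grids need not match. The window must start at or after
    the first measurement of each series.
    """
    t_a, t_b = float(window[0]), float(window[1])
    if not t_b > t_a:
        raise ValueError("window must satisfy t_b > t_a")
    for s in (influent, effluent):
        if t_a < s.days[0]:
            raise ValueError(
                f"window start {t_a} precedes first {s.compartment} measurement at {s.days[0]}"
            )
    cells_in = _step_integral(influent.days, influent.tcc, t_a, t_b)
    cells_out = _step_integral(effluent.days, effluent.tcc, t_a, t_b)
    return (cells_in - cells_out) * flow.q_ml_per_day


def standing_stock(profile: BedProfile, density: dict) -> float:
    """Total cells in the bed: ``sum_f mass_f * density_f``.

    ``density`` maps section label -> cells per g wet GAC and must cover
    every section of the profile.
    """
    missing = [lab for lab in profile.labels if lab not in density]
    if missing:
        raise KeyError(f"no cell density for bed section(s): {missing}")
    dens = np.array([density[lab] for lab in profile.labels], dtype=float)
    if (dens < 0).any() or np.isnan(dens).any():
        raise ValueError("cell densities must be non-negative and finite")
    return float(np.dot(np.asarray(profile.mass_g, dtype=float), dens))


def cell_budget(
    stock_start: float,
    stock_end: float,
    net_input: float,
    interval: float,
    t_start: float = 0.0,
    epsilon: float = 0.0,
    eq1_literal: bool = False,
) -> CellBudget:
    """Balance one interval; see the module docstring for the convention."""
    if not interval > 0:
        raise ValueError("interval must be positive")
    delta = (stock_end - stock_start) - net_input
    if eq1_literal:
        delta = -delta
    rate = delta / interval
    if rate > epsilon:
        phase = "growth"
    elif rate < -epsilon:
        phase = "decay"
    else:
        phase = "balanced"
    return CellBudget(
        t_start=t_start,
        t_end=t_start + interval,
        net_input=float(net_input),
        stock_start=float(stock_start),
        stock_end=float(stock_end),
        delta_cells=float(delta),
        rate=float(rate),
        phase=phase,
    )


def budget_series(
    takedown_days,
    stocks,
    influent: TCCSeries,
    effluent: TCCSeries,
    flow: FlowSpec,
    start_day: float | None = 0.0,
    epsilon: float = 0.0,
    eq1_literal: bool = False,
) -> list[CellBudget]:
    """One :class:`CellBudget` per consecutive takedown pair.

    ``stocks`` are the standing stocks (cells) at each takedown day.
    If ``start_day`` is not None an initial interval from ``start_day`` to
    the first takedown is prepended with ``stock_start = 0`` (virgin GAC).
    """
    days = np.asarray(takedown_days, dtype=float)
    stocks = np.asarray(stocks, dtype=float)
    if len(days) != len(stocks):
        raise ValueError("takedown_days and stocks must have equal length")
    if len(days) < 2 and start_day is None:
        raise ValueError("need at least two takedowns (or a start_day)")
    if len(days) and not np.all(np.diff(days) > 0):
        raise ValueError("takedown days must be strictly increasing")

    pairs: list[tuple[float, float, float, float]] = []
    if start_day is not None:
        if len(days) == 0 or days[0] <= start_day:
            raise ValueError("first takedown must follow start_day")
        pairs.append((float(start_day), float(days[0]), 0.0, float(stocks[0])))
    for i in range(len(days) - 1):
        pairs.append((float(days[i]), float(days[i + 1]), float(stocks[i]), float(stocks[i + 1])))

    budgets = []
    for t0, t1, s0, s1 in pairs:
        net = cumulative_net_input(influent, effluent, flow, (t0, t1))
        budgets.append(
            cell_budget(
                s0, s1, net, t1 - t0, t_start=t0, epsilon=epsilon, eq1_literal=eq1_literal
            )
        )
    return budgets
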