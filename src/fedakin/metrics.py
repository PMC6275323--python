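"""Derived predictions: iron turnover rate, radical production, rate summaries.

The iron turnover rate (TOR) quantifies catalytic redox cycling: the summed
instantaneous oxidation flux of Fe(II) species, normalized by total iron so
the result has units of per second.  The flux sum runs over reactions 21-23
(free Fe(II): oxygenation, superoxide, Fenton) and 25-27 (the Fe(II)DA
complex analogues).  Fold-change comparisons cancel the normalization, so
the absolute TOR scale is a documented convention.

Hydroxyl-radical production combines Fenton chemistry of free Fe(II)
(reaction 23) and of the Fe(II)-dopamine complex (reaction 26).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product as _iterprod
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import ConfigurationError
from .simulate import (Scenario, Trajectory, simulate, IntegrationError,
                       FE_SPECIES, AIR_PERCENT)

__all__ = [
    "TOR_REACTIONS", "OH_REACTIONS", "TurnoverSeries", "GridResult",
    "UndefinedMetricError", "turnover_rate", "oh_production_rate",
    "initial_rate", "steady_state_grid", "fold_change",
]

TOR_REACTIONS = (21, 22, 23, 25, 26, 27)
OH_REACTIONS = (23, 26)
DAC_FORMATION_REACTIONS = (5, 6)
DAC_DECAY_REACTION = 9


class UndefinedMetricError(ValueError):
    """Metric undefined for this input (e.g. no iron in the system)."""


@dataclass
class TurnoverSeries:
    """TOR(t) = sum of Fe(II)-oxidation fluxes / total iron, per second."""

    times: np.ndarray
    tor: np.ndarray

    def at(self, t: float) -> float:
        return float(np.interp(t, self.times, self.tor))


def turnover_rate(traj: Trajectory) -> TurnoverSeries:
    fe_total = traj.fe_total()
    fe0 = float(fe_total[0])
    if fe0 <= 0:
        raise UndefinedMetricError("total iron is zero; TOR undefined")
    flux_sum = sum(traj.flux(rid) for rid in TOR_REACTIONS)
    return TurnoverSeries(times=traj.times, tor=flux_sum / fe0)


def oh_production_rate(traj: Trajectory) -> np.ndarray:
    """Instantaneous hydroxyl-radical production, M/s (reactions 23 + 26)."""
    return sum(traj.flux(rid) for rid in OH_REACTIONS)


def dac_production_rate(traj: Trajectory, gross: bool = False) -> np.ndarray:
    """Aminochrome production, M/s: formation fluxes net of first-order decay.

    ``gross=True`` omits the decay term (reaction 9).
    """
    rate = sum(traj.flux(rid) for rid in DAC_FORMATION_REACTIONS)
    if not gross:
        rate = rate - traj.flux(DAC_DECAY_REACTION)
    return rate


def initial_rate(traj: Trajectory, species: str, window: float = 7200.0) -> float:
    """Least-squares slope of [species] over [0, window] seconds, in uM/h."""
    mask = traj.times <= window
    if mask.sum() < 3:
        raise ValueError("need at least 3 samples inside the window")
    t = traj.times[mask]
    c = traj[species][mask]
    slope = np.polyfit(t, c, 1)[0]        # M/s
    return float(slope * 1e6 * 3600.0)


def fold_change(metric_with: float, metric_without: float) -> float:
    if metric_without <= 0:
        raise UndefinedMetricError("denominator must be positive")
    return float(metric_with) / float(metric_without)


@dataclass
class GridResult:
    """Steady-state metric over a grid of clamped concentrations.

    ``table`` is long-format: one row per cell with the axis values, the
    metric (M/s), and a convergence flag (False when the pseudo-equilibrium
    criterion was not met within the simulation horizon).
    """

    axes: dict[str, np.ndarray]
    metric: str
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


_AXIS_SPECIES = {"DA": "DA", "H2O2": "H2O2", "O2": "O2"}

#: Relative-derivative threshold defining pseudo-equilibrium, per second.
PSEUDO_EQ_TOL = 1e-6
#: Fallback horizon when the derivative criterion is never met, seconds.
PSEUDO_EQ_HORIZON = 24 * 3600.0


def _steady_state_metric(sc: Scenario, metric: str,
                         gross_dac: bool = False) -> tuple[float, bool]:
    """Simulate to pseudo-equilibrium and evaluate the metric there.

    Pseudo-equilibrium: every unclamped species satisfies
    |dC/dt| / max(C, atol) < PSEUDO_EQ_TOL; otherwise the final state of a
    24 h simulated horizon is used and the cell is flagged unconverged.
    """
    from .simulate import _CompiledNetwork, _IDX
    from .network import build_network

    traj = simulate(sc)
    net = build_network(sc.ph, overrides=sc.overrides)
    compiled = _CompiledNetwork(net, sc.disabled_reactions, sc.effective_clamps())
    free = ~compiled.clamp_mask
    converged_at = None
    for i, t in enumerate(traj.times):
        if t == 0.0:
            continue
        dy = compiled.rhs(t, traj.conc[i])
        rel = np.abs(dy[free]) / np.maximum(traj.conc[i][free], sc.atol)
        if np.all(rel < PSEUDO_EQ_TOL):
            converged_at = i
            break
    i = converged_at if converged_at is not None else len(traj.times) - 1
    if metric == "oh_rate":
        series = oh_production_rate(traj)
    elif metric == "dac_rate":
        series = dac_production_rate(traj, gross=gross_dac)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return float(series[i]), converged_at is not None


def steady_state_grid(base: Scenario, axes: Mapping[str, Sequence[float]],
                      metric: str = "oh_rate", gross_dac: bool = False,
                      t_end: float = PSEUDO_EQ_HORIZON) -> GridResult:
    """Sweep clamped-species grids and record the steady-state metric per cell.

    ``axes`` maps clamped axis names (subset of DA, H2O2, O2; concentrations
    in molar) to value lists; every combination is simulated with those
    species held fixed.  Non-convergent or failing cells are flagged rather
    than fatal.
    """
    names = list(axes)
    for name in names:
        if name not in _AXIS_SPECIES:
            raise ConfigurationError(f"unsupported grid axis {name!r}")
    values = [np.asarray(axes[n], dtype=float) for n in names]
    rows = []
    for combo in _iterprod(*values):
        init = dict(base.init)
        clamps = set(base.clamps)
        sc = base
        o2_mode = base.o2_mode
        for name, v in zip(names, combo):
            sp = _AXIS_SPECIES[name]
            init[sp] = float(v)
            if sp == "O2":
                o2_mode = "clamped"
            else:
                clamps.add(sp)
        sc = replace(base, init=init, clamps=frozenset(clamps),
                     o2_mode=o2_mode, t_end=t_end)
        row = dict(zip(names, combo))
        try:
            value, ok = _steady_state_metric(sc, metric, gross_dac)
            row[metric] = value
            row["converged"] = ok
        except IntegrationError:
            row[metric] = np.nan
            row["converged"] = False
        rows.append(row)
    return GridResult(axes={n: v for n, v in zip(names, values)},
                      metric=metric, table=pd.DataFrame(rows))
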