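"""One-at-a-time rate-constant sensitivity against a reference dataset.

The sensitivity statistic is the relative residual

    r = (1/n) * sum_i |MP_i - ED_i| / ED_i

between model predictions MP and reference data ED.  Sweeping a single rate
constant over a log grid while holding the rest at their table values traces
r(k); the minimum ("shift point") marks the rate constant best supported by
the reference data, and the spread of r over the sweep measures how
influential the reaction is.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import build_network, _parse_param_key
from .simulate import Scenario, simulate, IntegrationError
from .observables import predict_observable

__all__ = [
    "SweepResult", "relative_residual", "sweep_rate_constant", "influence_score",
]


def relative_residual(model_pred: Sequence[float], exp_data: Sequence[float]) -> float:
    """Mean absolute relative deviation of predictions from reference data."""
    mp = np.asarray(model_pred, dtype=float)
    ed = np.asarray(exp_data, dtype=float)
    if mp.shape != ed.shape or mp.ndim != 1:
        raise ValueError("model and data series must be 1-D and equal length")
    if mp.size == 0:
        raise ValueError("need at least one data point")
    if np.any(ed == 0):
        raise ValueError("reference data contains zeros; relative residual undefined")
    return float(np.mean(np.abs(mp - ed) / np.abs(ed)))


@dataclass
class SweepResult:
    """r(k) along a log-spaced grid for one rate constant."""

    reaction_id: int
    direction: str                     # 'f' or 'r'
    k_values: np.ndarray
    r_values: np.ndarray
    shift_point: float                 # k at minimal r (first on ties)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "reaction_id": self.reaction_id,
            "direction": self.direction,
            "k": self.k_values,
            "r": self.r_values,
        })


def _reference_vectors(reference: pd.DataFrame):
    """Group a tidy reference dataset by observable.

    Expects columns ``time_min``, ``observable``, ``value`` with values in
    uM (the dataset CSV schema).  Replicates, if present, are averaged per
    (observable, time).
    """
    ref = (reference.groupby(["observable", "time_min"], as_index=False)["value"]
           .mean())
    groups = {}
    for name, sub in ref.groupby("observable"):
        sub = sub.sort_values("time_min")
        groups[name] = (sub["time_min"].to_numpy() * 60.0,
                        sub["value"].to_numpy() * 1e-6)
    return groups


def sweep_rate_constant(reaction_key, reference: pd.DataFrame, scenario: Scenario,
                        decades: float = 6.0, points_per_decade: int = 5,
                        k_range: tuple[float, float] | None = None) -> SweepResult:
    """Sweep one rate constant on a log grid and score each value by r.

    ``reaction_key`` follows the override syntax (int for a forward
    constant, ``"13r"`` for a reverse one).  By default the grid spans
    ``decades`` decades centred on the table value with
    ``points_per_decade`` points per decade; ``k_range`` overrides the
    bounds.  Model observables are concatenated across all observables
    present in the reference with equal weight.  Failed simulations score
    an infinite residual and the sweep continues.
    """
    rid, direction = _parse_param_key(reaction_key)
    net = build_network(scenario.ph, overrides=scenario.overrides)
    k_table = net.k(rid) if direction == "f" else net.k_rev(rid)
    if k_range is None:
        half = decades / 2.0
        lo, hi = k_table * 10 ** (-half), k_table * 10 ** half
    else:
        lo, hi = k_range
    n_points = int(round(points_per_decade * np.log10(hi / lo))) + 1
    k_values = np.geomspace(lo, hi, n_points)

    groups = _reference_vectors(reference)
    ref_concat = np.concatenate([v for _, v in groups.values()])
    all_times = sorted({t for ts, _ in groups.values() for t in ts})
    key = str(rid) + direction
    r_values = np.empty(n_points)
    for j, k in enumerate(k_values):
        sc = scenario.with_overrides({key: float(k)})
        sc = replace(sc, sample_times=tuple(all_times))
        try:
            traj = simulate(sc)
            preds = [predict_observable(traj, name, ts)
                     for name, (ts, _) in groups.items()]
            r_values[j] = relative_residual(np.concatenate(preds), ref_concat)
        except (IntegrationError, ValueError):
            r_values[j] = np.inf
    shift = float(k_values[int(np.argmin(r_values))])
    return SweepResult(reaction_id=rid, direction=direction,
                       k_values=k_values, r_values=r_values, shift_point=shift)


def influence_score(sweep: SweepResult) -> float:
    """Spread of r over the sweep: max(r) - min(r), ignoring failed cells."""
    finite = sweep.r_values[np.isfinite(sweep.r_values)]
    if finite.size == 0:
        return 0.0
    return float(finite.max() - finite.min())
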