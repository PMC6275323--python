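"""Registry of headline model results and the conditions that produce them.

Each entry recomputes one reported quantity of the study system from scratch
-- simulating the scenario, applying the relevant observable or metric --
and pairs it with the published reference value and the documented relative
tolerance.  The registry backs both the ``fedakin reproduce`` CLI command
and the repository's acceptance script.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .metrics import fold_change, initial_rate, turnover_rate
from .simulate import Scenario, event_time, simulate

__all__ = ["Target", "REGISTRY", "run_target", "run_all"]


@dataclass(frozen=True)
class Target:
    key: str
    description: str
    units: str
    reference: float
    rel_tol: float
    cmp: str                         # 'eq' (two-sided) or 'le' (upper bound)
    compute: Callable[[int], tuple[float, int]]

    def passed(self, value: float) -> bool:
        if self.cmp == "le":
            return value <= self.reference
        return abs(value - self.reference) <= self.rel_tol * abs(self.reference)


def _autox_h2o2_rate(ph: float):
    def compute(seed: int) -> tuple[float, int]:
        sc = Scenario(ph=ph, init={"DA": 20e-6}, o2_mode="clamped", t_end=7200.0)
        traj = simulate(sc)
        return initial_rate(traj, "H2O2", 7200.0), len(traj.times)
    return compute


def _max_dac(seed: int) -> tuple[float, int]:
    sc = Scenario(ph=7.0, init={"DA": 20e-6}, o2_mode="clamped", t_end=7200.0)
    traj = simulate(sc)
    return float(traj["DAC"].max() * 1e6), len(traj.times)


def _tor_fold(ph: float):
    def compute(seed: int) -> tuple[float, int]:
        t_eval = 50 * 60.0
        tors = {}
        for da in (30e-6, 0.0):
            init = {"FeII": 5e-6}
            if da:
                init["DA"] = da
            sc = Scenario(ph=ph, init=init, o2_mode="clamped", t_end=7200.0,
                          sample_times=(t_eval,))
            tors[da] = turnover_rate(simulate(sc)).at(t_eval)
        return fold_change(tors[30e-6], tors[0.0]), 2
    return compute


def _anoxic_bis_ratio(seed: int) -> tuple[float, int]:
    vals = {}
    for ph in (6.5, 7.0):
        sc = Scenario(ph=ph, init={"FeIII": 5e-6, "DA": 50e-6}, o2_mode="anoxic",
                      o2_percent_saturation=0.0, t_end=7200.0)
        vals[ph] = simulate(sc).at("FeIIIDA2", 7200.0)
    return 100.0 * vals[6.5] / vals[7.0], 2


def _h2o2_ph_ratio(seed: int) -> tuple[float, int]:
    vals = {}
    for ph in (6.5, 7.4):
        sc = Scenario(ph=ph, init={"DA": 20e-6, "FeIII": 5e-6},
                      o2_mode="clamped", t_end=7200.0)
        vals[ph] = simulate(sc).at("H2O2", 7200.0)
    return 100.0 * vals[6.5] / vals[7.4], 2


def _fe2_half_life(seed: int) -> tuple[float, int]:
    sc = Scenario(ph=7.0, init={"FeII": 5e-6}, o2_mode="closed",
                  t_end=12 * 3600.0)
    traj = simulate(sc)
    t_half = event_time(traj, "FeII", 0.5)
    value = np.nan if t_half is None else t_half / 3600.0
    return float(value), len(traj.times)


def _fe2_depletion_time(seed: int) -> tuple[float, int]:
    sc = Scenario(ph=7.0, init={"FeII": 5e-6, "DA": 10e-6}, o2_mode="clamped",
                  t_end=24 * 3600.0)
    traj = simulate(sc)
    t95 = event_time(traj, "FeII", 0.05)
    value = np.nan if t95 is None else t95 / 60.0
    return float(value), len(traj.times)


REGISTRY: dict[str, Target] = {t.key: t for t in [
    Target("autox_h2o2_rate_pH7.4",
           "H2O2 production rate from 20 uM dopamine autoxidation at pH 7.4 "
           "(air-saturated, 2 h window)", "uM/h", 0.24, 0.30, "eq",
           _autox_h2o2_rate(7.4)),
    Target("autox_h2o2_rate_pH7.0",
           "H2O2 production rate from 20 uM dopamine autoxidation at pH 7.0",
           "uM/h", 0.12, 0.30, "eq", _autox_h2o2_rate(7.0)),
    Target("autox_h2o2_rate_pH6.5",
           "H2O2 production rate from 20 uM dopamine autoxidation at pH 6.5",
           "uM/h", 0.08, 0.30, "eq", _autox_h2o2_rate(6.5)),
    Target("autox_max_dac_pH7.0",
           "Maximum aminochrome over 2 h from 20 uM dopamine without iron at "
           "pH 7.0 (upper bound)", "uM", 0.1, 0.0, "le", _max_dac),
    Target("tor_fold_50min_pH6.5",
           "Fold increase of the Fe turnover rate at t=50 min from 30 uM "
           "dopamine (5 uM Fe(II), 21% O2) at pH 6.5", "fold", 10.0, 0.30,
           "eq", _tor_fold(6.5)),
    Target("tor_fold_50min_pH7.0",
           "Same turnover-rate fold change at pH 7.0", "fold", 2.0, 0.30,
           "eq", _tor_fold(7.0)),
    Target("tor_fold_50min_pH7.4",
           "Same turnover-rate fold change at pH 7.4", "fold", 1.3, 0.30,
           "eq", _tor_fold(7.4)),
    Target("anoxic_bis_ratio_pH6.5_vs_7.0",
           "Fe(III)DA2 at 2 h under anoxia (5 uM Fe(III), 50 uM DA): pH 6.5 "
           "as percent of pH 7.0", "%", 60.0, 0.30, "eq", _anoxic_bis_ratio),
    Target("h2o2_ratio_FeIII_pH6.5_vs_7.4",
           "H2O2 at 2 h (20 uM DA + 5 uM Fe(III), 21% O2): pH 6.5 as percent "
           "of pH 7.4", "%", 10.0, 0.50, "eq", _h2o2_ph_ratio),
    Target("fe2_half_life_closed_pH7.0",
           "Half-life of 5 uM Fe(II) in an air-saturated closed system at "
           "pH 7.0, no dopamine", "h", 2.0, 0.30, "eq", _fe2_half_life),
    Target("fe2_95pct_oxidation_pH7.0",
           "Time for 5 uM Fe(II) to reach 95% oxidation with 10 uM dopamine "
           "at pH 7.0, 21% O2", "min", 70.0, 0.30, "eq", _fe2_depletion_time),
]}


def run_target(key: str, seed: int = 0) -> dict:
    """Recompute one registry entry; returns a result record."""
    if key not in REGISTRY:
        raise KeyError(f"unknown target {key!r}; known: {', '.join(REGISTRY)}")
    t = REGISTRY[key]
    value, n = t.compute(seed)
    record = {
        "target": key, "description": t.description, "units": t.units,
        "value": value, "reference": t.reference, "n": n, "cmp": t.cmp,
        "rel_tol": t.rel_tol, "passed": t.passed(value),
    }
    if t.cmp == "eq" and t.reference:
        record["rel_deviation"] = (value - t.reference) / abs(t.reference)
    return record


def run_all(seed: int = 0) -> list[dict]:
    return [run_target(key, seed) for key in REGISTRY]
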