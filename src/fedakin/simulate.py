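"""Stiff ODE integration of the reaction network with flux accounting.

A :class:`Scenario` fixes the initial state, pH, dissolved-oxygen mode and
duration; :func:`simulate` integrates the mass-action system and returns a
:class:`Trajectory` carrying per-species concentrations and per-reaction net
fluxes on a shared time grid.

Oxygen handling mirrors the bench setups being modelled: ``closed`` starts
from a chosen percent of air saturation and lets O2 evolve by reaction flux;
``clamped`` holds O2 at that level (continuous sparging); ``anoxic`` clamps
O2 at zero.  Air saturation at 22 degC in 0.1 M NaCl is taken as 2.5e-4 M
(configurable), and x% saturation scales linearly as (x/21) of that value.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .network import (SPECIES, FE_BUDGET, SKELETON_BUDGET, ReactionNetwork,
                      build_network, ConfigurationError)

__all__ = [
    "Scenario", "Trajectory", "IntegrationError",
    "simulate", "event_time", "reaction_flux_oracle", "oracle_rhs",
    "O2_AIR_SATURATION_M", "AIR_PERCENT",
]

#: Dissolved [O2] of an air-saturated solution (22 degC, 0.1 M NaCl), molar.
O2_AIR_SATURATION_M = 2.5e-4
#: O2 content of air, percent; the scenario field is expressed relative to this.
AIR_PERCENT = 21.0

_IDX = {s: i for i, s in enumerate(SPECIES)}

FE_SPECIES = tuple(s for s in SPECIES if FE_BUDGET.get(s, 0))
SKELETON_SPECIES = tuple(s for s in SPECIES if SKELETON_BUDGET.get(s, 0))


class IntegrationError(RuntimeError):
    """Solver failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass(frozen=True)
class Scenario:
    """A fully specified in silico experiment.

    Concentrations are molar and times are seconds throughout the model
    layer; the reporting layer (datasets, CLI) uses uM and minutes.
    """

    ph: float
    init: Mapping[str, float] = field(default_factory=dict)
    o2_mode: str = "clamped"            # closed | clamped | anoxic
    o2_percent_saturation: float = AIR_PERCENT
    o2_air_saturation_molar: float = O2_AIR_SATURATION_M
    clamps: frozenset[str] = frozenset()
    t_end: float = 7200.0
    overrides: Mapping | None = None
    disabled_reactions: frozenset[int] = frozenset()
    rtol: float = 1e-8
    atol: float = 1e-14
    max_step: float = np.inf
    sample_times: tuple[float, ...] = ()
    n_grid: int = 200

    def __post_init__(self):
        if self.o2_mode not in ("closed", "clamped", "anoxic"):
            raise ConfigurationError(f"unknown o2_mode {self.o2_mode!r}")
        if self.o2_percent_saturation < 0:
            raise ConfigurationError("o2_percent_saturation must be >= 0")
        for s, c in self.init.items():
            if s not in _IDX:
                raise ConfigurationError(f"unknown species {s!r} in init")
            if c < 0:
                raise ConfigurationError(f"negative initial [{s}] = {c}")
        for s in self.clamps:
            if s not in _IDX:
                raise ConfigurationError(f"unknown clamped species {s!r}")
        object.__setattr__(self, "clamps", frozenset(self.clamps))
        object.__setattr__(self, "disabled_reactions",
                           frozenset(self.disabled_reactions))
        object.__setattr__(self, "sample_times",
                           tuple(float(t) for t in self.sample_times))

    @property
    def o2_molar(self) -> float:
        if self.o2_mode == "anoxic":
            return 0.0
        return (self.o2_percent_saturation / AIR_PERCENT) * self.o2_air_saturation_molar

    def initial_state(self) -> np.ndarray:
        y0 = np.zeros(len(SPECIES))
        for s, c in self.init.items():
            y0[_IDX[s]] = c
        if "O2" not in self.init:
            y0[_IDX["O2"]] = self.o2_molar
        return y0

    def effective_clamps(self) -> frozenset[str]:
        clamps = set(self.clamps)
        if self.o2_mode in ("clamped", "anoxic"):
            clamps.add("O2")
        return frozenset(clamps)

    def with_overrides(self, extra: Mapping) -> "Scenario":
        merged = dict(self.overrides or {})
        merged.update(extra)
        return replace(self, overrides=merged)

    def to_dict(self) -> dict:
        return {
            "ph": self.ph, "init": dict(self.init), "o2_mode": self.o2_mode,
            "o2_percent_saturation": self.o2_percent_saturation,
            "o2_air_saturation_molar": self.o2_air_saturation_molar,
            "clamps": sorted(self.clamps), "t_end": self.t_end,
            "overrides": dict(self.overrides) if self.overrides else {},
            "disabled_reactions": sorted(self.disabled_reactions),
            "rtol": self.rtol, "atol": self.atol,
            "sample_times": list(self.sample_times),
        }

    @classmethod
    def from_dict(cls, doc: Mapping) -> "Scenario":
        doc = dict(doc)
        if "clamps" in doc:
            doc["clamps"] = frozenset(doc["clamps"])
        if "disabled_reactions" in doc:
            doc["disabled_reactions"] = frozenset(doc["disabled_reactions"])
        if "sample_times" in doc:
            doc["sample_times"] = tuple(doc["sample_times"])
        if "overrides" in doc and not doc["overrides"]:
            doc["overrides"] = None
        return cls(**doc)


class _CompiledNetwork:
    """Vectorized kinetics: directed processes with stoichiometry matrices."""

    def __init__(self, net: ReactionNetwork, disabled: frozenset[int],
                 clamps: frozenset[str]):
        self.net = net
        procs = []       # (reaction_id, direction, k, reactant_idx, stoich)
        n_sp = len(SPECIES)
        for r in net.reactions:
            if r.id in disabled:
                continue
            stoich = np.zeros(n_sp)
            for s in r.reactants:
                stoich[_IDX[s]] -= 1
            for s in r.products:
                stoich[_IDX[s]] += 1
            ridx = np.array([_IDX[s] for s in r.reactants], dtype=int)
            procs.append((r.id, "f", net.k_forward[r.id], ridx, stoich))
            if r.reversible:
                pidx = np.array([_IDX[s] for s in r.products], dtype=int)
                procs.append((r.id, "r", net.k_reverse[r.id], pidx, -stoich))
        self.proc_ids = [(rid, d) for rid, d, _, _, _ in procs]
        self.k = np.array([k for _, _, k, _, _ in procs])
        self.reactant_idx = [ridx for _, _, _, ridx, _ in procs]
        self.S = np.column_stack([st for _, _, _, _, st in procs])
        self.clamp_mask = np.zeros(n_sp, dtype=bool)
        for s in clamps:
            self.clamp_mask[_IDX[s]] = True
        # per-reaction signed projection: net flux(reaction) = fwd - rev
        self.reaction_ids = sorted({rid for rid, _ in self.proc_ids})

    def process_fluxes(self, y: np.ndarray) -> np.ndarray:
        yc = np.maximum(y, 0.0)
        v = self.k.copy()
        for j, ridx in enumerate(self.reactant_idx):
            for i in ridx:
                v[j] *= yc[i]
        return v

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        dy = self.S @ self.process_fluxes(y)
        dy[self.clamp_mask] = 0.0
        return dy

    def net_reaction_fluxes(self, y: np.ndarray) -> dict[int, float]:
        v = self.process_fluxes(y)
        out: dict[int, float] = {rid: 0.0 for rid in self.reaction_ids}
        for (rid, d), vj in zip(self.proc_ids, v):
            out[rid] += vj if d == "f" else -vj
        return out


@dataclass
class Trajectory:
    """Time-resolved solution: concentrations (M) and net fluxes (M/s)."""

    times: np.ndarray                 # seconds, shape (n,)
    conc: np.ndarray                  # molar, shape (n, n_species)
    fluxes: np.ndarray                # M/s, shape (n, 29); column j = reaction j+1
    scenario: Scenario
    flux_reaction_ids: tuple[int, ...]

    def __getitem__(self, species: str) -> np.ndarray:
        return self.conc[:, _IDX[species]]

    def flux(self, reaction_id: int) -> np.ndarray:
        try:
            j = self.flux_reaction_ids.index(reaction_id)
        except ValueError:
            raise KeyError(f"no flux recorded for reaction {reaction_id}") from None
        return self.fluxes[:, j]

    def at(self, species: str, t: float) -> float:
        return float(np.interp(t, self.times, self[species]))

    def flux_at(self, reaction_id: int, t: float) -> float:
        return float(np.interp(t, self.times, self.flux(reaction_id)))

    def fe_total(self) -> np.ndarray:
        return sum(self[s] for s in FE_SPECIES)

    def skeleton_total(self) -> np.ndarray:
        return sum(SKELETON_BUDGET[s] * self[s] for s in SKELETON_SPECIES)

    def to_frame(self):
        """Tidy concentrations: columns time_s, species, conc_M."""
        import pandas as pd
        n = len(self.times)
        return pd.DataFrame({
            "time_s": np.repeat(self.times, len(SPECIES)),
            "species": np.tile(SPECIES, n),
            "conc_M": self.conc.ravel(),
        })

    def flux_frame(self):
        """Tidy fluxes: columns time_s, reaction_id, flux_M_per_s."""
        import pandas as pd
        n = len(self.times)
        rids = np.array(self.flux_reaction_ids)
        return pd.DataFrame({
            "time_s": np.repeat(self.times, len(rids)),
            "reaction_id": np.tile(rids, n),
            "flux_M_per_s": self.fluxes.ravel(),
        })


def _time_grid(sc: Scenario) -> np.ndarray:
    t_end = float(sc.t_end)
    if t_end <= 0:
        raise ConfigurationError("t_end must be positive")
    t0 = min(1e-3, t_end / 1e6)
    grid = np.concatenate([[0.0],
                           np.geomspace(t0, t_end, sc.n_grid),
                           np.asarray(sc.sample_times, dtype=float)])
    grid = np.unique(grid[(grid >= 0) & (grid <= t_end)])
    return grid


def simulate(sc: Scenario) -> Trajectory:
    """Integrate the scenario's mass-action ODE system.

    Uses LSODA with the scenario's tolerances.  Clamped species have their
    net derivative zeroed (their sources and sinks still drive the other
    species), and their output series are forced exactly to the initial
    value.  Concentrations more negative than a small multiple of ``atol``
    raise :class:`IntegrationError`; shallower negatives are clipped to 0.
    """
    net = build_network(sc.ph, overrides=sc.overrides)
    compiled = _CompiledNetwork(net, sc.disabled_reactions, sc.effective_clamps())
    y0 = sc.initial_state()
    grid = _time_grid(sc)
    sol = solve_ivp(compiled.rhs, (0.0, sc.t_end), y0, method="LSODA",
                    t_eval=grid, rtol=sc.rtol, atol=sc.atol,
                    max_step=sc.max_step)
    if not sol.success:
        last = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"solver failed: {sol.message}", last_time=last)
    conc = sol.y.T.copy()
    neg_floor = -1e3 * sc.atol
    worst = conc.min(initial=0.0)
    if worst < neg_floor and worst < -1e-12:
        raise IntegrationError(
            f"negative concentration {worst:.3e} M beyond tolerance",
            last_time=float(sol.t[-1]))
    np.clip(conc, 0.0, None, out=conc)
    for s in sc.effective_clamps():
        conc[:, _IDX[s]] = y0[_IDX[s]]
    fluxes = np.empty((len(grid), len(compiled.reaction_ids)))
    for i in range(len(grid)):
        nf = compiled.net_reaction_fluxes(conc[i])
        fluxes[i] = [nf[rid] for rid in compiled.reaction_ids]
    return Trajectory(times=grid, conc=conc, fluxes=fluxes, scenario=sc,
                      flux_reaction_ids=tuple(compiled.reaction_ids))


def event_time(traj: Trajectory, species: str, level: float) -> float | None:
    """First time the species crosses ``level`` x its initial concentration.

    Linear interpolation between grid points; ``None`` if never crossed.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be strictly between 0 and 1")
    series = traj[species]
    c0 = series[0]
    if c0 <= 0:
        raise ValueError(f"{species} has zero initial concentration")
    target = level * c0
    # crossing downward from c0: first index at or below target
    idx = np.nonzero(series <= target)[0]
    if idx.size == 0:
        return None
    i = idx[0]
    if i == 0:
        return float(traj.times[0])
    t0, t1 = traj.times[i - 1], traj.times[i]
    c_prev, c_next = series[i - 1], series[i]
    if c_prev == c_next:
        return float(t1)
    frac = (c_prev - target) / (c_prev - c_next)
    return float(t0 + frac * (t1 - t0))


def reaction_flux_oracle(net: ReactionNetwork,
                         state: Mapping[str, float]) -> dict[tuple[int, str], float]:
    """Brute-force per-process fluxes, independent of the vectorized RHS.

    Returns ``{(reaction_id, 'f'|'r'): k * prod(reactant concentrations)}``
    computed reaction-by-reaction straight from the table.
    """
    out: dict[tuple[int, str], float] = {}
    for r in net.reactions:
        v = net.k_forward[r.id]
        for s in r.reactants:
            v *= max(float(state.get(s, 0.0)), 0.0)
        out[(r.id, "f")] = v
        if r.reversible:
            v = net.k_reverse[r.id]
            for s in r.products:
                v *= max(float(state.get(s, 0.0)), 0.0)
            out[(r.id, "r")] = v
    return out


def oracle_rhs(net: ReactionNetwork, state: Mapping[str, float]) -> dict[str, float]:
    """Stoichiometry-weighted sum of the oracle fluxes, species by species."""
    fluxes = reaction_flux_oracle(net, state)
    dy = {s: 0.0 for s in SPECIES}
    for r in net.reactions:
        vf = fluxes[(r.id, "f")]
        for s in r.reactants:
            dy[s] -= vf
        for s in r.products:
            dy[s] += vf
        if r.reversible:
            vr = fluxes[(r.id, "r")]
            for s in r.products:
                dy[s] -= vr
            for s in r.reactants:
                dy[s] += vr
    return dy
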