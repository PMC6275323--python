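"""Synthetic experimental datasets emulating the bench measurements.

Each dataset is a set of replicate, noisy observable time series (ferrozine
Fe(II), H2O2, aminochrome, Fe(III)DA2) generated by simulating a scenario,
reading the observables off the trajectory, and adding independent Gaussian
noise with sd = max(relative_sd * value, floor), truncated at zero because
assay readouts are non-negative.  Defaults: triplicate measurements every
10 min over 0-120 min, 5% relative noise with floors of 0.02 uM (H2O2, DAC)
and 0.05 uM (iron species).  The noise model is a declared synthetic
stand-in; the real assays' error structure is unpublished.

``bench_scenario`` catalogues the bench conditions being emulated
(figure-style names, e.g. ``fig1_pH7.0`` for 20 uM dopamine autoxidation).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .network import ConfigurationError, build_network
from .observables import OBSERVABLE_SPECIES, SpectralSystem, predict_observable
from .simulate import Scenario, simulate

__all__ = [
    "NoiseModel", "SyntheticDataset", "generate_dataset", "bench_scenario",
    "scenario_catalogue", "fixture_spectral_system", "DEFAULT_SAMPLE_TIMES_MIN",
]

DEFAULT_SAMPLE_TIMES_MIN: tuple[float, ...] = tuple(float(t) for t in range(0, 121, 10))

#: Default per-observable noise floors, uM.
DEFAULT_FLOORS_UM: dict[str, float] = {
    "H2O2": 0.02, "DAC": 0.02, "FeII_ferrozine": 0.05, "FeIIIDA2": 0.05,
}


def fixture_spectral_system() -> SpectralSystem:
    """Spectral system with synthetic fixture values for unpublished constants.

    The 475 nm absorptivity of Fe(III)DA2 (1500 per M cm) and the ferrozine
    coefficients (27900 / 1860 per M cm for the Fe(II)- and Fe(III)-derived
    signal) are synthetic fixtures for testing, not measured values; the
    measured aminochrome and 580 nm coefficients are the class defaults.
    """
    return SpectralSystem(
        eps_FeIIIDA2_475=1500.0,
        eps_FeIIFZ_562_fromFeII=27900.0,
        eps_FeIIFZ_562_fromFeIII=1860.0,
    )


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise: sd = max(relative_sd * value, floor)."""

    relative_sd: float = 0.05
    floors_uM: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FLOORS_UM))
    replicates: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.relative_sd < 0:
            raise ValueError("relative_sd must be >= 0")
        if any(v < 0 for v in self.floors_uM.values()):
            raise ValueError("noise floors must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    def floor(self, observable: str) -> float:
        return float(self.floors_uM.get(observable, 0.0))


@dataclass
class SyntheticDataset:
    """Replicate noisy observable series with their generating metadata.

    ``truth`` and ``replicates`` are tidy frames with columns
    ``time_min, observable, value, unit`` (plus ``replicate`` in the noisy
    frame); values are uM.  The metadata is sufficient to regenerate the
    dataset bit-exactly.
    """

    scenario: Scenario
    noise: NoiseModel
    observables: tuple[str, ...]
    sample_times_min: tuple[float, ...]
    truth: pd.DataFrame
    replicates: pd.DataFrame
    scenario_id: str = "scenario"

    def metadata(self) -> dict:
        net = build_network(self.scenario.ph, overrides=self.scenario.overrides)
        return {
            "scenario_id": self.scenario_id,
            "scenario": self.scenario.to_dict(),
            "noise": {
                "relative_sd": self.noise.relative_sd,
                "floors_uM": dict(self.noise.floors_uM),
                "replicates": self.noise.replicates,
                "seed": self.noise.seed,
            },
            "observables": list(self.observables),
            "sample_times_min": list(self.sample_times_min),
            "network_hash": net.content_hash(),
        }

    def to_csv(self, path: str | Path) -> None:
        """Write the replicate table plus a sidecar JSON next to it."""
        path = Path(path)
        out = self.replicates.copy()
        out.insert(0, "scenario_id", self.scenario_id)
        out.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps(self.metadata(), indent=1))

    @classmethod
    def regenerate(cls, metadata: Mapping) -> "SyntheticDataset":
        """Rebuild a dataset bit-exactly from its sidecar metadata."""
        sc = Scenario.from_dict(metadata["scenario"])
        nm = NoiseModel(**metadata["noise"])
        ds = generate_dataset(sc, metadata["observables"], nm,
                              metadata["sample_times_min"])
        ds.scenario_id = metadata.get("scenario_id", "scenario")
        return ds


def _check_observables_computable(sc: Scenario, observables: Sequence[str]) -> None:
    has_fe = any(sc.init.get(s, 0.0) > 0 for s in
                 ("FeII", "FeIII", "AFO", "FeIIDA", "FeIIIDA", "FeIIIDA2"))
    for name in observables:
        if name not in OBSERVABLE_SPECIES:
            raise ConfigurationError(f"unknown observable {name!r}")
        if name in ("FeII_ferrozine", "FeIIIDA2") and not has_fe:
            raise ConfigurationError(
                f"observable {name!r} requested for an iron-free scenario")


def generate_dataset(sc: Scenario, observables: Sequence[str],
                     noise: NoiseModel | None = None,
                     sample_times_min: Sequence[float] = DEFAULT_SAMPLE_TIMES_MIN,
                     ) -> SyntheticDataset:
    """Simulate a scenario and emit replicate noisy observable series.

    Noise draws are deterministic for a fixed ``noise.seed`` and are
    consumed in a fixed (observable, replicate, time) order, so regenerating
    from metadata is bit-identical.
    """
    noise = noise or NoiseModel()
    observables = tuple(observables)
    _check_observables_computable(sc, observables)
    times_min = tuple(float(t) for t in sample_times_min)
    times_s = np.array(times_min) * 60.0
    if times_s.max(initial=0.0) > sc.t_end:
        raise ConfigurationError("sample times extend beyond scenario t_end")
    sc_run = replace(sc, sample_times=tuple(times_s))
    traj = simulate(sc_run)

    rng = np.random.default_rng(noise.seed)
    truth_rows, rep_rows = [], []
    for name in observables:
        truth_uM = predict_observable(traj, name, times_s) * 1e6
        for t, v in zip(times_min, truth_uM):
            truth_rows.append((t, name, v, "uM"))
        for rep in range(1, noise.replicates + 1):
            sd = np.maximum(noise.relative_sd * truth_uM, noise.floor(name))
            noisy = truth_uM + rng.standard_normal(len(times_min)) * sd
            noisy = np.maximum(noisy, 0.0)
            for t, v in zip(times_min, noisy):
                rep_rows.append((rep, t, name, v, "uM"))
    truth = pd.DataFrame(truth_rows, columns=["time_min", "observable", "value", "unit"])
    reps = pd.DataFrame(rep_rows, columns=["replicate", "time_min", "observable",
                                           "value", "unit"])
    return SyntheticDataset(scenario=sc, noise=noise, observables=observables,
                            sample_times_min=times_min, truth=truth,
                            replicates=reps)


# --------------------------------------------------------------------------
# Scenario catalogue: the bench conditions the generator emulates.

def _autoxidation(ph: float) -> Scenario:
    return Scenario(ph=ph, init={"DA": 20e-6}, o2_mode="clamped",
                    o2_percent_saturation=21.0, t_end=7200.0)


def _fe_spike(ph: float, fe_species: str, fe: float, da: float,
              o2_mode: str = "clamped", o2_pct: float = 21.0) -> Scenario:
    init = {fe_species: fe}
    if da > 0:
        init["DA"] = da
    return Scenario(ph=ph, init=init, o2_mode=o2_mode,
                    o2_percent_saturation=o2_pct, t_end=7200.0)


def _catalogue() -> dict[str, Scenario]:
    cat: dict[str, Scenario] = {}
    for ph in (6.5, 7.0, 7.4):
        tag = f"pH{ph}"
        # 20 uM DA autoxidation, air-saturated (H2O2 and DAC readouts)
        cat[f"fig1_{tag}"] = _autoxidation(ph)
        # 20 uM DA + 5 uM Fe(II) or Fe(III), air-saturated
        cat[f"fig2A_{tag}"] = _fe_spike(ph, "FeII", 5e-6, 20e-6)
        cat[f"fig2B_{tag}"] = _fe_spike(ph, "FeIII", 5e-6, 20e-6)
        cat[f"fig3A_{tag}"] = _fe_spike(ph, "FeII", 5e-6, 20e-6)
        cat[f"fig3B_{tag}"] = _fe_spike(ph, "FeIII", 5e-6, 20e-6)
        # 5 uM Fe(II) + 10 uM DA, air-saturated (Fe(II) decay readout)
        cat[f"fig4A_{tag}"] = _fe_spike(ph, "FeII", 5e-6, 10e-6)
        # anoxic 5 uM Fe(III) + 50 uM DA (bis-complex formation)
        cat[f"fig4D_{tag}"] = _fe_spike(ph, "FeIII", 5e-6, 50e-6,
                                        o2_mode="anoxic", o2_pct=0.0)
        # 5 uM Fe(II) +/- 30 uM DA for turnover-rate readouts
        cat[f"fig5_{tag}_DA30"] = _fe_spike(ph, "FeII", 5e-6, 30e-6)
        cat[f"fig5_{tag}_DA0"] = _fe_spike(ph, "FeII", 5e-6, 0.0)
    # variable-O2 Fe(II) oxidation at pH 7.0
    for pct in (2.5, 5.0, 21.0):
        cat[f"fig4B_pH7.0_O2_{pct}"] = _fe_spike(7.0, "FeII", 5e-6, 10e-6,
                                                 o2_pct=pct)
        cat[f"fig4C_pH7.0_O2_{pct}"] = _fe_spike(7.0, "FeII", 5e-6, 10e-6,
                                                 o2_pct=pct)
    # clamped-species grid bases (50 uM DA held fixed at pH 7.0; open axes
    # are supplied to steady_state_grid)
    cat["fig6A"] = Scenario(ph=7.0, init={"FeII": 5e-6, "DA": 50e-6},
                            clamps=frozenset({"DA"}), o2_mode="clamped",
                            o2_percent_saturation=5.0, t_end=PSEUDO_HORIZON)
    for label, ph in (("fig6B", 6.5), ("fig6C", 6.5)):
        cat[label] = Scenario(ph=ph, init={"FeII": 5e-6}, o2_mode="clamped",
                              o2_percent_saturation=5.0, t_end=PSEUDO_HORIZON)
    return cat


PSEUDO_HORIZON = 24 * 3600.0


def scenario_catalogue() -> tuple[str, ...]:
    return tuple(sorted(_catalogue()))


def bench_scenario(name: str) -> Scenario:
    """Look up a catalogued bench scenario by its figure-style name."""
    cat = _catalogue()
    if name not in cat:
        raise ConfigurationError(
            f"unknown scenario {name!r}; catalogue: {', '.join(sorted(cat))}")
    return cat[name]
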