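"""Simulator behavior: closed forms, conservation, clamps, flux accounting."""

import numpy as np
import pytest

from fedakin.network import SPECIES, ConfigurationError, build_network
from fedakin.simulate import (O2_AIR_SATURATION_M, Scenario, Trajectory,
                              event_time, oracle_rhs, reaction_flux_oracle,
                              simulate)
from fedakin.synthdata import bench_scenario
from conftest import random_states

ALL_BUT_21 = frozenset(range(1, 30)) - {21}


def test_reaction_21_only_matches_exponential_closed_form():
    """With only Fe(II) oxygenation active and O2 clamped, decay is exact
    first-order: [FeII](t) = [FeII]0 * exp(-k21 [O2] t), half-life ~1 h at
    pH 7.4."""
    checkpoints = tuple(np.linspace(300, 7200, 10))
    sc = Scenario(ph=7.4, init={"FeII": 5e-6}, o2_mode="clamped",
                  disabled_reactions=ALL_BUT_21, t_end=7200.0,
                  sample_times=checkpoints)
    traj = simulate(sc)
    k = 0.77 * O2_AIR_SATURATION_M
    for t in checkpoints:
        expected = 5e-6 * np.exp(-k * t)
        assert traj.at("FeII", t) == pytest.approx(expected, rel=1e-6)
    t_half = event_time(traj, "FeII", 0.5)
    assert t_half == pytest.approx(np.log(2) / k, rel=1e-3)


def test_anoxic_dopamine_alone_is_inert():
    """Without O2 there is no reactant pair: every species stays constant."""
    sc = Scenario(ph=7.0, init={"DA": 20e-6}, o2_mode="anoxic",
                  o2_percent_saturation=0.0, t_end=7200.0)
    traj = simulate(sc)
    assert np.allclose(traj["DA"], 20e-6, rtol=1e-12)
    for s in SPECIES:
        if s != "DA":
            assert np.all(traj[s] == 0.0)


def test_clamped_species_series_bit_identical():
    sc = Scenario(ph=7.0, init={"FeII": 5e-6, "DA": 10e-6, "H2O2": 1e-7},
                  o2_mode="clamped", clamps=frozenset({"H2O2"}), t_end=3600.0)
    traj = simulate(sc)
    assert np.all(traj["H2O2"] == 1e-7)
    assert np.all(traj["O2"] == traj["O2"][0])


def test_closed_mode_o2_monotone_without_sources():
    """Disabling every O2-producing reaction, closed-mode O2 never rises."""
    o2_sources = frozenset({2, 7, 15, 18, 19})   # incl. reverse of 2
    sc = Scenario(ph=7.4, init={"DA": 20e-6, "FeII": 5e-6}, o2_mode="closed",
                  disabled_reactions=o2_sources, t_end=7200.0)
    traj = simulate(sc)
    o2 = traj["O2"]
    assert np.all(np.diff(o2) <= 1e-18)


@pytest.mark.parametrize("ph", [6.5, 7.0, 7.4])
def test_rhs_equals_flux_oracle_on_random_states(ph):
    """Vectorized RHS equals the stoichiometry-weighted brute-force fluxes
    at 1000 random non-negative states."""
    from fedakin.simulate import _CompiledNetwork
    net = build_network(ph)
    compiled = _CompiledNetwork(net, frozenset(), frozenset())
    rng = np.random.default_rng(int(ph * 10))
    for state in random_states(rng, 1000):
        y = np.array([state[s] for s in SPECIES])
        rhs = compiled.rhs(0.0, y)
        expected = oracle_rhs(net, state)
        fluxes = reaction_flux_oracle(net, state)
        scale = sum(abs(v) for v in fluxes.values()) + 1e-300
        for i, s in enumerate(SPECIES):
            assert abs(rhs[i] - expected[s]) <= 1e-12 * scale, s


@pytest.mark.parametrize("name", [
    "fig1_pH7.0", "fig2A_pH7.4", "fig2B_pH6.5", "fig4A_pH7.0", "fig4D_pH7.0",
    "fig5_pH6.5_DA30",
])
def test_fe_and_skeleton_conservation(name):
    """Elemental budgets drift by less than 10x the solver rtol on shipped
    scenarios (only O2 is ever clamped there)."""
    sc = bench_scenario(name)
    traj = simulate(sc)
    for total in (traj.fe_total(), traj.skeleton_total()):
        if np.max(total) == 0.0:
            continue
        drift = np.abs(total - total[0]) / total[0]
        assert np.max(drift) < 10 * sc.rtol


def test_flux_oracle_examples():
    net74 = build_network(7.4)
    zero = reaction_flux_oracle(net74, {})
    assert all(v == 0.0 for v in zero.values())
    fl = reaction_flux_oracle(net74, {"FeII": 1e-6, "O2": 1e-4})
    assert fl[(21, "f")] == pytest.approx(7.7e-11, rel=1e-12)
    fl = reaction_flux_oracle(net74, {"DAQ": 1e-6})
    assert fl[(4, "f")] == pytest.approx(4.45e-6, rel=1e-12)


def _toy_trajectory(times, series, species="FeII"):
    conc = np.zeros((len(times), len(SPECIES)))
    conc[:, SPECIES.index(species)] = series
    sc = Scenario(ph=7.0, init={species: series[0]}, t_end=float(times[-1]))
    return Trajectory(times=np.asarray(times, float), conc=conc,
                      fluxes=np.zeros((len(times), 29)), scenario=sc,
                      flux_reaction_ids=tuple(range(1, 30)))


def test_event_time_linear_interpolation():
    traj = _toy_trajectory([0.0, 10.0], [4e-6, 2e-6])
    assert event_time(traj, "FeII", 0.75) == pytest.approx(5.0)


def test_event_time_analytic_half_life():
    t = np.linspace(0, 5, 2001)
    traj = _toy_trajectory(t, 1e-6 * np.exp(-np.log(2) * t))
    assert event_time(traj, "FeII", 0.5) == pytest.approx(1.0, abs=1e-3)


def test_event_time_never_crossed_and_errors():
    traj = _toy_trajectory([0.0, 10.0], [4e-6, 4e-6])
    assert event_time(traj, "FeII", 0.5) is None
    zero = _toy_trajectory([0.0, 10.0], [0.0, 0.0])
    with pytest.raises(ValueError):
        event_time(zero, "FeII", 0.5)
    with pytest.raises(ValueError):
        event_time(traj, "FeII", 1.5)


def test_scenario_validation_errors():
    with pytest.raises(ConfigurationError):
        Scenario(ph=7.0, init={"DA": -1e-6})
    with pytest.raises(ConfigurationError):
        Scenario(ph=7.0, init={"Unobtainium": 1e-6})
    with pytest.raises(ConfigurationError):
        Scenario(ph=7.0, o2_mode="sparged")
    with pytest.raises(ConfigurationError):
        Scenario(ph=7.0, clamps=frozenset({"Xe"}))


def test_scenario_round_trip():
    sc = Scenario(ph=6.5, init={"FeIII": 5e-6, "DA": 50e-6}, o2_mode="anoxic",
                  o2_percent_saturation=0.0, clamps=frozenset({"DA"}),
                  t_end=1234.0, overrides={"13r": 2.0}, sample_times=(60.0,))
    assert Scenario.from_dict(sc.to_dict()) == sc


def test_o2_percent_scaling():
    sc = Scenario(ph=7.0, init={"FeII": 5e-6}, o2_mode="clamped",
                  o2_percent_saturation=5.0)
    assert sc.o2_molar == pytest.approx((5.0 / 21.0) * O2_AIR_SATURATION_M)
    anox = Scenario(ph=7.0, init={"FeII": 5e-6}, o2_mode="anoxic")
    assert anox.o2_molar == 0.0
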