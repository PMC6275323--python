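import numpy as np
import pytest

from fedakin.simulate import Scenario


@pytest.fixture
def fast_solver():
    """Looser solver settings for tests where speed beats precision."""
    return {"rtol": 1e-6, "atol": 1e-12}


@pytest.fixture
def fe_da_scenario(fast_solver):
    """5 uM Fe(II) + 10 uM dopamine at pH 7.0, air-saturated sparged."""
    return Scenario(ph=7.0, init={"FeII": 5e-6, "DA": 10e-6},
                    o2_mode="clamped", t_end=7200.0, **fast_solver)


def random_states(rng, n, scale=1e-5):
    """Random non-negative concentration maps over all species."""
    from fedakin.network import SPECIES
    states = []
    for _ in range(n):
        conc = rng.uniform(0.0, scale, size=len(SPECIES))
        conc[rng.uniform(size=len(SPECIES)) < 0.2] = 0.0   # exercise zeros
        states.append(dict(zip(SPECIES, conc)))
    return states
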