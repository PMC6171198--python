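import numpy as np
import pytest

import packscr as p


@pytest.fixture(scope="session")
def design_2015_coarse():
    """2015-like design with a 1.5-km fit mask (0.62 sigma at the nominal
    sigma of 2424 m) — the problem size used for simulation-heavy checks."""
    design = p.make_design("2015-like")
    mask = design.mask(1500.0)
    return design, design.traps(), mask


@pytest.fixture(scope="session")
def simulated_2015(design_2015_coarse):
    """One seeded study-like simulated survey plus its truth record."""
    design, traps, mask = design_2015_coarse
    scenario = p.study_scenario(seed=7, mask=mask)
    history, truth = p.simulate(scenario)
    return design, traps, mask, history, truth


def make_traps(coords, K=3, activity=None):
    act = np.ones(K, dtype=np.int8)
    traps = []
    for j, (x, y) in enumerate(coords):
        a = act.copy() if activity is None else np.asarray(activity[j])
        traps.append(p.TrapDeployment(f"T{j + 1}", float(x), float(y), a))
    return traps
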