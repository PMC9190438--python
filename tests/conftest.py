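import numpy as np
import pandas as pd
import pytest

from ketseq.diffexpr import run_de
from ketseq.simulate import SimulationDesign, make_profiles, simulate_experiment

NULL_MIX = {"induced": 0, "suppressed": 0, "rebound_up": 0, "rebound_down": 0, "null": 1.0}


def simulate_one(region="frontal_cortex", sex="male", n_genes=2000, seed=0, class_mix=None, **kw):
    """One-experiment simulation helper used across the suite."""
    design = SimulationDesign(experiments=((region, sex),), n_genes=n_genes, seed=seed, **kw)
    profiles = make_profiles(n_genes, seed=seed, class_mix=class_mix)
    cm, meta, truth = simulate_experiment(design, profiles)
    return cm, meta, truth


@pytest.fixture(scope="session")
def null_experiment():
    """Fully null male frontal cortex simulation plus its DE result."""
    cm, meta, truth = simulate_one(seed=11, class_mix=NULL_MIX)
    res = run_de(cm, "frontal_cortex", "male")
    return cm, truth, res


@pytest.fixture(scope="session")
def mixed_experiment():
    """Default class-mix male frontal cortex simulation plus DE result."""
    cm, meta, truth = simulate_one(seed=12)
    res = run_de(cm, "frontal_cortex", "male")
    return cm, truth.set_index("gene"), res


@pytest.fixture(scope="session")
def hippocampus_experiment():
    """Default class-mix male hippocampus simulation (has rebound genes)."""
    cm, meta, truth = simulate_one(region="hippocampus", n_genes=1000, seed=13)
    res = run_de(cm, "hippocampus", "male")
    return cm, truth.set_index("gene"), res
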