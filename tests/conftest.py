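import numpy as np
import pandas as pd
import pytest

from oatnp import synthdata


@pytest.fixture(scope="session")
def compound_pool():
    return synthdata.load_compound_pool()


@pytest.fixture(scope="session")
def noisefree_panel():
    """Deterministic panel: the four planted vitamin fold changes, no noise."""
    cfg = synthdata.SynthConfig(seed=11, noise_sigma=0.0, n_metabolites=300)
    return synthdata.generate_metabolome(cfg)


@pytest.fixture(scope="session")
def noisy_panel():
    """Default study conditions: 6 vs 6, sigma 0.3, 1000 metabolites."""
    cfg = synthdata.SynthConfig(seed=7)
    return synthdata.generate_metabolome(cfg)


@pytest.fixture(scope="session")
def separation_panel():
    """Panel with strong planted class structure: 50 effects at FC 2."""
    pool = synthdata.load_compound_pool()
    extra = [f"metabolite_{i:04d}" for i in range(50 - 4)]
    effects = tuple((m, 2.0) for m in ["biotin", "thiamine", "pyridoxal", "pyridoxamine"] + extra)
    cfg = synthdata.SynthConfig(seed=13, planted_effects=effects)
    return synthdata.generate_metabolome(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
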