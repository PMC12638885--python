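import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from metstab.synth import SynthConfig, generate_met, generate_multitrait_met

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_scale_met():
    """One balanced 30x6x6 MET at the published yield variance components."""
    cfg = SynthConfig(seed=42)
    data, truth = generate_met(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def toy_met():
    """Small 5x3x2 MET, cheap enough for brute-force oracles."""
    cfg = SynthConfig(
        G=5, E=3, R=2, mu=100.0, sigma2_g=25.0, sigma2_gei=9.0,
        sigma2_e=4.0, sigma2_env=16.0, sigma2_block=1.0, gei_rank=2, seed=3,
    )
    data, truth = generate_met(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def multitrait_met():
    """30x6x6 MET with six correlated traits (yield-like scale)."""
    corr = np.full((6, 6), 0.5)
    np.fill_diagonal(corr, 1.0)
    cfg = SynthConfig(
        n_traits=6,
        trait_cor=corr,
        trait_names=("DM", "NC", "NP", "NPC", "NS", "YD"),
        seed=11,
    )
    data, truth = generate_multitrait_met(cfg)
    return cfg, data, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
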