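import numpy as np
import pytest

from neurosig.simulate import SimulationConfig, generate_cohort


def zero_confounds():
    return {"age": 0.0, "sex": 0.0, "motion": 0.0, "site": 0.0}


def null_config(n_per_group, seed=0, **kw):
    """A cohort draw with no group effects, no latent factor, no confounding."""
    zeros = {}
    return SimulationConfig(
        n_per_group=n_per_group,
        effect_map={},
        latent_loadings=[],
        confound_coefficients=zero_confounds(),
        block_correlation=0.0,
        seed=seed,
        **kw,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Default-structure cohort at test scale, shared across tests."""
    cfg = SimulationConfig(
        n_per_group={"CTRL": 300, "MDD": 150, "ANX": 100, "MDDANX": 100, "STR": 100},
        seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
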