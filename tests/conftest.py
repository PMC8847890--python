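import warnings

import numpy as np
import pytest

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")

from cocoaferm import inference as inf  # noqa: E402
from cocoaferm import preprocessing as pp  # noqa: E402
from cocoaferm import synthetic_data as sd  # noqa: E402
from cocoaferm.model_core import build_variant  # noqa: E402


@pytest.fixture(scope="session")
def baseline_params():
    """Nominal baseline (MI(0)) parameter set on the scaled space."""
    variant = build_variant("MI(0)")
    return {n: sd.DEFAULT_TRUE_PARAMS[n] for n in variant.parameter_names}


@pytest.fixture(scope="session")
def full_params():
    """All 43 parameters (full model preset)."""
    return dict(sd.DEFAULT_TRUE_PARAMS)


@pytest.fixture(scope="session")
def init_state():
    return sd.DEFAULT_INITIAL_STATE.copy()


@pytest.fixture(scope="session")
def times17():
    return np.linspace(0.0, 160.0, 17)


@pytest.fixture(scope="session")
def synthetic_trial():
    """One synthetic baseline trial with its ground truth."""
    config = sd.GeneratorConfig(n_timepoints=17, noise_sd=0.03, seed=42, grid="uniform")
    dataset, truth = sd.generate_trial(config)
    return dataset, truth


@pytest.fixture(scope="session")
def quick_fit(synthetic_trial):
    """A short but real posterior fit, shared across tests that need one."""
    dataset, _ = synthetic_trial
    scaled = pp.max_scale(dataset)
    sampler = inf.SamplerConfig(chains=4, iterations=900, warmup=300, seed=3)
    return inf.fit("MI(0)", scaled, sampler=sampler)
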