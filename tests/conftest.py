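import warnings

import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from silac_ipac.ipac_classify import ClassifierConfig, classify_dataset
from silac_ipac.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def noisy_dataset():
    """Default study conditions: 2 resins x 2 orientations x 2 replicates,
    500 proteins, 4-fold planted enrichment, log2 noise 0.5."""
    config = SimulationConfig(seed=1)
    records, design, truth = simulate_dataset(config)
    return config, records, design, truth


@pytest.fixture(scope="session")
def noisy_verdicts(noisy_dataset):
    _, records, design, truth = noisy_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        verdicts, stats = classify_dataset(records, design, ClassifierConfig())
    return verdicts, stats, truth
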