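import pandas as pd
import pytest

from cilioprior.labels import LabelSet
from cilioprior.synthetic import SimulationConfig, simulate_screen


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=200, seed=11)


@pytest.fixture
def separable_config() -> SimulationConfig:
    return SimulationConfig(n_genes=400, effect_size=5.0, seed=3)


@pytest.fixture
def separable_screen(separable_config):
    reps, truth = simulate_screen(separable_config)
    return reps, truth


@pytest.fixture
def combined_features(separable_screen) -> tuple[pd.DataFrame, LabelSet]:
    reps, truth = separable_screen
    combined = pd.concat(
        [rep.add_prefix(f"rep{i}_") for i, rep in enumerate(reps, 1)], axis=1
    )
    return combined, truth
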