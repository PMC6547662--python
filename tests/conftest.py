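import numpy as np
import pytest

from foliarnirs.calibration import ExperimentConfig
from foliarnirs.preprocess import PreprocessRecipe
from foliarnirs.simulate import GeneratorParams, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20190604)


@pytest.fixture(scope="session")
def small_dataset():
    """60 synthetic foliar samples at default noise (session-cached)."""
    from dataclasses import replace

    params = replace(GeneratorParams(), n_samples=60)
    dataset, truth = generate_dataset(params, seed=7)
    return dataset, truth


@pytest.fixture(scope="session")
def fast_config():
    """Reduced recipe grid and k_max for quick workflow tests."""
    recipes = (
        PreprocessRecipe([]),
        PreprocessRecipe([("snv",)]),
        PreprocessRecipe([("snv",), ("sg_derivative", 11, 2, 1)]),
    )
    return ExperimentConfig(recipes=recipes, k_max=8, min_samples=20)
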