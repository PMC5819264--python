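import numpy as np
import pandas as pd
import pytest

import morphoscreen as ms


@pytest.fixture(scope="session")
def small_config():
    """A small but structurally complete synthetic screen."""
    return ms.SynthConfig(n_traits_mean=30, n_traits_cv=30, n_traits_ratio=10,
                          n_wt=30, n_mutants=120, n_latent_factors=10,
                          frac_holistic=0.15, frac_specific=0.2,
                          n_effect_modes=5, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return ms.generate_dataset(small_config)


@pytest.fixture(scope="session")
def small_detection(small_dataset):
    matrix, _ = small_dataset
    return ms.detect_effectors(matrix)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def toy_trait_matrix():
    """Hand-built 5-strain, 3-trait matrix (2 wild types)."""
    values = pd.DataFrame(
        {"size_mean": [4.0, 5.0, 6.0, 5.5, 4.5],
         "size_cv": [0.30, 0.25, 0.20, 0.22, 0.28],
         "bud_ratio": [0.40, 0.50, 0.45, 0.55, 0.35]},
        index=pd.Index(["wt1", "wt2", "wt3", "mutA", "mutB"], name="strain"))
    types = pd.Series({"size_mean": "mean", "size_cv": "cv",
                       "bud_ratio": "ratio"})
    is_wt = pd.Series([True, True, True, False, False], index=values.index)
    denom = pd.DataFrame({"bud_ratio": [20, 20, 20, 20, 20]},
                         index=values.index)
    return ms.TraitMatrix(values, types, is_wt, denom)
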