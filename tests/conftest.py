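import numpy as np
import pytest

from anatocog import generate_cohort, paper_like_config, run_subtyping


@pytest.fixture(scope="session")
def preset_cohort():
    """Strong-separation preset cohort: 81 PD + 20 controls, eight
    subtypes at the reference proportions, delta = 1.5."""
    return generate_cohort(paper_like_config(delta=1.5, seed=17))


@pytest.fixture(scope="session")
def preset_result(preset_cohort):
    """Full subtyping run on the preset cohort (constrained k-means,
    atypicality, validity metrics, 100 k-means++ stability restarts)."""
    return run_subtyping(preset_cohort, delta=1.5, seed=17, n_stability=100)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
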