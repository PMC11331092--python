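import numpy as np
import pandas as pd
import pytest

from swapmix.synth import GeneratorSpec, generate_session


@pytest.fixture(scope="session")
def tiny_session():
    """50-trial, 20-unit synthetic session with neural epochs."""
    spec = GeneratorSpec(n_sessions=1, trials_per_session=50, n_units=20, seed=0)
    return generate_session(spec, np.random.default_rng(0), 0)


@pytest.fixture(scope="session")
def small_session():
    """300-trial, 30-unit session for analyses needing more statistics."""
    spec = GeneratorSpec(n_sessions=1, trials_per_session=300, n_units=30, seed=1)
    return generate_session(spec, np.random.default_rng(1), 0)


def label_posteriors(truth) -> pd.DataFrame:
    """One-hot behavioral 'posteriors' from ground-truth labels (for tests
    that isolate neural components from behavioral-classification noise)."""
    lab = truth.type_labels
    return pd.DataFrame({
        "p_correct_post": (lab == "correct").astype(float),
        "p_swap_post": (lab == "swap").astype(float),
        "p_guess_post": (lab == "guess").astype(float),
    })
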