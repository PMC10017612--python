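import numpy as np
import pandas as pd
import pytest

from switcherr import (
    LatentParams,
    TrimConfig,
    classify_trials,
    generate_design,
    make_paradigm,
    simulate_dataset,
    trim_trials,
)


@pytest.fixture(scope="session")
def univalent():
    return make_paradigm("univalent")


@pytest.fixture(scope="session")
def bivalent():
    return make_paradigm("bivalent_congruency")


@pytest.fixture(scope="session")
def three_key():
    return make_paradigm("three_key")


@pytest.fixture(scope="session")
def all_paradigms(univalent, bivalent, three_key):
    return [univalent, bivalent, three_key]


def make_trials(
    paradigm,
    n_participants=2,
    n_blocks=4,
    block_length=60,
    T=0.9,
    R=0.9,
    seed=7,
    **kwargs,
):
    """Simulated, classified trial table for tests."""
    design = generate_design(paradigm, n_participants, n_blocks, block_length, seed)
    params = LatentParams(T=T, R=R, **kwargs)
    trials = simulate_dataset(design, paradigm, params, seed + 1)
    return classify_trials(trials, paradigm)


@pytest.fixture()
def trimmed_three_key(three_key):
    trials = make_trials(three_key, n_participants=3, n_blocks=6, block_length=60)
    return trim_trials(trials, TrimConfig())
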