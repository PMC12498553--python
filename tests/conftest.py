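"""Shared fixtures.

The expensive full-chain run (simulate -> preprocess -> train ->
latent -> classify at 30 samples per group) is computed once per session
and shared by the classification and permutation-null tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from cardiovae import (
    SimConfig,
    VAEConfig,
    classify_latent,
    extract_latent,
    generate_dataset,
    preprocess,
    train,
)


def full_chain(seed: int, n_per_group: int = 30) -> dict:
    """Simulate, preprocess, train and classify with one global seed."""
    data = generate_dataset(
        SimConfig(n_per_group=n_per_group, noise_cv=0.1, seed=seed)
    )
    pp = preprocess(data)
    params, trace = train(pp, VAEConfig(seed=seed))
    latent = extract_latent(pp, params)
    report = classify_latent(latent, pp.groups(), seed=seed)
    return {
        "data": data,
        "preprocessed": pp,
        "params": params,
        "trace": trace,
        "latent": latent,
        "groups": pp.groups(),
        "report": report,
    }


@pytest.fixture(scope="session")
def chain42() -> dict:
    return full_chain(42)


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(SimConfig(n_per_group=10, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
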