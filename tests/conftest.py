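"""Shared fixtures: packaged datasets, their MLE fits, and random parameter draws."""

from __future__ import annotations

import numpy as np
import pytest

from gmoee import ParamVector, datasets
from gmoee.estimation import fit_mle

DATASET_NAMES = (
    "aircon_boeing720",
    "nyc_ozone_1973",
    "wheaton_flood",
    "covid_recovery_m60",
)


def random_etas(n: int, seed: int, alpha_min: float = 0.05) -> list[ParamVector]:
    """Seeded random parameter vectors spread over the valid box."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(
            ParamVector(
                alpha=float(rng.uniform(alpha_min, 1.0)),
                lambda_=float(rng.uniform(0.05, 1.0)),
                theta=float(np.exp(rng.uniform(np.log(0.1), np.log(5.0)))),
                beta=float(np.exp(rng.uniform(np.log(0.2), np.log(10.0)))),
            )
        )
    return out


@pytest.fixture(scope="session")
def fixture_samples():
    return {name: datasets.load(name) for name in DATASET_NAMES}


@pytest.fixture(scope="session")
def fixture_mle_fits(fixture_samples):
    """Multi-start MLE fit of every packaged dataset (computed once)."""
    return {
        name: fit_mle(sample, starts=25, seed=0)
        for name, sample in fixture_samples.items()
    }
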