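import numpy as np
import pytest

from ginet.core_io import CovariateSet
from ginet.synth_data import generate_dataset


@pytest.fixture(scope="session")
def tiny_data():
    """Small coherent dataset: genotypes, transformed expression,
    covariates, annotation, truth (two injected trans edges)."""
    return generate_dataset("tiny", seed=11, counts=False)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def plain_covariates(n, seed=0, cohorts=("A", "B")):
    """Minimal covariate set: two cohorts, two sexes, random ages."""
    r = np.random.default_rng(seed)
    return CovariateSet(
        samples=[f"S{i:04d}" for i in range(n)],
        cohort=np.array([cohorts[i % len(cohorts)] for i in range(n)], dtype=object),
        sex=r.choice(["F", "M"], n).astype(object),
        age=r.normal(56, 14.8, n),
    )
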