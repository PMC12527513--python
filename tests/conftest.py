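import math

import numpy as np
import pytest

from marcplot import MetaDataset, StudyEffect

#: Intraclass correlation used throughout simulation-based tests: a
#: typical value for education achievement outcomes.
RHO = 0.2


def random_dataset(rng: np.random.Generator, k: int) -> MetaDataset:
    smd = rng.normal(0.15, 0.3, size=k)
    se = rng.uniform(0.02, 0.6, size=k)
    n = rng.integers(40, 2000, size=k)
    return MetaDataset(
        StudyEffect(f"S{i}", float(d), float(s), n_students=int(m))
        for i, (d, s, m) in enumerate(zip(smd, se, n))
    )


def brute_force_pool(dataset: MetaDataset, level: float = 0.95):
    """Independent pooling oracle: explicit loops at extended precision."""
    from scipy.stats import norm

    weights = [1.0 / (s.se * s.se) for s in dataset]
    sw = math.fsum(weights)
    swd = math.fsum(w * s.smd for w, s in zip(weights, dataset))
    est = swd / sw
    se = 1.0 / math.sqrt(sw)
    z = norm.ppf(1 - (1 - level) / 2)
    return est, se, est - z * se, est + z * se


@pytest.fixture
def two_studies() -> MetaDataset:
    return MetaDataset([StudyEffect("A", 0.1, 0.1), StudyEffect("B", 0.3, 0.2)])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
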