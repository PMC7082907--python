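"""Shared fixtures: small deterministic datasets and random-data helpers."""

from __future__ import annotations

import numpy as np
import pytest

import twistest as tw


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20200320)


def random_survival_dataset(
    rng: np.random.Generator,
    n: int = 40,
    *,
    n_groups: int = 2,
    preimmune: float = 0.0,
    censor: float = 0.3,
) -> tw.Dataset:
    """A random dataset with continuous (tie-free) times.

    Genotypes are uniform over ``n_groups`` allele counts; times are
    exponential and independent of genotype, censoring uniform.
    """
    counts = rng.integers(0, n_groups, size=n)
    z = (rng.random(n) < preimmune).astype(int)
    t = rng.exponential(1.0, size=n)
    c = rng.uniform(0, 1.0 / max(censor, 1e-9), size=n) if censor > 0 else np.full(n, np.inf)
    x = np.where(z == 1, 0.0, np.minimum(t, c))
    d = np.where(z == 1, 1, (t <= c).astype(int))
    # guarantee at least one event and at least two groups among Z=0
    if d[z == 0].sum() == 0 or np.unique(counts[z == 0]).size < 2:
        return random_survival_dataset(rng, n, n_groups=n_groups, preimmune=preimmune, censor=censor)
    return tw.dataset_from_arrays(x, d, z, counts)


@pytest.fixture
def toy_dataset() -> tw.Dataset:
    """Six subjects: two pre-immune, three events, one censored."""
    return tw.dataset_from_arrays(
        time=[0.0, 0.0, 1.0, 2.0, 3.0, 2.5],
        event=[1, 1, 1, 1, 1, 0],
        pre_immune=[1, 1, 0, 0, 0, 0],
        allele_count=[1, 2, 0, 1, 2, 0],
    )
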