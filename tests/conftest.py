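"""Shared fixtures and independent brute-force oracles.

The enumeration oracle for the pairwise overlap distribution counts, over
all C(N, n1) x C(N, n2) placements of two taxa's host sets, how often each
overlap arises — independent of any closed-form distribution used by the
implementation.
"""

from collections import Counter
from itertools import combinations

import numpy as np
import pandas as pd
import pytest


def enumerate_overlap_pmf(N: int, n1: int, n2: int) -> dict[int, float]:
    """Exact overlap distribution by exhaustive enumeration of site-set placements."""
    counts: Counter = Counter()
    for a in combinations(range(N), n1):
        sa = set(a)
        for b in combinations(range(N), n2):
            counts[len(sa & set(b))] += 1
    total = sum(counts.values())
    return {j: c / total for j, c in counts.items()}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_presence(rng):
    """27 hosts x 10 taxa random presence matrix with no structure."""
    hosts = [f"h{i}" for i in range(27)]
    taxa = [f"t{i}" for i in range(10)]
    mat = rng.random((27, 10)) < rng.uniform(0.2, 0.8, 10)
    return pd.DataFrame(mat, index=hosts, columns=taxa)


@pytest.fixture(scope="session")
def planted_dataset():
    """One synthetic dataset with a single strongly coupled planted cohort:
    8 rare OTUs whose presence odds are multiplied 500-fold in
    covariate-positive hosts, so they cooccur almost deterministically."""
    from cooclust.simulate import PlantedCohort, SimParams, generate_dataset

    params = SimParams(
        n_hosts=27,
        n_otus=300,
        n_covariates=6,
        n_functions=120,
        n_categories=12,
        seed=4,
        cohorts=(
            PlantedCohort(
                covariate=0, members=tuple(range(8)), effect=500.0,
                member_prevalence=0.03,
            ),
        ),
    )
    counts, covs, ann, fm, truth = generate_dataset(params)
    return {
        "params": params, "counts": counts, "covariates": covs,
        "annotation": ann, "functions": fm, "truth": truth,
    }
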