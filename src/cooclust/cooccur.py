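"""Exact probabilistic pairwise cooccurrence analysis of presence-absence matrices.

Given N hosts (sites) and a pair of taxa with occupancies n1 and n2, the
number of hosts containing both — conditional on the marginals and assuming
independent placement — follows the hypergeometric law

    P(j) = C(n2, j) C(N - n2, n1 - j) / C(N, n1),

supported on max(0, n1 + n2 - N) <= j <= min(n1, n2).  Both tail
probabilities are inclusive of the observed overlap, so p_lt + p_gt =
1 + P(obs); the expected overlap is n1 * n2 / N.  Because the distribution
is discrete, attainable p-values are coarse at small N, which is why
analyses at a few dozen sites use permissive cutoffs such as .01 rather
than a Bonferroni-corrected threshold.

The null for dataset-level counts of significant pairs is an
occupancy-preserving randomization: each taxon's presences are reassigned
to a uniform random host subset of the same size (column marginals kept,
row richness free).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "PairResult",
    "overlap_pmf",
    "pair_test",
    "all_pairs",
    "classify_pairs",
    "randomize_presence",
    "null_significant_counts",
    "bonferroni",
    "write_pairs",
]

PAIR_COLUMNS = [
    "taxon_a", "taxon_b", "n1", "n2", "obs",
    "expected", "p_lt", "p_gt", "pct_dev",
]


@dataclass(frozen=True)
class PairResult:
    """Cooccurrence statistics for one unordered taxon pair.

    ``p_lt``/``p_gt`` are the probabilities of an overlap <= / >= the
    observed one under the hypergeometric model; both include the observed
    point mass.  ``pct_dev`` is 100 * (obs - expected) / expected, the
    percent deviation of observed from expected cooccurrence.
    """

    taxon_a: str
    taxon_b: str
    N: int
    n1: int
    n2: int
    obs: int
    expected: float
    p_lt: float
    p_gt: float
    pct_dev: float


def overlap_pmf(N: int, n1: int, n2: int) -> np.ndarray:
    """Probability mass of the pairwise overlap, indexed by overlap j = 0..min(n1, n2).

    Entries outside the support max(0, n1 + n2 - N)..min(n1, n2) are zero.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if not (0 <= n1 <= N and 0 <= n2 <= N):
        raise ValueError(f"occupancies must lie in [0, N]; got n1={n1}, n2={n2}, N={N}")
    j = np.arange(min(n1, n2) + 1)
    return hypergeom.pmf(j, N, n1, n2)


def pair_test(pres: pd.DataFrame, a: str, b: str) -> PairResult:
    """Exact cooccurrence test for taxa *a* and *b* in a presence matrix."""
    if a == b:
        raise ValueError("pair_test requires two distinct taxa")
    for t in (a, b):
        if t not in pres.columns:
            raise KeyError(f"taxon {t!r} not in presence matrix")
    va = pres[a].to_numpy(dtype=bool)
    vb = pres[b].to_numpy(dtype=bool)
    N = len(va)
    n1, n2 = int(va.sum()), int(vb.sum())
    obs = int((va & vb).sum())
    expected = n1 * n2 / N
    # canonical marginal order keeps the result bit-identical under (a, b) swap
    k1, k2 = sorted((n1, n2))
    p_lt = float(hypergeom.cdf(obs, N, k1, k2))
    p_gt = float(hypergeom.sf(obs - 1, N, k1, k2))
    pct_dev = 100.0 * (obs - expected) / expected if expected > 0 else np.nan
    return PairResult(a, b, N, n1, n2, obs, expected, p_lt, p_gt, pct_dev)


def all_pairs(pres: pd.DataFrame, expected_min: float | None = 1.0) -> pd.DataFrame:
    """Cooccurrence statistics for every unordered taxon pair.

    Pairs whose expected overlap n1*n2/N falls below *expected_min* are
    excluded when it is set (default 1.0, matching the conventional filter
    that makes reported pair universes smaller than C(T, 2)).  Pass ``None``
    to keep all pairs.
    """
    if pres.shape[1] < 2:
        raise ValueError("need at least two taxa")
    X = pres.to_numpy(dtype=np.int64)
    N = X.shape[0]
    occ = X.sum(axis=0)
    overlap = X.T @ X
    iu, ju = np.triu_indices(X.shape[1], k=1)
    n1, n2, obs = occ[iu], occ[ju], overlap[iu, ju]
    expected = n1 * n2 / N
    if expected_min is not None:
        keep = expected >= expected_min
        iu, ju, n1, n2, obs, expected = (
            a[keep] for a in (iu, ju, n1, n2, obs, expected)
        )
    k1, k2 = np.minimum(n1, n2), np.maximum(n1, n2)
    p_lt = hypergeom.cdf(obs, N, k1, k2)
    p_gt = hypergeom.sf(obs - 1, N, k1, k2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct_dev = np.where(expected > 0, 100.0 * (obs - expected) / expected, np.nan)
    taxa = pres.columns.to_numpy()
    tbl = pd.DataFrame(
        {
            "taxon_a": taxa[iu],
            "taxon_b": taxa[ju],
            "n1": n1,
            "n2": n2,
            "obs": obs,
            "expected": expected,
            "p_lt": p_lt,
            "p_gt": p_gt,
            "pct_dev": pct_dev,
        }
    )
    tbl.attrs["n_hosts"] = N
    return tbl


def classify_pairs(tbl: pd.DataFrame, alpha: float = 0.01) -> pd.DataFrame:
    """Label each pair positive (p_gt <= alpha), negative (p_lt <= alpha), or random.

    The comparison is inclusive (<= alpha) because the p-values are discrete.
    At alpha < 0.5 a pair can satisfy at most one direction.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    out = tbl.copy()
    label = np.full(len(tbl), "random", dtype=object)
    label[tbl["p_lt"].to_numpy() <= alpha] = "negative"
    label[tbl["p_gt"].to_numpy() <= alpha] = "positive"
    out["label"] = label
    out.attrs.update(tbl.attrs)
    out.attrs["alpha"] = alpha
    return out


def randomize_presence(pres: pd.DataFrame, seed: int | None = None) -> pd.DataFrame:
    """Occupancy-preserving randomization: reassign each taxon's presences
    to a uniform random subset of hosts of the same size.

    Per-taxon occupancy is conserved exactly; per-host richness is not.
    """
    rng = np.random.default_rng(seed)
    X = pres.to_numpy(dtype=bool)
    n_hosts = X.shape[0]
    out = np.zeros_like(X)
    for t in range(X.shape[1]):
        k = int(X[:, t].sum())
        out[rng.choice(n_hosts, size=k, replace=False), t] = True
    return pd.DataFrame(out, index=pres.index, columns=pres.columns)


def null_significant_counts(
    pres: pd.DataFrame,
    alpha: float = 0.01,
    reps: int = 5,
    seed: int | None = None,
    expected_min: float | None = 1.0,
) -> pd.DataFrame:
    """Counts of significant pairs expected under occupancy-preserving randomization.

    Randomizes the matrix *reps* times, reruns the full pairwise analysis on
    each, and returns one row per replicate (``n_positive``, ``n_negative``)
    with the min/max range in ``attrs['range']``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    seeds = np.random.SeedSequence(seed).generate_state(reps)
    rows = []
    for r in range(reps):
        rand = randomize_presence(pres, seed=int(seeds[r]))
        lab = classify_pairs(all_pairs(rand, expected_min=expected_min), alpha)["label"]
        rows.append(
            {"rep": r, "n_positive": int((lab == "positive").sum()),
             "n_negative": int((lab == "negative").sum())}
        )
    out = pd.DataFrame(rows).set_index("rep")
    out.attrs["range"] = {
        "n_positive": (int(out["n_positive"].min()), int(out["n_positive"].max())),
        "n_negative": (int(out["n_negative"].min()), int(out["n_negative"].max())),
    }
    return out


def bonferroni(alpha: float, m: int) -> float:
    """Bonferroni-corrected per-comparison threshold: alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / m


def write_pairs(tbl: pd.DataFrame, path) -> None:
    tbl.to_csv(path, sep="\t", index=False)
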