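"""Functional clustering of cooccurring OTU cohorts.

A *cohort* is the set of bacterial OTUs that cooccur significantly (in
either direction) with a given covariate — a eukaryotic microbe, a diet
item, or a host species.  A covariate qualifies only when at least two
OTUs reach the stricter selection threshold; its cohort then contains
every OTU reaching the (possibly looser) membership threshold.

Within each ontology category's function space the cohort is summarized by
two statistics computed purely from pairwise distances:

* mean nearest-neighbor distance (MNN) — the average, over members, of the
  distance to the closest fellow member; small values mean tight clustering;
* centroid displacement — the distance between the cohort centroid and the
  centroid of all OTUs, obtained from pairwise distances alone via

      |c_A - c_B|^2 = mean_{a,b} d^2(a,b)
                      - 1/2 mean_{a,a'} d^2(a,a') - 1/2 mean_{b,b'} d^2(b,b'),

  the means running over all ordered pairs including self-pairs.  For
  Euclidean-embeddable distances this equals the direct centroid distance;
  for non-Euclidean input the squared value can dip below zero, in which
  case it is clamped to 0 and flagged.

Both statistics are referred to a null of uniform random subsets of the
same size drawn from the OTUs present in that category's function space
(5,000 draws by default): the reported fractions are the proportions of
draws with smaller MNN / smaller displacement than observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Cohort",
    "NullResult",
    "select_cohorts",
    "mean_nearest_neighbor",
    "centroid_displacement",
    "null_percentiles",
    "cohort_report",
    "plot_cohort_summary",
]


@dataclass(frozen=True)
class Cohort:
    """Bacterial OTUs significantly cooccurring with one covariate."""

    covariate: str
    members: frozenset
    direction: str = "pooled"       # positive | negative | pooled
    alpha_member: float = 0.05


@dataclass(frozen=True)
class NullResult:
    """Null-distribution comparison for one observed (MNN, displacement) pair.

    ``frac_tighter``: fraction of random subsets with smaller MNN than
    observed (small values mean the cohort is unusually clustered).
    ``frac_less_displaced``: fraction with smaller centroid displacement.
    """

    frac_tighter: float
    frac_less_displaced: float
    reps: int
    null_mnn: np.ndarray
    null_displacement: np.ndarray


def select_cohorts(
    pairs: pd.DataFrame,
    covariates: list[str],
    bacteria: list[str],
    alpha_select: float = 0.01,
    alpha_member: float = 0.05,
    direction: str = "pooled",
) -> list[Cohort]:
    """Identify covariates with >= 2 significantly cooccurring bacterial OTUs.

    A covariate is included iff at least two bacterial OTUs cooccur with it
    at *alpha_select*; its cohort then contains every bacterial OTU reaching
    *alpha_member*.  ``direction`` pools greater- and less-than-expected
    partners by default; ``positive``/``negative`` restrict to one tail.
    Covariates with a single interacting OTU are excluded because a
    one-member set has no clustering statistic.
    """
    for a in (alpha_select, alpha_member):
        if not 0 < a < 1:
            raise ValueError("significance thresholds must lie in (0, 1)")
    if direction not in ("pooled", "positive", "negative"):
        raise ValueError(f"unknown direction {direction!r}")
    bact = set(bacteria)
    cohorts = []
    for cov in covariates:
        mask = (pairs["taxon_a"] == cov) | (pairs["taxon_b"] == cov)
        sub = pairs.loc[mask]
        partner = np.where(sub["taxon_a"] == cov, sub["taxon_b"], sub["taxon_a"])
        is_bact = np.fromiter(
            (p in bact for p in partner), dtype=bool, count=len(partner)
        )
        if direction == "positive":
            sig = sub["p_gt"].to_numpy()
        elif direction == "negative":
            sig = sub["p_lt"].to_numpy()
        else:
            sig = np.minimum(sub["p_gt"].to_numpy(), sub["p_lt"].to_numpy())
        if int((is_bact & (sig <= alpha_select)).sum()) < 2:
            continue
        members = frozenset(partner[is_bact & (sig <= alpha_member)])
        cohorts.append(Cohort(cov, members, direction, alpha_member))
    return cohorts


def mean_nearest_neighbor(dm: pd.DataFrame, subset) -> float:
    """Mean over subset members of the distance to their nearest fellow member.

    Members whose distances to every other member are undefined (NaN) are
    excluded with a warning.
    """
    ids = list(subset)
    if len(ids) < 2:
        raise ValueError("mean nearest-neighbor distance needs >= 2 members")
    D = dm.loc[ids, ids].to_numpy(copy=True)
    np.fill_diagonal(D, np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mins = np.nanmin(D, axis=1)
    bad = np.isnan(mins)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} members have no defined distance to any other member",
            stacklevel=2,
        )
        mins = mins[~bad]
    return float(mins.mean())


def _displacement_sq(D2: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> float:
    cross = D2[np.ix_(idx_a, idx_b)].mean()
    within_a = D2[np.ix_(idx_a, idx_a)].mean()
    within_b = D2[np.ix_(idx_b, idx_b)].mean()
    return float(cross - 0.5 * within_a - 0.5 * within_b)


def centroid_displacement(
    dm: pd.DataFrame, subset, background, return_clamped: bool = False
):
    """Distance between the subset centroid and the background centroid,
    computed from pairwise distances alone.

    *background* should contain every OTU in the relevant function space
    (a superset of *subset*).  Negative squared displacements — possible
    for non-Euclidean dissimilarities such as Bray-Curtis — are clamped to
    zero; pass ``return_clamped=True`` to also receive the clamping flag.
    """
    sub = list(subset)
    bg = list(background)
    if not sub:
        raise ValueError("subset must be non-empty")
    D = dm.loc[bg, bg].to_numpy()
    pos = {o: i for i, o in enumerate(bg)}
    idx_a = np.array([pos[o] for o in sub])
    idx_b = np.arange(len(bg))
    sq = _displacement_sq(D**2, idx_a, idx_b)
    clamped = sq < 0
    value = float(np.sqrt(max(sq, 0.0)))
    return (value, clamped) if return_clamped else value


def null_percentiles(
    dm: pd.DataFrame,
    subset_size: int,
    background,
    reps: int = 5000,
    seed: int | None = None,
    observed_mnn: float | None = None,
    observed_displacement: float | None = None,
) -> NullResult:
    """Null distributions of MNN and displacement for random subsets.

    Draws *reps* uniform subsets of *subset_size* OTUs without replacement
    from *background*, recomputes both statistics for each, and returns the
    fractions of draws with strictly smaller MNN / displacement than the
    observed values (NaN fractions when no observed value is supplied).
    Deterministic given *seed*.
    """
    if reps < 100:
        raise ValueError("reps must be >= 100")
    bg = list(background)
    if subset_size > len(bg):
        raise ValueError("subset_size exceeds background size")
    rng = np.random.default_rng(seed)
    D = dm.loc[bg, bg].to_numpy()
    D2 = D**2
    # cross-term to the full background is a per-row constant: precompute
    row_mean_sq = np.nanmean(D2, axis=1)
    bg_mean_sq = float(np.nanmean(D2))
    null_mnn = np.empty(reps)
    null_disp = np.empty(reps)
    n = len(bg)
    big = np.nanmax(D) * 2 + 1 if np.isfinite(np.nanmax(D)) else 1.0
    for r in range(reps):
        idx = rng.choice(n, size=subset_size, replace=False)
        sub = D[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, big)
        null_mnn[r] = np.nanmin(sub, axis=1).mean()
        sq = row_mean_sq[idx].mean() - 0.5 * D2[np.ix_(idx, idx)].mean() - 0.5 * bg_mean_sq
        null_disp[r] = np.sqrt(max(sq, 0.0))
    frac_tighter = (
        float((null_mnn < observed_mnn).mean()) if observed_mnn is not None else np.nan
    )
    frac_less = (
        float((null_disp < observed_displacement).mean())
        if observed_displacement is not None
        else np.nan
    )
    return NullResult(frac_tighter, frac_less, reps, null_mnn, null_disp)


def cohort_report(
    cohorts: list[Cohort],
    category_distances: dict[str, pd.DataFrame],
    reps: int = 5000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Clustering statistics for every cohort in every category's function space.

    *category_distances* maps category label to that category's OTU distance
    matrix (see :func:`cooclust.function_space.bray_curtis` applied per
    category).  For each cohort x category cell the members are restricted
    to OTUs with defined profiles in that space; cells with < 2 usable
    members are dropped with a note in the ``status`` column of the log.

    Fractions of exactly zero are reported as 1/reps with
    ``below_resolution = True`` so log-scale displays stay finite.
    """
    seeds = np.random.SeedSequence(seed).generate_state(
        max(1, len(cohorts) * max(1, len(category_distances)))
    )
    rows = []
    k = 0
    for cohort in cohorts:
        for cat, dm in category_distances.items():
            rep_seed = int(seeds[k % len(seeds)])
            k += 1
            # OTUs with a defined (non-NaN off-diagonal) row in this space
            M = dm.to_numpy().copy()
            np.fill_diagonal(M, np.nan)
            defined = dm.index[~np.all(np.isnan(M), axis=1)]
            background = list(defined)
            members = [o for o in cohort.members if o in set(background)]
            if len(members) < 2:
                rows.append(
                    {"covariate": cohort.covariate, "category": cat,
                     "n_members": len(members), "status": "dropped: <2 members in space"}
                )
                continue
            mnn = mean_nearest_neighbor(dm, members)
            disp, clamped = centroid_displacement(
                dm, members, background, return_clamped=True
            )
            null = null_percentiles(
                dm, len(members), background, reps=reps, seed=rep_seed,
                observed_mnn=mnn, observed_displacement=disp,
            )
            rows.append(
                {
                    "covariate": cohort.covariate,
                    "category": cat,
                    "n_members": len(members),
                    "mnn": mnn,
                    "displacement": disp,
                    "displacement_clamped": clamped,
                    "frac_tighter": max(null.frac_tighter, 1.0 / reps),
                    "frac_less_displaced": max(null.frac_less_displaced, 1.0 / reps),
                    "below_resolution": null.frac_tighter == 0.0
                    or null.frac_less_displaced == 0.0,
                    "reps": reps,
                    "status": "ok",
                }
            )
    return pd.DataFrame(rows)


def plot_cohort_summary(report: pd.DataFrame, path) -> None:
    """Summary figure: one point per cohort x category, sized by MNN and
    colored by the log-scale fraction of random draws that were tighter."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ok = report[report["status"] == "ok"]
    if ok.empty:
        raise ValueError("nothing to plot: no cohort passed the reporting filters")
    cats = {c: i for i, c in enumerate(sorted(ok["category"].unique()))}
    covs = {c: i for i, c in enumerate(sorted(ok["covariate"].unique()))}
    fig, ax = plt.subplots(figsize=(1.2 * len(cats) + 3, 0.6 * len(covs) + 2))
    sc = ax.scatter(
        [cats[c] for c in ok["category"]],
        [covs[c] for c in ok["covariate"]],
        s=40 + 400 * ok["mnn"],
        c=np.log10(ok["frac_tighter"]),
        cmap="viridis",
    )
    ax.set_xticks(list(cats.values()), list(cats.keys()), rotation=45, ha="right")
    ax.set_yticks(list(covs.values()), list(covs.keys()))
    fig.colorbar(sc, ax=ax, label="log10 fraction of random subsets tighter")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
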