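"""Synthetic gut-microbiome datasets with planted, recoverable structure.

The generator emulates the shape of a small-host-cohort amplicon study:
a few dozen hosts from two host-species groups, hundreds to a thousand
bacterial OTUs with strongly skewed occupancy, binary eukaryote/diet
covariates, and an OTU-by-function binary matrix under a two-level
ontology.  *Planted cohorts* give the data recoverable structure: a chosen
set of OTUs has its presence odds multiplied in covariate-positive hosts
(planting positive or negative cooccurrence with that covariate) and shares
a core of functions within one ontology category (planting functional
clustering).

Generative choices, all exposed as parameters:

* per-OTU prevalence ~ Beta(a, b), default (0.7, 4): most OTUs rare, a few
  widespread — the many-rare-OTU shape typical of 16S surveys;
* presence per host is Bernoulli(prevalence); cohort members' odds are
  multiplied by ``effect`` in covariate-positive hosts, then clamped to
  [0.01, 0.99] (with a warning) so every occupancy outcome stays possible;
* sequencing depth per host ~ Poisson(mean_depth); counts of present OTUs
  are 1 + a multinomial allocation of the remaining depth with lognormal
  relative-abundance weights, giving realistic rarefaction behavior while
  guaranteeing presence == (count > 0);
* covariates are independent Bernoulli(0.5) per host;
* every OTU carries each non-core function with probability
  ``p_background``; cohort members carry each of their core functions with
  probability ``p_core``.

Everything is deterministic given ``seed``.  The generator also emits a
taxon annotation table (OTUs assigned to phyla and families, covariates
tagged by domain) and a truth record of all planted memberships.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .function_space import FunctionMatrix, write_function_matrix
from .community import write_annotation, write_community

__all__ = ["PlantedCohort", "SimParams", "generate_dataset", "write_dataset"]

PHYLA = ["Proteobacteria", "Firmicutes", "Bacteroidetes", "Actinobacteria"]


@dataclass(frozen=True)
class PlantedCohort:
    """A planted set of OTUs tied to one covariate and one function category.

    ``effect`` multiplies each member's presence odds in covariate-positive
    hosts (> 1 plants positive cooccurrence, < 1 negative).  Members carry
    each of ``n_core_functions`` core functions (drawn within ``category``)
    with probability ``p_core``.  ``member_prevalence``, when set, overrides
    the Beta-drawn baseline prevalence of members so that planted signal is
    not erased by members happening to be vanishingly rare.
    """

    covariate: int
    members: tuple[int, ...]
    effect: float = 8.0
    category: int = 0
    n_core_functions: int = 8
    p_core: float = 0.9
    member_prevalence: float | None = 0.2

    def validate(self, params: "SimParams") -> None:
        if len(self.members) < 2:
            raise ValueError("a planted cohort needs >= 2 member OTUs")
        if self.effect <= 0:
            raise ValueError(
                f"cohort on covariate {self.covariate}: effect must be > 0"
            )
        if not 0 <= self.p_core <= 1:
            raise ValueError("p_core must lie in [0, 1]")
        if not 0 <= self.covariate < params.n_covariates:
            raise ValueError(
                f"cohort references covariate {self.covariate} "
                f"but only {params.n_covariates} exist"
            )
        if not 0 <= self.category < params.n_categories:
            raise ValueError(
                f"cohort references category {self.category} "
                f"but only {params.n_categories} exist"
            )
        if any(not 0 <= m < params.n_otus for m in self.members):
            raise ValueError("cohort member OTU index out of range")


@dataclass(frozen=True)
class SimParams:
    """Shape and law parameters of one synthetic dataset."""

    n_hosts: int = 27
    n_otus: int = 1000
    n_covariates: int = 10
    prevalence_a: float = 0.7
    prevalence_b: float = 4.0
    mean_depth: float = 30_000.0
    abundance_sigma: float = 1.5
    n_functions: int = 120
    n_categories: int = 12
    p_background: float = 0.3
    cohorts: tuple[PlantedCohort, ...] = field(default_factory=tuple)
    n_families: int = 40
    seed: int = 0

    def validate(self) -> None:
        if self.n_hosts < 2 or self.n_otus < 2:
            raise ValueError("need at least 2 hosts and 2 OTUs")
        for n in (self.n_covariates, self.n_functions, self.n_categories,
                  self.n_families):
            if n < 1:
                raise ValueError("all counts must be positive")
        for c in self.cohorts:
            c.validate(self)


def _apply_effect(p: np.ndarray, effect: float) -> np.ndarray:
    odds = p / (1.0 - p)
    return (odds * effect) / (1.0 + odds * effect)


def generate_dataset(params: SimParams):
    """Generate (counts, covariates, annotation, FunctionMatrix, truth).

    ``counts`` is hosts x OTUs; ``covariates`` is a hosts x covariates 0/1
    DataFrame; ``annotation`` covers OTUs and covariates; ``truth`` records
    every planted membership (empty lists when nothing was planted).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    hosts = [f"host{i:03d}" for i in range(params.n_hosts)]
    otus = [f"otu{i:04d}" for i in range(params.n_otus)]
    covs = [f"cov{i:02d}" for i in range(params.n_covariates)]

    prevalence = rng.beta(params.prevalence_a, params.prevalence_b, params.n_otus)
    for c in params.cohorts:
        if c.member_prevalence is not None:
            prevalence[list(c.members)] = c.member_prevalence

    cov_mat = rng.integers(0, 2, size=(params.n_hosts, params.n_covariates))

    # per-host presence probabilities; cohort effects act on the odds scale
    P = np.tile(prevalence, (params.n_hosts, 1))
    for c in params.cohorts:
        pos_hosts = cov_mat[:, c.covariate] == 1
        mem = np.array(c.members)
        adjusted = _apply_effect(P[np.ix_(pos_hosts, mem)], c.effect)
        clipped = np.clip(adjusted, 0.01, 0.99)
        if not np.allclose(adjusted, clipped):
            warnings.warn(
                f"cohort on {covs[c.covariate]}: adjusted presence probabilities "
                "clamped to [0.01, 0.99]",
                stacklevel=2,
            )
        P[np.ix_(pos_hosts, mem)] = clipped
    presence = rng.random(P.shape) < P

    # counts: each present OTU gets 1 read plus a lognormal-weighted
    # multinomial share of the remaining Poisson depth
    counts = np.zeros(P.shape, dtype=np.int64)
    for h in range(params.n_hosts):
        present = np.flatnonzero(presence[h])
        if len(present) == 0:
            continue
        depth = max(int(rng.poisson(params.mean_depth)), len(present))
        w = rng.lognormal(0.0, params.abundance_sigma, len(present))
        counts[h, present] = 1 + rng.multinomial(depth - len(present), w / w.sum())

    counts_df = pd.DataFrame(counts, index=hosts, columns=otus)
    cov_df = pd.DataFrame(cov_mat, index=hosts, columns=covs)

    # taxonomy: families nested in the four widespread phyla
    fam_phylum = rng.integers(0, len(PHYLA), params.n_families)
    fam_of_otu = rng.integers(0, params.n_families, params.n_otus)
    ann = pd.DataFrame(
        {
            "domain": ["bacteria"] * params.n_otus
            + ["eukaryote" if i % 2 == 0 else "diet" for i in range(params.n_covariates)],
            "phylum": [PHYLA[fam_phylum[f]] for f in fam_of_otu]
            + [""] * params.n_covariates,
            "family": [f"fam{f:03d}" for f in fam_of_otu] + [""] * params.n_covariates,
        },
        index=pd.Index(otus + covs, name="taxon"),
    )

    # functions: round-robin category assignment, uniform background carriage
    cats = [f"cat{i % params.n_categories:02d}" for i in range(params.n_functions)]
    fns = [f"fn{i:03d}" for i in range(params.n_functions)]
    fn_presence = rng.random((params.n_otus, params.n_functions)) < params.p_background
    truth_cohorts = []
    for c in params.cohorts:
        cat_label = f"cat{c.category:02d}"
        cat_fns = [i for i, lab in enumerate(cats) if lab == cat_label]
        if c.n_core_functions > len(cat_fns):
            raise ValueError(
                f"cohort on covariate {c.covariate}: category {cat_label} has only "
                f"{len(cat_fns)} functions, fewer than n_core_functions"
            )
        core = rng.choice(cat_fns, size=c.n_core_functions, replace=False)
        mem = np.array(c.members)
        fn_presence[np.ix_(mem, core)] = (
            rng.random((len(mem), len(core))) < c.p_core
        )
        truth_cohorts.append(
            {
                "covariate": covs[c.covariate],
                "members": [otus[m] for m in c.members],
                "effect": c.effect,
                "category": cat_label,
                "core_functions": [fns[i] for i in sorted(core)],
                "p_core": c.p_core,
            }
        )
    fm = FunctionMatrix(
        pd.DataFrame(fn_presence, index=otus, columns=fns),
        pd.Series(cats, index=fns),
    )
    truth = {"cohorts": truth_cohorts}
    return counts_df, cov_df, ann, fm, truth


def write_dataset(outdir, counts, covariates, annotation, fm, truth) -> dict:
    """Write all generator outputs as plain-text tables; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "community": outdir / "community.tsv",
        "covariates": outdir / "covariates.tsv",
        "annotation": outdir / "annotation.tsv",
        "functions": outdir / "functions.tsv",
        "truth": outdir / "truth.json",
    }
    write_community(counts, paths["community"])
    covariates.to_csv(paths["covariates"], sep="\t")
    write_annotation(annotation, paths["annotation"])
    write_function_matrix(fm, paths["functions"])
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return {k: str(v) for k, v in paths.items()}
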