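# Methods

This note records the statistical model, the generative assumptions of the
synthetic data, the numerical choices, and the limits of what the test
suite demonstrates.

## Pairwise cooccurrence model

Hosts are treated as exchangeable sites. For a taxon pair with occupancies
`n1`, `n2` among `N` hosts, the overlap under independent placement is
hypergeometric with pmf `P(j) = C(n2,j)·C(N−n2,n1−j)/C(N,n1)` on
`max(0, n1+n2−N) ≤ j ≤ min(n1,n2)`; the implementation uses
`scipy.stats.hypergeom`, evaluated with the marginals in canonical
(sorted) order so results are bit-identical under label swap. The test
suite checks the pmf and both tails against exhaustive enumeration of all
`C(N,n1)·C(N,n2)` site-set placements for every configuration with
`N ≤ 8`.

Decisions:

* **Inclusive tails.** `p_lt` and `p_gt` both include the observed point
  mass. This matches the standard probabilistic cooccurrence model, makes
  `p_lt + p_gt = 1 + P(obs)` an exact identity (tested), and yields the
  characteristic discreteness of attainable p-values at small `N`.
* **Significance is `p ≤ α`**, not `<`, because the p-values are discrete.
* **`expected_min = 1` by default** in `all_pairs`: pairs whose expected
  overlap is below one host are excluded, which is why reported pair
  universes are smaller than `C(T, 2)`. Exposed as a flag; `None` keeps
  every pair.
* **Randomization null.** `randomize_presence` reassigns each taxon's
  presences to a uniform random host subset of the same size: per-taxon
  occupancy is conserved, per-host richness is not. Fixed-row-and-column
  null models are deliberately out of scope. Repeated randomization of a
  pair reproduces the hypergeometric overlap law (chi-square check in the
  suite).

## Community curation

The depth filter retains hosts with **strictly more than** `min_total`
sequences (default 10,000); a host at exactly the threshold is dropped.
Rarefaction is a single multivariate-hypergeometric draw per host to a
common depth (default 10,000), seeded and recorded — not an average over
repeated subsamples, so downstream presence patterns come from one
realized matrix. Presence is `count > 0`; taxa must occur in ≥ 2 hosts to
enter the pairwise analysis (a single-host taxon carries no overlap
information). Phylum summaries are incidence proportions (richness), not
read-count proportions.

## Function space

Functional profiles are binary OTU-by-function vectors under a two-level
ontology; Bray-Curtis on binary profiles is
`1 − 2|shared|/(|u|+|v|)`, chosen for robustness to false-negative
annotations (an unannotated function affects only profiles that carry it).
All-zero profiles have undefined distances; they are reported as missing
and excluded from every downstream statistic, with a count in the log.
Only ontology categories with ≥ 8 distinct functions present in the data
define a per-category space; smaller categories are dropped with a log
entry.

"Functional similarity" is `1 − d` by default — bounded and defined at
`d = 0` — with `1/d` (plus an explicit cap at zero distance) as an option,
since "inverse of the distance" admits both readings.

The deviation-similarity regression fits similarity against percent
cooccurrence deviation within each phylum. Pairwise observations sharing
an OTU are not independent, so the headline p-value is a Mantel-style
permutation test (OTU identities shuffled within the phylum's block of
the similarity matrix, one-sided for positive association, `(1+k)/(1+m)`
estimator); the naive OLS p-value is emitted alongside for comparability.
Calibration of the permutation test at nominal level .1 over 200 null
draws is part of the suite.

## Cohorts and clustering statistics

A covariate (eukaryote, diet item, host species) qualifies when **two or
more** bacterial OTUs cooccur with it at `alpha_select` (default .01);
its cohort then contains every bacterial OTU reaching `alpha_member`
(default .05). The two thresholds are deliberately distinct config keys;
positive and negative cooccurrers are pooled by default, with a flag to
restrict direction. Covariates with a single interacting OTU are excluded
— a one-member set has no clustering statistic.

Mean nearest-neighbor distance is the average over members of the
distance to the closest fellow member. Centroid displacement is computed
purely from pairwise distances via

    |c_A − c_B|² = mean d²(A,B) − ½·mean d²(A,A) − ½·mean d²(B,B)

with all means over ordered pairs including self-pairs. For Euclidean
distances this equals the direct centroid distance exactly (checked to
1e−9 on random point clouds); Bray-Curtis is not Euclidean-embeddable in
general, so a negative squared displacement can occur — it is clamped to
zero and flagged rather than propagated as an imaginary number.

The null draws uniform random subsets of the cohort's size **from the
OTUs present in that category's function space** (not the global OTU
list), keeping the null comparable to the observed statistic's support;
5,000 draws by default. Reported fractions are the proportions of draws
with *smaller* MNN (`frac_tighter`) and *smaller* displacement
(`frac_less_displaced`); exact zeros are reported as `1/reps` with a
`below_resolution` flag so log-scale displays stay finite. Percentile
ranks of subsets drawn from the null itself are uniform (KS-checked).

## Interaction graphs

Significant OTU pairs collapse onto family-level nodes (eukaryote and
diet nodes stay at their own rank) with edge multiplicity counting the
OTU-level pairs behind each family pair; within-family pairs are
self-loops. A self-loop adds 2 to the degree (standard undirected
convention, recorded in graph metadata). Parallel edges are collapsed
into multiplicities rather than drawn separately. The family-size versus
degree association is a Spearman rank correlation.

## Synthetic data generator

The generator emulates the shape of a small-cohort amplicon survey; the
field data it mimics are observational, so every law below is an artifact
choice, stated here and exposed as a parameter:

* **Shape defaults:** 27 hosts, up to ~10³ OTUs, binary covariates drawn
  Bernoulli(0.5) per host, 120 functions in 12 categories (so every
  category clears the 8-function rule).
* **Prevalence:** per-OTU occurrence probability ~ Beta(0.7, 4) —
  skewed-rare, the many-rare-OTU shape of 16S surveys.
* **Counts:** per-host depth ~ Poisson(mean_depth, default 30,000 so the
  >10,000 filter and 10,000-deep rarefaction behave realistically); each
  present OTU receives 1 read plus a multinomial share with lognormal
  (σ = 1.5) weights. The base read guarantees presence ⇔ count > 0; the
  exact abundance law is irrelevant to the presence-based statistics
  downstream.
* **Planted cohorts:** members' presence odds are multiplied by `effect`
  in covariate-positive hosts (clamped into [0.01, 0.99] with a warning
  so all outcomes stay possible); members carry each of `n_core_functions`
  core functions in one category with probability `p_core` (default 0.9)
  against a global background carriage of `p_background` (default 0.3).
  Members get an overridable baseline prevalence (default 0.2) so planted
  signal is not erased by members happening to be vanishingly rare; the
  background rate is a dataset-level parameter rather than per-cohort.
* OTUs are assigned families nested in the four widespread phyla so that
  graph and regression stages have realistic grouping labels.

**Documented recovery conditions.** The end-to-end recovery checks run at
27 hosts, 300 OTUs, 12 categories, one 8-member cohort with presence-odds
effect 16 and p_core 0.9, defaults everywhere downstream. At these
conditions the cohort is detected in ~19–20 of 20 seeds, a median of ~7 of
8 members is recovered at `alpha_member = .05`, and the cohort is tighter
in its core category than ≥ 98% of 5,000 random subsets in a clear
majority of seeds. Two properties of these conditions are worth stating
plainly: (a) weaker effects (e.g. 8) still give majority member recovery
but make the 98%-tightness outcome marginal; (b) growing the OTU pool at a
fixed membership threshold dilutes cohorts with false members (≈ 2×α×T
per covariate), so at several thousand OTUs the clustering signal of a
small planted core washes out — a real property of the selection rule, not
an implementation artifact. The unit test fixture for "all within-cohort
pairs significant" uses the strong-coupling regime (rare baseline 0.03,
effect 500), since at 27 hosts only near-deterministic co-presence drives
pairwise `p_gt` below .01.

**What passing tests do not show.** The generator has no phylogenetic
signal, no compositional coupling between OTUs beyond the planted
cohorts, no read-level error, and covariates independent of everything
unplanted. Recovery results therefore demonstrate correctness of the
inference chain, not expected power on real microbiome data, where
unmodeled host effects induce diffuse positive cooccurrence.

## Pipeline and reproducibility

Stage seeds derive from the master seed as `crc32(f"{seed}:{stage}") mod
2³¹`, so stages are independently reproducible and a run is byte-identical
given config + seed. The manifest records version, config, per-stage seeds
and row counts at every filter. Problem sizes used by the test suite and
the acceptance script (300-OTU recovery runs, 10⁴-pair calibration, 5,000
null draws, 200 KS trials at 400 draws) were chosen to exercise every code
path at study-like shape while keeping a full run fast on one CPU.

## Known limitations

* Tail probabilities use double-precision hypergeometric routines; for
  `N` up to ~10⁴ this is accurate to ~1e−12 but is not exact rational
  arithmetic.
* `cohort_report` computes one category space at a time from the full
  distance matrix; at ≫ 10⁴ OTUs memory for the dense matrix, not time,
  becomes the binding constraint.
* The Mantel permutation regression treats phyla as fixed groups; no
  hierarchical pooling across phyla is attempted.
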