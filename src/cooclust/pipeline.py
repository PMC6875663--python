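"""End-to-end orchestration: simulate/load -> prep -> cooccur -> function space
-> cohorts -> graphs, with stage-level seeds derived from one master seed.

Every stage writes its tables into the run directory and records row counts
in a machine-readable manifest, so filters can be audited after the fact.
All thresholds are config keys with the field-standard defaults: host depth
filter > 10,000 sequences, rarefaction to 10,000, occupancy >= 2 hosts,
graph/selection significance .01, membership significance .05, expected
overlap >= 1, ontology categories with >= 8 functions, 5 cooccurrence
randomizations and 5,000 cohort-null draws.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, community, cohorts as cohorts_mod, cooccur
from . import function_space as fspace
from . import graphs as graphs_mod
from . import simulate as sim

__all__ = ["RunConfig", "stage_seed", "run_pipeline"]


@dataclass
class RunConfig:
    """Declarative configuration of one pipeline run."""

    # inputs: either paths to the four tables, or simulate=True + sim_params
    community_path: str | None = None
    covariates_path: str | None = None
    annotation_path: str | None = None
    functions_path: str | None = None
    simulate: bool = False
    sim_params: dict = field(default_factory=dict)

    depth: int = 10_000
    min_total: int = 10_000
    min_hosts: int = 2
    alpha_graph: float = 0.01
    alpha_select: float = 0.01
    alpha_member: float = 0.05
    expected_min: float | None = 1.0
    min_functions: int = 8
    null_reps_cooccur: int = 5
    null_reps_cohort: int = 5000
    n_perm_regression: int = 999
    similarity_mode: str = "one_minus"
    seed: int = 0

    def validate(self) -> None:
        for a in (self.alpha_graph, self.alpha_select, self.alpha_member):
            if not 0 < a < 1:
                raise ValueError("significance thresholds must lie in (0, 1)")
        for n in (self.depth, self.min_hosts, self.min_functions,
                  self.null_reps_cooccur, self.null_reps_cohort):
            if n < 1:
                raise ValueError("all counts must be positive")
        if not self.simulate and self.community_path is None:
            raise ValueError("either set simulate=True or provide input paths")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**raw)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    return zlib.crc32(f"{master}:{stage}".encode()) % (2**31)


def _load_inputs(cfg: RunConfig):
    if cfg.simulate:
        params = sim.SimParams(
            **{**cfg.sim_params, "seed": stage_seed(cfg.seed, "simulate")}
        )
        return sim.generate_dataset(params)
    counts = community.read_community(cfg.community_path)
    covs = pd.read_csv(cfg.covariates_path, sep="\t", index_col=0)
    ann = community.read_annotation(cfg.annotation_path)
    fm = fspace.read_function_matrix(cfg.functions_path) if cfg.functions_path else None
    return counts, covs, ann, fm, {"cohorts": []}


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Run every stage, write all tables + manifest into *outdir*, return the manifest.

    Any stage failure aborts with the stage name prepended to the error.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config": {k: v for k, v in asdict(cfg).items()},
        "seeds": {}, "counts": {}, "outputs": {},
    }

    def _stage(name):
        s = stage_seed(cfg.seed, name)
        manifest["seeds"][name] = s
        return s

    stage = "load"
    try:
        counts, covs, ann, fm, truth = _load_inputs(cfg)
        _stage("simulate") if cfg.simulate else None
        manifest["counts"]["hosts_in"] = len(counts)
        manifest["counts"]["otus_in"] = counts.shape[1]

        stage = "prep"
        counts = community.filter_hosts(counts, cfg.min_total)
        counts = community.rarefy(counts, cfg.depth, seed=_stage("rarefy"))
        pres = community.to_presence(counts)
        pres = community.filter_occupancy(pres, cfg.min_hosts)
        covs = covs.loc[counts.index].astype(bool)
        joint = pd.concat([pres, covs], axis=1)
        manifest["counts"]["hosts_retained"] = len(counts)
        manifest["counts"]["otus_retained"] = pres.shape[1]
        manifest["counts"]["covariates"] = covs.shape[1]
        community.write_community(counts, outdir / "community_rarefied.tsv")
        joint.astype(int).to_csv(outdir / "presence.tsv", sep="\t")

        stage = "cooccur"
        pairs = cooccur.classify_pairs(
            cooccur.all_pairs(joint, expected_min=cfg.expected_min), cfg.alpha_graph
        )
        cooccur.write_pairs(pairs, outdir / "pairs.tsv")
        manifest["counts"]["pairs"] = len(pairs)
        manifest["counts"]["pairs_positive"] = int((pairs["label"] == "positive").sum())
        manifest["counts"]["pairs_negative"] = int((pairs["label"] == "negative").sum())
        null_counts = cooccur.null_significant_counts(
            joint, alpha=cfg.alpha_graph, reps=cfg.null_reps_cooccur,
            seed=_stage("cooccur_null"), expected_min=cfg.expected_min,
        )
        null_counts.to_csv(outdir / "null_significant_counts.tsv", sep="\t")
        manifest["counts"]["null_range"] = null_counts.attrs["range"]

        stage = "funcspace"
        report = regressions = None
        if fm is not None:
            fm_used = fspace.FunctionMatrix(
                fm.presence.loc[[o for o in fm.otus if o in pres.columns]],
                fm.categories,
            )
            spaces = fspace.subset_categories(fm_used, cfg.min_functions)
            manifest["counts"]["function_categories"] = len(spaces)
            dm_all = fspace.bray_curtis(fm_used)
            sim_all = fspace.similarity(dm_all, mode=cfg.similarity_mode, cap=1.0)
            phyla = ann.loc[list(fm_used.otus), "phylum"]
            regressions = fspace.deviation_similarity_regression(
                pairs, sim_all, phyla, n_perm=cfg.n_perm_regression,
                seed=_stage("regression"),
            )
            regressions.to_csv(outdir / "deviation_similarity.tsv", sep="\t", index=False)

            stage = "cohorts"
            bacteria = [t for t in joint.columns if t in ann.index
                        and ann.loc[t, "domain"] == "bacteria"]
            covariate_ids = [c for c in covs.columns]
            cohort_list = cohorts_mod.select_cohorts(
                pairs, covariate_ids, bacteria,
                alpha_select=cfg.alpha_select, alpha_member=cfg.alpha_member,
            )
            manifest["counts"]["cohorts"] = len(cohort_list)
            cat_dms = {cat: fspace.bray_curtis(sp) for cat, sp in spaces.items()}
            report = cohorts_mod.cohort_report(
                cohort_list, cat_dms, reps=cfg.null_reps_cohort,
                seed=_stage("cohort_null"),
            )
            report.to_csv(outdir / "cohort_stats.tsv", sep="\t", index=False)
            manifest["counts"]["cohort_rows"] = len(report)

        stage = "graphs"
        for direction in ("positive", "negative"):
            g = graphs_mod.build_graph(pairs, ann, direction=direction)
            graphs_mod.write_graphml(g, outdir / f"graph_{direction}.graphml")
            graphs_mod.write_edgelist(g, outdir / f"graph_{direction}_edges.tsv")
            graphs_mod.graph_stats(g).to_csv(
                outdir / f"graph_{direction}_stats.tsv", sep="\t"
            )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["outputs"] = sorted(p.name for p in outdir.iterdir() if p.is_file())
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
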