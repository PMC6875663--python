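"""Run the whole pipeline from one config and inspect the manifest.

Simulate mode: generate a dataset with one planted cohort, apply the depth
filter and rarefaction, test all pairs, build function-space statistics and
family-level graphs, and write every table plus a manifest into a run
directory.  The same RunConfig + seed always reproduces the run byte for
byte.
"""

import json
import tempfile
import warnings
from pathlib import Path

from cooclust.pipeline import RunConfig, run_pipeline
from cooclust.simulate import PlantedCohort

warnings.simplefilter("ignore")

cfg = RunConfig(
    simulate=True,
    sim_params=dict(
        n_hosts=27, n_otus=200, n_covariates=6, n_functions=96, n_categories=12,
        cohorts=(PlantedCohort(covariate=0, members=tuple(range(8)), effect=16.0),),
    ),
    null_reps_cooccur=5,
    null_reps_cohort=1000,
    n_perm_regression=199,
    seed=7,
)

outdir = Path(tempfile.mkdtemp()) / "run"
manifest = run_pipeline(cfg, outdir)

print("stage accounting from the manifest:")
print(json.dumps(manifest["counts"], indent=2))
print("\nfiles written:")
for name in manifest["outputs"]:
    print(" ", name)
print("\nThe null_range entry shows how many significant pairs occupancy-"
      "preserving randomization would produce by chance; the planted cohort "
      "makes the observed pairs_positive exceed it.")
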