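"""Bundled example data.

``load_lizard_host_counts`` returns the published per-host sequence-count
table from a two-species lizard gut-microbiome survey (18 silky anoles and
9 rainbow ameivas): reads in the four widespread bacterial phyla plus
selected eukaryote and diet-item orders and a non-target column.  It is the
worked example for the host-depth accounting: summing the four bacterial
phyla per host and applying the > 10,000-sequence filter retains all 27
hosts, the analysis set of the original survey.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

BACTERIAL_PHYLA = ["Proteobacteria", "Firmicutes", "Bacteroidetes", "Actinobacteria"]
EUKARYOTE_ORDERS = ["Basidiobolales", "Mucorales", "Tritrichomonadida", "Eugregarinorida"]
DIET_ORDERS = [
    "Orthoptera", "Diptera", "Hemiptera", "Coleoptera",
    "Hymenoptera", "Psocoptera", "Araneae",
]

__all__ = [
    "load_lizard_host_counts",
    "BACTERIAL_PHYLA",
    "EUKARYOTE_ORDERS",
    "DIET_ORDERS",
]


def load_lizard_host_counts() -> pd.DataFrame:
    """Per-host sequence counts (27 lizard hosts x 16 taxon columns)."""
    with resources.files("cooclust.data").joinpath("lizard_host_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", index_col=0)
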