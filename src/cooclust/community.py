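"""Host-by-taxon community matrices: loading, filtering, rarefaction, binarization.

The central observational object is a host-by-taxon count matrix (hosts as
rows, OTUs or higher-rank taxa as columns, non-negative integer counts).
This module implements the end-stage curation steps applied before any
cooccurrence modelling: discarding shallowly sequenced hosts, rarefying the
survivors to a common depth, binarizing to presence-absence, and dropping
taxa too rare to carry pairwise signal.  It also computes per-host phylum
incidence proportions used for community summaries.

Matrices are plain :class:`pandas.DataFrame` objects (index = host ids,
columns = taxon ids); taxon annotations are a DataFrame indexed by taxon id
with columns ``domain``, ``phylum``, ``family``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

VALID_DOMAINS = frozenset({"bacteria", "eukaryote", "diet", "host_species"})

__all__ = [
    "read_community",
    "write_community",
    "read_annotation",
    "write_annotation",
    "validate_community",
    "filter_hosts",
    "rarefy",
    "to_presence",
    "filter_occupancy",
    "phylum_proportions",
]


def read_community(path, sep: str | None = None) -> pd.DataFrame:
    """Read a host-by-taxon count matrix from TSV/CSV (hosts as rows).

    The delimiter is inferred from the file extension unless given.
    """
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    validate_community(df)
    return df


def write_community(m: pd.DataFrame, path, sep: str = "\t") -> None:
    m.to_csv(path, sep=sep)


def read_annotation(path) -> pd.DataFrame:
    """Read a taxon annotation table (columns: taxon, domain, phylum, family)."""
    ann = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    bad = set(ann["domain"]) - VALID_DOMAINS
    if bad:
        raise ValueError(f"unknown taxon domains: {sorted(bad)}")
    return ann


def write_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index_label="taxon")


def validate_community(m: pd.DataFrame) -> None:
    """Check the community-matrix invariants: unique ids, non-negative integer counts."""
    if m.index.has_duplicates:
        raise ValueError("duplicate host ids in community matrix")
    if m.columns.has_duplicates:
        raise ValueError("duplicate taxon ids in community matrix")
    vals = m.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        raise ValueError("community matrix must be numeric")
    if (vals < 0).any():
        raise ValueError("community matrix contains negative counts")
    if not np.allclose(vals, np.round(vals)):
        raise ValueError("community matrix contains non-integer counts")


def filter_hosts(m: pd.DataFrame, min_total: int = 10_000) -> pd.DataFrame:
    """Retain hosts whose total sequence count is strictly greater than *min_total*.

    The comparison is strict: a host at exactly *min_total* is discarded.
    Raises ``ValueError`` if no host survives.
    """
    if min_total < 0:
        raise ValueError("min_total must be non-negative")
    keep = m.sum(axis=1) > min_total
    if not keep.any():
        raise ValueError(f"no hosts survive the > {min_total} total-sequence filter")
    return m.loc[keep]


def rarefy(m: pd.DataFrame, depth: int = 10_000, seed: int | None = None) -> pd.DataFrame:
    """Subsample each host's sequences without replacement to a common *depth*.

    Each row is drawn from a multivariate hypergeometric distribution on its
    own sequence pool, so every rarefied cell is bounded by the original cell
    and each row sums exactly to *depth*.  Deterministic given *seed*.

    Hosts whose total is below *depth* raise an error naming the host; filter
    first with :func:`filter_hosts`.
    """
    totals = m.sum(axis=1)
    short = totals[totals < depth]
    if len(short):
        raise ValueError(
            f"hosts below rarefaction depth {depth}: {list(short.index)}"
        )
    rng = np.random.default_rng(seed)
    counts = m.to_numpy().astype(np.int64)
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return pd.DataFrame(out, index=m.index, columns=m.columns)


def to_presence(m: pd.DataFrame) -> pd.DataFrame:
    """Binarize a count matrix: presence means count > 0."""
    return m > 0


def filter_occupancy(p: pd.DataFrame, min_hosts: int = 2) -> pd.DataFrame:
    """Retain taxa present in at least *min_hosts* hosts.

    Cooccurrence tail probabilities are uninformative for taxa seen in a
    single host, so the default keeps taxa occurring in two or more hosts.
    """
    if min_hosts < 1:
        raise ValueError("min_hosts must be >= 1")
    occ = p.sum(axis=0)
    keep = occ >= min_hosts
    if not keep.any():
        warnings.warn("occupancy filter removed every taxon", stacklevel=2)
    return p.loc[:, keep]


def phylum_proportions(
    p: pd.DataFrame, ann: pd.DataFrame, phyla: list[str]
) -> pd.DataFrame:
    """Per-host proportion of present bacterial OTUs in each listed phylum.

    Proportions are computed on OTU incidence (richness), not read counts:
    for each host, (present OTUs in phylum) / (present bacterial OTUs).
    Hosts with zero present bacterial OTUs get ``NaN`` for every phylum.
    """
    if not phyla:
        raise ValueError("phyla list must be non-empty")
    bacterial = [t for t in p.columns if ann.loc[t, "domain"] == "bacteria"]
    pres = p[bacterial]
    denom = pres.sum(axis=1).astype(float)
    out = {}
    phylum_of = ann.loc[bacterial, "phylum"]
    for ph in phyla:
        members = phylum_of.index[phylum_of == ph]
        out[ph] = pres[members].sum(axis=1) / denom.where(denom > 0)
    return pd.DataFrame(out, index=p.index)
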