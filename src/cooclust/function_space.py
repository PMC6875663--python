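"""Functional distance geometry over OTUs.

Each OTU carries a binary profile of metabolic functions (e.g. KEGG
orthologs), with every function assigned to one category of a two-level
ontology.  Dissimilarity between profiles is Bray-Curtis, which on binary
vectors reduces to 1 - 2|shared| / (|u| + |v|); it is robust to missing
annotations because absent functions only enter through the profiles that
carry them.  Function space can be restricted to one ontology category at a
time, keeping only categories with enough distinct functions to define a
meaningful geometry.

The regression utilities relate each pair's percent cooccurrence deviation
to its functional similarity, with a Mantel-style permutation test (OTU
identities shuffled in the similarity matrix) because pairwise observations
sharing an OTU are not independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FunctionMatrix",
    "read_function_matrix",
    "write_function_matrix",
    "bray_curtis",
    "similarity",
    "subset_categories",
    "deviation_similarity_regression",
]


@dataclass
class FunctionMatrix:
    """OTU-by-function binary matrix plus a per-function category label."""

    presence: pd.DataFrame          # otus x functions, boolean
    categories: pd.Series = field(default=None)  # function id -> category label

    def __post_init__(self):
        if self.categories is None:
            raise ValueError("every function needs a category label")
        missing = set(self.presence.columns) - set(self.categories.index)
        if missing:
            raise ValueError(f"functions without category label: {sorted(missing)[:5]}")
        self.presence = self.presence.astype(bool)
        self.categories = self.categories.loc[self.presence.columns]
        # normalized axis names so round-trips through TSV compare equal
        self.presence.index.name = "otu"
        self.presence.columns.name = "function"
        self.categories.index.name = "function"
        self.categories.name = "category"

    @property
    def otus(self) -> pd.Index:
        return self.presence.index

    @property
    def functions(self) -> pd.Index:
        return self.presence.columns


def read_function_matrix(path) -> FunctionMatrix:
    """Read an OTU-by-function TSV whose header carries ``category:function`` labels."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    cats, fns = [], []
    for col in df.columns:
        cat, _, fn = col.partition(":")
        if not fn:
            raise ValueError(f"function column {col!r} lacks a 'category:function' label")
        cats.append(cat)
        fns.append(fn)
    df.columns = fns
    return FunctionMatrix(df > 0, pd.Series(cats, index=fns))


def write_function_matrix(fm: FunctionMatrix, path) -> None:
    out = fm.presence.astype(int).copy()
    out.columns = [f"{fm.categories[f]}:{f}" for f in out.columns]
    out.to_csv(path, sep="\t", index_label="otu")


def bray_curtis(fm: FunctionMatrix, subset=None) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between binary functional profiles.

    *subset* optionally restricts to a set of function ids.  Distances
    involving an all-zero profile are undefined and returned as ``NaN``
    (with a warning); downstream statistics exclude them.
    """
    cols = fm.functions if subset is None else [f for f in fm.functions if f in set(subset)]
    X = fm.presence[list(cols)].to_numpy(dtype=np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least two OTUs")
    sizes = X.sum(axis=1)
    shared = X @ X.T
    tot = sizes[:, None] + sizes[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - 2.0 * shared / tot
    empty = sizes == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} OTUs have all-zero profiles; their distances are undefined",
            stacklevel=2,
        )
        d[empty, :] = np.nan
        d[:, empty] = np.nan
    np.fill_diagonal(d, np.where(empty, np.nan, 0.0))
    return pd.DataFrame(d, index=fm.otus, columns=fm.otus)


def similarity(dm: pd.DataFrame, mode: str = "one_minus", cap: float | None = None) -> pd.DataFrame:
    """Convert a distance matrix to a similarity matrix.

    ``one_minus`` (default) maps d to 1 - d, bounded and defined at d = 0;
    ``reciprocal`` maps d to 1/d, with zero distances mapped to *cap*
    (an error if no cap is given).
    """
    if mode == "one_minus":
        return 1.0 - dm
    if mode == "reciprocal":
        d = dm.to_numpy(copy=True)
        zero = d == 0
        if zero.any() and cap is None:
            raise ValueError("reciprocal similarity needs a cap when distances are zero")
        with np.errstate(divide="ignore"):
            s = 1.0 / d
        if cap is not None:
            s[zero] = cap
        return pd.DataFrame(s, index=dm.index, columns=dm.columns)
    raise ValueError(f"unknown similarity mode {mode!r}")


def subset_categories(fm: FunctionMatrix, min_functions: int = 8) -> dict[str, FunctionMatrix]:
    """Split the function matrix into per-category submatrices.

    Only categories with at least *min_functions* distinct functions present
    in the dataset are kept; smaller categories are dropped with a warning.
    Raises if no category qualifies.
    """
    if min_functions < 1:
        raise ValueError("min_functions must be >= 1")
    present = fm.presence.any(axis=0)
    out: dict[str, FunctionMatrix] = {}
    dropped = []
    for cat, fns in fm.categories.groupby(fm.categories):
        fns_present = [f for f in fns.index if present[f]]
        if len(fns_present) >= min_functions:
            out[cat] = FunctionMatrix(
                fm.presence[fns_present], fm.categories.loc[fns_present]
            )
        else:
            dropped.append(cat)
    if dropped:
        warnings.warn(
            f"categories below the {min_functions}-function threshold dropped: {dropped}",
            stacklevel=2,
        )
    if not out:
        raise ValueError("no ontology category meets the minimum function count")
    return out


def _pair_xy(pairs: pd.DataFrame, sim: pd.DataFrame, otus: list) -> tuple[np.ndarray, ...]:
    """Extract (x = pct_dev, y = similarity, a_idx, b_idx) for pairs within *otus*."""
    pos = {o: i for i, o in enumerate(sim.index)}
    members = set(otus)
    mask = pairs["taxon_a"].isin(members) & pairs["taxon_b"].isin(members)
    sub = pairs.loc[mask]
    ia = sub["taxon_a"].map(pos).to_numpy()
    ib = sub["taxon_b"].map(pos).to_numpy()
    S = sim.to_numpy()
    x = sub["pct_dev"].to_numpy(dtype=float)
    y = S[ia, ib]
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok], ia[ok], ib[ok]


def _perm_regression(
    x: np.ndarray, y_from: callable, idx_pool: np.ndarray,
    ia: np.ndarray, ib: np.ndarray, n_perm: int, rng: np.random.Generator,
) -> tuple[float, float, float, float]:
    """Slope/r/naive-p plus a one-sided Mantel permutation p for r > 0."""
    y = y_from(ia, ib)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 0.0, 1.0, 1.0
    fit = stats.linregress(x, y)
    exceed = 0
    for _ in range(n_perm):
        perm = idx_pool[rng.permutation(len(idx_pool))]
        remap = dict(zip(idx_pool, perm))
        pa = np.array([remap[i] for i in ia])
        pb = np.array([remap[i] for i in ib])
        yp = y_from(pa, pb)
        if np.ptp(yp) == 0:
            r = 0.0
        else:
            r = np.corrcoef(x, yp)[0, 1]
        if r >= fit.rvalue:
            exceed += 1
    p_perm = (1 + exceed) / (1 + n_perm)
    return float(fit.slope), float(fit.rvalue), float(fit.pvalue), float(p_perm)


def deviation_similarity_regression(
    pairs: pd.DataFrame,
    sim: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Regress functional similarity on percent cooccurrence deviation, per phylum.

    For each group (phylum) with >= 3 OTUs carrying defined similarities,
    fits similarity ~ pct_dev over within-group pairs and reports the
    least-squares slope, Pearson correlation, the naive OLS p-value, and a
    Mantel-style permutation p-value (one-sided for positive association,
    OTU identities shuffled within the group's block of the similarity
    matrix).  A ``between`` row does the same for cross-group pairs, with
    labels permuted over the union of grouped OTUs.

    *groups* maps OTU id to group label; OTUs absent from the similarity
    matrix or with undefined (NaN) similarity rows are excluded.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    rng = np.random.default_rng(seed)
    S = sim.to_numpy()
    offdiag = S.copy()
    np.fill_diagonal(offdiag, np.nan)
    defined = ~np.all(np.isnan(offdiag), axis=1)
    usable = set(sim.index[defined]) & set(groups.index)

    def y_from(ia, ib):
        return S[ia, ib]

    rows = []
    pos = {o: i for i, o in enumerate(sim.index)}
    for g, members in groups.groupby(groups):
        otus = [o for o in members.index if o in usable]
        if len(otus) < 3:
            warnings.warn(f"group {g!r} has < 3 usable OTUs; skipped", stacklevel=2)
            continue
        x, y, ia, ib = _pair_xy(pairs, sim, otus)
        if len(x) < 3:
            warnings.warn(f"group {g!r} has < 3 usable pairs; skipped", stacklevel=2)
            continue
        idx_pool = np.array([pos[o] for o in otus])
        slope, r, p_naive, p_perm = _perm_regression(
            x, y_from, idx_pool, ia, ib, n_perm, rng
        )
        rows.append(
            {"group": g, "n_otus": len(otus), "n_pairs": len(x),
             "slope": slope, "r": r, "p_naive": p_naive, "p_perm": p_perm}
        )

    # cross-group analogue: pairs whose two OTUs carry different labels
    grouped = [o for o in groups.index if o in usable]
    if len(grouped) >= 3:
        members = set(grouped)
        mask = (
            pairs["taxon_a"].isin(members)
            & pairs["taxon_b"].isin(members)
            & (pairs["taxon_a"].map(groups) != pairs["taxon_b"].map(groups))
        )
        sub = pairs.loc[mask]
        if len(sub) >= 3:
            ia = sub["taxon_a"].map(pos).to_numpy()
            ib = sub["taxon_b"].map(pos).to_numpy()
            x = sub["pct_dev"].to_numpy(dtype=float)
            y = S[ia, ib]
            ok = np.isfinite(x) & np.isfinite(y)
            idx_pool = np.array([pos[o] for o in grouped])
            slope, r, p_naive, p_perm = _perm_regression(
                x[ok], y_from, idx_pool, ia[ok], ib[ok], n_perm, rng
            )
            rows.append(
                {"group": "between", "n_otus": len(grouped), "n_pairs": int(ok.sum()),
                 "slope": slope, "r": r, "p_naive": p_naive, "p_perm": p_perm}
            )
    out = pd.DataFrame(rows)
    out.attrs["n_perm"] = n_perm
    return out
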