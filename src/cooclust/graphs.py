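"""Family-level interaction graphs from significant taxon pairs.

Significant OTU-level pairs are collapsed onto an undirected graph whose
nodes are bacterial families (plus eukaryote and diet-item nodes), with
edge multiplicity counting the OTU-level pairs behind each family pair.
Pairs within one family become self-loops — a self-loop contributes 2 to
the node's degree, the standard undirected convention, recorded in the
graph metadata so cross-tool comparisons are unambiguous.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["build_graph", "graph_stats", "write_graphml", "write_edgelist"]


def _node_for(taxon: str, ann: pd.DataFrame) -> tuple[str, str]:
    """Map a taxon to its graph node: bacteria collapse to family, other
    domains (eukaryote orders, diet items, host species) stay as themselves."""
    domain = ann.loc[taxon, "domain"]
    if domain == "bacteria":
        fam = ann.loc[taxon, "family"]
        if pd.isna(fam) or fam == "":
            raise ValueError(f"bacterial taxon {taxon!r} lacks a family label")
        return str(fam), "bacteria"
    return taxon, domain


def build_graph(
    pairs: pd.DataFrame,
    ann: pd.DataFrame,
    direction: str = "positive",
    alpha: float | None = None,
) -> nx.Graph:
    """Collapse significant pairs (label == *direction*) to a family-level graph.

    Every taxon in the table must be annotated; unannotated taxa raise an
    error listing their ids.  If *alpha* is given the table is re-thresholded
    on the matching tail probability, otherwise the existing labels are used.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    taxa = pd.unique(pd.concat([pairs["taxon_a"], pairs["taxon_b"]]))
    missing = [t for t in taxa if t not in ann.index]
    if missing:
        raise ValueError(f"unannotated taxa: {missing}")
    if alpha is not None:
        col = "p_gt" if direction == "positive" else "p_lt"
        sig = pairs.loc[pairs[col] <= alpha]
    else:
        sig = pairs.loc[pairs["label"] == direction]

    g = nx.Graph(direction=direction, self_loop_degree=2)
    members: dict[str, set] = {}
    for t in taxa:
        node, domain = _node_for(t, ann)
        members.setdefault(node, set()).add(t)
        if node not in g:
            g.add_node(node, domain=domain)
    for node, mem in members.items():
        g.nodes[node]["n_members"] = len(mem)
    for a, b in zip(sig["taxon_a"], sig["taxon_b"]):
        na, _ = _node_for(a, ann)
        nb, _ = _node_for(b, ann)
        if g.has_edge(na, nb):
            g[na][nb]["multiplicity"] += 1
        else:
            g.add_edge(na, nb, multiplicity=1)
    return g


def graph_stats(g: nx.Graph) -> pd.DataFrame:
    """Per-node degree (self-loops count twice), self-loop multiplicity, and
    the member-count vs degree rank association.

    The Spearman correlation between a node's member-OTU count and its
    multiplicity-weighted degree — a family-abundance vs connectivity
    summary — is stored in ``attrs['size_degree_spearman']``.
    """
    rows = []
    for node in g.nodes:
        deg = 0
        loops = 0
        for nbr, data in g[node].items():
            mult = data["multiplicity"]
            if nbr == node:
                loops = mult
                deg += 2 * mult
            else:
                deg += mult
        rows.append(
            {"node": node, "domain": g.nodes[node].get("domain"),
             "n_members": g.nodes[node].get("n_members", 1),
             "degree": deg, "self_loops": loops}
        )
    out = pd.DataFrame(rows).set_index("node")
    if len(out) >= 3 and out["degree"].nunique() > 1 and out["n_members"].nunique() > 1:
        rho, p = stats.spearmanr(out["n_members"], out["degree"])
        out.attrs["size_degree_spearman"] = float(rho)
        out.attrs["size_degree_p"] = float(p)
    else:
        out.attrs["size_degree_spearman"] = np.nan
        out.attrs["size_degree_p"] = np.nan
    return out


def write_graphml(g: nx.Graph, path) -> None:
    nx.write_graphml(g, path)


def write_edgelist(g: nx.Graph, path) -> None:
    rows = [
        {"node_a": a, "node_b": b, "multiplicity": d["multiplicity"]}
        for a, b, d in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "multiplicity"]).to_csv(
        path, sep="\t", index=False
    )
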