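"""Assembly of the heterogeneous TF-miRNA-gene network from typed edge tables.

All interaction layers (directed regulations and undirected PPI) are
flattened into one undirected simple graph: self-loops are dropped,
parallel edges from different layers merge into a single edge whose
``interaction_types`` attribute records provenance, and PPI rows are kept
only when their confidence score is strictly greater than the cutoff
(curated regulatory tables carry no score and are taken as-is).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

__all__ = ["build_network", "network_to_table", "degree_stats", "largest_component"]

NODE_TYPES = {"TF", "miRNA", "gene"}


def build_network(edge_tables, ppi_conf_min: float = 0.7) -> nx.Graph:
    """Merge typed edge tables into one undirected simple graph.

    ``edge_tables`` is a DataFrame, or an iterable/dict of DataFrames, with
    columns source, target, source_type, target_type, interaction_type and
    (for PPI rows) confidence.  Raises if one id is declared with two
    different node types.
    """
    if isinstance(edge_tables, pd.DataFrame):
        frames = [edge_tables]
    elif isinstance(edge_tables, dict):
        frames = list(edge_tables.values())
    else:
        frames = list(edge_tables)
    table = pd.concat(frames, ignore_index=True)

    is_ppi = table["interaction_type"] == "ppi"
    conf = pd.to_numeric(table["confidence"], errors="coerce")
    keep = ~is_ppi | (conf > ppi_conf_min)          # strict ">"
    keep &= table["source"] != table["target"]      # no self-loops
    table = table.loc[keep]

    types: dict[str, str] = {}
    for col, tcol in (("source", "source_type"), ("target", "target_type")):
        for node, t in zip(table[col], table[tcol]):
            prev = types.setdefault(node, t)
            if prev != t:
                raise ValueError(
                    f"conflicting node_type for '{node}': {prev} vs {t}")

    g = nx.Graph()
    for node, t in types.items():
        g.add_node(node, node_type=t)
    for row in table.itertuples(index=False):
        u, v = row.source, row.target
        c = float(row.confidence) if pd.notna(row.confidence) else None
        if g.has_edge(u, v):
            data = g.edges[u, v]
            data["interaction_types"] = tuple(sorted(
                set(data["interaction_types"]) | {row.interaction_type}))
            if c is not None:
                data["confidence"] = max(c, data.get("confidence") or c)
        else:
            g.add_edge(u, v, interaction_types=(row.interaction_type,),
                       confidence=c)
    return g


def network_to_table(net: nx.Graph) -> pd.DataFrame:
    """One row per edge; provenance joined with ';'.  Inverse of build_network
    up to layer splitting (re-building the table yields an identical graph)."""
    rows = []
    for u, v, data in sorted(net.edges(data=True)):
        a, b = sorted((u, v))
        rows.append((a, b, net.nodes[a]["node_type"], net.nodes[b]["node_type"],
                     ";".join(data["interaction_types"]), data.get("confidence")))
    return pd.DataFrame(rows, columns=["source", "target", "source_type",
                                       "target_type", "interaction_type",
                                       "confidence"])


def degree_stats(net: nx.Graph) -> dict:
    """Degree histogram plus a log-log least-squares power-law fit.

    The fit regresses log10(count) on log10(degree) over nonzero histogram
    bins with degree >= 1; for a regular graph (one distinct degree) the fit
    is undefined and slope/r2 are None.
    """
    degrees = np.array([d for _, d in net.degree()])
    degrees = degrees[degrees >= 1]
    ks, counts = np.unique(degrees, return_counts=True)
    hist = {int(k): int(c) for k, c in zip(ks, counts)}
    if len(ks) < 2:
        return {"histogram": hist, "slope": None, "intercept": None, "r2": None}
    x, y = np.log10(ks), np.log10(counts)
    slope, intercept = np.polyfit(x, y, 1)
    yhat = slope * x + intercept
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else None
    return {"histogram": hist, "slope": float(slope),
            "intercept": float(intercept), "r2": r2}


def largest_component(net: nx.Graph) -> nx.Graph:
    """Induced subgraph on the largest connected component.

    Size ties are broken in favour of the component containing the
    lexicographically smallest node id, for determinism.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    comps = list(nx.connected_components(net))
    max_size = max(len(c) for c in comps)
    best = min((c for c in comps if len(c) == max_size), key=min)
    return net.subgraph(best).copy()
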