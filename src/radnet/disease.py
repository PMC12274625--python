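"""Disease association of key molecules and category-level roll-up.

Per disease, the overlap between the key molecules and the disease's
annotated molecules is tested with the hypergeometric upper tail against a
universe of annotated network molecules; BH adjustment across diseases with
adjusted p <= 0.05 defines the significant (radiation-related) diseases.
Categories are then tested the same way one level up: how many of a
category's diseases are significant, against the background of all testable
diseases.
"""

from __future__ import annotations

import logging

import networkx as nx
import pandas as pd

from .diffexpr import bh_adjust
from .enrich import hypergeom_upper

__all__ = ["disease_enrichment", "category_rollup", "disease_subnetwork",
           "disease_band"]

logger = logging.getLogger(__name__)


def disease_enrichment(key_molecules, assoc: pd.DataFrame, universe,
                       *, alpha: float = 0.05) -> pd.DataFrame:
    """Per-disease hypergeometric enrichment of the key molecules.

    ``universe`` is the set of molecules eligible for annotation (by
    default callers pass the annotated molecules of the network).
    """
    uni = set(universe)
    key = set(key_molecules) & uni
    if not key:
        raise ValueError("no key molecule lies in the annotation universe")
    ann = assoc[assoc["molecule_id"].isin(uni)]
    rows = []
    for did, group in sorted(ann.groupby("disease_id")):
        members = set(group["molecule_id"])
        k = len(key & members)
        rows.append((did, k, len(members), len(key), len(uni),
                     hypergeom_upper(k, len(members), len(key), len(uni))))
    out = pd.DataFrame(rows, columns=["disease_id", "k", "K", "n", "N", "p_raw"])
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] <= alpha
    return out


def category_rollup(disease_results: pd.DataFrame, cat_map: pd.DataFrame,
                    *, alpha: float = 0.05) -> pd.DataFrame:
    """Hypergeometric test of significant-disease counts per category.

    N = all tested diseases, K = diseases in the category, n = significant
    diseases, k = significant diseases in the category; BH across
    categories.
    """
    cats = cat_map.set_index("disease_id")["category_id"]
    missing = set(disease_results["disease_id"]) - set(cats.index)
    if missing:
        raise ValueError(f"disease(s) missing from category map: {sorted(missing)[:5]}")
    df = disease_results.copy()
    df["category_id"] = cats.loc[df["disease_id"]].values
    n_total = len(df)
    n_sig = int(df["significant"].sum())
    rows = []
    for cid, group in sorted(df.groupby("category_id")):
        big_k = len(group)
        k = int(group["significant"].sum())
        rows.append((cid, big_k, k,
                     hypergeom_upper(k, big_k, n_sig, n_total)))
    out = pd.DataFrame(rows, columns=["category_id", "n_diseases",
                                      "n_significant", "p_raw"])
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] <= alpha
    return out


def disease_band(count: int) -> str:
    """Bands used to annotate nodes: '1', '2-5' or '>5' diseases."""
    if count > 5:
        return ">5"
    if count >= 2:
        return "2-5"
    return "1"


def disease_subnetwork(key_net: nx.Graph, assoc: pd.DataFrame,
                       cat_map: pd.DataFrame, category: str) -> nx.Graph:
    """Induced subgraph on key molecules annotated to the category's diseases.

    Each node carries ``disease_count`` (distinct diseases of the category)
    and the display ``band``.
    """
    cat_diseases = set(cat_map.loc[cat_map["category_id"] == category,
                                   "disease_id"])
    if not cat_diseases:
        raise ValueError(f"unknown category '{category}'")
    ann = assoc[assoc["disease_id"].isin(cat_diseases)]
    counts = ann.groupby("molecule_id")["disease_id"].nunique()
    nodes = [n for n in key_net.nodes if n in counts.index]
    if not nodes:
        logger.warning("no key molecule annotated to category %s", category)
        return nx.Graph()
    sub = key_net.subgraph(nodes).copy()
    for n in sub.nodes:
        c = int(counts[n])
        sub.nodes[n]["disease_count"] = c
        sub.nodes[n]["band"] = disease_band(c)
    return sub
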