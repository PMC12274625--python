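"""Hypergeometric gene-set enrichment with BH correction.

A query set of molecules is tested against every set of a GMT-style
collection: with N the universe size, K the set size, n the query size and
k the observed overlap (all after restriction to the universe), the
enrichment p-value is the upper tail P(X >= k) of a hypergeometric draw.
Two significance policies mirror common practice: 'raw' (used for the
standard-set validation of key molecules and for module-level calls) and
'adjusted' (BH across sets; used everywhere else).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust
from .mcode import Module

__all__ = [
    "hypergeom_upper", "enrich_query", "count_significant", "enrich_modules",
]


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_query(query, collection: dict[str, set], universe,
                 *, p_policy: str = "adjusted", alpha: float = 0.05,
                 ) -> pd.DataFrame:
    """Test a molecule set against every gene set of a collection.

    Query and sets are restricted to the universe before counting.
    Significance follows ``p_policy``: 'raw' compares p_raw to alpha,
    'adjusted' compares the BH-adjusted value.
    """
    if p_policy not in {"raw", "adjusted"}:
        raise ValueError(f"unknown p_policy '{p_policy}'")
    uni = set(universe)
    q = set(query) & uni
    if not q:
        raise ValueError("query is empty after restriction to the universe")
    rows = []
    for name in sorted(collection):
        members = set(collection[name]) & uni
        k = len(q & members)
        rows.append((name, k, len(members), len(q), len(uni),
                     hypergeom_upper(k, len(members), len(q), len(uni))))
    out = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p_raw"])
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    p_eff = out["p_raw"] if p_policy == "raw" else out["p_adj"]
    out["significant"] = p_eff <= alpha
    return out


def count_significant(results: pd.DataFrame) -> int:
    """Breadth statistic: number of sets flagged significant."""
    return int(results["significant"].sum())


def enrich_modules(modules: list[Module], collection: dict[str, set],
                   universe, node_types: dict[str, str],
                   *, alpha: float = 0.05) -> pd.DataFrame:
    """Flag modules enriched in at least one set of the collection.

    Only protein-coding members (node_type != miRNA) enter the test; a
    module is 'key' iff its minimum raw hypergeometric p across sets is
    below alpha.
    """
    uni = set(universe)
    rows = []
    for mod in modules:
        coding = [n for n in mod.nodes if node_types.get(n) != "miRNA"]
        q = set(coding) & uni
        if not q:
            rows.append((mod.id, mod.score, len(mod.nodes), np.nan, None, False))
            continue
        best_p, best_set = np.inf, None
        for name in sorted(collection):
            members = set(collection[name]) & uni
            p = hypergeom_upper(len(q & members), len(members), len(q), len(uni))
            if p < best_p:
                best_p, best_set = p, name
        rows.append((mod.id, mod.score, len(mod.nodes), best_p, best_set,
                     bool(best_p < alpha)))
    return pd.DataFrame(rows, columns=["module_id", "score", "n_nodes",
                                       "min_p_raw", "best_set", "is_key"])
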