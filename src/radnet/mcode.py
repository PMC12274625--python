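"""Dense-module detection by the molecular complex detection (MCODE) scheme.

Three phases over a simple undirected graph:

1. *Vertex weighting* — each node is scored by the highest k-core of its
   closed neighbourhood: weight = k_max x density of that core subgraph,
   with density 2E / (V (V - 1)).  Nodes below the degree cutoff weigh 0.
2. *Complex prediction* — starting from the unused highest-weight vertex, a
   module grows outward admitting neighbours whose weight exceeds
   seed_weight x (1 - node_score_cutoff), to a bounded depth.  Modules are
   node-disjoint.
3. *Post-processing* — the optional haircut trims the module to its 2-core;
   modules whose subgraph does not reach the k-core threshold are dropped.
   An optional fluff step adds boundary neighbours with dense
   neighbourhoods (off by default, matching plugin defaults).

A module's score is its subgraph density times its node count, so a
k-clique scores exactly k.  Ties (seed order, neighbour visit order) are
broken by descending weight then ascending node id for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

__all__ = ["MCODEParams", "Module", "vertex_weight", "find_modules", "filter_modules"]


@dataclass(frozen=True)
class MCODEParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1
    max_depth: int = 100
    min_module_score: float = 3.0


@dataclass
class Module:
    id: int
    nodes: tuple[str, ...]
    score: float
    seed: str


def _density(g: nx.Graph) -> float:
    v = g.number_of_nodes()
    if v <= 1:
        return 0.0
    return 2.0 * g.number_of_edges() / (v * (v - 1))


def _highest_k_core(g: nx.Graph) -> tuple[int, nx.Graph]:
    """Max core number and the induced subgraph of nodes attaining it."""
    core = nx.core_number(g)
    k_max = max(core.values())
    sub = g.subgraph([n for n, k in core.items() if k >= k_max])
    return k_max, sub


def vertex_weight(graph: nx.Graph, node, degree_cutoff: int = 2) -> float:
    """Core-weighted local density of ``node``'s closed neighbourhood."""
    if graph.degree(node) < degree_cutoff:
        return 0.0
    closed = graph.subgraph([node, *graph.neighbors(node)])
    k_max, core_sub = _highest_k_core(closed)
    return k_max * _density(core_sub)


def find_modules(graph: nx.Graph, params: MCODEParams = MCODEParams(),
                 ) -> list[Module]:
    """Greedy seeded expansion into node-disjoint dense modules.

    Returned modules are sorted by descending score, then ascending smallest
    node id; each carries score = density x node count of its induced
    subgraph after post-processing.
    """
    if graph.number_of_nodes() == 0:
        return []
    weights = {n: vertex_weight(graph, n, params.degree_cutoff)
               for n in graph.nodes}
    order = sorted(graph.nodes, key=lambda n: (-weights[n], str(n)))
    used: set = set()
    raw_modules: list[tuple[set, str]] = []

    for seed in order:
        if seed in used or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt = []
            for node in frontier:
                for nb in sorted(graph.neighbors(node),
                                 key=lambda n: (-weights[n], str(n))):
                    if nb in members or nb in used:
                        continue
                    if weights[nb] > threshold:
                        members.add(nb)
                        nxt.append(nb)
            frontier = nxt
            depth += 1
        used |= members
        raw_modules.append((members, seed))

    modules: list[Module] = []
    for members, seed in raw_modules:
        sub = graph.subgraph(members).copy()
        if params.haircut:
            sub = nx.k_core(sub, 2)
        if sub.number_of_nodes() == 0:
            continue
        if not nx.is_connected(sub):
            # haircut can sever weakly attached parts; keep the seed's side
            comps = list(nx.connected_components(sub))
            keep = next((c for c in comps if seed in c),
                        sorted(comps, key=lambda c: (-len(c), min(map(str, c))))[0])
            sub = sub.subgraph(keep).copy()
        if params.fluff:
            extra = set()
            for node in list(sub.nodes):
                for nb in graph.neighbors(node):
                    if nb in sub or nb in used or nb in extra:
                        continue
                    closed = graph.subgraph([nb, *graph.neighbors(nb)])
                    if _density(closed) > params.fluff_density:
                        extra.add(nb)
            if extra:
                used |= extra
                sub = graph.subgraph(set(sub.nodes) | extra).copy()
        # discard modules that do not reach the k-core threshold
        if max(nx.core_number(sub).values(), default=0) < params.k_core:
            continue
        score = _density(sub) * sub.number_of_nodes()
        modules.append(Module(0, tuple(sorted(sub.nodes, key=str)), score, seed))

    modules.sort(key=lambda mo: (-mo.score, str(mo.nodes[0])))
    for i, mo in enumerate(modules, start=1):
        mo.id = i
    return modules


def filter_modules(modules: list[Module], min_module_score: float = 3.0,
                   ) -> list[Module]:
    """Keep modules scoring strictly above the threshold."""
    return [m for m in modules if m.score > min_module_score]
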