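"""Dense-module detection on PPI networks (MCODE) and module-miRNA association.

The three MCODE stages:

1. *Vertex weighting* — each vertex's weight is k x density of the highest
   k-core of its closed neighborhood (the vertex plus its neighbors); for
   a vertex inside an isolated k-clique this gives (k-1) x 1. Vertices
   below the degree cutoff get weight 0.
2. *Complex prediction* — starting from the highest-weight unvisited seed,
   neighbors whose weight is within ``node_score_cutoff`` of the seed
   weight (w >= w_seed * (1 - cutoff)) are admitted breadth-first, up to
   ``max_depth`` hops; vertices join at most one complex.
3. *Post-processing* — complexes lacking a ``k_core``-core are discarded.
   Optional haircut (strip degree-1 vertices) and fluff are off by
   default. The module score is density x member count; modules are
   returned by descending score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .model import EdgeTable, ValidationError


@dataclass
class MCODEModule:
    members: frozenset[str]
    score: float
    seed_vertex: str

    def __len__(self) -> int:
        return len(self.members)


def _density(G: nx.Graph) -> float:
    n = G.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * G.number_of_edges() / (n * (n - 1))


def vertex_weights(G: nx.Graph, degree_cutoff: int = 2) -> dict[str, float]:
    """MCODE stage-1 weights: highest-k-core density of the closed neighborhood."""
    weights: dict[str, float] = {}
    for v in G.nodes:
        if G.degree(v) < degree_cutoff:
            weights[v] = 0.0
            continue
        H = G.subgraph(set(G[v]) | {v})
        core_num = nx.core_number(H)
        k = max(core_num.values())
        if k == 0:
            weights[v] = 0.0
            continue
        core = H.subgraph([u for u, c in core_num.items() if c >= k])
        weights[v] = k * _density(core)
    return weights


def ppi_graph(ppi: EdgeTable, confidence_min: float = 0.4) -> nx.Graph:
    """Undirected simple graph of physical interactions at/above a confidence."""
    df = ppi.table
    scores = pd.to_numeric(df["score"], errors="coerce")
    kept = df[scores >= confidence_min]
    G = nx.Graph()
    for row in kept.itertuples(index=False):
        if row.source_id != row.target_id:
            G.add_edge(row.source_id, row.target_id)
    return G


def mcode_cluster(
    ppi: EdgeTable,
    confidence_min: float = 0.4,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
    haircut: bool = False,
    fluff: bool = False,
    fluff_density: float = 0.1,
) -> list[MCODEModule]:
    """Run MCODE on a confidence-filtered PPI edge table.

    Deterministic for a given input: seeds are taken in descending weight
    with ties broken by vertex id, and neighbor admission iterates in
    sorted order.
    """
    if degree_cutoff < 1 or k_core < 1 or max_depth < 1:
        raise ValidationError("MCODE parameters must be positive")
    if not (0.0 <= node_score_cutoff <= 1.0):
        raise ValidationError("node_score_cutoff must lie in [0, 1]")
    G = ppi_graph(ppi, confidence_min)
    if G.number_of_edges() == 0:
        warnings.warn("no PPI edges at or above the confidence cutoff", stacklevel=2)
        return []

    w = vertex_weights(G, degree_cutoff)
    order = sorted(G.nodes, key=lambda v: (-w[v], v))
    visited: set[str] = set()
    complexes: list[tuple[set[str], str]] = []
    for seed in order:
        if seed in visited or w[seed] <= 0:
            continue
        threshold = w[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for u in frontier:
                for nb in sorted(G[u]):
                    if nb in visited or nb in members:
                        continue
                    if w[nb] >= threshold:
                        members.add(nb)
                        visited.add(nb)
                        nxt.append(nb)
            frontier = nxt
            depth += 1
        complexes.append((members, seed))

    modules: list[MCODEModule] = []
    for members, seed in complexes:
        H = G.subgraph(members).copy()
        if nx.k_core(H, k=k_core).number_of_nodes() == 0:
            continue
        if haircut:
            changed = True
            while changed:
                low = [v for v in H.nodes if H.degree(v) < 2]
                changed = bool(low)
                H.remove_nodes_from(low)
            if H.number_of_nodes() == 0:
                continue
        if fluff:
            extra = set()
            for v in list(H.nodes):
                for nb in G[v]:
                    if nb in H or nb in extra:
                        continue
                    nbh = G.subgraph(set(G[nb]) | {nb})
                    if _density(nbh) > fluff_density:
                        extra.add(nb)
            H = G.subgraph(set(H.nodes) | extra).copy()
        score = _density(H) * H.number_of_nodes()
        if score <= 0:
            continue
        modules.append(
            MCODEModule(members=frozenset(H.nodes), score=score, seed_vertex=seed)
        )
    modules.sort(key=lambda m: (-m.score, min(m.members)))
    return modules


def select_top_modules_and_associate(
    modules: list[MCODEModule],
    score_min: float,
    targets: EdgeTable,
    mirnas: set[str],
    rule: str = "above_median",
) -> tuple[list[MCODEModule], pd.Series, set[str]]:
    """Keep modules scoring above ``score_min`` and associate miRNAs to them.

    A miRNA's association is the number of selected-module member genes it
    targets, summed over modules. The model-2 candidate set contains the
    miRNAs whose association exceeds the configured rule (default: above
    the median association among the given miRNAs).
    """
    if score_min <= 0:
        raise ValidationError("score_min must be > 0")
    selected = [m for m in modules if m.score > score_min]
    df = targets.table
    sub = df[df["source_id"].isin(mirnas)]
    target_sets = {
        m: set(g.tolist()) if hasattr(g, "tolist") else set(g)
        for m, g in sub.groupby("source_id")["target_id"]
    }
    assoc = {}
    for m in sorted(mirnas):
        tset = target_sets.get(m, set())
        assoc[m] = sum(len(tset & mod.members) for mod in selected)
    counts = pd.Series(assoc, name="association").sort_values(
        ascending=False, kind="mergesort"
    )
    if rule == "above_median":
        cut = counts.median()
        model2 = {m for m, c in counts.items() if c > cut}
    else:
        raise ValidationError(f"unknown association rule: {rule!r}")
    return selected, counts, model2
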