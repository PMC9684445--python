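"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities by brute force
(exhaustive enumeration, direct formula evaluation) independently of the
implementation paths they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mirloop.ffl import CoRegNetwork
from mirloop.model import EdgeTable


# ---------------------------------------------------------------------------
# oracles


def bh_stepup_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg by the literal step-up definition:
    adj_p(i) = min over j >= i (in rank order) of min(1, p(j) * m / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, min(1.0, p[idx] * m / rank))
        adj[idx] = running
    return adj


def auc_pair_counting_oracle(scores, labels) -> float:
    """All-pairs AUC with half credit for ties."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    cases = scores[labels]
    ctrls = scores[~labels]
    total = 0.0
    for c in cases:
        for d in ctrls:
            if c > d:
                total += 1.0
            elif c == d:
                total += 0.5
    return total / (len(cases) * len(ctrls))


def _bfs_counts(adj: dict[str, set[str]], s: str) -> tuple[dict, dict]:
    dist = {s: 0}
    sigma = {s: 1.0}
    frontier = [s]
    while frontier:
        nxt = []
        for u in frontier:
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = 0.0
                    nxt.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
        frontier = nxt
    return dist, sigma


def betweenness_oracle(adj: dict[str, set[str]]) -> dict[str, float]:
    """Unnormalized betweenness (no endpoints) by exhaustive shortest-path
    counting: for every unordered pair (s, t) and interior vertex v, the
    fraction of shortest s-t paths through v is
    sigma_s(v) * sigma_t(v) / sigma_s(t) when v lies on a shortest path."""
    nodes = sorted(adj)
    bfs = {v: _bfs_counts(adj, v) for v in nodes}
    bet = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        dist_s, sigma_s = bfs[s]
        for t in nodes[i + 1:]:
            if t not in dist_s:
                continue
            dist_t, sigma_t = bfs[t]
            for v in nodes:
                if v in (s, t) or v not in dist_s or v not in dist_t:
                    continue
                if dist_s[v] + dist_t[v] == dist_s[t]:
                    bet[v] += sigma_s[v] * sigma_t[v] / sigma_s[t]
    return bet




def ffl_triple_scan_oracle(net: CoRegNetwork) -> set[tuple[str, str, str, str]]:
    """Exhaustive (TF, miRNA, gene-role) scan applying the class
    definitions independently of the implementation's enumeration order."""
    E = set(net.edges)
    tfs = [n for n, k in net.node_kinds.items() if k == "TF"]
    mirnas = [n for n, k in net.node_kinds.items() if k == "miRNA"]
    gene_roles = [n for n, k in net.node_kinds.items() if k != "miRNA"]
    out = set()
    for t in tfs:
        for m in mirnas:
            for g in gene_roles:
                if g == t or g == m:
                    continue
                tm, mt = (t, m) in E, (m, t) in E
                tg, mg = (t, g) in E, (m, g) in E
                if not (tg and mg):
                    continue
                if tm and mt:
                    out.add((t, m, g, "composite"))
                elif tm:
                    out.add((t, m, g, "TF-FFL"))
                elif mt:
                    out.add((t, m, g, "miRNA-FFL"))
    return out


def random_coreg_network(rng: np.random.Generator, n_tf=8, n_mirna=8, n_gene=8,
                         p_edge=0.25) -> CoRegNetwork:
    """Random signed co-regulatory network obeying the kind constraints."""
    tfs = [f"T{i}" for i in range(n_tf)]
    mirnas = [f"m{i}" for i in range(n_mirna)]
    genes = [f"g{i}" for i in range(n_gene)]
    kinds = {**{t: "TF" for t in tfs}, **{m: "miRNA" for m in mirnas},
             **{g: "gene" for g in genes}}
    edges = {}
    for t in tfs:
        for v in mirnas + genes + [x for x in tfs if x != t]:
            if rng.random() < p_edge:
                edges[(t, v)] = "activate" if rng.random() < 0.8 else "repress"
    for m in mirnas:
        for v in genes + tfs:
            if rng.random() < p_edge:
                edges[(m, v)] = "repress"
    return CoRegNetwork(node_kinds=kinds, edges=edges)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_bipartite_edges():
    """5 miRNA->gene records: A targets g1,g2; B targets g2,g3,g4."""
    rows = []
    for m, g in [("A", "g1"), ("A", "g2"), ("B", "g2"), ("B", "g3"), ("B", "g4")]:
        rows.append(
            {
                "source_id": m, "source_kind": "miRNA",
                "target_id": g, "target_kind": "gene",
                "relation": "targets", "sign": "repress",
                "origin": "toy", "evidence": "validated_strong", "score": np.nan,
            }
        )
    return EdgeTable(pd.DataFrame(rows))
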