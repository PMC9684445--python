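"""miRNA-centric network topology, centrality grouping and over-representation.

Centralities are computed on the undirected simple graph after iteratively
pruning nodes below a degree cutoff (i.e. restricting to the k-core at the
cutoff). Betweenness is unnormalized shortest-path betweenness without
endpoint counting. Candidate-panel grouping standardizes (degree,
betweenness) per miRNA and cuts a single-linkage dendrogram at a distance
threshold. Over-representation is the hypergeometric upper tail against a
user gene-set collection with Benjamini-Hochberg correction across sets.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from .io import edge_table_to_graph
from .model import EdgeTable, GeneSetCollection, ValidationError


def network_centralities(edges: EdgeTable, min_degree: int = 2) -> pd.DataFrame:
    """Degree and unnormalized betweenness after iterative degree filtering.

    Nodes with degree below ``min_degree`` are removed iteratively until
    stable (the graph's ``min_degree``-core), then betweenness is computed
    on the surviving undirected simple graph.
    """
    if len(edges) == 0:
        raise ValidationError("empty edge list")
    G = edge_table_to_graph(edges, directed=False)
    if min_degree > 0:
        G = nx.k_core(G, k=min_degree)
    bet = nx.betweenness_centrality(G, normalized=False)
    rows = [
        {"node_id": v, "degree": G.degree(v), "betweenness": bet[v]}
        for v in sorted(G.nodes)
    ]
    return pd.DataFrame(rows, columns=["node_id", "degree", "betweenness"]).set_index(
        "node_id"
    )


def group_mirnas_by_topology(stats_df: pd.DataFrame, tau: float = 0.5) -> list[list[str]]:
    """Cluster miRNAs by standardized (degree, betweenness) features.

    Single-linkage agglomeration on z-scored features, cut where the merge
    distance exceeds ``tau``. Groups are ordered by size (descending),
    then mean degree (descending), then smallest member id.
    """
    if len(stats_df) < 2:
        raise ValidationError("need at least 2 miRNAs to group")
    feats = stats_df[["degree", "betweenness"]].to_numpy(dtype=float)
    sd = feats.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (feats - feats.mean(axis=0)) / sd
    linkage = hierarchy.linkage(z, method="single")
    assignment = hierarchy.fcluster(linkage, t=tau, criterion="distance")
    ids = list(stats_df.index)
    groups: dict[int, list[str]] = {}
    for mid, cl in zip(ids, assignment):
        groups.setdefault(cl, []).append(mid)
    degree = stats_df["degree"]
    ordered = sorted(
        (sorted(g) for g in groups.values()),
        key=lambda g: (-len(g), -float(degree.loc[g].mean()), g[0]),
    )
    return ordered


def shared_target_genes(
    targets: EdgeTable, mirnas: set[str], min_mirnas: int = 2
) -> set[str]:
    """Genes targeted by at least ``min_mirnas`` of the given miRNAs."""
    if min_mirnas < 1:
        raise ValidationError("min_mirnas must be >= 1")
    df = targets.table
    sub = df[df["source_id"].isin(mirnas)]
    counts = sub.groupby("target_id")["source_id"].nunique()
    return set(counts[counts >= min_mirnas].index)


def ora_hypergeometric(
    query: set[str], sets: GeneSetCollection, universe: set[str]
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each gene set.

    Every set is intersected with the universe first; p-values are upper
    tails P(X >= overlap) with BH adjustment across sets.
    """
    if not query <= universe:
        raise ValidationError("query must be a subset of the universe")
    N = len(universe)
    n = len(query)
    rows = []
    for name, members in sets.items():
        s = members & universe
        k = len(query & s)
        p = float(stats.hypergeom.sf(k - 1, N, len(s), n)) if s else 1.0
        rows.append(
            {
                "set_name": name,
                "overlap": k,
                "set_size": len(s),
                "query_size": n,
                "universe_size": N,
                "p_value": p,
            }
        )
    out = pd.DataFrame(rows).set_index("set_name")
    out["adj_p"] = multipletests(out["p_value"], method="fdr_bh")[1] if len(out) else []
    return out.sort_values(["p_value", "set_name"], kind="mergesort")
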