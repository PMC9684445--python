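"""Signed TF-miRNA-gene co-regulatory network, FFL enumeration, hub ranking.

A feed-forward loop (FFL) is a three-node motif among a transcription
factor t, a miRNA m and a joint target gene g. Classes are topological and
disjoint (composite takes precedence):

* composite — t and m regulate each other and both regulate g
  (t->m, m->t, t->g, m->g);
* TF-FFL — t is the main regulator (t->m, t->g, m->g), no m->t;
* miRNA-FFL — m is the main regulator (m->t, m->g, t->g), no t->m.

Signs follow the standard assumption: miRNAs always repress their targets;
TFs activate unless the source database annotates repression. Signs are
carried on every edge for interpretation but do not enter classification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .model import EdgeTable, ValidationError, default_sign

logger = logging.getLogger(__name__)

FFL_COLUMNS = ("tf", "mirna", "gene", "ffl_class", "edge_signs")


@dataclass
class CoRegNetwork:
    """Directed signed network over miRNA, TF and gene nodes.

    A TF node keeps kind ``TF`` even when it is itself a regulation
    target (dual-role nodes).
    """

    node_kinds: dict[str, str]
    edges: dict[tuple[str, str], str]  # (source, target) -> sign

    def __post_init__(self) -> None:
        for (u, v), sign in self.edges.items():
            if u not in self.node_kinds or v not in self.node_kinds:
                raise ValidationError(f"edge ({u}, {v}) references unknown node")
            if self.node_kinds[u] == "miRNA" and sign != "repress":
                raise ValidationError(f"miRNA edge ({u}, {v}) must repress")

    def nodes_of_kind(self, kind: str) -> list[str]:
        return sorted(n for n, k in self.node_kinds.items() if k == kind)

    def out_neighbors(self, node: str) -> set[str]:
        return {v for (u, v) in self.edges if u == node}

    def to_graph(self) -> nx.DiGraph:
        G = nx.DiGraph()
        for n, k in self.node_kinds.items():
            G.add_node(n, kind=k)
        for (u, v), sign in self.edges.items():
            G.add_edge(u, v, sign=sign)
        return G


@dataclass
class FFLRecord:
    tf: str
    mirna: str
    gene: str
    ffl_class: str
    edge_signs: dict[tuple[str, str], str] = field(default_factory=dict)

    def triple(self) -> tuple[str, str, str, str]:
        return (self.tf, self.mirna, self.gene, self.ffl_class)


def _merge_edge(
    edges: dict[tuple[str, str], str], key: tuple[str, str], sign: str, source_kind: str
) -> None:
    if source_kind == "miRNA":
        sign = "repress"
    elif sign == "unknown":
        sign = default_sign(source_kind)
    if key in edges and edges[key] != sign:
        logger.warning(
            "sign conflict on edge %s -> %s (%s vs %s); keeping repress",
            key[0], key[1], edges[key], sign,
        )
        edges[key] = "repress"
    else:
        edges[key] = sign


def assemble_coregulatory_network(
    tf_mirna: EdgeTable,
    tf_gene: EdgeTable,
    mirna_gene: EdgeTable,
    keep_mirnas: set[str],
    keep_genes: set[str],
) -> CoRegNetwork:
    """Build the co-regulatory network restricted to the biomarker machinery.

    Nodes: the kept miRNAs, the kept genes, and every TF with an edge to
    (or, via miRNA targeting, from) either. miRNA->TF edges are derived
    from miRNA targets that are TFs. Duplicate edges are merged, an
    annotated repression winning over the activation default.
    """
    if not keep_mirnas or not keep_genes:
        raise ValidationError("keep sets must be non-empty")
    tf_ids = set(tf_mirna.table["source_id"]) | set(tf_gene.table["source_id"])

    edges: dict[tuple[str, str], str] = {}
    node_kinds: dict[str, str] = {}

    # which TFs connect to the kept material
    connected_tfs: set[str] = set()
    for row in tf_mirna.table.itertuples(index=False):
        if row.target_id in keep_mirnas:
            connected_tfs.add(row.source_id)
    for row in tf_gene.table.itertuples(index=False):
        if row.target_id in keep_genes:
            connected_tfs.add(row.source_id)
    for row in mirna_gene.table.itertuples(index=False):
        if row.source_id in keep_mirnas and row.target_id in tf_ids:
            connected_tfs.add(row.target_id)

    for t in connected_tfs:
        node_kinds[t] = "TF"
    for m in keep_mirnas:
        node_kinds[m] = "miRNA"
    for g in keep_genes - connected_tfs:
        node_kinds[g] = "gene"

    for row in tf_mirna.table.itertuples(index=False):
        if row.source_id in connected_tfs and row.target_id in keep_mirnas:
            _merge_edge(edges, (row.source_id, row.target_id), row.sign, "TF")
    for row in tf_gene.table.itertuples(index=False):
        if row.source_id in connected_tfs and (
            row.target_id in keep_genes or row.target_id in connected_tfs
        ):
            if row.source_id == row.target_id:
                continue
            _merge_edge(edges, (row.source_id, row.target_id), row.sign, "TF")
    for row in mirna_gene.table.itertuples(index=False):
        if row.source_id in keep_mirnas and (
            row.target_id in keep_genes or row.target_id in connected_tfs
        ):
            _merge_edge(edges, (row.source_id, row.target_id), row.sign, "miRNA")

    return CoRegNetwork(node_kinds=node_kinds, edges=edges)


def enumerate_and_classify_ffls(net: CoRegNetwork) -> list[FFLRecord]:
    """Enumerate every qualifying (TF, miRNA, gene) triple with its class.

    Each qualifying triple receives exactly one class, composite taking
    precedence. The gene role may be filled by a TF node that is itself a
    regulation target, but never by the triple's own TF (degenerate) or a
    miRNA node. The output is sorted and independent of edge-list order.
    """
    edge_set = set(net.edges)
    tfs = net.nodes_of_kind("TF")
    mirnas = net.nodes_of_kind("miRNA")
    gene_roles = set(net.nodes_of_kind("gene")) | set(tfs)

    records: list[FFLRecord] = []
    for t in tfs:
        t_out = net.out_neighbors(t)
        for m in mirnas:
            tm = (t, m) in edge_set
            mt = (m, t) in edge_set
            if not (tm or mt):
                continue
            m_out = net.out_neighbors(m)
            shared = (t_out & m_out & gene_roles) - {t, m}
            for g in sorted(shared):
                if tm and mt:
                    cls = "composite"
                elif tm:
                    cls = "TF-FFL"
                else:
                    cls = "miRNA-FFL"
                signs = {}
                for key in ((t, m), (m, t), (t, g), (m, g)):
                    if key in edge_set:
                        signs[key] = net.edges[key]
                records.append(FFLRecord(tf=t, mirna=m, gene=g, ffl_class=cls, edge_signs=signs))
    records.sort(key=lambda r: (r.tf, r.mirna, r.gene))
    return records


def ffl_class_counts(records: list[FFLRecord]) -> dict[str, int]:
    counts = {"TF-FFL": 0, "miRNA-FFL": 0, "composite": 0}
    for r in records:
        counts[r.ffl_class] += 1
    counts["total"] = len(records)
    return counts


def ffl_records_to_frame(records: list[FFLRecord]) -> pd.DataFrame:
    rows = [
        {
            "tf": r.tf,
            "mirna": r.mirna,
            "gene": r.gene,
            "ffl_class": r.ffl_class,
            "edge_signs": ";".join(
                f"{u}->{v}:{s}" for (u, v), s in sorted(r.edge_signs.items())
            ),
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(FFL_COLUMNS))


def rank_hubs(
    net: CoRegNetwork, top_k: int = 5
) -> tuple[list[str], list[str], list[str]]:
    """Top TFs and top genes by total degree, plus dual-role TF nodes.

    Degree is in-degree + out-degree on the co-regulatory network;
    rankings are per node kind with ties broken by id. Dual-role nodes
    are TFs with at least one incoming regulation edge.
    """
    if top_k < 1:
        raise ValidationError("top_k must be >= 1")
    degree: dict[str, int] = {n: 0 for n in net.node_kinds}
    incoming: dict[str, int] = {n: 0 for n in net.node_kinds}
    for u, v in net.edges:
        degree[u] += 1
        degree[v] += 1
        incoming[v] += 1

    def ranked(kind: str) -> list[str]:
        nodes = net.nodes_of_kind(kind)
        return sorted(nodes, key=lambda n: (-degree[n], n))[:top_k]

    dual = sorted(t for t in net.nodes_of_kind("TF") if incoming[t] >= 1)
    return ranked("TF"), ranked("gene"), dual
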