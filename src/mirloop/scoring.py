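"""NSR/TFP biomarker scoring on the disease-specific miRNA-mRNA network.

Two network features identify candidate biomarker miRNAs:

* NSR (number of single-line regulations): how many of a miRNA's target
  genes are regulated by that miRNA alone (gene in-degree 1 in the
  bipartite network). Significance comes from a degree-preserving
  rewiring (checkerboard-swap) permutation null.
* TFP (transcription factor percentage): the fraction of a miRNA's
  targets that are transcription factors. Significance is the
  hypergeometric upper tail, drawing the miRNA's target count from the
  network's gene universe with the network's TF genes as successes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import EdgeTable, TFCatalog, ValidationError

SCORE_COLUMNS = ("nsr", "p_nsr", "tfp", "p_tfp", "n_targets")


@dataclass
class MirnaMrnaNetwork:
    """Bipartite miRNA -> gene targeting network restricted to the DEMs."""

    mirnas: set[str]
    genes: set[str]
    edges: set[tuple[str, str]]
    tf_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for m, g in self.edges:
            if m not in self.mirnas or g not in self.genes:
                raise ValidationError(f"edge ({m}, {g}) endpoint missing from node sets")
        if self.mirnas & self.genes:
            raise ValidationError("miRNA and gene id sets overlap (network must be bipartite)")

    def targets_of(self, mirna: str) -> set[str]:
        return {g for m, g in self.edges if m == mirna}

    def gene_indegree(self) -> dict[str, int]:
        deg: dict[str, int] = {g: 0 for g in self.genes}
        for _, g in self.edges:
            deg[g] += 1
        return deg


def build_disease_network(
    dems: set[str], targets: EdgeTable, tfs: TFCatalog | None = None
) -> MirnaMrnaNetwork:
    """Induce the miRNA-mRNA network on the DEMs and their target genes.

    DEMs with no recorded targets are retained as isolated miRNAs.
    """
    if not dems:
        raise ValidationError("empty DEM set")
    df = targets.table
    bad = df["relation"] != "targets"
    if bad.any():
        raise ValidationError("target table contains non-'targets' relations")
    sub = df[df["source_id"].isin(dems)]
    edges = set(zip(sub["source_id"], sub["target_id"]))
    genes = {g for _, g in edges}
    tf_flags = genes & set(tfs.tf_ids) if tfs is not None else set()
    return MirnaMrnaNetwork(mirnas=set(dems), genes=genes, edges=edges, tf_flags=tf_flags)


def nsr_counts(net: MirnaMrnaNetwork) -> dict[str, int]:
    """Per-miRNA count of exclusively-regulated target genes."""
    indeg = net.gene_indegree()
    nsr = {m: 0 for m in net.mirnas}
    for m, g in net.edges:
        if indeg[g] == 1:
            nsr[m] += 1
    return nsr


def _rewire(
    sources: np.ndarray, targets: np.ndarray, edge_set: set[tuple[int, int]],
    n_swaps: int, rng: np.random.Generator,
) -> None:
    """In-place checkerboard swaps preserving both degree sequences."""
    n = len(sources)
    picks = rng.integers(0, n, size=(n_swaps, 2))
    for a, b in picks:
        if a == b:
            continue
        sa, ta = sources[a], targets[a]
        sb, tb = sources[b], targets[b]
        if sa == sb or ta == tb:
            continue
        if (sa, tb) in edge_set or (sb, ta) in edge_set:
            continue
        edge_set.discard((sa, ta))
        edge_set.discard((sb, tb))
        edge_set.add((sa, tb))
        edge_set.add((sb, ta))
        targets[a], targets[b] = tb, ta


def score_nsr_tfp(
    net: MirnaMrnaNetwork,
    null_permutations: int = 1000,
    seed: int = 0,
    swaps_per_edge: int = 10,
) -> pd.DataFrame:
    """Score every miRNA in the network by NSR and TFP with significance.

    ``p_nsr`` is the permutation upper tail of NSR under degree-preserving
    rewiring of the bipartite edges (``swaps_per_edge * |E|`` attempted
    checkerboard swaps per replicate), with the add-one pseudo-count
    ``(1 + #{null >= observed}) / (1 + permutations)``. ``p_tfp`` is the
    exact hypergeometric upper tail. miRNAs without targets get both
    scores 0 and p-values 1.
    """
    if null_permutations < 100:
        raise ValidationError("null_permutations must be >= 100 for p_nsr")
    if not net.tf_flags:
        raise ValidationError("TFP requested with an empty TF catalog")

    mirnas = sorted(net.mirnas)
    m_index = {m: i for i, m in enumerate(mirnas)}
    genes = sorted(net.genes)
    g_index = {g: i for i, g in enumerate(genes)}

    observed_nsr = nsr_counts(net)
    n_targets = {m: 0 for m in mirnas}
    tf_hits = {m: 0 for m in mirnas}
    for m, g in net.edges:
        n_targets[m] += 1
        if g in net.tf_flags:
            tf_hits[m] += 1

    N, K = len(genes), len(net.tf_flags)
    rows = []
    for m in mirnas:
        nt = n_targets[m]
        tfp = tf_hits[m] / nt if nt else 0.0
        p_tfp = float(stats.hypergeom.sf(tf_hits[m] - 1, N, K, nt)) if nt else 1.0
        rows.append((m, observed_nsr[m], np.nan, tfp, p_tfp, nt))
    result = pd.DataFrame(
        rows, columns=["mirna_id", *SCORE_COLUMNS]
    ).set_index("mirna_id")

    # permutation null for NSR
    rng = np.random.default_rng(seed)
    base_src = np.array([m_index[m] for m, _ in sorted(net.edges)])
    base_tgt = np.array([g_index[g] for _, g in sorted(net.edges)])
    n_edges = len(base_src)
    exceed = np.zeros(len(mirnas), dtype=int)
    obs = np.array([observed_nsr[m] for m in mirnas])
    for _ in range(null_permutations):
        src = base_src.copy()
        tgt = base_tgt.copy()
        edge_set = set(zip(src.tolist(), tgt.tolist()))
        _rewire(src, tgt, edge_set, swaps_per_edge * n_edges, rng)
        indeg = np.bincount(tgt, minlength=len(genes))
        single = indeg[tgt] == 1
        null_nsr = np.bincount(src[single], minlength=len(mirnas))
        exceed += null_nsr >= obs
    p_nsr = (1.0 + exceed) / (1.0 + null_permutations)
    result["p_nsr"] = np.where(result["n_targets"] > 0, p_nsr, 1.0)
    return result


def predict_biomarkers(scores: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """miRNAs significant on both NSR and TFP, ranked by descending NSR.

    Ties break by ascending p_nsr, then id.
    """
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")
    hits = scores[(scores["p_nsr"] < alpha) & (scores["p_tfp"] < alpha)]
    order = hits.assign(_id=hits.index).sort_values(
        by=["nsr", "p_nsr", "_id"], ascending=[False, True, True], kind="mergesort"
    )
    return list(order.index)
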