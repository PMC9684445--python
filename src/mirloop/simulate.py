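"""Synthetic expression and regulatory-network generators with planted truth.

The generators emulate the kind of data the pipeline consumes in practice —
serum miRNA microarray profiles (a few thousand features, 100–200 samples
per group, up-regulated disease features), multi-database miRNA-target /
TF-miRNA / TF-gene edge exports, and a STRING-style PPI edge list — while
recording the exact planted ground truth (differential features and their
shifts, biomarker miRNAs with their true single-line-regulation counts and
TF-target fractions, feed-forward-loop triples with their classes, dense
PPI modules) so every downstream stage can be tested for recovery.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    EdgeTable,
    ExpressionMatrix,
    SampleSheet,
    TFCatalog,
    ValidationError,
)

FFL_CLASSES = ("TF-FFL", "miRNA-FFL", "composite")


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded by the generators."""

    seed: int
    de_features: dict[str, float] = field(default_factory=dict)
    biomarker_mirnas: dict[str, dict] = field(default_factory=dict)
    planted_ffls: list[tuple[str, str, str, str]] = field(default_factory=list)
    planted_modules: list[set[str]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "de_features": self.de_features,
            "biomarker_mirnas": self.biomarker_mirnas,
            "planted_ffls": [list(t) for t in self.planted_ffls],
            "planted_modules": [sorted(m) for m in self.planted_modules],
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            seed=d["seed"],
            de_features=d["de_features"],
            biomarker_mirnas=d["biomarker_mirnas"],
            planted_ffls=[tuple(t) for t in d["planted_ffls"]],
            planted_modules=[set(m) for m in d["planted_modules"]],
            params=d["params"],
        )


def _mirna_id(i: int) -> str:
    return f"mir-{i + 1:04d}"


def _gene_id(i: int) -> str:
    return f"G{i + 1:05d}"


def _protein_id(i: int) -> str:
    return f"P{i + 1:04d}"


# ---------------------------------------------------------------------------
# case/control expression


def gen_case_control_expression(
    n_features: int = 2500,
    n_case: int = 150,
    n_control: int = 150,
    n_de: int = 100,
    shift_range: tuple[float, float] = (1.0, 3.0),
    noise_sd: float = 0.5,
    distortion: bool = False,
    seed: int = 0,
    cohort: str = "synthetic",
    baseline_mean: float = 8.0,
    baseline_sd: float = 2.0,
) -> tuple[ExpressionMatrix, SampleSheet, SyntheticTruth]:
    """Simulate a serum-profile-like log2 expression matrix.

    Per-feature baseline means are Normal(``baseline_mean``, ``baseline_sd``)
    log2 units with Gaussian cell noise; ``n_de`` randomly chosen features
    are shifted *upward* in cases by a per-feature amount drawn uniformly
    from ``shift_range``. With ``distortion`` on, every sample is passed
    through a random strictly increasing affine-plus-cube map, which
    quantile normalization must undo.
    """
    if n_features <= 0 or n_case <= 0 or n_control <= 0:
        raise ValidationError("feature and sample counts must be positive")
    if n_de < 0 or n_de > n_features:
        raise ValidationError("n_de must lie in [0, n_features]")
    lo, hi = shift_range
    if n_de and not (0.5 <= lo <= hi <= 4.0):
        raise ValidationError("shift_range must lie within [0.5, 4] log2 units")

    rng = np.random.default_rng(seed)
    features = [_mirna_id(i) for i in range(n_features)]
    samples = [f"case{i + 1:03d}" for i in range(n_case)] + [
        f"ctrl{i + 1:03d}" for i in range(n_control)
    ]

    baseline = rng.normal(baseline_mean, baseline_sd, size=n_features)
    X = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_features, n_case + n_control))

    de_idx = rng.choice(n_features, size=n_de, replace=False) if n_de else np.array([], int)
    shifts = rng.uniform(lo, hi, size=n_de)
    X[de_idx, :n_case] += shifts[:, None]

    if distortion:
        # per-sample strictly increasing map a + b*x + c*x^3, b, c > 0
        a = rng.uniform(-1.0, 1.0, size=X.shape[1])
        b = rng.uniform(0.8, 1.2, size=X.shape[1])
        c = rng.uniform(5e-4, 2e-3, size=X.shape[1])
        X = a[None, :] + b[None, :] * X + c[None, :] * X**3

    matrix = ExpressionMatrix(pd.DataFrame(X, index=features, columns=samples))
    sheet = SampleSheet(
        pd.DataFrame(
            {
                "sample_id": samples,
                "group": ["case"] * n_case + ["control"] * n_control,
                "cohort": cohort,
            }
        )
    )
    truth = SyntheticTruth(
        seed=seed,
        de_features={features[i]: float(s) for i, s in zip(de_idx, shifts)},
        params={
            "n_features": n_features,
            "n_case": n_case,
            "n_control": n_control,
            "n_de": n_de,
            "shift_range": list(shift_range),
            "noise_sd": noise_sd,
            "distortion": distortion,
            "cohort": cohort,
        },
    )
    return matrix, sheet, truth


# ---------------------------------------------------------------------------
# regulatory network with planted biomarkers and FFLs


def _edge_records(
    pairs: list[tuple[str, str]],
    source_kind: str,
    target_kind: str,
    relation: str,
    signs: list[str] | None = None,
) -> pd.DataFrame:
    n = len(pairs)
    from .model import default_sign

    return pd.DataFrame(
        {
            "source_id": [p[0] for p in pairs],
            "source_kind": source_kind,
            "target_id": [p[1] for p in pairs],
            "target_kind": target_kind,
            "relation": relation,
            "sign": signs if signs is not None else [default_sign(source_kind)] * n,
            "origin": "synthetic",
            "evidence": "validated_strong",
            "score": np.nan,
        }
    )


def gen_regulatory_truth(
    n_mirna: int = 60,
    n_gene: int = 1000,
    tf_fraction: float = 0.15,
    n_biomarkers: int = 5,
    single_line_boost: int = 30,
    tf_target_boost: float = 0.40,
    n_ffl_per_class: tuple[int, int, int] = (5, 3, 2),
    seed: int = 0,
    shared_targets_per_biomarker: int = 30,
    background_targets_per_mirna: int = 20,
    background_tf_mirna_edges: int = 40,
    background_tf_gene_edges: int = 80,
) -> tuple[EdgeTable, EdgeTable, EdgeTable, TFCatalog, SyntheticTruth]:
    """Simulate miRNA->gene, TF->miRNA and TF->gene tables with planted truth.

    Planted biomarker miRNAs each receive ``single_line_boost`` exclusive
    target genes touched by no other miRNA (their exact true NSR) plus
    ``shared_targets_per_biomarker`` targets guaranteed to be co-targeted,
    with a fraction ``tf_target_boost`` of all their targets drawn from the
    TF catalog. Feed-forward loops are planted on node sets disjoint from
    each other and from the biomarker machinery, wired with exactly the
    edges their class requires; background edges are drawn avoiding any
    pair that would reclassify a planted triple. Set the three
    ``background_*`` knobs to 0 to disable background wiring entirely.
    """
    if not (0.0 < tf_fraction < 1.0):
        raise ValidationError("tf_fraction must lie in (0, 1)")
    if single_line_boost < 0 or tf_target_boost < 0:
        raise ValidationError("boosts must be >= 0")
    if len(n_ffl_per_class) != 3:
        raise ValidationError("n_ffl_per_class must have 3 entries")

    rng = np.random.default_rng(seed)
    mirnas = [_mirna_id(i) for i in range(n_mirna)]
    genes = [_gene_id(i) for i in range(n_gene)]

    n_tf = max(1, round(tf_fraction * n_gene))
    tf_ids = [str(g) for g in rng.choice(genes, size=n_tf, replace=False)]
    tfs = TFCatalog(frozenset(tf_ids))
    non_tf_genes = [g for g in genes if g not in tfs.tf_ids]

    n_ffl_total = sum(n_ffl_per_class)
    if n_biomarkers + n_ffl_total > n_mirna:
        raise ValidationError("planted miRNAs (biomarkers + FFLs) exceed n_mirna")
    if n_ffl_total > n_tf:
        raise ValidationError("planted FFL TFs exceed TF budget")

    per_bm_targets = single_line_boost + shared_targets_per_biomarker
    n_tf_targets = round(tf_target_boost * per_bm_targets)
    if n_biomarkers * per_bm_targets + n_ffl_total > n_gene:
        raise ValidationError("planted genes exceed n_gene budget")
    if n_biomarkers * n_tf_targets > n_tf - n_ffl_total:
        raise ValidationError("planted TF targets exceed TF budget")

    biomarkers = mirnas[:n_biomarkers]
    ffl_mirnas = mirnas[n_biomarkers : n_biomarkers + n_ffl_total]
    background_mirnas = mirnas[n_biomarkers + n_ffl_total :]
    if background_targets_per_mirna and not background_mirnas:
        raise ValidationError("no miRNAs left for background edges")

    mirna_gene_pairs: list[tuple[str, str]] = []
    reserved: set[str] = set()  # genes no background edge may touch
    truth_bm: dict[str, dict] = {}

    tf_pool = [t for t in tf_ids]
    rng.shuffle(tf_pool)
    ffl_tfs = [tf_pool.pop() for _ in range(n_ffl_total)]
    gene_pool = [g for g in non_tf_genes]
    rng.shuffle(gene_pool)

    for m in biomarkers:
        n_tf_excl = min(n_tf_targets, single_line_boost)
        n_tf_shared = n_tf_targets - n_tf_excl
        excl = [tf_pool.pop() for _ in range(n_tf_excl)]
        excl += [gene_pool.pop() for _ in range(single_line_boost - n_tf_excl)]
        shared = [tf_pool.pop() for _ in range(n_tf_shared)]
        shared += [
            gene_pool.pop() for _ in range(shared_targets_per_biomarker - n_tf_shared)
        ]
        reserved.update(excl)
        mirna_gene_pairs += [(m, g) for g in excl + shared]
        # guarantee every shared gene is co-targeted so NSR stays exact
        if background_mirnas:
            co = rng.choice(background_mirnas, size=len(shared))
            mirna_gene_pairs += [(str(c), g) for c, g in zip(co, shared)]
        targets = excl + shared
        n_tf_hit = sum(g in tfs.tf_ids for g in targets)
        truth_bm[m] = {
            "nsr": single_line_boost if background_mirnas else per_bm_targets,
            "n_targets": len(targets),
            "tfp": n_tf_hit / len(targets) if targets else 0.0,
        }
        if not background_mirnas:
            reserved.update(shared)

    # planted FFLs: disjoint node triples, exact class wiring
    tf_mirna_pairs: list[tuple[str, str]] = []
    tf_gene_pairs: list[tuple[str, str]] = []
    planted_ffls: list[tuple[str, str, str, str]] = []
    forbidden_m_to_t: set[tuple[str, str]] = set()
    forbidden_t_to_m: set[tuple[str, str]] = set()
    k = 0
    for cls, count in zip(FFL_CLASSES, n_ffl_per_class):
        for _ in range(count):
            t, m, g = ffl_tfs[k], ffl_mirnas[k], gene_pool.pop()
            reserved.add(g)
            k += 1
            tf_gene_pairs.append((t, g))
            mirna_gene_pairs.append((m, g))
            if cls == "TF-FFL":
                tf_mirna_pairs.append((t, m))
                forbidden_m_to_t.add((m, t))
            elif cls == "miRNA-FFL":
                mirna_gene_pairs.append((m, t))
                forbidden_t_to_m.add((t, m))
            else:  # composite
                tf_mirna_pairs.append((t, m))
                mirna_gene_pairs.append((m, t))
            planted_ffls.append((t, m, g, cls))

    # background wiring, avoiding reserved genes and reclassifying pairs
    existing = set(mirna_gene_pairs)
    open_genes = [g for g in genes if g not in reserved]
    for m in background_mirnas:
        if not background_targets_per_mirna:
            break
        choice = rng.choice(open_genes, size=background_targets_per_mirna, replace=False)
        for g in choice:
            g = str(g)
            if (m, g) in existing or (m, g) in forbidden_m_to_t:
                continue
            existing.add((m, g))
            mirna_gene_pairs.append((m, g))

    bg_tf = [t for t in tf_ids]
    tm_existing = set(tf_mirna_pairs)
    for _ in range(background_tf_mirna_edges):
        t = str(rng.choice(bg_tf))
        m = str(rng.choice(mirnas))
        if (t, m) in tm_existing or (t, m) in forbidden_t_to_m:
            continue
        tm_existing.add((t, m))
        tf_mirna_pairs.append((t, m))
    tg_existing = set(tf_gene_pairs)
    for _ in range(background_tf_gene_edges):
        t = str(rng.choice(bg_tf))
        g = str(rng.choice(genes))
        if t == g or (t, g) in tg_existing:
            continue
        tg_existing.add((t, g))
        tf_gene_pairs.append((t, g))

    # a minority of TF edges carry an explicit repress annotation
    tm_signs = [
        "repress" if rng.random() < 0.15 else "activate" for _ in tf_mirna_pairs
    ]
    tg_signs = [
        "repress" if rng.random() < 0.15 else "activate" for _ in tf_gene_pairs
    ]

    mirna_gene = EdgeTable(
        _edge_records(mirna_gene_pairs, "miRNA", "gene", "targets")
    )
    tf_mirna = EdgeTable(
        _edge_records(tf_mirna_pairs, "TF", "miRNA", "regulates", tm_signs)
    )
    tf_gene = EdgeTable(
        _edge_records(tf_gene_pairs, "TF", "gene", "regulates", tg_signs)
    )

    truth = SyntheticTruth(
        seed=seed,
        biomarker_mirnas=truth_bm,
        planted_ffls=planted_ffls,
        params={
            "n_mirna": n_mirna,
            "n_gene": n_gene,
            "tf_fraction": tf_fraction,
            "n_biomarkers": n_biomarkers,
            "single_line_boost": single_line_boost,
            "tf_target_boost": tf_target_boost,
            "n_ffl_per_class": list(n_ffl_per_class),
            "shared_targets_per_biomarker": shared_targets_per_biomarker,
            "background_targets_per_mirna": background_targets_per_mirna,
            "background_tf_mirna_edges": background_tf_mirna_edges,
            "background_tf_gene_edges": background_tf_gene_edges,
        },
    )
    return mirna_gene, tf_mirna, tf_gene, tfs, truth


# ---------------------------------------------------------------------------
# PPI network with planted dense modules


def gen_ppi_with_modules(
    n_nodes: int = 400,
    p_background: float = 0.01,
    module_sizes: tuple[int, ...] = (15, 12, 10),
    p_within: float = 0.9,
    confidence_range: tuple[float, float] = (0.4, 0.99),
    seed: int = 0,
) -> tuple[EdgeTable, SyntheticTruth]:
    """Simulate a STRING-like confidence-scored PPI edge list.

    Planted modules are disjoint vertex blocks wired as near-cliques
    (each within-module pair present with probability ``p_within``);
    all other pairs appear with probability ``p_background``.
    """
    if any(s < 4 for s in module_sizes):
        raise ValidationError("module sizes must be >= 4")
    if sum(module_sizes) > n_nodes:
        raise ValidationError("planted modules exceed the node budget (must be disjoint)")
    if p_within <= p_background:
        raise ValidationError("p_within must exceed p_background")

    rng = np.random.default_rng(seed)
    nodes = [_protein_id(i) for i in range(n_nodes)]
    membership = np.full(n_nodes, -1)
    start = 0
    modules: list[set[str]] = []
    for mi, size in enumerate(module_sizes):
        membership[start : start + size] = mi
        modules.append(set(nodes[start : start + size]))
        start += size

    iu, ju = np.triu_indices(n_nodes, k=1)
    same = (membership[iu] >= 0) & (membership[iu] == membership[ju])
    p = np.where(same, p_within, p_background)
    keep = rng.random(len(p)) < p
    lo, hi = confidence_range
    conf = rng.uniform(lo, hi, size=int(keep.sum()))

    pairs = [(nodes[a], nodes[b]) for a, b in zip(iu[keep], ju[keep])]
    df = _edge_records(pairs, "gene", "gene", "interacts")
    df["evidence"] = "physical"
    df["sign"] = "unknown"
    df["score"] = conf
    ppi = EdgeTable(df)

    truth = SyntheticTruth(
        seed=seed,
        planted_modules=modules,
        params={
            "n_nodes": n_nodes,
            "p_background": p_background,
            "module_sizes": list(module_sizes),
            "p_within": p_within,
            "confidence_range": list(confidence_range),
        },
    )
    return ppi, truth
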