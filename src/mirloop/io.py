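"""Readers and writers for the package's external table formats.

Everything on disk is plain text: TSV with a header row for matrices and
edge tables, GMT for gene sets, YAML for the per-origin cutoff
configuration, GraphML/SIF for network export. The consensus target filter
— the union of strongly validated interactions with predictions supported
by enough independent databases at their per-database score cutoffs —
lives here because it is a pure table-to-table operation.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .model import (
    EDGE_COLUMNS,
    EdgeTable,
    ExpressionMatrix,
    GeneSetCollection,
    SampleSheet,
    TFCatalog,
    ValidationError,
    default_sign,
)

# ---------------------------------------------------------------------------
# expression matrices and sample sheets


def load_expression(path: str | Path, sheet: SampleSheet | None = None) -> ExpressionMatrix:
    """Load a features x samples TSV; optionally restrict/reorder to a sample sheet.

    The first column holds feature ids, the header row sample ids. Raises on
    duplicate feature rows, on sheet samples absent from the file, and on
    non-numeric cells (naming the offending row/column).
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        dups = sorted(raw.index[raw.index.duplicated()].unique())
        raise ValidationError(f"duplicate feature row(s) in {path}: {dups}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"non-numeric cell in {path} at feature {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r}: {raw.iat[i, j]!r}"
        )
    matrix = ExpressionMatrix(numeric.astype(float))
    if sheet is not None:
        missing = [s for s in sheet.sample_ids if s not in numeric.columns]
        if missing:
            raise ValidationError(f"sample sheet references absent sample(s): {missing}")
        matrix = matrix.subset_samples(sheet.sample_ids)
    return matrix


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.data.to_csv(path, sep="\t", index_label="feature_id")


def load_sample_sheet(path: str | Path) -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep="\t", dtype=str))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# edge tables


def load_edge_table(path: str | Path, expected_relation: str | None = None) -> EdgeTable:
    """Load an interaction TSV into a validated :class:`EdgeTable`.

    A missing ``sign`` column is filled by the default rule (miRNA sources
    repress, TF sources activate). Records whose relation differs from
    ``expected_relation`` are rejected with an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"score": str})
    if "sign" not in df.columns:
        df["sign"] = [default_sign(k) for k in df.get("source_kind", pd.Series(dtype=str))]
    else:
        blank = df["sign"].isna()
        df.loc[blank, "sign"] = [default_sign(k) for k in df.loc[blank, "source_kind"]]
    if "score" in df.columns:
        df["score"] = _coerce_scores(df["score"])
    table = EdgeTable(df)
    if expected_relation is not None:
        wrong = table.table["relation"] != expected_relation
        if wrong.any():
            found = sorted(table.table.loc[wrong, "relation"].unique())
            raise ValidationError(
                f"{path}: expected relation {expected_relation!r}, found {found}"
            )
    return table


def _coerce_scores(col: pd.Series) -> pd.Series:
    """Numeric where possible, original string (e.g. a score class) otherwise."""
    out = []
    for v in col:
        if pd.isna(v):
            out.append(np.nan)
            continue
        try:
            out.append(float(v))
        except (TypeError, ValueError):
            out.append(v)
    return pd.Series(out, index=col.index, dtype=object)


def write_edge_table(table: EdgeTable, path: str | Path) -> None:
    table.table.loc[:, list(table.table.columns)].to_csv(path, sep="\t", index=False)


def load_tf_catalog(path: str | Path) -> TFCatalog:
    """One TF gene id per line (blank lines ignored)."""
    ids = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return TFCatalog(frozenset(ids))


def write_tf_catalog(catalog: TFCatalog, path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(catalog.tf_ids)) + "\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)


def load_gmt(path: str | Path) -> GeneSetCollection:
    """Standard GMT: set name, description, then member genes, tab-separated."""
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
        name, desc, *genes = fields
        if name in sets:
            raise ValidationError(f"duplicate gene set name: {name!r}")
        genes = [g for g in genes if g]
        sets[name] = frozenset(genes)
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = []
    for name, members in collection.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *sorted(members)]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# per-origin cutoff configuration


def load_cutoff_config(path: str | Path) -> dict[str, dict]:
    """YAML mapping origin -> {direction: ge|le|class_in, value | classes}."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, Mapping):
        raise ValidationError("cutoff config must be a mapping of origin -> rule")
    return dict(cfg)


# ---------------------------------------------------------------------------
# consensus target filter


def _record_passes(rule: Mapping, score) -> bool:
    direction = rule.get("direction", "ge")
    if direction == "ge":
        return pd.notna(score) and float(score) >= float(rule["value"])
    if direction == "le":
        return pd.notna(score) and float(score) <= float(rule["value"])
    if direction == "class_in":
        classes = {str(c).strip().casefold() for c in rule["classes"]}
        return str(score).strip().casefold() in classes
    raise ValidationError(f"unknown cutoff direction: {direction!r}")


def consensus_target_filter(
    predicted: EdgeTable,
    validated: EdgeTable,
    cutoffs: Mapping[str, Mapping],
    min_sources: int = 3,
) -> EdgeTable:
    """Merge validated and multi-database-supported predicted miRNA targets.

    A predicted (miRNA, gene) pair is retained when it passes its
    per-origin score cutoff in at least ``min_sources`` distinct origins
    (databases). All strongly validated pairs are retained unconditionally.
    The output is deduplicated on (miRNA, gene); each record's ``status``
    column says whether the pair is validated, predicted, or both, and for
    predicted pairs ``score`` carries the number of supporting origins.
    """
    if min_sources < 1:
        raise ValidationError("min_sources must be >= 1")
    pred = predicted.table
    unknown = sorted(set(pred["origin"]) - set(cutoffs))
    if unknown:
        raise ValidationError(f"no cutoff configured for origin(s): {unknown}")

    support: dict[tuple[str, str], set[str]] = {}
    for row in pred.itertuples(index=False):
        if _record_passes(cutoffs[row.origin], row.score):
            support.setdefault((row.source_id, row.target_id), set()).add(row.origin)
    predicted_pairs = {p for p, origins in support.items() if len(origins) >= min_sources}
    validated_pairs = validated.pairs()

    records = []
    for pair in sorted(predicted_pairs | validated_pairs):
        in_pred = pair in predicted_pairs
        in_val = pair in validated_pairs
        status = "both" if (in_pred and in_val) else ("predicted" if in_pred else "validated")
        records.append(
            {
                "source_id": pair[0],
                "source_kind": "miRNA",
                "target_id": pair[1],
                "target_kind": "gene",
                "relation": "targets",
                "sign": "repress",
                "origin": "consensus",
                "evidence": "validated_strong" if in_val else "predicted",
                "score": float(len(support.get(pair, ()))) if in_pred else np.nan,
                "status": status,
            }
        )
    df = pd.DataFrame.from_records(
        records, columns=[*EDGE_COLUMNS, "status"]
    )
    out = EdgeTable(df.loc[:, list(EDGE_COLUMNS)])
    out.table["status"] = df["status"]
    return out


# ---------------------------------------------------------------------------
# network export


def edge_table_to_graph(table: EdgeTable, directed: bool = False) -> nx.Graph:
    """Simple (multi-edge-collapsed) graph from an edge table."""
    G: nx.Graph = nx.DiGraph() if directed else nx.Graph()
    for row in table.table.itertuples(index=False):
        if row.source_id == row.target_id:
            continue
        G.add_node(row.source_id, kind=row.source_kind)
        G.add_node(row.target_id, kind=row.target_kind)
        G.add_edge(row.source_id, row.target_id, relation=row.relation, sign=row.sign)
    return G


def write_graphml(G: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(G, str(path))


def write_sif(edges: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    """SIF export: one ``source<TAB>relation<TAB>target`` line per edge."""
    lines = [f"{s}\t{rel}\t{t}" for s, rel, t in edges]
    Path(path).write_text("\n".join(lines) + "\n")
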