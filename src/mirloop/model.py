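"""Shared data model for expression matrices, regulatory edge tables and gene sets.

All tabular objects are thin, validated wrappers around :class:`pandas.DataFrame`
so they interoperate with the usual scientific-Python stack while enforcing the
structural invariants the analysis relies on (unique identifiers, finite
values, bipartiteness of regulatory relations, and so on).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

NODE_KINDS = frozenset({"miRNA", "TF", "gene"})
RELATIONS = frozenset({"targets", "regulates", "interacts"})
SIGNS = frozenset({"activate", "repress", "unknown"})
EVIDENCE_KINDS = frozenset({"validated_strong", "predicted", "physical"})

#: canonical column order of an edge table
EDGE_COLUMNS = (
    "source_id",
    "source_kind",
    "target_id",
    "target_kind",
    "relation",
    "sign",
    "origin",
    "evidence",
    "score",
)

GROUP_CASE = "case"
GROUP_CONTROL = "control"


class ValidationError(ValueError):
    """An input object violates a structural invariant of the data model."""


def default_sign(source_kind: str) -> str:
    """Default regulatory sign when a source does not annotate one.

    miRNAs are assumed to repress their targets; TFs to activate theirs
    unless the source database says otherwise. Other sources get ``unknown``.
    """
    if source_kind == "miRNA":
        return "repress"
    if source_kind == "TF":
        return "activate"
    return "unknown"


@dataclass
class ExpressionMatrix:
    """Log2-intensity expression values, features in rows, samples in columns."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = sorted(df.index[df.index.duplicated()].unique())
            raise ValidationError(f"duplicate feature ids: {dups}")
        if df.columns.has_duplicates:
            dups = sorted(df.columns[df.columns.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValidationError("expression values must be numeric")
        if values.size and not np.all(np.isfinite(values)):
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at feature {df.index[bad[0]]!r}, "
                f"sample {df.columns[bad[1]]!r}"
            )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise ValidationError(f"samples not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[:, sample_ids].copy())

    def subset_features(self, feature_ids: list[str]) -> "ExpressionMatrix":
        missing = [f for f in feature_ids if f not in self.data.index]
        if missing:
            raise ValidationError(f"features not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[feature_ids].copy())


@dataclass
class SampleSheet:
    """Sample annotations: identifier, case/control group, cohort label."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "cohort"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"sample sheet missing columns: {sorted(missing)}")
        ids = self.table["sample_id"]
        if ids.duplicated().any():
            raise ValidationError(
                f"duplicate sample ids: {sorted(ids[ids.duplicated()].unique())}"
            )
        bad = set(self.table["group"]) - {GROUP_CASE, GROUP_CONTROL}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def ids_for_group(self, group: str) -> list[str]:
        return list(self.table.loc[self.table["group"] == group, "sample_id"])

    @property
    def case_ids(self) -> list[str]:
        return self.ids_for_group(GROUP_CASE)

    @property
    def control_ids(self) -> list[str]:
        return self.ids_for_group(GROUP_CONTROL)

    @property
    def labels(self) -> np.ndarray:
        """Boolean vector, True for case samples, in sheet order."""
        return (self.table["group"] == GROUP_CASE).to_numpy()


@dataclass
class EdgeTable:
    """Typed, signed, evidence-annotated interaction records.

    Holds miRNA->gene targeting, TF->miRNA / TF->gene regulation, or
    protein-protein (physical) interactions, one record per row. ``score``
    is a prediction score or interaction confidence and may hold a
    categorical label (e.g. a score-class string) for origins that publish
    one instead of a number.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        required = {"source_id", "target_id", "relation"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"edge table missing columns: {sorted(missing)}")
        for col, default in (
            ("source_kind", None),
            ("target_kind", None),
            ("sign", None),
            ("origin", "unspecified"),
            ("evidence", "predicted"),
            ("score", np.nan),
        ):
            if col not in df.columns:
                if default is None:
                    raise ValidationError(f"edge table missing column: {col}")
                df[col] = default
        self.table = df = df.loc[:, list(EDGE_COLUMNS)].reset_index(drop=True)

        for col, allowed in (
            ("source_kind", NODE_KINDS),
            ("target_kind", NODE_KINDS),
            ("relation", RELATIONS),
            ("sign", SIGNS),
            ("evidence", EVIDENCE_KINDS),
        ):
            bad = set(df[col]) - allowed
            if bad:
                raise ValidationError(f"unknown {col} token(s): {sorted(map(str, bad))}")

        regulatory = df["relation"].isin(["targets", "regulates"])
        loops = regulatory & (df["source_id"] == df["target_id"])
        if loops.any():
            ids = sorted(df.loc[loops, "source_id"].unique())
            raise ValidationError(f"self-loop(s) in regulatory relation: {ids}")

        key = df[["source_id", "target_id", "relation", "origin"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValidationError(
                "duplicate record for "
                f"({dup['source_id']}, {dup['target_id']}, {dup['relation']}, {dup['origin']})"
            )

        predicted = df["evidence"] == "predicted"
        score_missing = df["score"].isna()
        if (predicted & score_missing).any():
            ids = df.loc[predicted & score_missing, "source_id"].unique()[:5]
            raise ValidationError(
                f"predicted records without score, e.g. source(s) {list(ids)}"
            )

    def __len__(self) -> int:
        return len(self.table)

    def pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.table["source_id"], self.table["target_id"]))

    def restrict_sources(self, ids: set[str]) -> "EdgeTable":
        mask = self.table["source_id"].isin(ids)
        return EdgeTable(self.table.loc[mask].copy())


@dataclass(frozen=True)
class TFCatalog:
    """Set of gene identifiers designated as transcription factors."""

    tf_ids: frozenset[str]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.tf_ids

    def __len__(self) -> int:
        return len(self.tf_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with optional descriptions."""

    sets: dict[str, frozenset[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def items(self):
        return self.sets.items()


def make_edge_table(
    records: list[dict],
) -> EdgeTable:
    """Build an EdgeTable from a list of record dicts, filling defaults."""
    df = pd.DataFrame.from_records(records)
    return EdgeTable(df)
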