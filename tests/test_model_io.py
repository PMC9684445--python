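"""Data model validation, TSV/GMT round trips, and the consensus target filter."""

import numpy as np
import pandas as pd
import pytest

from mirloop import (
    EdgeTable,
    ExpressionMatrix,
    SampleSheet,
    ValidationError,
    consensus_target_filter,
    load_edge_table,
    load_expression,
    load_gmt,
)
from mirloop.io import write_edge_table, write_expression, write_gmt
from mirloop.model import GeneSetCollection, default_sign


def _sheet(samples, groups, cohort="c1"):
    return SampleSheet(
        pd.DataFrame({"sample_id": samples, "group": groups, "cohort": cohort})
    )


class TestExpressionIO:
    def test_round_trip_preserves_ids_and_values(self, tmp_path):
        m = ExpressionMatrix(
            pd.DataFrame(
                np.arange(12, dtype=float).reshape(3, 4),
                index=["f1", "f2", "f3"],
                columns=["s1", "s2", "s3", "s4"],
            )
        )
        path = tmp_path / "expr.tsv"
        write_expression(m, path)
        back = load_expression(path)
        pd.testing.assert_frame_equal(back.data, m.data, check_names=False)

    def test_sheet_restricts_and_orders_columns(self, tmp_path):
        m = ExpressionMatrix(
            pd.DataFrame(
                np.arange(8, dtype=float).reshape(2, 4),
                index=["f1", "f2"],
                columns=["s1", "s2", "s3", "s4"],
            )
        )
        path = tmp_path / "expr.tsv"
        write_expression(m, path)
        sheet = _sheet(["s3", "s1"], ["case", "control"])
        back = load_expression(path, sheet)
        assert back.sample_ids == ["s3", "s1"]

    def test_duplicate_feature_row_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("feature_id\ts1\nfA\t1.0\nfA\t2.0\n")
        with pytest.raises(ValidationError, match="fA"):
            load_expression(path)

    def test_absent_sample_named_in_error(self, tmp_path):
        path = tmp_path / "expr.tsv"
        path.write_text("feature_id\ts1\nfA\t1.0\n")
        with pytest.raises(ValidationError, match="S9"):
            load_expression(path, _sheet(["S9"], ["case"]))

    def test_non_numeric_cell_located(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("feature_id\ts1\ts2\nfA\t1.0\t2.0\nfB\toops\t3.0\n")
        with pytest.raises(ValidationError, match="fB.*s1"):
            load_expression(path)

    def test_non_finite_value_rejected(self):
        with pytest.raises(ValidationError, match="non-finite"):
            ExpressionMatrix(
                pd.DataFrame({"s1": [1.0, np.inf]}, index=["f1", "f2"])
            )


class TestEdgeTableIO:
    def _write(self, tmp_path, rows, columns):
        path = tmp_path / "edges.tsv"
        pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
        return path

    def test_signs_preserved(self, tmp_path):
        cols = ["source_id", "source_kind", "target_id", "target_kind",
                "relation", "sign", "origin", "evidence", "score"]
        rows = [
            ["T1", "TF", "m1", "miRNA", "regulates", "activate", "db", "validated_strong", ""],
            ["T1", "TF", "m2", "miRNA", "regulates", "repress", "db", "validated_strong", ""],
            ["T2", "TF", "m1", "miRNA", "regulates", "repress", "db", "validated_strong", ""],
            ["T2", "TF", "m3", "miRNA", "regulates", "activate", "db", "validated_strong", ""],
            ["T3", "TF", "m1", "miRNA", "regulates", "activate", "db", "validated_strong", ""],
        ]
        table = load_edge_table(self._write(tmp_path, rows, cols), "regulates")
        assert len(table) == 5
        assert list(table.table["sign"]) == [
            "activate", "repress", "repress", "activate", "activate"
        ]

    def test_missing_sign_column_defaults_by_source_kind(self, tmp_path):
        cols = ["source_id", "source_kind", "target_id", "target_kind",
                "relation", "origin", "evidence"]
        rows = [
            ["m1", "miRNA", "g1", "gene", "targets", "db", "validated_strong"],
            ["T1", "TF", "g1", "gene", "regulates", "db", "validated_strong"],
        ]
        table = load_edge_table(self._write(tmp_path, rows, cols))
        assert list(table.table["sign"]) == ["repress", "activate"]
        assert default_sign("gene") == "unknown"

    def test_regulatory_self_loop_rejected(self, tmp_path):
        cols = ["source_id", "source_kind", "target_id", "target_kind",
                "relation", "sign", "origin", "evidence"]
        rows = [["T1", "TF", "T1", "gene", "regulates", "activate", "db", "validated_strong"]]
        with pytest.raises(ValidationError, match="self-loop"):
            load_edge_table(self._write(tmp_path, rows, cols))

    def test_unknown_kind_token_rejected(self, tmp_path):
        cols = ["source_id", "source_kind", "target_id", "target_kind",
                "relation", "sign", "origin", "evidence"]
        rows = [["x", "lncRNA", "g1", "gene", "targets", "repress", "db", "validated_strong"]]
        with pytest.raises(ValidationError, match="lncRNA"):
            load_edge_table(self._write(tmp_path, rows, cols))

    def test_unexpected_relation_rejected(self, tmp_path):
        cols = ["source_id", "source_kind", "target_id", "target_kind",
                "relation", "sign", "origin", "evidence"]
        rows = [["m1", "miRNA", "g1", "gene", "targets", "repress", "db", "validated_strong"]]
        with pytest.raises(ValidationError, match="interacts"):
            load_edge_table(self._write(tmp_path, rows, cols), "interacts")

    def test_predicted_requires_score(self):
        with pytest.raises(ValidationError, match="without score"):
            EdgeTable(
                pd.DataFrame(
                    [{
                        "source_id": "m1", "source_kind": "miRNA",
                        "target_id": "g1", "target_kind": "gene",
                        "relation": "targets", "sign": "repress",
                        "origin": "db", "evidence": "predicted", "score": np.nan,
                    }]
                )
            )

    def test_edge_table_round_trip(self, tmp_path, toy_bipartite_edges):
        path = tmp_path / "edges.tsv"
        write_edge_table(toy_bipartite_edges, path)
        back = load_edge_table(path, "targets")
        assert back.pairs() == toy_bipartite_edges.pairs()


class TestGmt:
    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(
            {"setA": frozenset({"g1", "g2"}), "setB": frozenset({"g3"})},
            {"setA": "first", "setB": "second"},
        )
        path = tmp_path / "sets.gmt"
        write_gmt(coll, path)
        back = load_gmt(path)
        assert back.sets == coll.sets
        assert back.descriptions["setA"] == "first"

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError, match="empty"):
            GeneSetCollection({"bad": frozenset()})


# ---------------------------------------------------------------------------
# consensus target filter

CUTOFFS = {
    "mirdb": {"direction": "ge", "value": 84},
    "targetscan": {"direction": "le", "value": -0.4},
    "microt": {"direction": "ge", "value": 0.7},
    "mirdip": {"direction": "class_in", "classes": ["very high"]},
}


def _pred_records(entries):
    rows = []
    for mirna, gene, origin, score in entries:
        rows.append(
            {
                "source_id": mirna, "source_kind": "miRNA",
                "target_id": gene, "target_kind": "gene",
                "relation": "targets", "sign": "repress",
                "origin": origin, "evidence": "predicted", "score": score,
            }
        )
    return EdgeTable(pd.DataFrame(rows))


def _validated(pairs):
    rows = [
        {
            "source_id": m, "source_kind": "miRNA",
            "target_id": g, "target_kind": "gene",
            "relation": "targets", "sign": "repress",
            "origin": "mirtarbase", "evidence": "validated_strong", "score": np.nan,
        }
        for m, g in pairs
    ]
    return EdgeTable(pd.DataFrame(rows)) if rows else _empty_targets()


def _empty_targets():
    return EdgeTable(
        pd.DataFrame(
            columns=["source_id", "source_kind", "target_id", "target_kind",
                     "relation", "sign", "origin", "evidence", "score"]
        )
    )


class TestConsensusFilter:
    def test_pair_supported_by_three_databases_retained(self):
        pred = _pred_records([
            ("m1", "g1", "mirdb", 90.0),
            ("m1", "g1", "targetscan", -0.5),
            ("m1", "g1", "microt", 0.9),
            ("m1", "g1", "mirdip", "low"),
        ])
        out = consensus_target_filter(pred, _validated([]), CUTOFFS, min_sources=3)
        assert out.pairs() == {("m1", "g1")}
        assert list(out.table["status"]) == ["predicted"]

    def test_pair_with_two_sources_dropped(self):
        pred = _pred_records([
            ("m1", "g1", "mirdb", 90.0),
            ("m1", "g1", "microt", 0.9),
            ("m1", "g1", "targetscan", 0.2),   # fails the <= -0.4 cutoff
        ])
        out = consensus_target_filter(pred, _validated([]), CUTOFFS, min_sources=3)
        assert out.pairs() == set()

    def test_validated_pairs_always_retained(self):
        pred = _pred_records([("m1", "g1", "mirdb", 10.0)])
        out = consensus_target_filter(pred, _validated([("m2", "g9")]), CUTOFFS, 3)
        assert ("m2", "g9") in out.pairs()
        assert list(out.table["status"]) == ["validated"]

    def test_both_status_when_validated_and_predicted(self):
        pred = _pred_records([
            ("m1", "g1", "mirdb", 90.0),
            ("m1", "g1", "microt", 0.9),
            ("m1", "g1", "mirdip", "Very High "),  # class labels trimmed, case-folded
        ])
        out = consensus_target_filter(pred, _validated([("m1", "g1")]), CUTOFFS, 3)
        assert list(out.table["status"]) == ["both"]

    def test_unknown_origin_named_in_error(self):
        pred = _pred_records([("m1", "g1", "mystery_db", 1.0)])
        with pytest.raises(ValidationError, match="mystery_db"):
            consensus_target_filter(pred, _validated([]), CUTOFFS, 3)

    def test_matches_per_pair_counting_oracle(self, rng):
        """200 random pairs over 6 origins: retained set equals brute-force
        per-pair counting of passing origins."""
        origins = {f"db{i}": {"direction": "ge", "value": 0.5} for i in range(6)}
        entries = []
        truth_support = {}
        for k in range(200):
            pair = (f"m{k % 20}", f"g{k}")
            n_origins = rng.integers(1, 7)
            chosen = rng.choice(list(origins), size=n_origins, replace=False)
            passing = 0
            for origin in chosen:
                score = float(rng.random())
                passing += score >= 0.5
                entries.append((*pair, origin, score))
            truth_support[pair] = passing
        out = consensus_target_filter(
            _pred_records(entries), _validated([]), origins, min_sources=3
        )
        expected = {p for p, n in truth_support.items() if n >= 3}
        assert out.pairs() == expected

    @pytest.mark.parametrize("min_sources", [1, 2, 3, 4])
    def test_monotone_in_min_sources(self, rng, min_sources):
        origins = {f"db{i}": {"direction": "ge", "value": 0.3} for i in range(4)}
        entries = [
            (f"m{k % 5}", f"g{k % 30}", f"db{k % 4}", float(rng.random()))
            for k in range(120)
        ]
        # dedupe on (pair, origin)
        seen, uniq = set(), []
        for e in entries:
            key = (e[0], e[1], e[2])
            if key not in seen:
                seen.add(key)
                uniq.append(e)
        pred = _pred_records(uniq)
        bigger = consensus_target_filter(pred, _validated([]), origins, min_sources)
        if min_sources < 4:
            smaller = consensus_target_filter(pred, _validated([]), origins, min_sources + 1)
            assert smaller.pairs() <= bigger.pairs()
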