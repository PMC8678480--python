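import numpy as np
import pandas as pd
import pytest

from ceranet import (
    ExpressionMatrix,
    GeneSetCollection,
    GroupDesign,
    InteractionTable,
    SignatureMatrix,
    collapse_duplicates,
    read_expression,
    read_gmt,
    read_groups,
    read_interactions,
    write_expression,
    write_gmt,
    write_groups,
    write_interactions,
)
from ceranet.data_model import DataModelError


def _em(values, classes, samples=None):
    idx = list(values.keys())
    df = pd.DataFrame(list(values.values()), index=idx, columns=samples)
    return ExpressionMatrix(df, pd.Series(classes, index=idx))


class TestExpressionIO:
    def test_round_trip_identity(self, tiny_matrix, tmp_path):
        path = tmp_path / "expr.tsv"
        write_expression(tiny_matrix, path)
        back = read_expression(path)
        assert back.shape == (3, 4)
        assert back.feature_ids == tiny_matrix.feature_ids
        assert back.sample_ids == tiny_matrix.sample_ids
        assert (back.feature_class == tiny_matrix.feature_class).all()
        np.testing.assert_allclose(
            back.values.to_numpy(), tiny_matrix.values.to_numpy(), atol=1e-12
        )

    def test_duplicate_sample_header_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("feature_id\ts1\ts1\nG1\t1.0\t2.0\n")
        with pytest.raises(DataModelError, match="s1"):
            read_expression(path)

    def test_non_numeric_cell_located(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("feature_id\tfeature_class\ts1\ts2\nG1\tmRNA\t1.0\toops\n")
        with pytest.raises(DataModelError, match="G1.*s2"):
            read_expression(path)

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        with pytest.raises(DataModelError, match="empty"):
            read_expression(path)

    def test_class_map_file(self, tmp_path):
        (tmp_path / "e.tsv").write_text("feature_id\ts1\ts2\nG1\t1\t2\nL1\t3\t4\n")
        (tmp_path / "cm.tsv").write_text("G1\tmRNA\nL1\tlncRNA\n")
        m = read_expression(tmp_path / "e.tsv", class_map=tmp_path / "cm.tsv")
        assert m.feature_class.tolist() == ["mRNA", "lncRNA"]

    def test_missing_class_is_error(self, tmp_path):
        (tmp_path / "e.tsv").write_text("feature_id\ts1\ts2\nG1\t1\t2\n")
        with pytest.raises(DataModelError, match="class"):
            read_expression(tmp_path / "e.tsv")


class TestCollapseDuplicates:
    def test_mean_of_probe_rows(self):
        df = pd.DataFrame(
            [[1.0, 3.0], [3.0, 5.0], [7.0, 7.0]],
            index=["GENE1", "GENE1", "GENE2"],
            columns=["a", "b"],
        )
        m = ExpressionMatrix(df, pd.Series(["mRNA", "mRNA", "mRNA"], index=df.index))
        out = collapse_duplicates(m)
        assert out.feature_ids == ["GENE1", "GENE2"]
        np.testing.assert_allclose(out.values.loc["GENE1"].to_numpy(), [2.0, 4.0])

    def test_identity_without_duplicates(self, tiny_matrix):
        out = collapse_duplicates(tiny_matrix)
        pd.testing.assert_frame_equal(out.values, tiny_matrix.values)

    @pytest.mark.parametrize("k", [2, 5])
    def test_identical_copies_unchanged(self, k):
        row = [1.5, 2.5, 3.5]
        df = pd.DataFrame([row] * k, index=["G"] * k, columns=["a", "b", "c"])
        m = ExpressionMatrix(df, pd.Series(["lncRNA"] * k, index=df.index))
        np.testing.assert_allclose(collapse_duplicates(m).values.loc["G"].to_numpy(), row)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        ids = ["A", "B", "A", "C", "B"]
        df = pd.DataFrame(rng.normal(size=(5, 4)), index=ids)
        m = ExpressionMatrix(df, pd.Series(["mRNA"] * 5, index=df.index))
        once = collapse_duplicates(m)
        twice = collapse_duplicates(once)
        pd.testing.assert_frame_equal(once.values, twice.values)

    def test_conflicting_class_rejected(self):
        df = pd.DataFrame([[1.0], [2.0]], index=["X", "X"], columns=["s"])
        m = ExpressionMatrix(df, pd.Series(["mRNA", "lncRNA"], index=df.index))
        with pytest.raises(DataModelError, match="X"):
            collapse_duplicates(m)


class TestInteractions:
    def test_round_trip_and_dedup(self, tmp_path):
        rows = [
            ("MIR1", "LNC1", "miRNA", "lncRNA", "db1"),
            ("MIR1", "G1", "miRNA", "mRNA", "db1"),
            ("MIR1", "G1", "miRNA", "mRNA", "db2"),  # duplicate edge
            ("TF1", "G2", "TF", "mRNA", "db3"),
            ("MIR2", "G3", "miRNA", "mRNA", "db1"),
            ("MIR3", "G4", "miRNA", "mRNA", "db1"),
        ]
        it = InteractionTable(pd.DataFrame(rows, columns=list(InteractionTable.COLUMNS)))
        assert len(it) == 5  # de-duplicated on (regulator, target)
        path = tmp_path / "edges.tsv"
        write_interactions(it, path)
        back = read_interactions(path)
        pd.testing.assert_frame_equal(back.records, it.records)

    def test_malformed_line_reports_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "regulator\ttarget\tregulator_class\ttarget_class\tsource\n"
            "MIR1\tG1\tmiRNA\tmRNA\tdb\nbroken line\n"
        )
        with pytest.raises(DataModelError, match="line 3"):
            read_interactions(path)

    def test_self_interaction_rejected(self):
        rows = [("A", "A", "TF", "mRNA", "db")]
        with pytest.raises(DataModelError, match="self-interaction"):
            InteractionTable(pd.DataFrame(rows, columns=list(InteractionTable.COLUMNS)))


class TestGmt:
    def test_gmt_semantics(self, tmp_path):
        path = tmp_path / "s.gmt"
        path.write_text("S1\tdesc\tA\tB\nS2\tother\tC\n")
        gsc = read_gmt(path)
        assert gsc["S1"] == ["A", "B"]
        assert gsc["S2"] == ["C"]

    def test_round_trip(self, tmp_path):
        gsc = GeneSetCollection({"S1": ["A", "B", "C"], "S2": ["B"]}, {"S1": "d1", "S2": "d2"})
        path = tmp_path / "x.gmt"
        write_gmt(gsc, path)
        back = read_gmt(path)
        assert back.sets == gsc.sets

    def test_duplicate_members_collapsed(self):
        gsc = GeneSetCollection({"S": ["A", "B", "A"]})
        assert gsc["S"] == ["A", "B"]

    def test_malformed_line(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("S1\tonly-desc\n")
        with pytest.raises(DataModelError, match="line 1"):
            read_gmt(path)


class TestDesignsAndSignature:
    def test_groups_round_trip(self, design4, tmp_path):
        path = tmp_path / "g.tsv"
        write_groups(design4, path)
        back = read_groups(path)
        assert (back.groups == design4.groups).all()

    def test_single_group_rejected(self):
        with pytest.raises(DataModelError):
            GroupDesign(pd.Series(["case"] * 4, index=list("abcd")))

    def test_small_group_rejected(self):
        with pytest.raises(DataModelError, match="fewer than 2"):
            GroupDesign(pd.Series(["case", "control", "control"], index=list("abc")))

    def test_signature_invariants(self):
        df = pd.DataFrame([[1.0, 2.0], [3.0, 4.0]], columns=["T1", "T2"])
        SignatureMatrix(df)  # valid
        with pytest.raises(DataModelError, match="non-negative"):
            SignatureMatrix(df - 5.0)
        with pytest.raises(DataModelError, match="2 cell types"):
            SignatureMatrix(df[["T1"]])
        same = pd.DataFrame([[1.0, 1.0], [2.0, 2.0]], columns=["T1", "T2"])
        with pytest.raises(DataModelError, match="identical"):
            SignatureMatrix(same)
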