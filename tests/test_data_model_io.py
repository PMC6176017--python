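"""Containers, ternary categorization and plain-text I/O."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import httimpute as h
from conftest import make_matrix


class TestExpressionMatrix:
    def test_duplicate_probe_rejected(self):
        df = pd.DataFrame(np.zeros((2, 2)), index=["A", "A"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="duplicate probe.*A"):
            h.ExpressionMatrix(df)

    def test_non_finite_rejected_with_coordinates(self):
        df = pd.DataFrame([[0.0, np.nan]], index=["P1"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="P1.*s2"):
            h.ExpressionMatrix(df)

    def test_subset_preserves_order_and_meta(self):
        meta = pd.DataFrame(
            {"compound": ["c1", "c2"], "dose_level": [1, 2], "time_point": [1, 1]},
            index=["s1", "s2"],
        )
        m = make_matrix([[1.0, 2.0], [3.0, 4.0]], ["B", "A"], ["s1", "s2"], meta)
        sub = m.subset_samples(["s2"])
        assert sub.sample_ids == ["s2"]
        assert list(sub.sample_meta.index) == ["s2"]
        assert m.subset_probes(["A"]).probe_ids == ["A"]


class TestCategorize:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.25, h.UP),
            (-0.30, h.DOWN),
            (0.0, h.UNCHANGED),
            (0.1, h.UNCHANGED),  # boundary values fall in the dead zone
            (-0.1, h.UNCHANGED),
            (0.1000001, h.UP),
            (-0.1000001, h.DOWN),
        ],
    )
    def test_threshold_rule(self, value, expected):
        cat = h.categorize(make_matrix([[value]]))
        assert cat.classes.iloc[0, 0] == expected

    def test_idempotent_in_class_space(self):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(0, 0.3, size=(30, 8)))
        cat = h.categorize(m)
        again = h.categorize(make_matrix(cat.classes.to_numpy()))
        assert (again.classes.to_numpy() == cat.classes.to_numpy()).all()

    def test_class_counts_partition_cells(self):
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(0, 0.2, size=(40, 12)))
        cat = h.categorize(m)
        assert cat.class_counts().sum() == 40 * 12
        left = cat.subset_samples(cat.sample_ids[:5])
        right = cat.subset_samples(cat.sample_ids[5:])
        assert (left.class_counts() + right.class_counts()).equals(cat.class_counts())

    @settings(max_examples=30, derandomize=True)
    @given(
        values=st.lists(
            st.floats(-1, 1, allow_nan=False, width=32), min_size=1, max_size=30
        ),
        up1=st.floats(0.01, 0.5),
        up2=st.floats(0.01, 0.5),
    )
    def test_lower_up_threshold_monotone(self, values, up1, up2):
        lo, hi = sorted([up1, up2])
        m = make_matrix(np.array(values, dtype=float).reshape(-1, 1))
        n_hi = (h.categorize(m, h.CategorizationConfig(-0.6, hi)).classes == h.UP).sum().sum()
        n_lo = (h.categorize(m, h.CategorizationConfig(-0.6, lo)).classes == h.UP).sum().sum()
        assert n_lo >= n_hi

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            h.CategorizationConfig(0.2, 0.1)


class TestMatrixIO:
    def test_expression_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        m = make_matrix(rng.normal(size=(5, 3)))
        path = tmp_path / "m.tsv"
        h.write_expression_matrix(m, path)
        back = h.read_expression_matrix(path)
        assert back.probe_ids == m.probe_ids
        assert back.sample_ids == m.sample_ids
        assert np.array_equal(back.data.to_numpy(), m.data.to_numpy())

    def test_categorized_round_trip(self, tmp_path):
        m = make_matrix(np.random.default_rng(3).normal(0, 0.3, size=(6, 4)))
        cat = h.categorize(m)
        path = tmp_path / "c.tsv"
        h.write_categorized(cat, path)
        back = h.read_categorized(path)
        assert (back.classes.to_numpy() == cat.classes.to_numpy()).all()

    def test_duplicate_probe_row_named(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("probe_id\ts1\ts2\nPX\t1\t2\nPX\t3\t4\n")
        with pytest.raises(ValueError, match="PX"):
            h.read_expression_matrix(path)

    def test_duplicate_sample_column_named(self, tmp_path):
        path = tmp_path / "dup.tsv"
        path.write_text("probe_id\tsA\tsA\nP1\t1\t2\n")
        with pytest.raises(ValueError, match="sA"):
            h.read_expression_matrix(path)

    def test_non_numeric_cell_coordinates(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("probe_id\ts1\ts2\nP1\t1.0\tow\n")
        with pytest.raises(ValueError, match="P1.*s2"):
            h.read_expression_matrix(path)


class TestProbeListIO:
    def test_round_trip_with_comments(self, tmp_path):
        path = tmp_path / "list.txt"
        path.write_text("# header\nP1\nP2\n\nP3\n")
        ps = h.read_probe_list(path)
        assert ps.probes == frozenset({"P1", "P2", "P3"})
        out = tmp_path / "out.txt"
        h.write_probe_list(ps, out)
        assert h.read_probe_list(out).probes == ps.probes

    def test_duplicates_rejected(self, tmp_path):
        path = tmp_path / "list.txt"
        path.write_text("P1\nP1\n")
        with pytest.raises(ValueError, match="P1"):
            h.read_probe_list(path)


class TestGMT:
    def test_members_parsed(self, tmp_path):
        path = tmp_path / "o.gmt"
        path.write_text("CAT1\tfirst\tg1\tg2\tg3\tg4\tg5\nCAT2\tsecond\tg6\tg7\n")
        ont = h.read_gmt(path)
        assert len(ont.categories["CAT1"].members) == 5
        assert ont.categories["CAT2"].name == "second"

    def test_empty_set_skipped_with_warning(self, tmp_path):
        path = tmp_path / "o.gmt"
        path.write_text("CAT1\tdesc\n" "CAT2\tdesc\tg1\n")
        with pytest.warns(UserWarning, match="CAT1"):
            ont = h.read_gmt(path)
        assert list(ont.categories) == ["CAT2"]

    def test_malformed_line_number_reported(self, tmp_path):
        path = tmp_path / "o.gmt"
        path.write_text("CAT1\tdesc\tg1\nonlyonefield\n")
        with pytest.raises(ValueError, match="line 2"):
            h.read_gmt(path)

    def test_round_trip(self, tmp_path, small_sim):
        _, ontology, _, _ = small_sim
        path = tmp_path / "o.gmt"
        h.write_gmt(ontology, path)
        back = h.read_gmt(path)
        assert {c: g.members for c, g in back.categories.items()} == {
            c: g.members for c, g in ontology.categories.items()
        }

    def test_cyclic_parent_edges_rejected(self):
        cats = {
            "A": h.GeneSet("A", "A", frozenset({"g1"})),
            "B": h.GeneSet("B", "B", frozenset({"g2"})),
        }
        with pytest.raises(ValueError, match="cycle"):
            h.Ontology(cats, (("A", "B"), ("B", "A")))

    def test_ancestors_follow_parent_edges(self):
        cats = {c: h.GeneSet(c, c, frozenset({f"g{c}"})) for c in "ABC"}
        ont = h.Ontology(cats, (("A", "B"), ("B", "C")))
        assert ont.ancestors("A") == {"B", "C"}
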