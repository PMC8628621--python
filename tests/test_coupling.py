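import numpy as np
import pandas as pd
import pytest

import phylotable as pt
from phylotable.tree_ops import tree_signature

from conftest import assert_coupled_invariant


class TestMatch:
    def test_set_intersection_semantics(self, basic_tree):
        df = pd.DataFrame({"species": ["A", "B", "D"], "x": [1.0, 2.0, 3.0]})
        ctd, report = pt.match(basic_tree, df)
        assert ctd.taxa == ["A", "B"]
        assert report.label_column == "species"
        assert report.n_matched == 2
        assert report.n_tips_dropped == 1
        assert report.n_rows_dropped == 1
        assert report.n_duplicate_rows_dropped == 0
        assert_coupled_invariant(ctd)

    def test_best_matching_column_selected(self, basic_tree):
        df = pd.DataFrame({"x": ["q", "r", "s"], "sp": ["C", "B", "A"]})
        ctd, report = pt.match(basic_tree, df)
        assert report.label_column == "sp"
        assert report.n_tips_dropped == 0
        assert report.n_rows_dropped == 0
        assert ctd.n_taxa == 3

    def test_perfect_overlap_rows_follow_tip_order(self, basic_tree):
        df = pd.DataFrame({"species": ["C", "A", "B"], "x": [3.0, 1.0, 2.0]})
        ctd, report = pt.match(basic_tree, df)
        assert report.n_tips_dropped == 0 and report.n_rows_dropped == 0
        assert ctd.taxa == basic_tree.tip_labels == ["A", "B", "C"]
        assert ctd.table.data["x"].tolist() == [1.0, 2.0, 3.0]

    def test_multi_tree_forced_to_common_sampling(self):
        trees = pt.parse_newick("((A:1,B:1):1,C:1);((A:1,B:1):1,(C:1,D:1):1);")
        df = pd.DataFrame({"species": ["A", "B", "C", "D"], "x": [1, 2, 3, 4]})
        ctd, report = pt.match(trees, df)
        assert set(ctd.taxa) == {"A", "B", "C"}
        for tree in ctd.trees:
            assert tree.tip_set == {"A", "B", "C"}
        assert report.per_tree_tips_dropped == [0, 1]
        assert report.n_rows_dropped == 1

    def test_no_overlap_is_an_error(self, basic_tree):
        df = pd.DataFrame({"species": ["X", "Y", "Z"]})
        with pytest.raises(pt.MatchError, match="no overlap"):
            pt.match(basic_tree, df)

    def test_single_shared_taxon_is_an_error(self, basic_tree):
        df = pd.DataFrame({"species": ["A", "X", "Y"]})
        with pytest.raises(pt.MatchError):
            pt.match(basic_tree, df)

    def test_explicit_label_column_missing(self, basic_tree):
        df = pd.DataFrame({"species": ["A", "B", "C"]})
        with pytest.raises(pt.TableValidationError, match="nope"):
            pt.match(basic_tree, df, label_column="nope")

    def test_duplicate_rows_keep_first_and_are_counted(self, basic_tree):
        df = pd.DataFrame({"species": ["A", "B", "A", "C"], "x": [1, 2, 99, 3]})
        ctd, report = pt.match(basic_tree, df)
        assert report.n_duplicate_rows_dropped == 1
        assert report.n_rows_dropped == 0
        assert ctd.table.data.set_index("species")["x"]["A"] == 1

    def test_tie_between_columns_warns_and_uses_leftmost(self, basic_tree):
        df = pd.DataFrame({"c1": ["A", "B", "x"], "c2": ["C", "A", "y"]})
        with pytest.warns(pt.TiedColumnsWarning):
            _, report = pt.match(basic_tree, df)
        assert report.label_column == "c1"

    def test_match_is_idempotent(self, anolis_like):
        ctd2, report = pt.match(pt.pull(anolis_like, "trees"), pt.pull(anolis_like, "table"))
        assert report.n_tips_dropped == 0
        assert report.n_rows_dropped == 0
        assert report.n_duplicate_rows_dropped == 0
        assert ctd2.taxa == anolis_like.taxa


class TestDropTaxa:
    def test_drop_one(self, basic_tree):
        df = pd.DataFrame({"species": ["A", "B", "C"], "x": [1, 2, 3]})
        ctd, _ = pt.match(basic_tree, df)
        out = pt.drop_taxa(ctd, {"C"})
        assert out.n_taxa == 2
        for tree in out.trees:
            assert tree.n_tips == 2
        assert out.dropped_tips_total == 1
        assert out.dropped_rows_total == 1
        assert_coupled_invariant(out)

    def test_drop_nothing_is_identity(self, anolis_like):
        out = pt.drop_taxa(anolis_like, set())
        assert out.taxa == anolis_like.taxa
        pd.testing.assert_frame_equal(out.table.data, anolis_like.table.data)

    def test_cannot_drop_below_two(self, basic_tree):
        df = pd.DataFrame({"species": ["A", "B", "C"]})
        ctd, _ = pt.match(basic_tree, df)
        with pytest.raises(pt.MatchError, match="fewer than 2"):
            pt.drop_taxa(ctd, {"B", "C"})

    def test_unknown_label_named(self, anolis_like):
        with pytest.raises(pt.TableValidationError, match="spX"):
            pt.drop_taxa(anolis_like, {"spX"})


class TestQuery:
    def test_island_filter_with_derived_column(self, anolis_like):
        out = pt.query(
            anolis_like, where='island == "Cuba"', select={"Index": "SVL + hostility"}
        )
        assert isinstance(out, pt.CoupledTreeData)
        assert out.taxa == ["sp1", "sp2"]
        for tree in out.trees:
            assert tree.n_tips == 2
        # hand sums: 3.5+0.5 and 4.0+1.0
        assert out.table.data["Index"].tolist() == [4.0, 5.0]
        # taxon labels implicitly retained even though select omitted them
        assert out.table.label_column in out.table.column_names
        assert_coupled_invariant(out)

    def test_group_head_one_per_ecomorph(self, anolis_like):
        out = pt.query(anolis_like, group_by="ecomorph", head=1)
        assert isinstance(out, pt.CoupledTreeData)
        # first trunk anole is sp1, first crown anole is sp2
        assert set(out.taxa) == {"sp1", "sp2"}
        for tree in out.trees:
            assert tree.n_tips == 2
        assert_coupled_invariant(out)

    def test_filter_aggregate_by_group_detaches(self, six_row_bench):
        with pytest.warns(pt.DetachedTableWarning):
            out = pt.query(
                six_row_bench,
                where='Disc1 == "A"',
                aggregate={"sum_Cont2": ("Cont2", "sum"), "mean_Cont3": ("Cont3", "mean")},
                group_by="Disc10",
            )
        assert isinstance(out, pt.TraitTable)
        # filtered rows: s1,s2,s4,s6; groups in appearance order X (s1,s4), Y (s2,s6)
        assert out.data["Disc10"].tolist() == ["X", "Y"]
        assert out.data["sum_Cont2"].tolist() == [9.0, 34.0]
        assert out.data["mean_Cont3"].tolist() == [4.0, 7.0]

    def test_global_aggregation_detaches(self, anolis_like):
        with pytest.warns(pt.DetachedTableWarning):
            out = pt.query(anolis_like, aggregate={"mean_SVL": ("SVL", "mean")})
        assert isinstance(out, pt.TraitTable)
        assert out.data["mean_SVL"].tolist() == [pytest.approx(18.5 / 6)]

    def test_filter_composition(self, anolis_like):
        step = pt.query(pt.query(anolis_like, where="SVL > 1.6"), where="hostility < 0.9")
        direct = pt.query(anolis_like, where="SVL > 1.6 & hostility < 0.9")
        pd.testing.assert_frame_equal(step.table.data, direct.table.data)
        assert [tree_signature(t) for t in step.trees] == [
            tree_signature(t) for t in direct.trees
        ]

    def test_callable_predicate_and_derivation(self, anolis_like):
        out = pt.query(
            anolis_like,
            where=lambda df: df["island"] != "Cuba",
            select={"log_SVL": lambda df: np.log(df["SVL"])},
        )
        assert set(out.taxa) == {"sp3", "sp4", "sp5", "sp6"}
        assert out.table.data["log_SVL"].tolist() == pytest.approx(
            np.log([2.5, 5.0, 1.5, 2.0]).tolist()
        )

    def test_select_list_keeps_label(self, anolis_like):
        out = pt.query(anolis_like, select=["SVL"])
        assert out.table.column_names == ["species", "SVL"]
        assert out.n_taxa == 6

    def test_bad_predicate_is_an_error(self, anolis_like):
        with pytest.raises(pt.QueryError):
            pt.query(anolis_like, where="nonexistent == 1")

    def test_filter_below_two_taxa_is_an_error(self, anolis_like):
        with pytest.raises(pt.QueryError, match="at least 2"):
            pt.query(anolis_like, where="SVL > 4.5")

    def test_group_by_requires_collapsing_or_head(self, anolis_like):
        with pytest.raises(pt.QueryError):
            pt.query(anolis_like, group_by="island", select={"y": "SVL * 2"})

    def test_query_counts_removed_taxa(self, anolis_like):
        out = pt.query(anolis_like, where='island != "Cuba"')
        assert out.dropped_tips_total == 2
        assert out.dropped_rows_total == 2


class TestExtractAndPull:
    def test_extract_single_vector(self, anolis_like):
        vec = pt.extract_vector(anolis_like, "SVL")
        assert isinstance(vec, pd.Series)
        assert list(vec.index) == anolis_like.taxa
        assert len(vec) == 6

    def test_extract_two_vectors(self, anolis_like):
        out = pt.extract_vector(anolis_like, "SVL", "ecomorph")
        assert len(out) == 2
        assert [s.name for s in out] == ["SVL", "ecomorph"]

    def test_vector_values_match_table_cells(self, anolis_like):
        for trait in ["SVL", "hostility", "island"]:
            vec = pt.extract_vector(anolis_like, trait)
            cells = anolis_like.table.data.set_index("species")[trait]
            for taxon in anolis_like.taxa:
                assert vec[taxon] == cells[taxon]

    def test_unknown_trait(self, anolis_like):
        with pytest.raises(pt.TableValidationError, match="nope"):
            pt.extract_vector(anolis_like, "nope")

    def test_pull_table_is_a_copy(self, anolis_like):
        pulled = pt.pull(anolis_like, "table")
        pulled.data.loc[0, "SVL"] = -1.0
        assert anolis_like.table.data.loc[0, "SVL"] == 3.5

    def test_pull_trees_count_and_independence(self, anolis_like):
        trees = pt.pull(anolis_like, "trees")
        assert len(trees) == 1
        trees[0].dendropy_tree.seed_node.child_nodes()[0].edge.length = 99.0
        assert anolis_like.trees[0].dendropy_tree.seed_node.child_nodes()[0].edge.length == 1.0

    def test_pull_invalid_selector(self, anolis_like):
        with pytest.raises(ValueError):
            pt.pull(anolis_like, "everything")


class TestApplyExternal:
    def test_single_tree_returns_single_result(self, anolis_like):
        assert pt.apply_external(anolis_like, lambda tree, table: tree.n_tips) == 6

    def test_function_sees_the_shared_table(self, anolis_like):
        n = pt.apply_external(anolis_like, lambda tree, table: table.n_rows)
        assert n == 6

    def test_exception_annotated_with_tree_index(self, anolis_like):
        def boom(tree, table):
            raise RuntimeError("bad model fit")

        with pytest.raises(RuntimeError, match="bad model fit") as excinfo:
            pt.apply_external(anolis_like, boom)
        assert any("tree 1" in note for note in excinfo.value.__notes__)


class TestSummarizeAndPeek:
    def test_character_and_missing_counts(self, anolis_like):
        s = pt.summarize(anolis_like)
        assert s.n_taxa == 6
        assert s.n_trees == 1
        assert s.n_discrete == 2  # island, ecomorph
        assert s.n_continuous == 2  # SVL, hostility
        assert s.n_missing == 0
        assert s.dropped_tips_total == 0
        assert s.dropped_rows_total == 0

    def test_counts_accumulate_after_drop(self, anolis_like):
        out = pt.drop_taxa(anolis_like, {"sp6"})
        s = pt.summarize(out)
        assert s.dropped_tips_total == 1
        assert s.dropped_rows_total == 1

    def test_missing_cells_counted(self, basic_tree):
        df = pd.DataFrame({"species": ["A", "B", "C"], "x": [1.0, None, 3.0]})
        ctd, _ = pt.match(basic_tree, df)
        assert pt.summarize(ctd).n_missing == 1

    def test_peek_head_and_tail(self, anolis_like):
        head = pt.peek(anolis_like, "head", 2)
        assert "sp1" in head and "sp3" not in head
        assert "tree 1: 6 tips" in head
        tail = pt.peek(anolis_like, "tail", 10)  # more rows than exist
        assert "sp6" in tail and "sp1" in tail

    def test_peek_does_not_mutate(self, anolis_like):
        before = anolis_like.table.data.copy()
        pt.peek(anolis_like, "head", 3)
        pd.testing.assert_frame_equal(anolis_like.table.data, before)


class TestMethodAPI:
    def test_methods_mirror_functions(self, anolis_like):
        assert anolis_like.extract_vector("SVL").tolist() == [3.5, 4.0, 2.5, 5.0, 1.5, 2.0]
        out = anolis_like.query(where='island == "Cuba"')
        assert out.n_taxa == 2
        assert anolis_like.drop_taxa({"sp1"}).n_taxa == 5
        assert "taxa" in str(anolis_like.summarize())
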