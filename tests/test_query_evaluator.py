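"""Row-wise evaluation semantics and the filtering laws."""

import math
import random

import pytest

from proteofilter.errors import ConfigurationError, EvaluationError, ValidationError
from proteofilter.go_annotations import AnnotationStore, GOTerm
from proteofilter.query_evaluator import (
    EvalContext,
    compute_double,
    eval_query,
    eval_statement,
    filter_table,
    matching_indices,
)
from proteofilter.query_language import (
    BoolOp,
    Comparator,
    Connective,
    DoubleStatement,
    GeneOntologyStatement,
    InStatement,
    SingleStatement,
    Transform,
    parse_query,
)
from proteofilter.tabular_io import DataTable

from oracle import naive_survivors, random_query, random_table


class TestComputeDouble:
    @pytest.mark.parametrize(
        ("transform", "a", "b", "expected"),
        [
            (Transform.LOG2, 8, 2, 2.0),
            (Transform.LOG2, 2, 2, 0.0),
            (Transform.LOG10, 1000, 1, 3.0),
            (Transform.ABS, -6, 2, 3.0),
            (Transform.NONE, 7, 2, 3.5),
            (Transform.LOG10, 5, 0, None),       # division by zero
            (Transform.LOG2, -4, 2, None),       # log of a negative ratio
            (Transform.LOG2, None, 2, None),     # missing input
            (Transform.LOG2, "x", 2, None),      # non-numeric input
            (Transform.NONE, -4, 2, -2.0),       # plain ratio keeps its sign
        ],
    )
    def test_values_and_undefined(self, transform, a, b, expected):
        result = compute_double(transform, a, b)
        if expected is None:
            assert result is None
        else:
            assert result == pytest.approx(expected)


class TestEvalStatement:
    @pytest.fixture
    def ctx(self, tiny_table):
        return EvalContext(table=tiny_table)

    def test_double_true_when_log_ratio_clears_threshold(self, tiny_table):
        table = DataTable(["APEX1", "APEX2"], [[10.0, 2.0]])
        ctx = EvalContext(table=table)
        stmt = DoubleStatement(Transform.LOG2, "APEX1", "APEX2", Comparator.GE, 1.0)
        # independent check: log2(5) ~ 2.32 >= 1
        assert math.log2(10 / 2) >= 1
        assert eval_statement(stmt, table.rows[0], ctx) is True

    def test_double_false_on_equal_values(self):
        table = DataTable(["APEX1", "APEX2"], [[2.0, 2.0]])
        stmt = DoubleStatement(Transform.LOG2, "APEX1", "APEX2", Comparator.GE, 1.0)
        assert eval_statement(stmt, table.rows[0], EvalContext(table=table)) is False

    def test_single_on_missing_cell_is_false(self):
        table = DataTable(["A"], [[None]])
        stmt = SingleStatement("A", Comparator.EQ, 1)
        assert eval_statement(stmt, table.rows[0], EvalContext(table=table)) is False

    def test_cross_type_comparison_raises(self):
        table = DataTable(["A"], [["text"]])
        stmt = SingleStatement("A", Comparator.GT, 5)
        with pytest.raises(EvaluationError, match="compare"):
            eval_statement(stmt, table.rows[0], EvalContext(table=table))

    def test_in_membership_is_column_wide(self, tiny_table):
        ctx = EvalContext(table=tiny_table)
        stmt = InStatement("GENE", "TARGETS")
        # every row's TARGETS is "G1", so only the row with GENE == "G1" matches
        results = [eval_statement(stmt, row, ctx) for row in tiny_table.rows]
        assert results == [False, True, False, False, False, False]

    def test_go_statement_via_store(self):
        table = DataTable(["ID"], [["P04637"], ["P99999"]])
        store = AnnotationStore(species="Homo sapiens")
        store.add("P04637", GOTerm("GO:0008283", "cell proliferation", "P"))
        ctx = EvalContext(table=table, annotations=store, id_column="ID")
        stmt = GeneOntologyStatement(("proliferation",))
        assert eval_statement(stmt, table.rows[0], ctx) is True
        assert eval_statement(stmt, table.rows[1], ctx) is False  # unannotated

    def test_go_statement_without_store_is_config_error(self):
        table = DataTable(["ID"], [["P04637"]])
        ctx = EvalContext(table=table, id_column="ID")
        with pytest.raises(ConfigurationError):
            eval_statement(GeneOntologyStatement(("x",)), table.rows[0], ctx)


class TestEvalQuery:
    def test_connectives(self):
        table = DataTable(["A"], [[1]])
        ctx = EvalContext(table=table)
        true_leaf = SingleStatement("A", Comparator.EQ, 1)
        false_leaf = SingleStatement("A", Comparator.EQ, 2)
        row = table.rows[0]
        assert eval_query(Connective(BoolOp.AND, (true_leaf, false_leaf)), row, ctx) is False
        assert eval_query(Connective(BoolOp.OR, (false_leaf, true_leaf)), row, ctx) is True

    def test_compound_query_second_arm(self):
        """A suppressor protein with halved abundance passes via the OR's second arm."""
        table = DataTable(["#PROTEIN ID", "APEX 1", "APEX 2"], [["P04637", 1.0, 2.0]])
        store = AnnotationStore(species="Homo sapiens")
        store.add("P04637", GOTerm("GO:0007050", "cell cycle arrest", "P"))
        store.add("P04637", GOTerm("GO:0040015", "suppression of growth", "P"))
        node = parse_query(
            "((Gene Ontology = proliferation and log2 (APEX 1/APEX 2) >= 1) or "
            "(Gene Ontology = cycle and Gene Ontology = suppression and "
            "log2 (APEX 1 /APEX 2) < 1))"
        )
        ctx = EvalContext(table=table, annotations=store, id_column="#PROTEIN ID")
        assert math.log2(1.0 / 2.0) < 1  # the arm-2 ratio condition, checked by hand
        assert eval_query(node, table.rows[0], ctx) is True


class TestFilterTable:
    def test_simple_count(self, tiny_table):
        filtered = filter_table(tiny_table, parse_query("APEX 1 > 5"))
        assert filtered.n_rows == 3
        assert [r[2] for r in filtered.rows] == [7.0, 9.0, 11.0]
        assert filtered.columns == tiny_table.columns

    def test_alias_spelling_matches(self, tiny_table):
        assert filter_table(tiny_table, parse_query("APEX1 > 5")).n_rows == 3

    def test_nothing_matches(self, tiny_table):
        filtered = filter_table(tiny_table, parse_query("APEX 1 > 100"))
        assert filtered.n_rows == 0
        assert filtered.columns == tiny_table.columns

    def test_unknown_column_is_validation_error(self, tiny_table):
        with pytest.raises(ValidationError, match="NOPE"):
            filter_table(tiny_table, parse_query("NOPE = 1"))

    def test_go_query_without_store_is_config_error(self, tiny_table):
        node = parse_query("GeneOntology=proliferation")
        with pytest.raises(ConfigurationError):
            filter_table(tiny_table, node, annotations=None, id_column="#PROTEIN ID")

    def test_idempotent(self, tiny_table):
        node = parse_query("APEX 1 > 5")
        once = filter_table(tiny_table, node)
        assert filter_table(once, node) == once


class TestFilteringLaws:
    """Algebraic laws on fuzzed tables; the haystack of `in` statements is
    always taken from the original input table, so AND = intersection and
    OR = union hold universally."""

    def test_and_is_intersection_or_is_union(self):
        rng = random.Random(11)
        for _ in range(60):
            table = random_table(rng, max_rows=40)
            q1, q2 = random_query(rng, 2), random_query(rng, 2)
            try:
                s1 = set(matching_indices(table, q1))
                s2 = set(matching_indices(table, q2))
                s_and = set(matching_indices(table, Connective(BoolOp.AND, (q1, q2))))
                s_or = set(matching_indices(table, Connective(BoolOp.OR, (q1, q2))))
            except EvaluationError:
                continue  # cross-type draws are legitimately rejected
            assert s_and == s1 & s2
            assert s_or == s1 | s2

    def test_subset_and_order_preserved(self):
        rng = random.Random(13)
        for _ in range(40):
            table = random_table(rng, max_rows=40)
            try:
                idx = matching_indices(table, random_query(rng))
            except EvaluationError:
                continue
            assert idx == sorted(idx)
            assert all(0 <= i < table.n_rows for i in idx)

    def test_matches_naive_oracle(self):
        """Engine vs the brute-force full-evaluation oracle, 300 random pairs."""
        rng = random.Random(17)
        checked = 0
        for _ in range(300):
            table = random_table(rng, max_rows=50)
            node = random_query(rng)
            try:
                expected = naive_survivors(table, node)
            except TypeError:
                with pytest.raises(EvaluationError):
                    matching_indices(table, node)
                continue
            assert matching_indices(table, node) == expected
            checked += 1
        assert checked > 200
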