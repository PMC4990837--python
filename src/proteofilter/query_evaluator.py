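"""Row-by-row evaluation of a query tree over a table.

Each statement is solved independently per row, then the connective tree is
evaluated: AND requires all children true, OR any — short-circuiting is used
but statements are side-effect free, so the result equals full evaluation.

Semantics of the awkward cases, fixed once:

* a statement over a missing cell, or an undefined arithmetic result
  (division by zero, a log of a non-positive ratio), evaluates **false** —
  a row lacking evidence does not meet the restrictions; it never errors and
  never counts as true;
* comparing a number with text is an evaluation error naming the row and
  statement (EQ/NE included — the comparators are total within one type
  only);
* ``in`` statement membership is tested against the haystack column of the
  **original** input table, computed once before filtering, so filtering
  with ``AND(q1, q2)`` always equals intersecting the survivors of ``q1``
  and ``q2``;
* text ordering (``<`` etc.) is lexicographic on code points, equality is
  case-sensitive and exact.
"""

from __future__ import annotations

import math
import operator
from dataclasses import dataclass, field

from .errors import ConfigurationError, EvaluationError, ValidationError
from .go_annotations import AnnotationStore, lookup_terms, match_keywords
from .query_language import (
    BoolOp,
    Comparator,
    Connective,
    DoubleStatement,
    GeneOntologyStatement,
    InStatement,
    QueryNode,
    SingleStatement,
    Statement,
    Transform,
    build_alias_map,
    iter_statements,
    resolve_column,
    validate,
)
from .tabular_io import Cell, DataTable

_COMPARE = {
    Comparator.EQ: operator.eq,
    Comparator.NE: operator.ne,
    Comparator.LT: operator.lt,
    Comparator.LE: operator.le,
    Comparator.GT: operator.gt,
    Comparator.GE: operator.ge,
}


@dataclass
class EvalContext:
    """Read-only evaluation state for one query over one table."""

    table: DataTable
    annotations: AnnotationStore | None = None
    id_column: str | None = None
    column_aliases: dict[str, str] = field(default_factory=dict)
    _haystacks: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.column_aliases:
            self.column_aliases = build_alias_map(self.table.columns)

    def column_of(self, name: str) -> int:
        resolved = resolve_column(name, self.column_aliases)
        if resolved is None:
            raise EvaluationError(f"column {name!r} not found in table")
        return self.table.column_index(resolved)

    def haystack(self, column_name: str) -> frozenset:
        """Set of the column's non-missing values, built lazily from the
        original table and cached for the lifetime of the context."""
        resolved = resolve_column(column_name, self.column_aliases)
        if resolved is None:
            raise EvaluationError(f"column {column_name!r} not found in table")
        if resolved not in self._haystacks:
            self._haystacks[resolved] = frozenset(
                v for v in self.table.column_values(resolved) if v is not None
            )
        return self._haystacks[resolved]


def compute_double(transform: Transform, a: Cell, b: Cell) -> float | None:
    """transform(a/b), or None when undefined.

    Undefined means: either input missing or non-numeric, b == 0, or a
    non-positive ratio under log2/log10.
    """
    if not isinstance(a, (int, float)) or not isinstance(b, (int, float)):
        return None
    if b == 0:
        return None
    ratio = a / b
    if transform is Transform.NONE:
        return ratio
    if transform is Transform.ABS:
        return abs(ratio)
    if ratio <= 0:
        return None
    return math.log2(ratio) if transform is Transform.LOG2 else math.log10(ratio)


def _compare(comparator: Comparator, left: Cell, right: Cell, stmt: Statement) -> bool:
    left_num = isinstance(left, (int, float))
    right_num = isinstance(right, (int, float))
    if left_num != right_num:
        from .query_language import _print_statement

        raise EvaluationError(
            f"cannot compare {type(left).__name__} with {type(right).__name__} "
            f"in statement: {_print_statement(stmt)}"
        )
    return _COMPARE[comparator](left, right)


def eval_statement(stmt: Statement, row: list[Cell], ctx: EvalContext) -> bool:
    """Evaluate one statement on one row; missing evidence is false."""
    if isinstance(stmt, SingleStatement):
        cell = row[ctx.column_of(stmt.field)]
        if cell is None:
            return False
        if stmt.modifier is Transform.ABS:
            if not isinstance(cell, (int, float)):
                from .query_language import _print_statement

                raise EvaluationError(
                    f"'abs' modifier on non-numeric cell {cell!r} "
                    f"in statement: {_print_statement(stmt)}"
                )
            cell = abs(cell)
        return _compare(stmt.comparator, cell, stmt.value, stmt)

    if isinstance(stmt, DoubleStatement):
        a = row[ctx.column_of(stmt.numerator_field)]
        b = row[ctx.column_of(stmt.denominator_field)]
        value = compute_double(stmt.transform, a, b)
        if value is None:
            return False
        return _COMPARE[stmt.comparator](value, stmt.threshold)

    if isinstance(stmt, GeneOntologyStatement):
        if ctx.annotations is None:
            raise ConfigurationError(
                "query contains a Gene Ontology statement but no annotation store was provided"
            )
        id_field = stmt.id_field or ctx.id_column
        if id_field is None:
            raise ConfigurationError(
                "Gene Ontology statement has no protein identifier column bound"
            )
        cell = row[ctx.column_of(id_field)]
        if cell is None:
            return False
        terms = lookup_terms(ctx.annotations, str(cell))
        if not terms:
            return False
        return match_keywords(terms, stmt.keywords)

    if isinstance(stmt, InStatement):
        cell = row[ctx.column_of(stmt.needle_field)]
        if cell is None:
            return False
        return cell in ctx.haystack(stmt.haystack_field)

    raise TypeError(f"not a statement: {stmt!r}")


def eval_query(node: QueryNode, row: list[Cell], ctx: EvalContext) -> bool:
    """Structural recursion over the tree; AND = all children, OR = any."""
    if isinstance(node, Connective):
        children = (eval_query(child, row, ctx) for child in node.children)
        return all(children) if node.op is BoolOp.AND else any(children)
    return eval_statement(node, row, ctx)


def matching_indices(
    table: DataTable,
    node: QueryNode,
    annotations: AnnotationStore | None = None,
    id_column: str | None = None,
) -> list[int]:
    """Indices of rows satisfying the query, in original order."""
    issues = validate(node, table.columns) if id_column is None else validate_with_id(node, table, id_column)
    if issues:
        raise ValidationError("; ".join(issues))
    if annotations is None and any(
        isinstance(s, GeneOntologyStatement) for s in iter_statements(node)
    ):
        raise ConfigurationError(
            "query contains a Gene Ontology statement; provide a GAF annotation store"
        )
    ctx = EvalContext(table=table, annotations=annotations, id_column=id_column)
    survivors: list[int] = []
    for i, row in enumerate(table.rows):
        try:
            if eval_query(node, row, ctx):
                survivors.append(i)
        except EvaluationError as exc:
            raise EvaluationError(f"row {i}: {exc}") from None
    return survivors


def validate_with_id(node: QueryNode, table: DataTable, id_column: str) -> list[str]:
    """Validation variant that treats unbound GO statements as bound to ``id_column``."""
    from .query_language import bind_go_context

    bound = bind_go_context(node, id_column, species="")
    return validate(bound, table.columns)


def filter_table(
    table: DataTable,
    node: QueryNode,
    annotations: AnnotationStore | None = None,
    id_column: str | None = None,
) -> DataTable:
    """All the fields of the original table, restricted to surviving rows."""
    return table.subset(matching_indices(table, node, annotations, id_column))
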