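"""Independent brute-force query evaluation used as a test oracle.

This module re-implements filtering from the AST down, on purpose and from
scratch: fully parenthesized semantics (every child of a connective is
evaluated — no short-circuiting), its own arithmetic, its own column
resolution, and its own GO keyword matching over a plain ``id -> set of
term names`` dictionary.  It must never call into
``proteofilter.query_evaluator``.
"""

from __future__ import annotations

import math

from proteofilter.query_language import (
    BoolOp,
    Comparator,
    Connective,
    DoubleStatement,
    GeneOntologyStatement,
    InStatement,
    SingleStatement,
    Transform,
)

_OPS = {
    Comparator.EQ: lambda a, b: a == b,
    Comparator.NE: lambda a, b: a != b,
    Comparator.LT: lambda a, b: a < b,
    Comparator.LE: lambda a, b: a <= b,
    Comparator.GT: lambda a, b: a > b,
    Comparator.GE: lambda a, b: a >= b,
}


def _resolve(name: str, columns: list[str]) -> int:
    squeezed = "".join(name.split())
    for i, col in enumerate(columns):
        if col == name or "".join(col.split()) == squeezed:
            return i
    raise KeyError(name)


def _is_num(x) -> bool:
    return isinstance(x, (int, float))


def _eval_stmt(stmt, row, table, go_names: dict[str, set[str]] | None, id_column: str | None):
    columns = table.columns
    if isinstance(stmt, SingleStatement):
        cell = row[_resolve(stmt.field, columns)]
        if cell is None:
            return False
        if stmt.modifier is Transform.ABS:
            cell = abs(cell)
        if _is_num(cell) != _is_num(stmt.value):
            raise TypeError("cross-type comparison")
        return _OPS[stmt.comparator](cell, stmt.value)
    if isinstance(stmt, DoubleStatement):
        a = row[_resolve(stmt.numerator_field, columns)]
        b = row[_resolve(stmt.denominator_field, columns)]
        if not _is_num(a) or not _is_num(b) or b == 0:
            return False
        ratio = a / b
        if stmt.transform is Transform.LOG2:
            if ratio <= 0:
                return False
            value = math.log(ratio, 2)
        elif stmt.transform is Transform.LOG10:
            if ratio <= 0:
                return False
            value = math.log(ratio, 10)
        elif stmt.transform is Transform.ABS:
            value = abs(ratio)
        else:
            value = ratio
        return _OPS[stmt.comparator](value, stmt.threshold)
    if isinstance(stmt, InStatement):
        needle = row[_resolve(stmt.needle_field, columns)]
        if needle is None:
            return False
        hay_idx = _resolve(stmt.haystack_field, columns)
        for other in table.rows:
            value = other[hay_idx]
            if value is None:
                continue
            if value == needle or (_is_num(value) and _is_num(needle) and value == needle):
                return True
        return False
    if isinstance(stmt, GeneOntologyStatement):
        assert go_names is not None, "oracle needs a GO name map for GO statements"
        id_idx = _resolve(stmt.id_field or id_column, columns)
        cell = row[id_idx]
        if cell is None:
            return False
        key = str(cell)
        names = go_names.get(key)
        if names is None and "." in key:  # versioned Ensembl id
            names = go_names.get(key.rsplit(".", 1)[0])
        return any(k.lower() in n.lower() for n in (names or ()) for k in stmt.keywords)
    raise TypeError(stmt)


def naive_eval(node, row, table, go_names=None, id_column=None) -> bool:
    """Full (non-short-circuit) evaluation of the tree on one row."""
    if isinstance(node, Connective):
        results = [naive_eval(c, row, table, go_names, id_column) for c in node.children]
        return all(results) if node.op is BoolOp.AND else any(results)
    return _eval_stmt(node, row, table, go_names, id_column)


def naive_survivors(table, node, go_names=None, id_column=None) -> list[int]:
    return [i for i, row in enumerate(table.rows) if naive_eval(node, row, table, go_names, id_column)]


def go_names_from_gaf(gaf_path, term_tsv_path, taxon: int) -> dict[str, set[str]]:
    """Plain-text GAF digestion for the oracle: id/synonym -> set of term names."""
    names = {}
    with open(term_tsv_path, encoding="utf-8") as handle:
        for line in handle:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2:
                names[parts[0]] = parts[1]
    out: dict[str, set[str]] = {}
    with open(gaf_path, encoding="utf-8") as handle:
        for line in handle:
            if line.startswith("!") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if cols[12].split("|")[0] != f"taxon:{taxon}":
                continue
            term_name = names.get(cols[4], "")
            keys = [cols[1]] + [s for s in cols[10].split("|") if s]
            for key in keys:
                # the oracle strips Ensembl version suffixes the same way a
                # curator would read them
                out.setdefault(key, set()).add(term_name)
    return out


# ---------------------------------------------------------------------------
# random tables and queries for fuzzing


def random_table(rng, max_rows: int = 100):
    """Table with typed columns: NUM1/NUM2/NUM3 numeric, TXT1/TXT2 text."""
    from proteofilter.tabular_io import DataTable

    n = rng.randrange(1, max_rows + 1)
    words = ["alpha", "beta", "gamma", "delta", "epsilon"]
    rows = []
    for _ in range(n):
        row = []
        for _ in range(3):
            row.append(None if rng.random() < 0.08 else round(rng.uniform(-10, 10), 3))
        for _ in range(2):
            row.append(None if rng.random() < 0.08 else rng.choice(words))
        rows.append(row)
    return DataTable(["NUM1", "NUM2", "NUM3", "TXT1", "TXT2"], rows)


def random_statement(rng):
    kind = rng.randrange(4)
    num_cols = ["NUM1", "NUM2", "NUM3"]
    txt_cols = ["TXT1", "TXT2"]
    comparators = list(Comparator)
    if kind == 0:  # numeric single
        return SingleStatement(
            rng.choice(num_cols),
            rng.choice(comparators),
            round(rng.uniform(-10, 10), 2),
            Transform.ABS if rng.random() < 0.3 else Transform.NONE,
        )
    if kind == 1:  # text single
        return SingleStatement(
            rng.choice(txt_cols),
            rng.choice(comparators),
            rng.choice(["alpha", "beta", "gamma", "zeta"]),
        )
    if kind == 2:  # double
        return DoubleStatement(
            rng.choice([Transform.LOG2, Transform.LOG10, Transform.ABS]),
            rng.choice(num_cols),
            rng.choice(num_cols),
            rng.choice(comparators),
            round(rng.uniform(-3, 3), 2),
        )
    return InStatement(rng.choice(txt_cols), rng.choice(txt_cols))


def random_query(rng, max_depth: int = 3):
    if max_depth <= 1 or rng.random() < 0.4:
        return random_statement(rng)
    op = rng.choice([BoolOp.AND, BoolOp.OR])
    n_children = rng.randrange(2, 4)
    return Connective(op, tuple(random_query(rng, max_depth - 1) for _ in range(n_children)))
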