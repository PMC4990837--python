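"""The boolean clause language over result-table fields.

A query is a tree of statements joined by ``and``/``or`` with parentheses;
``and`` binds tighter than ``or``, parentheses override, and both keywords
are case-insensitive.  Four statement kinds exist:

* *single* — one field compared to a literal, optionally through ``abs``
  (the "modifier" for discriminating values around zero):
  ``SCORE >= 0.9``, ``abs LOGFC > 1``
* *Gene Ontology* — the row's protein identifier looked up in a GO
  annotation store and matched against keywords; comma-separated keywords
  in one statement are OR-combined:
  ``GeneOntology = proliferation, growth``
* *double* — a transformed ratio of two fields of the same row against a
  numeric threshold: ``log2(APEX 1/APEX 2) >= 1``
* *in* — the row's value in one field must occur somewhere in another
  field's column: ``GENE in TARGETS``

Field tokens may be double-quoted to include arbitrary characters; unquoted
multi-word names (``APEX 1``) are accepted and joined on single spaces,
terminated by a comparator, ``/``, ``in``, a connective, or a parenthesis.

Grammar::

    query      := or_expr
    or_expr    := and_expr { "or" and_expr }
    and_expr   := primary { "and" primary }
    primary    := "(" query ")" | statement
    statement  := go_stmt | double_stmt | in_stmt | single_stmt
    go_stmt    := ("GeneOntology" | "Gene Ontology") "=" keyword { "," keyword }
    double_stmt:= ("log2"|"log10"|"abs") "(" field "/" field ")" comparator number
    in_stmt    := field "in" field
    single_stmt:= [ "abs" ] field comparator literal
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field, replace
from enum import Enum
from typing import Union

from .errors import QueryParseError
from .tabular_io import normalize_name, parse_cell


class Comparator(Enum):
    EQ = "="
    NE = "!="
    LT = "<"
    LE = "<="
    GT = ">"
    GE = ">="


class Transform(Enum):
    NONE = "none"
    LOG2 = "log2"
    LOG10 = "log10"
    ABS = "abs"


class BoolOp(Enum):
    AND = "and"
    OR = "or"


@dataclass(frozen=True)
class SingleStatement:
    """Compare one field's cell to a literal; ``modifier`` is NONE or ABS."""

    field: str
    comparator: Comparator
    value: Union[int, float, str]
    modifier: Transform = Transform.NONE


@dataclass(frozen=True)
class GeneOntologyStatement:
    """Match the row's protein ID annotations against keywords (OR across them).

    ``id_field`` and ``species`` are not part of the query text — they are
    bound later from the run configuration (see :func:`bind_go_context`).
    """

    keywords: tuple[str, ...]
    id_field: str | None = None
    species: str | None = None


@dataclass(frozen=True)
class DoubleStatement:
    """Compare transform(numerator/denominator) of one row to a threshold."""

    transform: Transform
    numerator_field: str
    denominator_field: str
    comparator: Comparator
    threshold: float


@dataclass(frozen=True)
class InStatement:
    """True when the row's needle cell occurs anywhere in the haystack column."""

    needle_field: str
    haystack_field: str


Statement = Union[SingleStatement, GeneOntologyStatement, DoubleStatement, InStatement]


@dataclass(frozen=True)
class Connective:
    op: BoolOp
    children: tuple["QueryNode", ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise ValueError("a connective needs at least two children")


QueryNode = Union[Statement, Connective]

_RESERVED = {"and", "or", "in"}
_TRANSFORMS = {"log2": Transform.LOG2, "log10": Transform.LOG10, "abs": Transform.ABS}
_COMPARATORS = {c.value: c for c in Comparator}

# ---------------------------------------------------------------------------
# tokenizer


@dataclass(frozen=True)
class _Token:
    kind: str  # WORD | QUOTED | CMP | LPAREN | RPAREN | SLASH | COMMA
    text: str
    pos: int


_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<quoted>"(?:[^"\\]|\\.)*")
  | (?P<cmp>>=|<=|!=|=|<|>)
  | (?P<lparen>\()
  | (?P<rparen>\))
  | (?P<slash>/)
  | (?P<comma>,)
  | (?P<word>[^\s"<>=!/(),]+)
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[_Token]:
    tokens: list[_Token] = []
    pos = 0
    while pos < len(text):
        match = _TOKEN_RE.match(text, pos)
        if match is None:
            raise QueryParseError(f"unexpected character {text[pos]!r}", pos)
        kind = match.lastgroup
        if kind != "ws":
            raw = match.group()
            if kind == "quoted":
                raw = re.sub(r"\\(.)", r"\1", raw[1:-1])
            tokens.append(_Token(kind.upper(), raw, pos))
        pos = match.end()
    return tokens


# ---------------------------------------------------------------------------
# parser


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.index = 0

    # -- token helpers -----------------------------------------------------
    def _peek(self, offset: int = 0) -> _Token | None:
        i = self.index + offset
        return self.tokens[i] if i < len(self.tokens) else None

    def _next(self) -> _Token:
        token = self._peek()
        if token is None:
            raise QueryParseError("unexpected end of query", len(self.text))
        self.index += 1
        return token

    def _at_word(self, *words: str, offset: int = 0) -> bool:
        token = self._peek(offset)
        return token is not None and token.kind == "WORD" and token.text.lower() in words

    def _expect(self, kind: str, what: str) -> _Token:
        token = self._peek()
        if token is None or token.kind != kind:
            pos = token.pos if token else len(self.text)
            got = repr(token.text) if token else "end of query"
            raise QueryParseError(f"expected {what}, got {got}", pos)
        return self._next()

    # -- grammar -----------------------------------------------------------
    def parse(self) -> QueryNode:
        if not self.tokens:
            raise QueryParseError("empty query", 0)
        node = self._or_expr()
        trailing = self._peek()
        if trailing is not None:
            raise QueryParseError(f"unexpected trailing {trailing.text!r}", trailing.pos)
        return node

    def _or_expr(self) -> QueryNode:
        children = [self._and_expr()]
        while self._at_word("or"):
            self._next()
            children.append(self._and_expr())
        if len(children) == 1:
            return children[0]
        return Connective(BoolOp.OR, tuple(children))

    def _and_expr(self) -> QueryNode:
        children = [self._primary()]
        while self._at_word("and"):
            self._next()
            children.append(self._primary())
        if len(children) == 1:
            return children[0]
        return Connective(BoolOp.AND, tuple(children))

    def _primary(self) -> QueryNode:
        token = self._peek()
        if token is None:
            raise QueryParseError("dangling connective: expected a statement", len(self.text))
        if token.kind == "LPAREN":
            self._next()
            node = self._or_expr()
            self._expect("RPAREN", "')'")
            return node
        return self._statement()

    def _statement(self) -> Statement:
        if self._go_key_length() > 0:
            return self._go_statement()
        token = self._peek()
        if (
            token is not None
            and token.kind == "WORD"
            and token.text.lower() in _TRANSFORMS
            and (peeked := self._peek(1)) is not None
            and peeked.kind == "LPAREN"
        ):
            return self._double_statement()
        modifier = Transform.NONE
        if self._at_word("abs"):
            self._next()
            modifier = Transform.ABS
        field = self._field("field name")
        nxt = self._peek()
        if nxt is not None and nxt.kind == "WORD" and nxt.text.lower() == "in":
            self._next()
            haystack = self._field("haystack field name")
            if modifier is not Transform.NONE:
                raise QueryParseError("'abs' cannot modify an 'in' statement", nxt.pos)
            return InStatement(field, haystack)
        comparator = self._comparator()
        value = self._literal()
        return SingleStatement(field, comparator, value, modifier)

    def _go_key_length(self) -> int:
        """Number of tokens forming a Gene Ontology key at the cursor, else 0."""
        if self._at_word("geneontology") and self._is_cmp_at(1, "="):
            return 1
        if self._at_word("gene") and self._at_word("ontology", offset=1) and self._is_cmp_at(2, "="):
            return 2
        return 0

    def _is_cmp_at(self, offset: int, symbol: str) -> bool:
        token = self._peek(offset)
        return token is not None and token.kind == "CMP" and token.text == symbol

    def _go_statement(self) -> GeneOntologyStatement:
        for _ in range(self._go_key_length()):
            self._next()
        self._next()  # the '='
        keywords = [self._keyword()]
        while (token := self._peek()) is not None and token.kind == "COMMA":
            self._next()
            keywords.append(self._keyword())
        return GeneOntologyStatement(tuple(keywords))

    def _keyword(self) -> str:
        token = self._peek()
        if token is not None and token.kind == "QUOTED":
            self._next()
            return token.text
        words: list[str] = []
        while (token := self._peek()) is not None and token.kind == "WORD":
            if token.text.lower() in _RESERVED:
                break
            words.append(self._next().text)
        if not words:
            pos = token.pos if token else len(self.text)
            raise QueryParseError("empty Gene Ontology keyword", pos)
        return " ".join(words)

    def _double_statement(self) -> DoubleStatement:
        transform = _TRANSFORMS[self._next().text.lower()]
        self._expect("LPAREN", "'('")
        numerator = self._field("numerator field")
        self._expect("SLASH", "'/'")
        denominator = self._field("denominator field")
        self._expect("RPAREN", "')'")
        comparator = self._comparator()
        token = self._expect_literal_token()
        threshold = parse_cell(token.text)
        if not isinstance(threshold, (int, float)):
            raise QueryParseError(
                f"double statement threshold must be a number, got {token.text!r}", token.pos
            )
        return DoubleStatement(transform, numerator, denominator, comparator, float(threshold))

    def _field(self, what: str) -> str:
        token = self._peek()
        if token is not None and token.kind == "QUOTED":
            self._next()
            return normalize_name(token.text)
        words: list[str] = []
        while (token := self._peek()) is not None and token.kind == "WORD":
            if token.text.lower() in _RESERVED:
                break
            words.append(self._next().text)
        if not words:
            pos = token.pos if token else len(self.text)
            raise QueryParseError(f"expected {what}", pos)
        return " ".join(words)

    def _comparator(self) -> Comparator:
        token = self._expect("CMP", "a comparator (=, !=, <, <=, >, >=)")
        return _COMPARATORS[token.text]

    def _expect_literal_token(self) -> _Token:
        token = self._peek()
        if token is None or token.kind not in ("WORD", "QUOTED"):
            pos = token.pos if token else len(self.text)
            raise QueryParseError("expected a literal value", pos)
        return self._next()

    def _literal(self) -> Union[int, float, str]:
        token = self._peek()
        if token is not None and token.kind == "QUOTED":
            self._next()
            return token.text  # quoted literals are always text
        words: list[str] = []
        while (token := self._peek()) is not None and token.kind == "WORD":
            if token.text.lower() in _RESERVED:
                break
            words.append(self._next().text)
        if not words:
            pos = token.pos if token else len(self.text)
            raise QueryParseError("expected a literal value", pos)
        if len(words) == 1:
            parsed = parse_cell(words[0])
            return parsed if parsed is not None else words[0]
        return " ".join(words)


def parse_query(text: str) -> QueryNode:
    """Parse a query string into its AST.

    Raises :class:`~proteofilter.errors.QueryParseError` with the character
    position on unbalanced parentheses, dangling connectives, unknown
    comparators, or empty keyword lists.
    """
    if not text or not text.strip():
        raise QueryParseError("empty query", 0)
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# canonical printing

_SAFE_WORD_RE = re.compile(r'[^\s"<>=!/(),]+\Z')


def _word_is_safe(word: str) -> bool:
    if not _SAFE_WORD_RE.match(word):
        return False
    if word.lower() in _RESERVED or word.lower() in _TRANSFORMS:
        return False
    return True


def _quote(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _print_field(name: str) -> str:
    words = name.split(" ")
    if all(_word_is_safe(w) for w in words) and words[0].lower() not in ("gene", "geneontology"):
        return name
    return _quote(name)


def _print_number(value: float) -> str:
    if isinstance(value, int) or float(value).is_integer():
        return str(int(value))
    return repr(float(value))


def _print_statement(stmt: Statement) -> str:
    if isinstance(stmt, SingleStatement):
        prefix = "abs " if stmt.modifier is Transform.ABS else ""
        if isinstance(stmt.value, str):
            value = _quote(stmt.value)
        else:
            value = _print_number(stmt.value)
        return f"{prefix}{_print_field(stmt.field)} {stmt.comparator.value} {value}"
    if isinstance(stmt, GeneOntologyStatement):
        keywords = ", ".join(_quote(k) for k in stmt.keywords)
        return f"GeneOntology = {keywords}"
    if isinstance(stmt, DoubleStatement):
        if stmt.transform is Transform.NONE:
            # a plain (untransformed) ratio is constructible through the API
            # but has no concrete syntax in the clause language
            raise ValueError("a double statement without a transform has no textual form")
        return (
            f"{stmt.transform.value}({_print_field(stmt.numerator_field)} / "
            f"{_print_field(stmt.denominator_field)}) "
            f"{stmt.comparator.value} {_print_number(stmt.threshold)}"
        )
    if isinstance(stmt, InStatement):
        return f"{_print_field(stmt.needle_field)} in {_print_field(stmt.haystack_field)}"
    raise TypeError(f"not a statement: {stmt!r}")


def canonicalize(node: QueryNode) -> str:
    """Deterministic fully parenthesized text; parsing it back gives ``node``."""
    if isinstance(node, Connective):
        joined = f" {node.op.value} ".join(canonicalize(child) for child in node.children)
        return f"({joined})"
    return f"({_print_statement(node)})"


# ---------------------------------------------------------------------------
# validation against a table schema


def build_alias_map(columns: list[str]) -> dict[str, str]:
    """Map normalized and whitespace-stripped spellings to actual column names.

    ``APEX1`` resolves to column ``APEX 1``; exact (normalized) names always
    win over stripped aliases, and a stripped alias shared by two columns is
    dropped as ambiguous.
    """
    aliases: dict[str, str] = {}
    stripped_seen: dict[str, str | None] = {}
    for name in columns:
        canonical = normalize_name(name)
        aliases[canonical] = canonical
        stripped = canonical.replace(" ", "")
        if stripped in stripped_seen:
            stripped_seen[stripped] = None  # ambiguous
        else:
            stripped_seen[stripped] = canonical
    for stripped, target in stripped_seen.items():
        if target is not None and stripped not in aliases:
            aliases[stripped] = target
    return aliases


def resolve_column(name: str, aliases: dict[str, str]) -> str | None:
    canonical = normalize_name(name)
    if canonical in aliases:
        return aliases[canonical]
    return aliases.get(canonical.replace(" ", ""))


def iter_statements(node: QueryNode):
    """Yield every statement leaf of the tree, left to right."""
    if isinstance(node, Connective):
        for child in node.children:
            yield from iter_statements(child)
    else:
        yield node


def bind_go_context(node: QueryNode, id_field: str, species: str) -> QueryNode:
    """Return a copy with every Gene Ontology statement's context filled in."""
    if isinstance(node, Connective):
        return Connective(node.op, tuple(bind_go_context(c, id_field, species) for c in node.children))
    if isinstance(node, GeneOntologyStatement):
        return replace(node, id_field=id_field, species=species)
    return node


def validate(node: QueryNode, columns: list[str]) -> list[str]:
    """Statically check a query against a column list; issues are data, not exceptions.

    Reports statements referencing absent columns (after normalization and
    aliasing), statically detectable ill-typed comparisons (the ``abs``
    modifier on a text literal), and Gene Ontology statements with no bound
    identifier column.  An empty list means the query is runnable.
    """
    aliases = build_alias_map(columns)
    issues: list[str] = []

    def check_field(name: str, stmt: Statement) -> None:
        if resolve_column(name, aliases) is None:
            issues.append(f"column {name!r} not found (statement: {_print_statement(stmt)})")

    for stmt in iter_statements(node):
        if isinstance(stmt, SingleStatement):
            check_field(stmt.field, stmt)
            if stmt.modifier is Transform.ABS and isinstance(stmt.value, str):
                issues.append(
                    f"'abs' modifier requires a numeric literal, got text {stmt.value!r} "
                    f"(statement: {_print_statement(stmt)})"
                )
        elif isinstance(stmt, DoubleStatement):
            check_field(stmt.numerator_field, stmt)
            check_field(stmt.denominator_field, stmt)
        elif isinstance(stmt, InStatement):
            check_field(stmt.needle_field, stmt)
            check_field(stmt.haystack_field, stmt)
        elif isinstance(stmt, GeneOntologyStatement):
            if stmt.id_field is None:
                issues.append(
                    "Gene Ontology statement has no protein identifier column bound "
                    "(set id_field / --id-column)"
                )
            else:
                check_field(stmt.id_field, stmt)
            if not stmt.keywords:
                issues.append("Gene Ontology statement has an empty keyword list")
    return issues
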