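"""Deterministic generator of study-shaped synthetic inputs.

Emulates the shape of a shotgun-proteomics comparison export: a table with
a ``#PROTEIN ID`` column (identifiers drawn from all four supported classes
— Ensembl ENSP/ENST, UniProt accessions, numeric Gene IDs), a gene symbol
column, two APEX abundance columns whose log2 ratio separates constructed
"over-expressed" rows from the rest, and a ``TARGETS`` column for ``in``
queries.  Alongside the table it emits a matching mini-GAF (annotations for
a constructed subset, a decoy taxon for another) and a GO term-name TSV.

Ground truth — the exact surviving row sets for the worked queries below —
is computed at generation time from the construction parameters, never by
the filtering engine, so it can serve as an independent oracle in
end-to-end tests.

Only shape and identifier realism are attempted; APEX values are uniform
draws, not realistic abundance distributions.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from pathlib import Path

from .tabular_io import Cell, DataTable, parse_cell, write_table

#: the worked single-and-double query: over-expressed proliferation proteins
SIMPLE_QUERY = "GeneOntology=proliferation and log2(APEX1/APEX2)>=1"

#: its compound extension: also select under-expressed cell-cycle suppressors
COMPOUND_QUERY = (
    "((Gene Ontology = proliferation and log2 (APEX 1/APEX 2) >= 1) or "
    "(Gene Ontology = cycle and Gene Ontology = suppression and "
    "log2 (APEX 1 /APEX 2) < 1))"
)

#: the membership query: gene symbols that occur in the TARGETS column
IN_QUERY = "GENE in TARGETS"

TABLE_COLUMNS = ["#PROTEIN ID", "GENE", "APEX 1", "APEX 2", "TARGETS"]

_TERM_PROLIFERATION = ("GO:0008283", "cell proliferation", "P")
_TERM_CYCLE = ("GO:0007050", "cell cycle arrest", "P")
_TERM_SUPPRESSION = ("GO:0040015", "suppression of growth", "P")
_DECOY_TERMS = (
    ("GO:0005739", "mitochondrion", "C"),
    ("GO:0016301", "kinase activity", "F"),
)

HUMAN_TAXON = 9606
_DECOY_TAXON = 10090  # annotations under this taxon must be filtered out
_UNRELATED_TAXON = 559292


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic data set; same spec -> identical outputs."""

    n_rows: int = 200
    seed: int = 0
    fraction_annotated_proliferation: float = 0.30
    fraction_cycle_suppressor: float = 0.20
    fraction_over_expressed: float = 0.35
    fraction_human: float = 0.85
    fraction_targets: float = 0.40
    apex_range: tuple[float, float] = (0.5, 20.0)
    missing_rate: float = 0.02


@dataclass(frozen=True)
class GroundTruth:
    """Surviving row indices per worked query, fixed at generation time."""

    simple_query: frozenset[int]
    compound_query: frozenset[int]
    in_query: frozenset[int]


@dataclass(frozen=True)
class _RowPlan:
    base_id: str          # identifier as stored in the GAF
    table_id: str         # identifier as shown in the table (may carry .N version)
    gene: str
    apex1: float | None
    apex2: float | None
    target: str
    proliferation: bool   # carries the proliferation term
    cycle_suppressor: bool  # carries both cycle-arrest and growth-suppression terms
    decoy_annotated: bool
    human: bool           # annotation lines use the human taxon


def _draw_identifier(rng: random.Random, row_index: int, seen: set[str]) -> tuple[str, str]:
    kind = row_index % 4
    while True:
        if kind == 0:
            base = f"ENSP{rng.randrange(10**10, 10**11)}"
        elif kind == 1:
            base = f"P{rng.randrange(0, 100000):05d}"
        elif kind == 2:
            base = str(rng.randrange(1000, 999999))
        else:
            base = f"ENST{rng.randrange(10**10, 10**11)}"
        if base not in seen:
            seen.add(base)
            break
    table_id = base
    if kind in (0, 3) and rng.random() < 0.3:
        table_id = f"{base}.{rng.randrange(1, 5)}"  # versioned in the table only
    return base, table_id


def _plan(spec: FixtureSpec) -> list[_RowPlan]:
    rng = random.Random(spec.seed)
    lo, hi = spec.apex_range
    plans: list[_RowPlan] = []
    genes = [f"G{i:04d}" for i in range(spec.n_rows)]
    seen_ids: set[str] = set()
    for i in range(spec.n_rows):
        base_id, table_id = _draw_identifier(rng, i, seen_ids)
        proliferation = rng.random() < spec.fraction_annotated_proliferation
        cycle_suppressor = rng.random() < spec.fraction_cycle_suppressor
        decoy_annotated = rng.random() < 0.3
        human = rng.random() < spec.fraction_human
        over = rng.random() < spec.fraction_over_expressed
        # ratios keep a margin around 2.0 so rounding cannot cross log2 = 1
        ratio = rng.uniform(2.2, 8.0) if over else rng.uniform(0.25, 1.7)
        apex2: float | None = round(rng.uniform(lo, hi), 4)
        apex1: float | None = round(apex2 * ratio, 4)
        if rng.random() < spec.missing_rate:
            if rng.random() < 0.5:
                apex1 = None
            else:
                apex2 = None
        if rng.random() < spec.fraction_targets:
            target = genes[rng.randrange(spec.n_rows)]
        else:
            target = f"X{rng.randrange(10**6):06d}"  # never a gene symbol
        plans.append(
            _RowPlan(
                base_id=base_id,
                table_id=table_id,
                gene=genes[i],
                apex1=apex1,
                apex2=apex2,
                target=target,
                proliferation=proliferation,
                cycle_suppressor=cycle_suppressor,
                decoy_annotated=decoy_annotated,
                human=human,
            )
        )
    return plans


def _log2_ratio(plan: _RowPlan) -> float | None:
    if plan.apex1 is None or plan.apex2 is None or plan.apex2 == 0:
        return None
    if plan.apex1 / plan.apex2 <= 0:
        return None
    return math.log2(plan.apex1 / plan.apex2)


def _ground_truth(plans: list[_RowPlan]) -> GroundTruth:
    target_pool = {p.target for p in plans}
    simple: set[int] = set()
    compound: set[int] = set()
    in_set: set[int] = set()
    for i, plan in enumerate(plans):
        ratio = _log2_ratio(plan)
        over = ratio is not None and ratio >= 1
        under = ratio is not None and ratio < 1
        arm1 = plan.proliferation and plan.human and over
        arm2 = plan.cycle_suppressor and plan.human and under
        if arm1:
            simple.add(i)
        if arm1 or arm2:
            compound.add(i)
        if plan.gene in target_pool:
            in_set.add(i)
    return GroundTruth(frozenset(simple), frozenset(compound), frozenset(in_set))


def generate_table(spec: FixtureSpec) -> tuple[DataTable, GroundTruth]:
    """Build the synthetic comparison table and its query ground truth."""
    plans = _plan(spec)
    # numeric Gene IDs go through the same cell-typing rule the readers use,
    # so a written-and-reread fixture equals the in-memory one
    rows: list[list[Cell]] = [
        [parse_cell(p.table_id), p.gene, p.apex1, p.apex2, p.target] for p in plans
    ]
    return DataTable(list(TABLE_COLUMNS), rows), _ground_truth(plans)


def _gaf_line(object_id: str, symbol: str, term: tuple[str, str, str], taxon: int, synonyms: str) -> str:
    go_id, _name, aspect = term
    cols = [
        "FIXTURE",        # 1 DB
        object_id,        # 2 DB Object ID
        symbol,           # 3 DB Object Symbol
        "",               # 4 Qualifier
        go_id,            # 5 GO ID
        "REF:0000001",    # 6 DB:Reference
        "IEA",            # 7 Evidence Code
        "",               # 8 With/From
        aspect,           # 9 Aspect
        "",               # 10 DB Object Name
        synonyms,         # 11 Synonyms (pipe-separated)
        "protein",        # 12 DB Object Type
        f"taxon:{taxon}",  # 13 Taxon
        "20160819",       # 14 Date
        "FIXTURE",        # 15 Assigned By
        "",               # 16 Annotation Extension
        "",               # 17 Gene Product Form ID
    ]
    return "\t".join(cols)


def generate_gaf(spec: FixtureSpec, gaf_path: str | Path, term_names_path: str | Path) -> None:
    """Write the GAF annotating the generated proteins, plus the term-name TSV.

    Annotations of non-"human" rows are written under a decoy taxon so the
    species filter must exclude them; a few lines for identifiers absent
    from the table use a third, unrelated taxon.  Gene symbols are emitted
    as synonyms, so gene-symbol lookups resolve to the same term sets.
    """
    plans = _plan(spec)
    all_terms = [_TERM_PROLIFERATION, _TERM_CYCLE, _TERM_SUPPRESSION, *_DECOY_TERMS]
    lines = ["!gaf-version: 2.2", "! synthetic annotation fixture"]
    for plan in plans:
        taxon = HUMAN_TAXON if plan.human else _DECOY_TAXON
        terms: list[tuple[str, str, str]] = []
        if plan.proliferation:
            terms.append(_TERM_PROLIFERATION)
        if plan.cycle_suppressor:
            terms.extend((_TERM_CYCLE, _TERM_SUPPRESSION))
        if plan.decoy_annotated:
            terms.append(_DECOY_TERMS[sum(map(ord, plan.base_id)) % 2])
        for term in terms:
            lines.append(_gaf_line(plan.base_id, plan.gene, term, taxon, synonyms=plan.gene))
    # identifiers that exist only in an unrelated organism
    for j in range(5):
        lines.append(
            _gaf_line(f"YDR{j:03d}W", f"YEAST{j}", all_terms[j % len(all_terms)], _UNRELATED_TAXON, "")
        )
    Path(gaf_path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    tsv = "".join(f"{go_id}\t{name}\n" for go_id, name, _ in all_terms)
    Path(term_names_path).write_text(tsv, encoding="utf-8")


def _format_mztab_cell(value: Cell) -> str:
    if value is None:
        return "null"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_mztab(table: DataTable, path: str | Path, section: str = "PRT") -> None:
    """Serialize a table as one mzTab section (with a minimal MTD block)."""
    from .tabular_io import MZTAB_SECTIONS

    header_token = MZTAB_SECTIONS[section]
    lines = [
        "MTD\tmzTab-version\t1.0.0",
        "MTD\tmzTab-mode\tSummary",
        "MTD\tmzTab-type\tIdentification",
        "MTD\tdescription\tsynthetic fixture",
        header_token + "\t" + "\t".join(table.columns),
    ]
    for row in table.rows:
        lines.append(section + "\t" + "\t".join(_format_mztab_cell(c) for c in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_fixture_set(spec: FixtureSpec, directory: str | Path) -> dict:
    """Emit the full fixture family into ``directory``.

    Returns a dict with the table, the ground truth, and the paths of the
    XLSX / CSV / mzTab serializations, the GAF, and the term-name TSV.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    table, truth = generate_table(spec)
    paths = {
        "xlsx": directory / "table.xlsx",
        "csv": directory / "table.csv",
        "mztab": directory / "table.mztab",
        "gaf": directory / "annotations.gaf",
        "term_names": directory / "term_names.tsv",
    }
    write_table(table, paths["xlsx"], format="xlsx")
    _write_csv(table, paths["csv"])
    write_mztab(table, paths["mztab"])
    generate_gaf(spec, paths["gaf"], paths["term_names"])
    return {"table": table, "ground_truth": truth, "paths": paths}


def _write_csv(table: DataTable, path: Path) -> None:
    import csv

    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(table.columns)
        for row in table.rows:
            writer.writerow(["" if c is None else (repr(c) if isinstance(c, float) else c) for c in row])
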