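"""Protein identifier -> Gene Ontology term mapping from local GAF files.

The annotation store is built offline from a GAF 2.x file (tab-separated,
17 columns, ``!`` comment lines) restricted to one species, plus a
two-column TSV supplying human-readable names for GO term IDs (derivable
from go-basic.obo).  Keyword matching for Gene Ontology query statements is
a case-insensitive substring test against term *names* — the keyword
``proliferation`` matches a protein annotated with ``cell proliferation``.

Identifiers of all supported classes (Ensembl ENSP/ENST, UniProt
accessions, numeric Gene IDs) resolve through one map; the GAF object
identifier (column 2) and every pipe-separated synonym (column 11) are
merged as keys at load time.  No GO-graph (is-a ancestor) propagation is
performed: a protein matches only its directly annotated terms.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum, auto
from pathlib import Path

from .errors import InputError

logger = logging.getLogger(__name__)


class IDType(Enum):
    ENSEMBL_PROTEIN = auto()
    ENSEMBL_TRANSCRIPT = auto()
    UNIPROT = auto()
    GENE_ID = auto()
    UNKNOWN = auto()


_ENSP_RE = re.compile(r"ENSP\d+(\.\d+)?\Z")
_ENST_RE = re.compile(r"ENST\d+(\.\d+)?\Z")
# UniProt accession, the two official shapes (6 or 10 characters)
_UNIPROT_RE = re.compile(r"(?:[OPQ][0-9][A-Z0-9]{3}[0-9]|[A-NR-Z][0-9](?:[A-Z][A-Z0-9]{2}[0-9]){1,2})\Z")
_GO_ID_RE = re.compile(r"GO:\d{7}\Z")
_VERSION_SUFFIX_RE = re.compile(r"\.\d+\Z")

#: species name -> NCBI taxon id; extensible per-call via ``extra_taxa``
SPECIES_TAXA: dict[str, int] = {
    "Homo sapiens": 9606,
    "Mus musculus": 10090,
    "Rattus norvegicus": 10116,
    "Danio rerio": 7955,
    "Drosophila melanogaster": 7227,
    "Caenorhabditis elegans": 6239,
    "Saccharomyces cerevisiae": 559292,
    "Arabidopsis thaliana": 3702,
    "Escherichia coli": 562,
}


def detect_id_type(identifier: str) -> IDType:
    """Classify an identifier string; a pure function of its shape."""
    identifier = identifier.strip()
    if _ENSP_RE.match(identifier):
        return IDType.ENSEMBL_PROTEIN
    if _ENST_RE.match(identifier):
        return IDType.ENSEMBL_TRANSCRIPT
    if _UNIPROT_RE.match(identifier):
        return IDType.UNIPROT
    if identifier.isdigit():
        return IDType.GENE_ID
    return IDType.UNKNOWN


@dataclass(frozen=True)
class GOTerm:
    """One Gene Ontology term: ``GO:nnnnnnn`` id, name, and aspect (P/F/C)."""

    go_id: str
    name: str = ""
    aspect: str = ""

    def __post_init__(self) -> None:
        if not _GO_ID_RE.match(self.go_id):
            raise ValueError(f"malformed GO id: {self.go_id!r}")


def normalize_identifier(identifier: str) -> str:
    """Strip whitespace and the ``.N`` version suffix of Ensembl-style IDs."""
    identifier = identifier.strip()
    id_type = detect_id_type(identifier)
    if id_type in (IDType.ENSEMBL_PROTEIN, IDType.ENSEMBL_TRANSCRIPT):
        identifier = _VERSION_SUFFIX_RE.sub("", identifier)
    return identifier


@dataclass
class AnnotationStore:
    """GO terms per protein identifier for one species."""

    species: str
    by_id: dict[str, set[GOTerm]] = field(default_factory=dict)

    def add(self, identifier: str, term: GOTerm) -> None:
        self.by_id.setdefault(normalize_identifier(identifier), set()).add(term)

    def terms_for(self, identifier: str) -> frozenset[GOTerm]:
        return frozenset(self.by_id.get(normalize_identifier(identifier), ()))


def lookup_terms(store: AnnotationStore, identifier: str) -> frozenset[GOTerm]:
    """Term set for an identifier of any supported class; empty when unknown."""
    return store.terms_for(identifier)


def match_keywords(terms: frozenset[GOTerm] | set[GOTerm], keywords: list[str] | tuple[str, ...]) -> bool:
    """True iff ANY keyword is a case-insensitive substring of ANY term name.

    Multiple keywords in one Gene Ontology statement are OR-combined; a
    conjunctive requirement needs two statements joined by ``and``.
    """
    if not keywords:
        raise ValueError("keyword list must be non-empty")
    lowered = [k.lower() for k in keywords]
    return any(k in term.name.lower() for term in terms for k in lowered)


def species_taxon(species: str, extra_taxa: dict[str, int] | None = None) -> int | None:
    """Resolve a species name (or a literal taxon number) to an NCBI taxon id."""
    table = dict(SPECIES_TAXA)
    if extra_taxa:
        table.update(extra_taxa)
    for name, taxon in table.items():
        if name.lower() == species.strip().lower():
            return taxon
    if species.strip().isdigit():
        return int(species.strip())
    return None


def load_term_names(path: str | Path) -> dict[str, str]:
    """Read the two-column (go_id <TAB> name) TSV of term names."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"term-name table not found: {path}")
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) >= 2:
                names[parts[0].strip()] = parts[1].strip()
    return names


def _first_taxon(taxon_field: str) -> int | None:
    """GAF column 13 may hold ``taxon:9606`` or ``taxon:9606|taxon:...``;
    the first entry is the annotated organism."""
    first = taxon_field.split("|", 1)[0].strip()
    if first.lower().startswith("taxon:"):
        first = first[len("taxon:"):]
    return int(first) if first.isdigit() else None


def load_gaf(
    path: str | Path,
    species: str,
    term_names: dict[str, str] | None = None,
    *,
    extra_taxa: dict[str, int] | None = None,
) -> AnnotationStore:
    """Build an :class:`AnnotationStore` from a GAF 2.x file for one species.

    Every annotation line whose (first) taxon matches the requested species
    contributes its object identifier and all synonyms as keys for the line's
    GO term.  Malformed lines are skipped with a logged warning naming the
    line number; a species with zero annotations yields an empty store and a
    configuration warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"GAF file not found: {path}")
    taxon = species_taxon(species, extra_taxa)
    if taxon is None:
        logger.warning("species %r not in the built-in taxon table; no annotations will match", species)
    term_names = term_names or {}
    store = AnnotationStore(species=species)
    n_lines = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 13:
                logger.warning("%s:%d: malformed GAF line (%d columns), skipped", path, lineno, len(cols))
                continue
            object_id, go_id, aspect = cols[1].strip(), cols[4].strip(), cols[8].strip()
            if not _GO_ID_RE.match(go_id):
                logger.warning("%s:%d: malformed GO id %r, skipped", path, lineno, go_id)
                continue
            line_taxon = _first_taxon(cols[12])
            if line_taxon is None:
                logger.warning("%s:%d: malformed taxon field %r, skipped", path, lineno, cols[12])
                continue
            if taxon is None or line_taxon != taxon:
                continue
            term = GOTerm(go_id=go_id, name=term_names.get(go_id, ""), aspect=aspect)
            store.add(object_id, term)
            for synonym in cols[10].split("|"):
                synonym = synonym.strip()
                if synonym:
                    store.add(synonym, term)
            n_lines += 1
    if n_lines == 0:
        logger.warning("no annotations for species %r in %s", species, path)
    return store
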