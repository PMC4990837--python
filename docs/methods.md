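# Methods

## The filtering model

`proteofilter` treats a mass-spectrometry result table as an ordered list of
rows over named columns, each cell a number, text, or missing. A query is a
finite tree: leaves are statements, internal nodes are `and`/`or`
connectives with at least two children. Every statement is solved
independently per row, then the tree is evaluated structurally — AND is the
conjunction of its children, OR the disjunction. Short-circuiting is used
for speed; because statements are side-effect free, the result is provably
identical to full evaluation (this equivalence is fuzz-tested against a
non-short-circuiting re-implementation).

Precedence is encoded at parse time only: `and` binds tighter than `or`,
both left-associative, parentheses override. The AST itself is
precedence-free; consecutive same-operator operands are flattened into one
n-ary connective.

## Statement semantics

**Single** — the cell is compared to the literal with one of
`= != < <= > >=`. The optional `abs` modifier takes the magnitude first,
which is the practical way to select "far from zero" values such as log
fold-changes of either sign. Comparators are total within a type: numbers
compare numerically, text compares by code point (equality case-sensitive
and exact). A number-vs-text comparison is an evaluation error naming the
row and statement — silently coercing would hide schema mistakes.

**Double** — `t(a/b) cmp threshold` with `t` in {log2, log10, abs}. The
value is *undefined* (and the statement false) when either cell is missing
or non-numeric, when `b = 0`, or when the ratio is non-positive under a
logarithm. A plain untransformed ratio is constructible through the API
(`Transform.NONE`) but has no concrete query syntax; users can divide in
their pipeline instead.

**Gene Ontology** — the row's identifier cell (from the bound identifier
column) is normalized (whitespace stripped; Ensembl ``.N`` version suffixes
removed) and looked up in the annotation store; the statement is true when
any keyword is a case-insensitive substring of any annotated term's *name*.
Substring-on-names is a deliberate interpretation: requiring exact equality
would make a keyword like `proliferation` match nothing, while searching
definitions would match far too much. Multiple keywords in one statement are
OR-combined (tested as an exact OR-decomposition); conjunction requires two
statements joined by `and`. Missing or unannotated identifiers evaluate
false.

**In** — membership of the row's needle cell in the set of non-missing
values of the haystack column, computed **once from the original input
table** and cached. Column-wise scope (rather than any per-row pairing) is
the design choice here; fixing the haystack to the original table makes the
algebra clean: survivors of `AND(q1, q2)` always equal the intersection of
the individual survivor sets, and OR the union — both laws are fuzz-tested.

**Missing data.** Any statement over a missing cell or an undefined
arithmetic result is false, never an error and never true: a row lacking
evidence does not meet the restrictions. Filtering is therefore monotone
(survivors are a subset, idempotent under re-filtering) but *not* closed
under negation — there is deliberately no `not` operator.

## The query grammar

```
query      := or_expr
or_expr    := and_expr { "or" and_expr }
and_expr   := primary { "and" primary }
primary    := "(" query ")" | statement
statement  := go_stmt | double_stmt | in_stmt | single_stmt
go_stmt    := ("GeneOntology" | "Gene Ontology") "=" keyword { "," keyword }
double_stmt:= ("log2"|"log10"|"abs") "(" field "/" field ")" comparator number
in_stmt    := field "in" field
single_stmt:= [ "abs" ] field comparator literal
```

Keywords `and`/`or`/`in` and the transform and `GeneOntology` heads are
case-insensitive. Unquoted field tokens are greedy runs of words terminated
by a comparator, `/`, `)`, `,`, or a reserved word, joined on single spaces
— so `APEX 1/APEX 2` parses without quotes; double quotes always work and
win ties. An unquoted literal that fully parses as a number is numeric,
otherwise text; quoted literals are always text. The parser is a small
hand-written recursive-descent over a regex tokenizer: the grammar is tiny
and the greedy multi-word field rule is easier to state directly than to
express in a generated-parser formalism. Parse errors carry the character
position.

`canonicalize` prints a deterministic, fully parenthesized form and is an
exact round trip (`parse(canonicalize(parse(s))) == parse(s)`), verified on
a seeded 200-query fuzz corpus and by a derandomized hypothesis property.

Gene Ontology statements need an identifier column and species that the
query text cannot carry (they are job-level settings); the AST fields exist
but are bound from the run configuration (`bind_go_context`) before
validation. `validate` is static and name-based: it reports unknown columns
(after normalization and aliasing), unbound GO statements, and the one
ill-typed combination detectable from names alone (`abs` on a text
literal); value-level type clashes surface at evaluation time.

## Column names and aliasing

Column names are normalized by trimming and collapsing internal whitespace,
compared case-sensitively. A second alias level maps whitespace-stripped
spellings to columns (`APEX1` resolves to `APEX 1`), because both spellings
occur in the wild in the same document; an alias claimed by two columns is
dropped as ambiguous rather than guessed.

## File formats

* **XLSX** via openpyxl; first non-empty row is the header (an assumption —
  result exports put the header first). Numeric cells keep their type;
  string cells go through the same numeric-detection rule as text formats so
  the three readers agree.
* **CSV/TSV** via the stdlib csv module. Comment handling: in the contiguous
  leading block, a line starting with the comment prefix is dropped *unless*
  it already splits into ≥ 2 delimited fields — this protects a header whose
  first cell is literally `#PROTEIN ID` while removing a prose preamble;
  after the header, prefix lines are dropped wherever they occur. Ragged
  rows are schema errors citing the line number.
* **mzTab** by first-column token dispatch (MTD ignored; PRH/PEH/PSH/SMH
  headers; PRT/PEP/PSM/SML data lines; `null` is the missing marker).
  Optional columns are kept verbatim; mzTab-M 2.0 small-molecule lines
  satisfy the same token rule. The hand parser exists because the reader
  must report *which* sections a file actually contains and reject data
  lines preceding their header; pyteomics' mzTab reader serves as an
  independent cross-check in the test suite.
* **GAF 2.x**: 17-column tab-separated, `!` comments. Column 2 (object id)
  and all pipe-separated column-11 synonyms key the line's GO term; the
  *first* entry of the taxon column identifies the organism. Malformed lines
  are skipped with a logged warning and line number. Species names map to
  NCBI taxa via a small built-in table (extensible per call); term names
  come from a two-column TSV. Biopython's GAF iterator is the cross-check
  oracle in tests. No is-a ancestor closure is computed — a protein matches
  only its directly annotated terms; this is a documented limitation, and
  keyword substring matching partly compensates (e.g. `cycle` matches any
  term name containing it).

**Round-trip caveat:** the cell-typing rule is applied uniformly on read,
so a *text* cell whose content looks like a number, or an empty-string
cell, is not representable distinctly from a number or from missing after a
write/read cycle. Within this rule, write-then-read is an exact identity
(floats serialized via `repr`, integers kept integral), tested across xlsx
and tsv.

## Identifier classes

`detect_id_type` is a pure function of the string: `ENSP`+digits →
Ensembl protein, `ENST`+digits → Ensembl transcript (both tolerate a `.N`
version, which lookups strip), the two official UniProt accession shapes
(6 or 10 characters), all-digits → Gene ID, else unknown. Transcript IDs
resolve only through the GAF's object-id/synonym columns — no external ID
mapping service is consulted; an ENST absent from those columns simply does
not annotate.

## The synthetic-data generator

`fixtures.generate_table` emulates the shape of a two-sample APEX
comparison export: columns `#PROTEIN ID` (cycling through all four
identifier classes, ~30 % of Ensembl IDs carrying a version suffix in the
table but not in the GAF), `GENE`, `APEX 1`, `APEX 2`, `TARGETS`. Defaults:
200 rows; 30 % of rows carry a proliferation annotation and 20 % the
cycle-arrest + growth-suppression pair, 85 % of annotated rows under the
human taxon and the rest under a decoy taxon that the species filter must
exclude; 35 % of rows are constructed over-expressed with the abundance
ratio drawn uniformly from [2.2, 8] (the rest from [0.25, 1.7] — both
intervals keep a margin around ratio 2 so that rounding to 4 decimals can
never move a row across the log2 = 1 threshold); abundances uniform on
[0.5, 20]; 2 % missing-cell rate on the APEX columns; 40 % of `TARGETS`
cells hold a real gene symbol. These are the generator's fixed study
conditions, chosen as plausible magnitudes for a mid-sized comparison
experiment; APEX values are uniform draws, not realistic spectral-count
distributions — passing tests demonstrate the *filtering semantics*, not
robustness to real abundance noise.

Ground truth (the exact survivor sets of the worked simple, compound, and
`in` queries) is computed at generation time from the construction flags
and plain `math.log2`, never by the engine under test, so end-to-end tests
compare two independent routes. Identifiers are drawn unique by
construction; all outputs are deterministic functions of the spec
(text outputs byte-identical; XLSX identical at table level).

## Numerical choices

No comparison tolerance anywhere: IEEE double semantics, thresholds compare
exactly as computed. Table equality in tests allows ≤ 1e-9 relative error
on floats (serialization uses shortest-round-trip `repr`, so in practice
trips are exact) and zero tolerance on integers and text.

## Problem sizes

The fuzz suites use 1000 random (table ≤ 100 rows, query depth ≤ 3) pairs
for engine-vs-oracle equivalence, 500 term/keyword sets for the
OR-decomposition, 200 queries for the parse/print fixpoint, and the 200-row
fixture for the end-to-end worked example — sizes at which every property
is exercised densely while the whole suite runs in seconds.

## Known limitations

* No `not` operator, cross-row aggregation, or query optimization.
* GO matching ignores term synonyms and definitions, and performs no
  graph propagation.
* One worksheet / one mzTab section per run; no legacy XLS; no spectra.
* The species table ships with nine common organisms; others must be given
  as explicit taxon numbers or via `extra_taxa`.
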