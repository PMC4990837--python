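# proteofilter

Filtering a shotgun-proteomics (or metabolomics) result table is usually the
first step between a mass-spectrometry pipeline's output — thousands of rows
of proteins with identifiers and abundance estimates — and a biologically
interpretable shortlist. `proteofilter` is an offline library and command-line
tool that does this with a small boolean query language evaluated row by row,
joined against local Gene Ontology (GO) annotations by protein identifier.

It reads XLSX worksheets, CSV/TSV files (including exports with a leading
comment block), and single sections (PRT/PEP/PSM/SML) of mzTab files, and
writes the surviving rows — all original columns — to XLSX or TSV.

## The query language

A query is a tree of *statements* joined by `and` / `or`, with parentheses;
`and` binds tighter than `or`. Statements come in four kinds:

| kind | example | meaning |
|---|---|---|
| single | `SCORE >= 0.9`, `abs LOGFC > 1` | one field against a literal; the optional `abs` modifier discriminates values around 0 by magnitude |
| double | `log2(APEX 1/APEX 2) >= 1` | a transformed ratio of two fields of the same row against a threshold (`log2`, `log10`, `abs`) |
| Gene Ontology | `GeneOntology = proliferation, growth` | the row's protein identifier (Ensembl ENSP/ENST, UniProt accession, or numeric Gene ID) is looked up in a GAF-derived annotation store; comma-separated keywords are OR-combined, matching case-insensitively as substrings of term names |
| in | `GENE in TARGETS` | the row's value in one column occurs somewhere in another column |

For a two-sample comparison with APEX abundance columns, selecting
over-expressed proliferation proteins *plus* under-expressed cell-cycle
suppressors is:

```
((Gene Ontology = proliferation and log2 (APEX 1/APEX 2) >= 1) or
 (Gene Ontology = cycle and Gene Ontology = suppression and log2 (APEX 1 /APEX 2) < 1))
```

Note the two GO statements joined by `and` in the second arm: keywords inside
*one* statement are OR-combined, so a conjunctive requirement needs two
statements. Unquoted multi-word column names (`APEX 1`) are accepted;
double-quote a name to include arbitrary characters (`"#PROTEIN ID"`).

## Worked example

```python
from proteofilter import filter_table, load_gaf, load_term_names, parse_query, bind_go_context
from proteofilter.fixtures import FixtureSpec, write_fixture_set, SIMPLE_QUERY

out = write_fixture_set(FixtureSpec(n_rows=200, seed=42), "demo")
table = out["table"]
store = load_gaf(out["paths"]["gaf"], "Homo sapiens",
                 load_term_names(out["paths"]["term_names"]))

node = bind_go_context(parse_query(SIMPLE_QUERY), "#PROTEIN ID", "Homo sapiens")
survivors = filter_table(table, node, store)
print(table.n_rows, "rows in,", survivors.n_rows, "rows out")
```

prints

```
200 rows in, 19 rows out
```

— the 19 rows that are both annotated with a proliferation term for
*Homo sapiens* and have `log2(APEX 1 / APEX 2) >= 1`, exactly the generator's
construction-time ground-truth set.

The same job from the shell:

```
proteofilter --input demo/table.xlsx --format xlsx --sheet filtered \
  --query "GeneOntology=proliferation and log2(APEX1/APEX2)>=1" \
  --id-column "#PROTEIN ID" --species "Homo sapiens" \
  --gaf demo/annotations.gaf --term-names demo/term_names.tsv \
  --output shortlist.xlsx
```

reports `200 rows in, 19 rows out -> shortlist.xlsx` on standard error and
exits 0; parse, validation, I/O, and configuration failures use distinct
nonzero exit codes, and a failed run never leaves a partial output file.

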