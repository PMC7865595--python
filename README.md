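# npderep

An NMR-based dereplication toolkit for natural-product chemistry.

Dereplication — the rapid identification of already-known compounds in an
extract — rests on three pillars: molecular structures, spectroscopic
signatures, and the taxonomy of the producing organisms. `npderep`
implements a complete desk workflow over those pillars:

* **Library building** (`npderep.taxondb`): from a list of genera and a
  taxonomic snapshot (compound identifiers keyed by organism binomials),
  assemble a validated compound library and write it as an SDF file. Every
  record passes an InChI round-trip check, SMILES/InChI agreement, and a
  molecular-formula reconciliation that accepts source formulas written
  without a charge sign or as the [M+H]⁺ ion observed in positive-mode ESI
  (the neutral formula M = [M+H]⁺ − H is then stored). Records whose
  recalculated InChIKeys collide are merged, pooling identifiers, names
  and organisms.
* **Chemical classification** (`npderep.chemclass`): a four-level
  hierarchy of substructure-defined classes (`01` primary-metabolite
  derived / `02` secondary metabolites, down to e.g.
  `01-01-14-005` = α-D-glucopyranose), matched stereo-aware with
  per-match atom lists, plus an eight-skeleton filter for
  Amaryllidaceae-type alkaloids (crinane, lycorane, galanthamine-,
  tazettine-, homolycorine-, montanine-, norbelladine-,
  phenanthridone-type).
* **¹³C shift prediction** (`npderep.nmr`): HOSE-code nearest-neighbour
  prediction. The HOSE code describes a carbon's environment sphere by
  sphere as a canonical string; predicted δ\_C is the mean shift stored in
  a reference table under the deepest matching sphere (4 → 3 → 2 → 1,
  then the table-wide mean).
* **Shift-list search** (`npderep.search`): a query is a list of observed
  δ\_C values (± multiplicities, ± a molecular-formula window such as
  `C(12-100) H(1-100) N(1-2) O(1-100)`) and a ppm tolerance. Candidates
  are matched by an optimal one-to-one assignment (maximum matched count,
  then minimum total |Δδ|, via the Hungarian algorithm) and ranked by
  matched count and mean absolute deviation (MAD).

Everything runs offline: `npderep.fixtures` generates a deterministic
snapshot, a reference shift table, and a 50-compound worked example (five
Amaryllidaceae alkaloids — tazettine, albomaculine, haemanthamine,
crinine, trisphaeridine — among 45 decoy natural products).

## Worked example

A mixture fraction shows an isolated aromatic singlet at δ\_H 9.16. HSQC
places its carbon at δ\_C 151.83; HMBC shows six surrounding carbons. That
one-proton neighbourhood becomes a seven-shift query:

```python
from npderep.fixtures import worked_example_bundle
from npderep.formula import parse_element_spec
from npderep.search import build_query, search_library

bundle = worked_example_bundle()
spec = parse_element_spec("C(12-100)H(1-100)N(1-2)O(1-100)", closed_world=True)
query = build_query(
    "151.83:1;100.36:1;105.40:1;122.82:0;124.03:0;129.6:0;143.74:0",
    tolerance=1.0, formula_spec=spec,
)
for hit in search_library(bundle.records, query):
    print(hit.record.names[0], hit.matched, round(hit.mad, 2))
```

prints

```
trisphaeridine 7 0.0
```

— at 1 ppm tolerance only trisphaeridine explains all seven shifts
(matched = 7, MAD = 0). Widening to 2 ppm admits a second candidate whose
predicted shifts sit 1–2 ppm off (papaverine, MAD 1.45); tolerance widening
only ever grows the hit list. The same search from the shell:

```bash
npderep fixtures --out fx
npderep search --library fx/worked_example_library.sdf \
    --shifts "151.83:1;100.36:1;105.40:1;122.82:0;124.03:0;129.6:0;143.74:0" \
    --tol 2 --formula "C(12-100)H(1-100)N(1-2)O(1-100)" --out hits.tsv
```

```
rank  inchikey                     name            matched  mad     assignment
1     RFILRSDHWIIIMN-UHFFFAOYSA-N  trisphaeridine  7        0.0000  0:7;1:9;...
2     XQYZDYMELSJDRZ-UHFFFAOYSA-N  papaverine      7        1.4457  0:9;1:3;...
```

Interestingly, trisphaeridine itself fails the Amaryllidaceae skeleton
filter (`npderep search --skeletons-only ...` drops it): its fully
aromatic phenanthridine core fits none of the eight canonical alkaloid
skeletons, even though the compound occurs in Amaryllidaceae — a caution
about structure-based stand-ins for biological taxonomy.

Library building from a genus list:

```bash
printf "Galanthus\nUrceolina\n" > genera.txt
npderep build --genera genera.txt --snapshot fx/worked_example_snapshot.json \
    --table fx/reference_table.tsv --nitrogen-only --out library.sdf
# wrote 7 records to library.sdf
```

The `--nitrogen-only` flag keeps possible alkaloids (≥ 1 N). Each SDF
record carries the structure (2D MOL block) plus tags: `KS_CID`, `NAME`,
`CAS`, `ORGANISMS`, `GENERA`, `MOLECULAR_FORMULA`, `INCHI`, `INCHIKEY`,
`PREDICTED_13C` (`atomIndex:shift:nH` triplets), `CLASSES`.

## Layout

```
src/npderep/
  formula.py     molecular-formula parsing, [M+H]+ arithmetic, range filters
  structures.py  InChI round-trip validation, SMIRKS standardization, dedup
  chemclass.py   class catalog, classification, stereo enumeration, skeletons
  nmr.py         HOSE codes, reference table, shift prediction
  search.py      shift-list queries, optimal assignment matching, ranking
  taxondb.py     snapshot providers, record validation, SDF emit/read
  fixtures.py    deterministic snapshot/table/worked-example generation
  cli.py         `npderep` command-line interface
  data/          class catalog, skeleton table, SMIRKS rules, genus list
```

See `docs/methods.md` for the scientific and numerical choices.
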