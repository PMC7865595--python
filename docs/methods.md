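# Methods

## Scope and model

`npderep` treats structural dereplication as a database problem over three
linked kinds of information: molecular structures (SMILES/InChI/MOL),
spectroscopic signatures (here, predicted ¹³C chemical shifts), and
taxonomy (which organisms produce which compounds). The toolkit builds the
database side (validated, organism-annotated, shift-annotated SDF
libraries) and the query side (tolerance-based shift-list search with
formula and skeleton constraints).

## Structure validation

A record is trusted only when its representations agree:

* the InChI **round trip** (decode → re-encode) must reproduce the input
  string character for character. This catches descriptors the decoder
  cannot represent — notably axial chirality of allenes and spirans, whose
  stereo layer is silently dropped on decoding;
* the InChI recalculated from the decoded structure must equal the source
  InChI (`inchi_mismatch` otherwise);
* the source formula must reconcile with the structure in one of three
  ways: exactly; ignoring a missing charge sign (common in source tables);
  or as the [M+H]⁺ ion formula of the structure, in which case the record
  is kept with status `protonated_adjusted` and the neutral formula.

Failures are never auto-repaired: rejected records go to a tab-separated
rejection report (ID, status, reason). External identifier-resolution
rescues are deliberately out of scope; a quarantine file keeps the
pipeline deterministic and auditable.

Tautomer normalization uses an ordered catalog of reaction-SMARTS rules
(`data/standardization_rules.tsv`), each applied to exhaustion: iminol →
amide (InChI decoding reconstructs aliphatic amides as iminols), C-nitroso
→ oxime, 1,3-dione enol → diketone. Tautomers share an InChI, so the
rules change the drawn form only; the overall pass is idempotent, and a
rule whose product fails sanitization is reported by ID and skipped. The
catalog is an editable text file because no published rule set is
exhaustive; rules can be removed or extended per project.

Deduplication merges records on the full 27-character recalculated
InChIKey (stereo-sensitive). Identifier, name and CAS lists are unioned
preserving first-seen order; organism and genus sets are unioned sorted;
scalar conflicts keep the first record's value and are logged.

## Chemical classification

Classes form a four-level hierarchy of dotted IDs: level 1 splits
primary-metabolite-derived (`01`) from secondary (`02`); deeper levels
refine (e.g. `02-02` terpenes → `02-02-01` monoterpenes →
`02-02-01-001` menthane skeleton; `01-01` sugars → `01-01-14`
hexopyranoses → `-005`/`-006` α-/β-D-glucopyranose). A node is assigned
when any of its patterns matches; every ancestor of an assigned node is
reported too (hierarchy closure), so menthol's path reads: secondary
metabolite, terpene, monoterpene, menthane compound. Matches record the
covered atom indices (0-based) per hit; closure-inherited assignments
carry the triggering descendant's atoms with `pattern_used = -1`.

Two pattern modes coexist in the catalog:

* `smarts` — the pattern text (SMILES or SMARTS) compiled as SMARTS and
  matched stereo-aware, so the α- and β-glucopyranose patterns are
  distinguished while staying substitution-agnostic at the anomeric
  oxygen;
* `scaffold` — the pattern is reduced to its Murcko scaffold and matched
  with generic bonds. Atom aromaticity still constrains the match, so a
  partially saturated ring skeleton tolerates unsaturation and oxidation
  variants (crinine's Δ1,2 vs. fully saturated crinanes) without matching
  flat aromatic frameworks.

The hexopyranose block is reconstructed programmatically rather than
shipped as 32 literal SMILES: stereo-enumerating the achiral scaffold
`OCC1OC(O)C(O)C(O)C1O` over its five assignable tetrahedral centres,
canonicalizing and deduplicating, yields exactly the 32 stereo-specified
chains (2⁵, no symmetry collapse), to which the generic achiral pattern is
added as the catalog's umbrella node. Enumeration assigns each parity
combination directly on atom chiral tags and relies on canonical-SMILES
deduplication to collapse meso and symmetry-equivalent forms; the test
suite cross-checks it against RDKit's independent stereoisomer enumerator.

The Amaryllidaceae skeleton filter holds eight patterns (crinane,
lycorane, galanthamine-, tazettine-, homolycorine-, montanine-,
norbelladine-, phenanthridone-type), shipped as config
(`data/amaryllidaceae_skeletons.tsv`) with provenance comments. Seven use
scaffold mode; the norbelladine linker is a raw SMARTS with
non-ring-atom constraints so the open-chain precursor motif does not fire
on ring-embedded C–C–N–C paths of the tetracyclic skeletons. A molecule
passes the filter when at least one skeleton matches. The fully aromatic
phenanthridine of trisphaeridine matches none — the known blind spot of
skeleton-based alkaloid definitions.

## HOSE codes and shift prediction

The HOSE code of an atom lists its neighbourhood sphere by sphere. Nodes
carry a token of bond symbol (`'' = # *`), element (lower-case when
aromatic), charge, and attached-H count; rings are unrolled, so an atom
reachable along two paths contributes to both branches. Child ordering is
canonical: each subtree gets a recursive canonical string (token plus
sorted child strings) computed at full depth, siblings are sorted by it,
and the per-sphere segments are then emitted level by level. Because the
ordering is fixed once at maximum depth, the cumulative code at depth d−1
is a string prefix of the code at depth d, and both table building and
lookup use the same prefixes. Automorphic atoms get identical codes; the
code is invariant under input atom renumbering. The rare consequence of
full-depth ordering is that two atoms in different molecules agreeing only
to depth d may render that prefix with different sibling orders and miss a
depth-d table hit; the predictor then falls back one sphere, a
conservative failure.

Stereochemistry is excluded from the code on purpose: constitution-level
¹³C prediction cannot separate enantiomers (crinine/vittatine-type pairs),
and pretending otherwise would overstate the method.

The reference table stores, per sphere depth 1–4, mean/count/spread of
the shifts pooled under each code (Welford accumulation; spread is the
population standard deviation). Prediction walks 4 → 3 → 2 → 1 and takes
the first hit's mean; with no hit anywhere it falls back to the table-wide
mean (`sphere_used = 0`), or 100.0 ppm for an empty table (logged).
Sphere depth is capped at 4 and sphere means are unweighted — standard
nearest-neighbour HOSE practice. Shifts outside −20…250 ppm are rejected
at build time. Training structures are self-predicted exactly at sphere 4
whenever carbons sharing a full-depth code share a shift value (true by
construction for the packaged fixtures).

## Shift-list matching

A query is a list of (δ\_C, multiplicity?) pairs, a ppm tolerance, an
optional element-range window, and two switches:

* `require_all` (default on): every query shift must find a partner. This
  is the right semantics for subset queries — a seven-shift HSQC/HMBC
  neighbourhood drawn from a mixture fraction must be fully explained by
  the candidate, while the candidate's remaining carbons go unpenalized.
* `multiplicity_mode` (`off` default, `strict`): `strict` requires equal
  attached-H counts; query shifts without a multiplicity stay
  unconstrained. Off by default because routine searches use shift values
  only.

Matching is a maximum-cardinality, minimum-total-|Δδ| one-to-one
assignment over pairs admissible within tolerance, solved with the
Hungarian algorithm on a cost matrix where inadmissible pairs carry a
penalty larger than any feasible total. One-to-one matching is the
stricter of the two common interpretations of tolerance search (the
alternative lets one candidate resonance satisfy several query shifts);
it was chosen because symmetry-equivalent carbons already contribute one
predicted value per atom, so coincident query shifts are absorbed exactly
when the molecule really has that many carbons. The exhaustive-search
equivalence is tested on 500 random instances.

Ranking: matched count (desc), MAD over assigned pairs (asc), InChIKey —
a total order, so results are identical across runs and platforms. The
element-range filter runs before matching; `closed_world` mode (default in
the CLI) also rejects formulas containing unlisted elements, the natural
reading of an alkaloid window written as C/H/N/O only.

## The synthetic fixtures

The fixture generator emulates a genus-indexed compound database snapshot
and a shift reference table so that every workflow runs offline and
deterministically.

* **Snapshot**: a pool of 50 valid natural-product structures (five
  Amaryllidaceae alkaloids, plus terpenes, phenylpropanoids, flavonoids,
  sugars and assorted alkaloids as decoys) distributed over genera with
  binomial species names. A `FixtureSpec` fixes genus/species/compound
  counts, a seed, the number of forced InChIKey collisions (identical
  structure under two identifiers) and of rows whose formula text is the
  [M+H]⁺ ion formula — the two validation paths the builder must handle.
  Generation is a pure function of the spec.
* **Shifts**: per-carbon reference shifts are a deterministic function of
  the carbon's HOSE-code prefix chain — a base value per carbon type
  (aromatic 128, olefinic 125, ester/amide carbonyl 170, ketone 200,
  acetal 98, C–O 68, C–N 48, alkyl 30 ppm) plus per-sphere pseudo-random
  contributions of decaying amplitude (±18, ±7, ±2.5, ±0.8 ppm, SHA-1
  keyed by the prefix). This emulates the locality of real ¹³C shifts:
  identical deep environments get identical shifts, and expected
  prediction error genuinely shrinks with matching depth, which is what
  the monotone-specificity test measures.
* **Worked example**: the five alkaloids and two near-miss decoys carry
  hand-assigned shift lists instead (chemically plausible magnitudes,
  including the handful of experimentally published values for these
  compounds); a shared code book gives any colliding environment the
  first-assigned value, keeping self-prediction exact. Papaverine's
  aromatic shifts sit 1.3–1.7 ppm from the seven-shift query (inside 2,
  outside 1 ppm) and harmine's 0.4–2.9 ppm (inside 5, outside 2), so the
  1 → 2 → 5 ppm tolerance ladder retrieves 1, 2 and 3 candidates — a
  non-vacuous monotonicity staircase with trisphaeridine always first.

What the fixtures do **not** emulate: real predicted-shift error against
experimental spectra (the engineered alkaloids self-predict exactly, so
worked-example MADs are optimistic), solvent and referencing effects,
signal overlap, and the true content of any live compound database.
Passing tests show the machinery is correct and deterministic, not that a
particular external database would yield the same hit counts.

## Numerical and design notes

* Formula rendering follows Hill order with a trailing charge sign;
  magnitudes > 1 are written magnitude-then-sign. Parsing accepts a bare
  trailing sign as |charge| = 1 only — outside brackets a magnitude digit
  is ambiguous with an atom count — while the bracketed ion notation
  (`[C16H18NO3]+`, `[SO4]2-`) carries any magnitude.
* SDF output is V2000 with 2D coordinates; record order is sorted by
  InChIKey, making builds byte-reproducible. `PREDICTED_13C` serializes
  `atomIndex:shift:nH` triplets (0-based, 2 decimals); a companion
  `PREDICTED_13C_SPHERES` tag preserves the sphere depths so reading a
  library back is lossless.
* Shift predictions attached to records are rounded to 2 decimals (the
  serialized precision) so in-memory and round-tripped records are equal.
* The empty library writes an empty file; the reader returns an empty
  list.
* The snapshot provider is a contract (`query_genus`, `fetch`), with the
  packaged JSON-serializable fixture as its only shipped implementation;
  a networked provider can be added behind the same two methods, but the
  toolkit intentionally ships none — service discontinuations are the
  main threat this design works around.
* Assignable stereocentres are those reported by RDKit's stereo
  perception; double-bond stereochemistry is never enumerated or assigned
  by the sugar machinery.
* Tolerances: shift comparisons are absolute differences on the δ scale
  in ppm; matching uses a 10⁶ penalty for inadmissible pairs, far above
  any feasible total deviation (≤ 8 shifts × tolerance).

## Known limitations

* The class catalog covers the exemplar branches (sugars with the full
  hexopyranose block, α-amino acids, the Amaryllidaceae skeletons,
  monoterpene/flavonoid anchors) plus the machinery to extend it; it is
  not a comprehensive chemical taxonomy.
* HOSE prediction quality is bounded by reference-table coverage; the
  packaged table only covers the fixture set. Real use requires building
  a table from an assigned-shift collection.
* Skeleton scaffolds match with generic bonds, so heavily rearranged
  (abeo-) skeletons may still fire a parent pattern; conversely aromatized
  skeletons (trisphaeridine) deliberately do not.
* Stereo descriptors in the fixture pool are representative, not verified
  absolute configurations; the toolkit's claims are constitution-level.
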