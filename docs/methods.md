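# Methods

## Model and scope

`chemlite` treats a compound knowledge base as a set of records
(CID, parent CID, structure identifiers, molecular formula,
literature/patent counts) each carrying an annotation fingerprint: a bitset
over a category index with one bit per top-level annotation category and one
per subcategory. The package's core claim is operational, not statistical:
given such a dump and a selection of categories, the six construction rules
produce a compact candidate database whose entries are structural skeletons
(InChIKey first blocks) with merged annotation, and exact-mass queries over
that database with metadata-weighted ranking recover known compounds at high
rank when the scoring terms carry signal.

The in-silico fragmentation and spectral-similarity scores themselves are
out of scope: they are consumed as externally supplied per-candidate values,
exactly as an identification workflow would hand them over.

## The category index

The index is an input, never hard-coded logic, because real annotation trees
are revised continually. The shipped reference index
(`src/chemlite/data/category_index.tsv`) freezes 14 top categories — the ten
selectable ones plus four deliberately unselected ones (physical properties,
spectra, literature, patents) so that rule 1 has something to discard — with
2–5 subcategories each, 58 bits total. Only one level of nesting is modeled;
deeper trees must be flattened onto their first-level subcategory before
export. Fingerprints are serialized as hex strings, least-significant bit =
bit 0.

Normalization: a fingerprint carrying a subcategory bit without its top bit
is treated as having the top bit too (applied on ingest). Per-category
scores gate on the top bit — after normalization the two conventions
coincide; for hand-constructed fingerprints the gate is the documented
behaviour.

## Construction rules: decisions worth recording

* **Best-CID metric.** "Most annotated" is measured as the number of
  fingerprint bits *within the active selection*; ties break to the lowest
  CID. Counting all bits instead would let never-selected categories (e.g.
  patent presence) decide the representative structure.
* **Filter order.** Element/disconnection filters run *after* collapsing, so
  eliminated counts are reported per skeleton and the accounting identity
  `kept + eliminated = total` is exact by construction.
* **Counts are summed** (not maximized) over merged entries — both across
  parent/child folds and across stereoisomer groups — reading the merged
  literature/patent totals as cumulative evidence for the skeleton.
* **Mixtures** are eliminated together with other disconnected structures
  under the single reason code `disconnected`; splitting and re-merging
  components is deliberately out of scope.
* **Charge stripping** removes the charge token from the formula only; no
  hydrogens are added or removed and structure strings are untouched, so the
  database presents a consistent neutral "base state" for adduct handling
  upstream.
* **Isotopically labelled entries** receive no special handling inside
  collapsed groups; a labelled stereoisomer record merges like any other and
  can shift nothing except the related-CID list (masses always come from the
  representative CID).

## Formula handling

Formulas are parsed from Hill-style strings with a trailing charge token in
sign-then-magnitude form (`+`, `-`, `+2`). The digits-before-sign form
(`2+`) is *not* read as a charge magnitude: in `C9H13N2+` the `2` is a
nitrogen count, and no lexical rule can distinguish the two readings, so the
dialect fixes the unambiguous order. Monoisotopic masses are summed from a
frozen most-abundant-isotope table (`data/isotope_masses.tsv`, 118
elements); the electron mass is neglected — a singly charged species is off
by ~0.00055 Da, well under the 5 ppm windows used here, and formulas are
neutralized before querying anyway. Multi-component detection is lexical: a
dot outside brackets in SMILES, or a dot in the InChI formula layer. This is
exact for the dump dialects in scope and avoids a structure-perception
dependency.

## Querying and ranking

Mass retrieval uses the symmetric relative window
`|m − m₀|/m₀·10⁶ ≤ ppm` (default 5 ppm); formula retrieval is exact
element-count equality on neutralized formulas. Scoring max-normalizes each
term within the candidate set — including terms already bounded in [0, 1],
for uniformity — and combines them as a weighted sum. All term weights
default to 1; the weight vector is configuration, not a fitted quantity.
An all-zero term contributes zero to every candidate and cannot reorder
anything; an all-zero *weight vector* is rejected as a user error. Ties
share the best rank by default (`1 + #strictly better`); a pessimistic mode
(`1 + #better-or-equal others`) is available since the field's convention
is not settled — the evaluation of a constant (uninformative) term is only
meaningful under the pessimistic mode, where an all-tied window cannot claim
rank 1 for free.

## The synthetic-data generator

`generate_fixture` emulates the features of real dumps that the rules act
on, with these defaults as the study conditions:

| parameter | default | rationale |
|---|---|---|
| `n_compounds` / `n_ikfb_groups` | 300 / 120 | ~2.5 CIDs per skeleton, matching the few-stereoisomers-per-skeleton regime |
| formula pool | `n_groups/4` | several skeletons per formula, so mass windows contain real isobaric competitors |
| `annotation_density` | 0.2 per (compound, top category) | sparse multi-category annotation; most compounds annotated somewhere, few everywhere |
| count model | discretized log-normal, μ=2, σ=2 | heavy-tailed literature/patent counts (zeros to tens of thousands) |
| `fraction_disconnected` / `fraction_blacklisted` | 0.03 / 0.01 | ~4% of skeletons eliminated, the order observed in large annotation-selected builds |
| `fraction_charged` | 0.05 | charged formulas are kept and neutralized, so this exercises rule 6 without changing sizes |
| `fraction_with_parent` | 0.3 | parent/child folding within skeleton groups |

Synthetic InChIKeys are valid-pattern 14-10-1 strings, not hashes of
structures, and SMILES are schematic chains — structure fidelity is
irrelevant to the rules except for dot detection. What the fixtures do *not*
emulate: real annotation co-occurrence structure (categories are drawn
independently), tautomer/isotope relationships between skeletons, and real
mass spectra. Passing tests therefore demonstrate the correctness of the
pipeline's set/arithmetic behaviour and the ranking machinery, not
identification performance on real samples.

`FixtureTruth` is computed inside the generator by a straight-line
re-derivation of the six rules over the raw generated rows; it shares no
code with the builder and serves as the independent oracle in the test
suite.

`generate_benchmark` draws queries from built database entries,
preferentially from mass windows with at least one competitor. With
probability *p* (the informativeness) the correct candidate's external
score is drawn strictly above the window (uniform on [0.9, 1.0] vs
[0, 0.85]); otherwise every candidate, correct included, scores i.i.d.
uniform on [0, 0.85] — the score then carries no information about
correctness. The expected rank-1 fraction is `p + (1 − p)·E[1/k]` for
window size *k*; with the default isomer clustering the second term is a
few parts in a thousand, so observed fractions track *p* within binomial
error at the test sizes used (200 queries).

## Problem sizes

The test suite and the acceptance script run the pipeline at 40–700
compounds per dump (up to 300 skeletons) and 200 benchmark queries —
comfortably inside a laptop-second budget while leaving every code path,
including parent folds, eliminations and contested mass windows, well
populated. The pipeline itself is linear in records and needs no scaling
machinery at these sizes.

## Known limitations

* The reference category index is a frozen synthetic snapshot, not a copy
  of any live classification tree; builds against real dumps should supply
  the matching index file.
* Lexical disconnection detection trusts the dump's SMILES/InChI strings;
  malformed bracket nesting could hide a dot (no such strings occur in the
  dialect).
* The lite CSV stores derived category scores, not raw fingerprints, so a
  database round-tripped through CSV cannot be re-scored under a *different*
  selection; rebuild from the dump instead.
* Benchmark de-duplication (multiple spectra or tautomeric forms of one
  compound) is the caller's responsibility; the runner treats rows
  independently.
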