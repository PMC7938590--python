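# chemlite

Annotation-driven subsetting of large compound knowledge bases into compact
candidate databases for non-target high-resolution mass-spectrometry (HR-MS)
screening — plus ppm-window candidate retrieval, metadata-weighted candidate
ranking, and benchmarking/gap-analysis utilities.

## The problem

Exact-mass (or molecular-formula) queries against a database of 100+ million
compounds return thousands of candidates per mass, most of which are vendor
screening-library entries that will never be observed in environmental or
biological samples. Identification workflows then spend most of their effort
discarding irrelevant structures, and metadata-based ranking drowns in noise.
A far smaller database restricted to compounds with *annotation content* —
documented agrochemical, drug, food, pharmacological, safety, toxicity or
use/manufacturing information — keeps nearly all realistically observable
candidates while shrinking candidate sets by orders of magnitude.

`chemlite` implements that construction as a reproducible pipeline over a
documented dump dialect, so the same rules can be applied to any
PubChem-style export, and provides the query/ranking and evaluation tooling
around it.

## The method

**Building.** Each compound record carries a *table-of-contents (TOC)
fingerprint*: a bitset with one bit per annotation category or subcategory
(governed by a versioned category index, shipped as
`src/chemlite/data/category_index.tsv`). A *selection* names the top
categories of interest; three are built in: `tier0` (the seven
environmental categories AgroChemInfo, DrugMedicInfo, FoodRelated,
PharmacoInfo, SafetyInfo, ToxicityInfo, KnownUse), `tier1` (adds
BioPathway) and `exposomics` (adds Identification and DisorderDisease).
The six construction rules:

1. keep records annotated in the selected categories;
2. fold child records onto their parent (neutral-form) record, imputing
   annotation and literature/patent counts to the parent;
3. collapse by InChIKey first block (IKFB, the 14-character structural
   skeleton), keeping the most-annotated CID as representative and listing
   all related CIDs;
4. remove entries containing excluded elements (65 rare-earth / noble-gas /
   platinum-group / radioactive elements);
5. remove disconnected (multi-component) structures — salts and mixtures
   cannot be observed at the mass of a single-component query;
6. strip charges from charged molecular formulas (structures untouched).

Each kept entry gets per-category scores (category present → 1 + number of
its subcategories present, else 0) and a total annotation count
`AnnoTypeCount` = number of selected top categories present (maximum 7
under `tier0`, 8 under `tier1`, 10 under `exposomics`). The accounting
identity `kept + eliminated = total` (by IKFB) holds for every build.

**Querying and ranking.** Candidates are all entries within a symmetric ppm
window of the query neutral mass `|m − m₀|/m₀ · 10⁶ ≤ ppm` (default 5 ppm),
or exact formula matches. Ranking uses the weighted max-normalized
convention of in-silico identification tools: for terms *i* with weights
*wᵢ*,

    score(c) = Σᵢ wᵢ · rawᵢ(c) / max_{c'} rawᵢ(c')

where raw values come from database columns (literature/patent counts,
category scores, annotation count) or external per-candidate tables
(spectral similarity, in-silico fragmenter scores) keyed by IKFB.
Candidates are ranked by descending combined score, ties sharing the best
rank.

**Evaluating.** A benchmark (known compounds + neutral masses + optional
external scores) is run query-by-query; ranks are bucketed as
`rank 1 / 2–3 / 4–10 / >10 / missing`. Gap reports partition suspect lists
by IKFB presence in the database; transformation mappings render to
predecessor/successor statements.

## Worked example

Everything is runnable without any downloads — the `fixtures` command
generates a synthetic dump with known ground truth:

```sh
chemlite fixtures --seed 4 --out-dir dump
chemlite build --compounds dump/compounds.tsv --counts dump/counts.tsv \
    --toc dump/toc.tsv --selection tier0 --out lite.csv --report report.json
```

```
wrote 108 entries to lite.csv
kept 108 + eliminated 6 = 114 skeletons
```

300 raw records collapse to 114 skeletons with annotation in the tier0
categories; 6 are eliminated by the structure filters (the report JSON
breaks this down by reason), leaving a 108-entry database. Querying one
mass:

```sh
chemlite query --db lite.csv --mass 336.103428 --ppm 5
```

```
 Rank  Identifier  CompoundName InChIKeyFirstBlock  MonoisotopicMass  Combined  ...
    1         369  Compound-369     KPBBLIKBLTFRAW        336.103428  1.775970
    2         648  Compound-648     PYXLJSOABVHPLH        336.103428  1.563366
    3         781  Compound-781     SDMFOUFCJNMITZ        336.103428  1.364865
```

Ten isobaric candidates fall in the 5 ppm window; with the default terms
(PubMed count, patent count, annotation count, weight 1 each) the combined
score is the sum of the three max-normalized columns, so `Combined` lies in
[0, 3] and the top candidate is the one with the best metadata profile
overall — e.g. rank 3 has the highest PubMed count (norm 1.0) but weak
patent/annotation support. External MS/MS evidence can be added via
`--external-scores` and a terms YAML.

The library API mirrors the CLI (`chemlite.build`, `candidates_by_mass`,
`score_candidates`, `run_benchmark`, …); see the module docstrings.

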