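"""The six-rule construction pipeline and its accounting."""

import pytest

from chemlite.builder import (
    apply_structure_filters,
    build,
    category_summary,
    collapse_by_ikfb,
    filter_annotated,
    map_to_parent,
)
from chemlite.fixtures import FixtureConfig, generate_fixture
from chemlite.records_io import read_dump
from chemlite.toc import TocFingerprint, builtin_selection

from conftest import make_record


def _agro_bits(idx, n_subs=0):
    return {idx.top_bit("AgroChemInfo"), *sorted(idx.sub_bits("AgroChemInfo"))[:n_subs]}


def test_filter_annotated(idx, tier0):
    outside = make_record(1, bits={idx.top_bit("Literature")})  # unselected category
    sub_only = make_record(2, bits={next(iter(idx.sub_bits("ToxicityInfo")))})
    kept = filter_annotated([outside, sub_only], tier0, idx)
    assert [r.cid for r in kept] == [2]  # a selected subcategory bit suffices
    assert filter_annotated([], tier0, idx) == []


def test_map_to_parent_unions_and_sums(idx):
    parent = make_record(10, pubmed=1, patent=2)
    child_a = make_record(11, parent=10, bits=_agro_bits(idx), pubmed=5, patent=0)
    child_b = make_record(12, parent=10, bits={idx.top_bit("KnownUse")}, pubmed=0, patent=7)
    lone = make_record(20, ikfb="BBBBBBBBBBBBBB")
    out = {r.cid: r for r in map_to_parent([parent, child_a, child_b, lone])}
    assert set(out) == {10, 20}
    merged = out[10]
    assert merged.fingerprint.bits == _agro_bits(idx) | {idx.top_bit("KnownUse")}
    assert (merged.pubmed_count, merged.patent_count) == (6, 9)
    assert out[20] == lone  # no parent: unchanged


def test_map_to_parent_materializes_missing_parent(idx):
    child = make_record(5, parent=99, bits=_agro_bits(idx), pubmed=3)
    (merged,) = map_to_parent([child])
    assert merged.cid == 99
    assert merged.fingerprint.bits == _agro_bits(idx)
    assert merged.pubmed_count == 3


def test_map_to_parent_rejects_cycles():
    a = make_record(1, parent=2)
    b = make_record(2, parent=1)
    with pytest.raises(ValueError, match="cycle"):
        map_to_parent([a, b])


def test_collapse_worked_stereo_group(idx, tier0):
    """Six annotated CIDs sharing a first block collapse to one entry with
    six related CIDs; unannotated stereoisomers of the same skeleton are not
    listed."""
    ikfb = "HXKKHQJGJAFBHI"
    annotated_cids = [4, 111033, 439938, 446260, 7311736, 44150279]
    unannotated_cids = [4631415, 7311735, 16655457]
    records = [
        make_record(cid, ikfb=ikfb, formula="C10H14N2", bits=_agro_bits(idx, n_subs=1), pubmed=cid % 10)
        for cid in annotated_cids
    ] + [make_record(cid, ikfb=ikfb, formula="C10H14N2") for cid in unannotated_cids]
    filtered = filter_annotated(records, tier0, idx)
    entries = collapse_by_ikfb(map_to_parent(filtered), tier0, idx)
    assert len(entries) == 1
    entry = entries[0]
    assert entry.ikfb == ikfb
    assert entry.related_cids == tuple(annotated_cids)
    assert len(entry.related_cids) == 6
    assert entry.best_cid == 4  # equal annotation: lowest CID wins
    assert entry.pubmed_count == sum(cid % 10 for cid in annotated_cids)


def test_collapse_best_cid_most_annotated(idx, tier0):
    light = make_record(100, bits=_agro_bits(idx, n_subs=0))
    heavy = make_record(200, bits=_agro_bits(idx, n_subs=3))
    (entry,) = collapse_by_ikfb([light, heavy], tier0, idx)
    assert entry.best_cid == 200
    assert entry.related_cids == (100, 200)


def test_collapse_best_ignores_unselected_bits(idx, tier0):
    """Annotation outside the active selection does not decide the best CID."""
    in_sel = make_record(300, bits=_agro_bits(idx, n_subs=1))
    out_sel = make_record(301, bits={idx.top_bit("Literature"), idx.top_bit("Patents"), idx.top_bit("SpectralInfo")})
    (entry,) = collapse_by_ikfb([in_sel, out_sel], tier0, idx)
    assert entry.best_cid == 300


def test_collapse_single_record(idx, tier0):
    (entry,) = collapse_by_ikfb([make_record(7, bits=_agro_bits(idx))], tier0, idx)
    assert entry.related_cids == (7,)
    assert entry.best_cid == 7


def test_structure_filters_partition(idx):
    platinum = make_record(1, formula="C6H12Pt", ikfb="AAAAAAAAAAAAAA")
    dotted = make_record(2, smiles="CC(=O)[O-].[Na+]", ikfb="BBBBBBBBBBBBBB")
    charged = make_record(3, formula="C9H13N2+", ikfb="CCCCCCCCCCCCCC")
    plain = make_record(4, ikfb="DDDDDDDDDDDDDD")
    entries = collapse_by_ikfb([platinum, dotted, charged, plain])
    kept, eliminated = apply_structure_filters(entries)
    assert len(kept) + len(eliminated) == len(entries)
    reasons = {e.ikfb: reason for e, reason in eliminated}
    assert reasons == {"AAAAAAAAAAAAAA": "element", "BBBBBBBBBBBBBB": "disconnected"}
    kept_by_ikfb = {e.ikfb: e for e in kept}
    neutralized = kept_by_ikfb["CCCCCCCCCCCCCC"]
    assert neutralized.formula.charge == 0
    assert dict(neutralized.formula.element_counts) == {"C": 9, "H": 13, "N": 2}
    # structure strings untouched by charge stripping
    assert neutralized.smiles == charged.smiles and neutralized.inchi == charged.inchi


def test_build_empty_input(idx, tier0):
    entries, report, eliminated = build([], tier0, idx)
    assert entries == [] and eliminated == []
    assert report.as_dict()["total_ikfb"] == 0


def test_build_deterministic(dump, idx, tier0):
    paths, _ = dump
    records = read_dump(paths["compounds"], paths["counts"], paths["toc"], idx)
    first = build(records, tier0, idx)
    second = build(records, tier0, idx)
    assert first[0] == second[0]
    assert first[1].as_dict() == second[1].as_dict()


def test_build_matches_truth_oracle(built):
    """Full pipeline output equals the generator's independent straight-line
    re-derivation of the six rules."""
    entries, report, eliminated, truth = built
    assert {e.ikfb for e in entries} == set(truth.kept)
    assert {e.ikfb: r for e, r in eliminated} == truth.eliminated
    for e in entries:
        t = truth.kept[e.ikfb]
        assert e.best_cid == t["best_cid"]
        assert list(e.related_cids) == t["related_cids"]
        assert dict(e.category_scores) == t["category_scores"]
        assert e.anno_total_count == t["anno_total_count"]
        assert e.pubmed_count == t["pubmed_count"]
        assert e.patent_count == t["patent_count"]


@pytest.mark.parametrize("seed", range(6))
def test_oracle_equivalence_across_seeds(tmp_path, idx, tier0, seed):
    cfg = FixtureConfig(n_compounds=150, n_ikfb_groups=60, seed=seed)
    paths, truth = generate_fixture(cfg, tmp_path)
    records = read_dump(paths["compounds"], paths["counts"], paths["toc"], idx)
    entries, report, eliminated = build(records, tier0, idx)
    assert {e.ikfb for e in entries} == set(truth.kept)
    assert {e.ikfb: r for e, r in eliminated} == truth.eliminated
    assert report.kept_ikfb + report.eliminated_ikfb == report.total_ikfb


def test_selection_nesting(dump, idx):
    """Wider selections keep a superset of skeletons."""
    paths, _ = dump
    records = read_dump(paths["compounds"], paths["counts"], paths["toc"], idx)
    kept = {}
    for name in ("tier0", "tier1", "exposomics"):
        entries, *_ = build(records, builtin_selection(name), idx)
        kept[name] = {e.ikfb for e in entries}
    assert kept["tier0"] <= kept["tier1"] <= kept["exposomics"]


def test_annotation_monotonicity(idx, tier0):
    """Adding an annotation bit never drops a kept skeleton or lowers a score."""
    import numpy as np

    rng = np.random.default_rng(5)
    base = [
        make_record(
            cid,
            ikfb=f"{'GROUP'}{chr(65 + cid % 4)}AAAAAAAA",
            bits=set(rng.choice(idx.width, size=rng.integers(0, 6), replace=False).tolist()),
        )
        for cid in range(1, 25)
    ]
    entries0, *_ = build(base, tier0, idx)
    kept0 = {e.ikfb for e in entries0}
    scores0 = {e.ikfb: dict(e.category_scores) for e in entries0}
    for _ in range(20):
        i = int(rng.integers(0, len(base)))
        extra = int(rng.integers(0, idx.width))
        boosted = list(base)
        rec = base[i]
        boosted[i] = make_record(
            rec.cid, ikfb=rec.ikfb, bits=set(rec.fingerprint.bits) | {extra}
        )
        entries1, *_ = build(boosted, tier0, idx)
        kept1 = {e.ikfb for e in entries1}
        assert kept0 <= kept1
        for e in entries1:
            if e.ikfb in scores0:
                for cat, s in scores0[e.ikfb].items():
                    assert e.category_scores[cat] >= s


def test_category_summary_counts_duplication(idx, tier0):
    agro = sorted(idx.sub_bits("AgroChemInfo"))
    rec = make_record(1, bits={idx.top_bit("AgroChemInfo"), agro[0], agro[1]})
    twin = make_record(2, bits={idx.top_bit("AgroChemInfo"), agro[0]})
    entries, *_ = build([rec, twin], tier0, idx)
    summary = category_summary(entries, idx)
    # one collapsed entry with 2 related CIDs, annotated in two subcategories:
    # it appears in both subcategory rows, CIDs counted with duplication
    subs = summary[summary["sub"] != "(top)"]
    assert len(subs) == 2
    assert set(subs["cid_count"]) == {2}
    assert set(subs["ikfb_count"]) == {1}
    # brute-force tally over a generated build
    assert summary["ikfb_count"].sum() == sum(len(e.fingerprint.bits) for e in entries)


def test_category_summary_empty(idx):
    assert len(category_summary([], idx)) == 0
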