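"""Candidate retrieval windows and weighted max-normalized ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from chemlite.builder import LiteEntry
from chemlite.formula import parse_formula
from chemlite.query import (
    MISSING,
    QuerySpec,
    ScoringTerm,
    candidates_by_formula,
    candidates_by_mass,
    rank_of,
    score_candidates,
)


def make_entry(ikfb, mass, formula="C10H14N2", name=None, pubmed=0, patent=0, scores=None, anno=0):
    f = parse_formula(formula)
    return LiteEntry(
        ikfb=ikfb,
        best_cid=1,
        related_cids=(1,),
        name=name or ikfb,
        smiles="CCN",
        inchi=f"InChI=1S/{formula}",
        inchikey=f"{ikfb}-UHFFFAOYSA-N",
        formula=f,
        monoisotopic_mass=mass,
        pubmed_count=pubmed,
        patent_count=patent,
        category_scores=scores or {},
        anno_total_count=anno,
    )


@pytest.fixture(scope="module")
def small_db():
    return [
        make_entry("A" * 14, 162.1157),
        make_entry("B" * 14, 162.1157 * (1 + 3e-6)),  # +3 ppm
        make_entry("C" * 14, 162.1157 * (1 - 3e-6)),  # -3 ppm
        make_entry("D" * 14, 200.0),
    ]


def test_mass_window_membership(small_db):
    q = QuerySpec(mode="mass", neutral_mass=162.1157, ppm=5.0)
    hits = candidates_by_mass(small_db, q)
    assert {e.ikfb[0] for e in hits} == {"A", "B", "C"}
    # ordered by ascending |delta mass|
    assert hits[0].ikfb[0] == "A"
    tight = QuerySpec(mode="mass", neutral_mass=162.1157, ppm=1.0)
    assert [e.ikfb[0] for e in candidates_by_mass(small_db, tight)] == ["A"]
    far = QuerySpec(mode="mass", neutral_mass=500.0, ppm=5.0)
    assert candidates_by_mass(small_db, far) == []


def test_mass_query_validation():
    with pytest.raises(ValueError):
        QuerySpec(mode="mass", neutral_mass=-1.0)
    with pytest.raises(ValueError):
        QuerySpec(mode="mass", neutral_mass=100.0, ppm=0.0)
    with pytest.raises(ValueError):
        QuerySpec(mode="nonsense")


@settings(deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_mass_window_matches_linear_scan_oracle(seed):
    rng = np.random.default_rng(seed)
    masses = rng.uniform(100, 110, size=60)
    db = [make_entry(f"{'M'}{i:013d}".replace("0", "A"), float(m)) for i, m in enumerate(masses)]
    target = float(rng.choice(masses))
    q = QuerySpec(mode="mass", neutral_mass=target, ppm=5.0)
    got = {e.ikfb for e in candidates_by_mass(db, q)}
    oracle = {
        db[i].ikfb
        for i in range(len(db))
        if abs(masses[i] - target) <= 5.0e-6 * target  # independent formulation
    }
    assert got == oracle


def test_ppm_window_symmetry(small_db):
    """+d and -d deviations are treated identically."""
    q = QuerySpec(mode="mass", neutral_mass=162.1157, ppm=3.0000001)
    hits = {e.ikfb[0] for e in candidates_by_mass(small_db, q)}
    assert {"B", "C"} <= hits


def test_formula_query():
    db = [
        make_entry("A" * 14, 162.1157, formula="C10H14N2"),
        make_entry("B" * 14, 162.1157, formula="N2C10H14"),  # same composition, odd order
        make_entry("C" * 14, 162.1157, formula="C10H14N2"),
        make_entry("D" * 14, 229.1094, formula="C9H16ClN5"),
    ]
    q = QuerySpec(mode="formula", formula=parse_formula("C10H14N2"))
    assert [e.ikfb[0] for e in candidates_by_formula(db, q)] == ["A", "B", "C"]
    none = QuerySpec(mode="formula", formula=parse_formula("C2H6O"))
    assert candidates_by_formula(db, none) == []
    with pytest.raises(ValueError):
        QuerySpec(mode="formula", formula=parse_formula("C6H5O-"))


TRIAZINE_MONA = {  # spectral similarities of the three isomer candidates
    "TERBUTYLAZINE1": 0.971,
    "PROPAZINEAAAAA": 0.703,
    "SECBUTYLAZINE1": 0.998,
}


def _triazine_candidates():
    return [
        make_entry("TERBUTYLAZINE1", 229.1094, formula="C9H16ClN5", name="Terbutylazine"),
        make_entry("PROPAZINEAAAAA", 229.1094, formula="C9H16ClN5", name="Propazine"),
        make_entry("SECBUTYLAZINE1", 229.1094, formula="C9H16ClN5", name="Secbutylazine"),
    ]


def test_isomer_ordering_by_spectral_similarity():
    """Scoring three isobaric isomers by the spectral-similarity term alone
    recovers the order secbutylazine > terbutylazine > propazine."""
    cands = _triazine_candidates()
    external = {("MoNA", ikfb): v for ikfb, v in TRIAZINE_MONA.items()}
    scored = score_candidates(cands, [ScoringTerm("MoNA", source="external")], external)
    names = [c.entry.name for c in sorted(scored, key=lambda c: c.rank)]
    assert names == ["Secbutylazine", "Terbutylazine", "Propazine"]
    assert rank_of(scored, "SECBUTYLAZINE1") == 1


def test_single_candidate_combined_equals_weight_sum():
    cands = [make_entry("A" * 14, 100.0, pubmed=42, patent=7, anno=3)]
    terms = [
        ScoringTerm("PubMed_Count", weight=0.5),
        ScoringTerm("Patent_Count", weight=1.5),
        ScoringTerm("AnnoTypeCount", weight=2.0),
    ]
    (scored,) = score_candidates(cands, terms)
    assert scored.combined == pytest.approx(4.0)
    assert scored.rank == 1


def test_dominant_candidate_ranks_first():
    cands = [
        make_entry("A" * 14, 100.0, pubmed=100, patent=100, anno=5),
        make_entry("B" * 14, 100.0, pubmed=10, patent=50, anno=2),
    ]
    terms = [ScoringTerm("PubMed_Count"), ScoringTerm("Patent_Count"), ScoringTerm("AnnoTypeCount")]
    scored = score_candidates(cands, terms)
    assert rank_of(scored, "A" * 14) == 1
    assert rank_of(scored, "B" * 14) == 2


def test_all_zero_term_is_neutral():
    cands = [
        make_entry("A" * 14, 100.0, pubmed=9),
        make_entry("B" * 14, 100.0, pubmed=3),
    ]
    with_zero = score_candidates(
        cands, [ScoringTerm("PubMed_Count"), ScoringTerm("Patent_Count")]
    )
    without = score_candidates(cands, [ScoringTerm("PubMed_Count")])
    assert [c.ikfb for c in with_zero] == [c.ikfb for c in without]
    assert all(c.raw_scores["Patent_Count"] == 0 for c in with_zero)


def test_zero_weights_rejected():
    cands = [make_entry("A" * 14, 100.0)]
    with pytest.raises(ValueError, match="weight"):
        score_candidates(cands, [ScoringTerm("PubMed_Count", weight=0.0)])


def test_unknown_db_term_rejected():
    cands = [make_entry("A" * 14, 100.0)]
    with pytest.raises(KeyError):
        score_candidates(cands, [ScoringTerm("NoSuchColumn")])


def test_missing_external_value_scores_zero():
    cands = [make_entry("A" * 14, 100.0), make_entry("B" * 14, 100.0)]
    external = {("Sim", "A" * 14): 0.9}
    scored = score_candidates(cands, [ScoringTerm("Sim", source="external")], external)
    assert rank_of(scored, "A" * 14) == 1
    (b,) = [c for c in scored if c.ikfb == "B" * 14]
    assert b.raw_scores["Sim"] == 0.0


def test_tie_rank_modes():
    cands = [
        make_entry("A" * 14, 100.0, pubmed=5),
        make_entry("B" * 14, 100.0, pubmed=5),
        make_entry("C" * 14, 100.0, pubmed=1),
    ]
    optimistic = score_candidates(cands, [ScoringTerm("PubMed_Count")])
    assert rank_of(optimistic, "A" * 14) == rank_of(optimistic, "B" * 14) == 1
    assert rank_of(optimistic, "C" * 14) == 3
    pessimistic = score_candidates(cands, [ScoringTerm("PubMed_Count")], tie_mode="pessimistic")
    assert rank_of(pessimistic, "A" * 14) == rank_of(pessimistic, "B" * 14) == 2


def test_rank_of_missing():
    scored = score_candidates([make_entry("A" * 14, 100.0, pubmed=1)], [ScoringTerm("PubMed_Count")])
    assert rank_of(scored, "Z" * 14) is MISSING


@settings(deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_scoring_properties_randomized(seed):
    """Normalization bounds, scale invariance, and rank monotonicity."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 8))
    cands = [
        make_entry(
            chr(65 + i) * 14,
            100.0,
            pubmed=int(rng.integers(0, 1000)),
            patent=int(rng.integers(0, 10000)),
            anno=int(rng.integers(0, 8)),
        )
        for i in range(n)
    ]
    terms = [
        ScoringTerm("PubMed_Count", weight=1.0),
        ScoringTerm("Patent_Count", weight=0.5),
        ScoringTerm("AnnoTypeCount", weight=2.0),
    ]
    scored = score_candidates(cands, terms)
    total_weight = sum(t.weight for t in terms)
    for c in scored:
        assert all(0.0 <= v <= 1.0 for v in c.normalized_scores.values())
        assert -1e-12 <= c.combined <= total_weight + 1e-12

    # scale invariance: multiplying one term's raws by a constant keeps ranks
    # (integer x3 keeps the scaling exact)
    rescored = score_candidates(
        [
            make_entry(
                e.ikfb,
                100.0,
                pubmed=e.pubmed_count * 3,
                patent=e.patent_count,
                anno=e.anno_total_count,
            )
            for e in cands
        ],
        terms,
    )
    assert {c.ikfb: c.rank for c in rescored} == {c.ikfb: c.rank for c in scored}

    # monotonicity: raising the target's raw value in a positive-weight term
    # never worsens its rank
    target = cands[0]
    before = rank_of(scored, target.ikfb)
    boosted = [
        make_entry(
            e.ikfb,
            100.0,
            pubmed=e.pubmed_count + (500 if e.ikfb == target.ikfb else 0),
            patent=e.patent_count,
            anno=e.anno_total_count,
        )
        for e in cands
    ]
    after = rank_of(score_candidates(boosted, terms), target.ikfb)
    assert after <= before
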