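"""Candidate retrieval and metadata-weighted scoring/ranking.

Retrieval follows the convention of exact-mass queries in non-target
screening: all database entries within a symmetric ppm window of the query
neutral mass (or exactly matching the query formula) are candidates.

Scoring follows the weighted, max-normalized multi-term convention of
in-silico identification tools: each term's raw values are divided by the
per-candidate-set maximum (so every term lands in [0, 1] regardless of its
native scale), the combined score is the weighted sum, and candidates are
ranked descending, ties sharing the best rank.  Raw values come either from
a database column of the entry (literature/patent counts, per-category
annotation scores, total annotation count) or from an externally supplied
per-candidate table (e.g. spectral-similarity or in-silico fragmenter
scores), keyed by InChIKey first block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .builder import LiteEntry

__all__ = [
    "MISSING",
    "QuerySpec",
    "ScoringTerm",
    "ScoredCandidate",
    "candidates_by_mass",
    "candidates_by_formula",
    "score_candidates",
    "rank_of",
    "DB_COLUMNS",
]


class _Missing:
    """Sentinel for a target absent from a candidate list."""

    def __repr__(self) -> str:  # pragma: no cover - trivial
        return "MISSING"


#: Returned by :func:`rank_of` when the target is not among the candidates.
MISSING = _Missing()


@dataclass(frozen=True)
class QuerySpec:
    """Either a mass query (neutral mass + ppm tolerance) or a formula query."""

    mode: str  # "mass" | "formula"
    neutral_mass: float | None = None
    ppm: float = 5.0
    formula: object | None = None  # MolecularFormula in formula mode

    def __post_init__(self) -> None:
        if self.mode == "mass":
            if self.neutral_mass is None or self.neutral_mass <= 0:
                raise ValueError("mass mode requires a positive neutral mass")
            if self.ppm <= 0:
                raise ValueError("ppm tolerance must be positive")
        elif self.mode == "formula":
            if self.formula is None:
                raise ValueError("formula mode requires a formula")
            if getattr(self.formula, "charge", 0) != 0:
                raise ValueError("formula queries must be charge-neutral")
        else:
            raise ValueError(f"unknown query mode {self.mode!r}")


#: Entry attributes addressable as database-column scoring sources.
DB_COLUMNS = {
    "PubMed_Count": lambda e: e.pubmed_count,
    "Patent_Count": lambda e: e.patent_count,
    "AnnoTypeCount": lambda e: e.anno_total_count,
}


@dataclass(frozen=True)
class ScoringTerm:
    """One scoring term: a raw-value source and its weight.

    ``source`` is ``"db"`` (resolve ``name`` against the entry: a fixed
    metadata column or a per-category score column) or ``"external"``
    (resolve ``(name, ikfb)`` in the externally supplied score table).
    """

    name: str
    weight: float = 1.0
    source: str = "db"  # "db" | "external"

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("term weight must be non-negative")
        if self.source not in ("db", "external"):
            raise ValueError(f"unknown term source {self.source!r}")

    def raw_value(
        self,
        entry: LiteEntry,
        external: Mapping[tuple[str, str], float] | None,
    ) -> float:
        if self.source == "external":
            if external is None:
                return 0.0
            return float(external.get((self.name, entry.ikfb), 0.0))
        if self.name in DB_COLUMNS:
            return float(DB_COLUMNS[self.name](entry))
        if self.name in entry.category_scores:
            return float(entry.category_scores[self.name])
        raise KeyError(
            f"scoring term {self.name!r} is neither a fixed column "
            f"({sorted(DB_COLUMNS)}) nor a category score of this database"
        )


@dataclass(frozen=True)
class ScoredCandidate:
    """A candidate with raw, max-normalized and combined scores plus rank."""

    entry: LiteEntry
    raw_scores: Mapping[str, float] = field(default_factory=dict)
    normalized_scores: Mapping[str, float] = field(default_factory=dict)
    combined: float = 0.0
    rank: int = 0

    @property
    def ikfb(self) -> str:
        return self.entry.ikfb


def candidates_by_mass(db: Iterable[LiteEntry], q: QuerySpec) -> list[LiteEntry]:
    """All entries within the symmetric ppm window of the query mass.

    Ordered by ascending absolute mass deviation (ties by IKFB for
    determinism).
    """
    if q.mode != "mass":
        raise ValueError("candidates_by_mass requires a mass-mode query")
    hits = [
        e
        for e in db
        if abs(e.monoisotopic_mass - q.neutral_mass) / q.neutral_mass * 1e6 <= q.ppm
    ]
    hits.sort(key=lambda e: (abs(e.monoisotopic_mass - q.neutral_mass), e.ikfb))
    return hits


def candidates_by_formula(db: Iterable[LiteEntry], q: QuerySpec) -> list[LiteEntry]:
    """All entries whose neutralized formula equals the query formula.

    Equality is element-count equality, independent of how the source
    string ordered its elements.
    """
    if q.mode != "formula":
        raise ValueError("candidates_by_formula requires a formula-mode query")
    want = dict(q.formula.element_counts)
    return [e for e in db if dict(e.formula.element_counts) == want]


def score_candidates(
    cands: Sequence[LiteEntry],
    terms: Sequence[ScoringTerm],
    external: Mapping[tuple[str, str], float] | None = None,
    tie_mode: str = "optimistic",
) -> list[ScoredCandidate]:
    """Score and rank a candidate set.

    Per term, raw values are normalized by the maximum over the candidate
    set (an all-zero term contributes 0 to everyone); the combined score is
    the weighted sum; candidates are sorted descending by combined score and
    assigned ranks.  With ``tie_mode="optimistic"`` (default) tied
    candidates share the best rank (1 + number of strictly better
    candidates); ``"pessimistic"`` charges each candidate for its ties as
    well (1 + number of other candidates scoring at least as high).
    """
    if tie_mode not in ("optimistic", "pessimistic"):
        raise ValueError(f"unknown tie_mode {tie_mode!r}")
    if terms and all(t.weight == 0 for t in terms):
        raise ValueError("all term weights are zero: no ranking signal")

    raws: dict[str, list[float]] = {
        t.name: [t.raw_value(e, external) for e in cands] for t in terms
    }
    maxima = {name: max(vals) if vals else 0.0 for name, vals in raws.items()}

    scored: list[ScoredCandidate] = []
    for i, entry in enumerate(cands):
        raw = {t.name: raws[t.name][i] for t in terms}
        norm = {
            t.name: (raw[t.name] / maxima[t.name] if maxima[t.name] > 0 else 0.0)
            for t in terms
        }
        combined = sum(t.weight * norm[t.name] for t in terms)
        scored.append(
            ScoredCandidate(entry=entry, raw_scores=raw, normalized_scores=norm, combined=combined)
        )

    scored.sort(key=lambda c: (-c.combined, c.ikfb))
    ranked: list[ScoredCandidate] = []
    for c in scored:
        if tie_mode == "optimistic":
            better = sum(1 for other in scored if other.combined > c.combined)
        else:
            better = sum(
                1 for other in scored if other is not c and other.combined >= c.combined
            )
        ranked.append(
            ScoredCandidate(
                entry=c.entry,
                raw_scores=c.raw_scores,
                normalized_scores=c.normalized_scores,
                combined=c.combined,
                rank=better + 1,
            )
        )
    return ranked


def rank_of(scored: Sequence[ScoredCandidate], target_ikfb: str):
    """Rank of the candidate with the given IKFB, or :data:`MISSING`."""
    for c in scored:
        if c.ikfb == target_ikfb:
            return c.rank
    return MISSING
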