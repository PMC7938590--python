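"""Benchmark execution, rank summaries, gap reports, transformation text.

A benchmark is a list of known compounds with their neutral masses and
(optionally) per-candidate external scores such as spectral similarities.
For each entry the runner retrieves candidates within the ppm window,
scores them with the configured terms, locates the correct compound by
InChIKey first block, and buckets the resulting rank.  The default buckets
— rank 1, 2–3, 4–10, >10, missing — reflect the way identification
performance is conventionally reported: "ranked first", "within top 3",
and the fraction of known compounds absent from the database entirely.

Gap reports partition a suspect or benchmark list by presence of the
compound's structural skeleton (IKFB) in the database, which is how missing
well-known chemicals (often transformation products) are detected and then
back-filled with annotated suspect-list content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .builder import LiteEntry
from .query import MISSING, QuerySpec, ScoringTerm, candidates_by_mass, rank_of, score_candidates
from .records_io import SuspectEntry, TransformationMapping

__all__ = [
    "BenchmarkEntry",
    "RankSummary",
    "GapReport",
    "DEFAULT_BUCKETS",
    "run_benchmark",
    "subset_benchmark_by_category",
    "gap_report",
    "transformation_statements",
    "write_benchmark_csv",
    "read_benchmark_csv",
]

#: (label, lowest rank, highest rank) — the conventional reporting buckets.
DEFAULT_BUCKETS = (
    ("rank 1", 1, 1),
    ("2-3", 2, 3),
    ("4-10", 4, 10),
    (">10", 11, None),
)


@dataclass(frozen=True)
class BenchmarkEntry:
    """One benchmark query: a known compound with its neutral mass."""

    name: str
    ikfb: str
    neutral_mass: float
    formula: object | None = None
    #: term name -> {candidate ikfb -> raw score}, restricted to this query
    external_scores: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.ikfb) != 14:
            raise ValueError(f"IKFB must be 14 characters, got {self.ikfb!r}")
        if self.neutral_mass <= 0:
            raise ValueError("neutral mass must be positive")


@dataclass
class RankSummary:
    """Bucketed rank counts over one benchmark run."""

    buckets: dict[str, int]
    total: int

    def fraction(self, label: str) -> float:
        return self.buckets[label] / self.total if self.total else 0.0

    def as_dict(self) -> dict:
        return {"buckets": dict(self.buckets), "total": self.total}


@dataclass
class GapReport:
    """Partition of a chemical list by presence in the database."""

    missing: list[tuple[str, str]]  # (name, ikfb)
    present: int
    missing_count: int

    def as_dict(self) -> dict:
        return {
            "present": self.present,
            "missing_count": self.missing_count,
            "missing": [{"name": n, "ikfb": k} for n, k in self.missing],
        }


def _bucket_label(rank, buckets) -> str:
    if rank is MISSING:
        return "missing"
    for label, lo, hi in buckets:
        if rank >= lo and (hi is None or rank <= hi):
            return label
    raise ValueError(f"rank {rank} not covered by buckets")  # pragma: no cover


def _validate_terms(db: Sequence[LiteEntry], terms: Sequence[ScoringTerm]) -> None:
    # fail fast on a term referencing an absent database column, before any
    # query runs
    if not db:
        return
    probe = db[0]
    for t in terms:
        if t.source == "db":
            t.raw_value(probe, None)


def run_benchmark(
    db: Sequence[LiteEntry],
    benchmark: Sequence[BenchmarkEntry],
    terms: Sequence[ScoringTerm],
    ppm: float = 5.0,
    buckets=DEFAULT_BUCKETS,
    tie_mode: str = "optimistic",
) -> tuple[RankSummary, list[dict]]:
    """Retrieve, score and rank every benchmark entry; bucket the ranks.

    Returns the summary plus a per-entry table (list of dicts with name,
    ikfb, number of candidates, and rank — ``None`` when missing).
    ``tie_mode`` is forwarded to the scorer: optimistic ties share the best
    rank, pessimistic ties are charged for each other.  Deterministic for
    fixed inputs.
    """
    _validate_terms(db, terms)
    counts = {label: 0 for label, *_ in buckets}
    counts["missing"] = 0
    rows: list[dict] = []
    for entry in benchmark:
        q = QuerySpec(mode="mass", neutral_mass=entry.neutral_mass, ppm=ppm)
        cands = candidates_by_mass(db, q)
        external = {
            (term, ikfb): value
            for term, per_ikfb in entry.external_scores.items()
            for ikfb, value in per_ikfb.items()
        }
        scored = score_candidates(cands, terms, external, tie_mode=tie_mode) if cands else []
        rank = rank_of(scored, entry.ikfb) if scored else MISSING
        counts[_bucket_label(rank, buckets)] += 1
        rows.append(
            {
                "name": entry.name,
                "ikfb": entry.ikfb,
                "n_candidates": len(cands),
                "rank": None if rank is MISSING else rank,
            }
        )
    return RankSummary(buckets=counts, total=len(benchmark)), rows


def subset_benchmark_by_category(
    benchmark: Sequence[BenchmarkEntry],
    db: Sequence[LiteEntry],
    top_category: str,
) -> list[BenchmarkEntry]:
    """Benchmark entries whose database match has annotation in a category.

    This mimics topic-specific suspect screening (e.g. restricting to
    compounds with agrochemical annotation).  Entries missing from the
    database are excluded.
    """
    by_ikfb = {e.ikfb: e for e in db}
    subset = []
    for entry in benchmark:
        match = by_ikfb.get(entry.ikfb)
        if match is not None and match.category_scores.get(top_category, 0) > 0:
            subset.append(entry)
    return subset


def gap_report(
    chemicals: Iterable[SuspectEntry | BenchmarkEntry],
    db: Sequence[LiteEntry],
) -> GapReport:
    """Partition a list of chemicals by IKFB presence in the database."""
    present_ikfbs = {e.ikfb for e in db}
    missing: list[tuple[str, str]] = []
    present = 0
    for chem in chemicals:
        if chem.ikfb in present_ikfbs:
            present += 1
        else:
            missing.append((chem.name, chem.ikfb))
    return GapReport(missing=missing, present=present, missing_count=len(missing))


def write_benchmark_csv(entries: Sequence[BenchmarkEntry], queries_path, scores_path=None) -> None:
    """Write a benchmark as two CSVs: queries, and per-candidate scores.

    Queries: Name, IKFB, NeutralMass.  Scores (optional): Name, Term,
    CandidateIKFB, Value — one row per (query, term, candidate).
    """
    import pandas as pd

    pd.DataFrame(
        [
            {"Name": e.name, "IKFB": e.ikfb, "NeutralMass": round(e.neutral_mass, 6)}
            for e in entries
        ],
        columns=["Name", "IKFB", "NeutralMass"],
    ).to_csv(queries_path, index=False)
    if scores_path is not None:
        rows = [
            {"Name": e.name, "Term": term, "CandidateIKFB": ikfb, "Value": value}
            for e in entries
            for term, per_ikfb in e.external_scores.items()
            for ikfb, value in per_ikfb.items()
        ]
        pd.DataFrame(rows, columns=["Name", "Term", "CandidateIKFB", "Value"]).to_csv(
            scores_path, index=False
        )


def read_benchmark_csv(queries_path, scores_path=None) -> list[BenchmarkEntry]:
    """Load a benchmark written by :func:`write_benchmark_csv`."""
    import pandas as pd

    queries = pd.read_csv(queries_path, dtype={"Name": str, "IKFB": str})
    scores: dict[str, dict[str, dict[str, float]]] = {}
    if scores_path is not None:
        for row in pd.read_csv(scores_path, dtype={"Name": str}).itertuples(index=False):
            scores.setdefault(row.Name, {}).setdefault(row.Term, {})[row.CandidateIKFB] = float(
                row.Value
            )
    return [
        BenchmarkEntry(
            name=row.Name,
            ikfb=row.IKFB,
            neutral_mass=float(row.NeutralMass),
            external_scores=scores.get(row.Name, {}),
        )
        for row in queries.itertuples(index=False)
    ]


def _serial_join(names: Sequence[str]) -> str:
    if len(names) == 1:
        return names[0]
    if len(names) == 2:
        return f"{names[0]} and {names[1]}"
    return ", ".join(names[:-1]) + f", and {names[-1]}"


def transformation_statements(
    mappings: Sequence[TransformationMapping],
) -> list[tuple[str, str]]:
    """Human-readable transformation statements, one per predecessor.

    Successors are grouped in input order under each predecessor and joined
    with a serial comma ("A, B, and C"; two items use a plain "and").
    """
    successors: dict[str, list[str]] = {}
    for m in mappings:
        successors.setdefault(m.predecessor_name, [])
        if m.successor_name not in successors[m.predecessor_name]:
            successors[m.predecessor_name].append(m.successor_name)
    return [
        (
            pred,
            f"{pred} has known environmental transformation products "
            f"that include {_serial_join(succ)}",
        )
        for pred, succ in successors.items()
    ]
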