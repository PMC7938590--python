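"""Six-rule construction pipeline: raw compound records -> compact database.

The pipeline turns a large annotated compound dump into a compact candidate
database suitable for exact-mass/formula retrieval in non-target HR-MS
screening:

1. keep only records with annotation in the selected categories;
2. map child records onto their parent (neutral-form) record, imputing
   annotation and counts to the parent;
3. collapse by InChIKey first block (IKFB, the structural skeleton),
   retaining the most-annotated CID as the representative and listing all
   related CIDs;
4. drop entries containing blacklisted elements;
5. drop disconnected (multi-component) structures — they cannot be observed
   at the mass/formula of a single-component query;
6. strip charges from charged molecular formulas (structures untouched).

Element and disconnection filters run after collapsing so that eliminated
counts are reported per IKFB, and the accounting identity
``kept + eliminated = total`` holds by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .formula import (
    DEFAULT_BLACKLIST,
    ElementBlacklist,
    MolecularFormula,
    contains_excluded_element,
    is_multicomponent,
    neutralize_formula,
)
from .toc import (
    CategoryIndex,
    CategorySelection,
    TocFingerprint,
    anno_total_count,
    category_score,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CompoundRecord",
    "LiteEntry",
    "BuildReport",
    "filter_annotated",
    "map_to_parent",
    "collapse_by_ikfb",
    "apply_structure_filters",
    "build",
    "category_summary",
]

_REASON_ELEMENT = "element"
_REASON_DISCONNECTED = "disconnected"


@dataclass(frozen=True)
class CompoundRecord:
    """One raw database entry, keyed by its integer compound identifier."""

    cid: int
    name: str = ""
    smiles: str = ""
    inchi: str = ""
    inchikey: str = ""
    formula: MolecularFormula = field(default_factory=MolecularFormula)
    monoisotopic_mass: float = 0.0
    parent_cid: int | None = None
    pubmed_count: int = 0
    patent_count: int = 0
    fingerprint: TocFingerprint = field(default_factory=TocFingerprint)

    @property
    def ikfb(self) -> str:
        """InChIKey first block — the 14-character structural skeleton."""
        return self.inchikey[:14]


@dataclass(frozen=True)
class LiteEntry:
    """One collapsed database row, keyed by InChIKey first block.

    Identity fields come from the group's best (most annotated) CID;
    literature/patent counts are summed and fingerprints unioned over all
    related CIDs.
    """

    ikfb: str
    best_cid: int
    related_cids: tuple[int, ...]
    name: str
    smiles: str
    inchi: str
    inchikey: str
    formula: MolecularFormula
    monoisotopic_mass: float
    pubmed_count: int
    patent_count: int
    fingerprint: TocFingerprint = field(default_factory=TocFingerprint)
    category_scores: Mapping[str, int] = field(default_factory=dict)
    anno_total_count: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "category_scores", dict(self.category_scores))


@dataclass
class BuildReport:
    """Accounting over one build: kept + eliminated = total, by IKFB."""

    kept_ikfb: int = 0
    eliminated_ikfb: int = 0
    total_ikfb: int = 0
    parent_cids: int = 0
    annotated_cids: int = 0
    eliminated_reasons: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "kept_ikfb": self.kept_ikfb,
            "eliminated_ikfb": self.eliminated_ikfb,
            "total_ikfb": self.total_ikfb,
            "parent_cids": self.parent_cids,
            "annotated_cids": self.annotated_cids,
            "eliminated_reasons": dict(self.eliminated_reasons),
        }


def _selection_bits(sel: CategorySelection, idx: CategoryIndex) -> frozenset[int]:
    bits: set[int] = set()
    for name in sel.top_categories:
        bits |= idx.category_bits(name)
    return frozenset(bits)


def filter_annotated(
    records: Iterable[CompoundRecord], sel: CategorySelection, idx: CategoryIndex
) -> list[CompoundRecord]:
    """Rule 1: keep records whose fingerprint touches the selected categories.

    Any bit of a selected category counts — top or subcategory.
    """
    bits = _selection_bits(sel, idx)
    return [r for r in records if r.fingerprint.bits & bits]


def map_to_parent(records: Sequence[CompoundRecord]) -> list[CompoundRecord]:
    """Rule 2: fold child records onto their parents (the neutral forms).

    Each child's fingerprint is unioned into its parent and its counts are
    summed onto the parent; the child row is then dropped.  Parents absent
    from the input are materialized as stubs from the child's structure
    fields.  Records without a parent pass through unchanged.  Parent chains
    are followed to the root; cycles are an error.
    """
    by_cid = {r.cid: r for r in records}

    def root_of(cid: int) -> int:
        seen = {cid}
        while True:
            rec = by_cid.get(cid)
            if rec is None or rec.parent_cid is None or rec.parent_cid == rec.cid:
                return cid
            cid = rec.parent_cid
            if cid in seen:
                raise ValueError(f"parent cycle involving CID {cid}")
            seen.add(cid)

    merged: dict[int, CompoundRecord] = {}
    for rec in records:
        root = root_of(rec.cid)
        if root not in merged:
            proto = by_cid.get(root)
            if proto is None:
                # parent not in the dump: materialize a stub carrying the
                # child's structure fields under the parent CID
                proto = replace(
                    rec, cid=root,
                    pubmed_count=0, patent_count=0,
                    fingerprint=TocFingerprint(),
                )
            merged[root] = replace(proto, parent_cid=None)
        if rec.cid == root:
            continue  # own payload already in base
        base = merged[root]
        merged[root] = replace(
            base,
            fingerprint=base.fingerprint | rec.fingerprint,
            pubmed_count=base.pubmed_count + rec.pubmed_count,
            patent_count=base.patent_count + rec.patent_count,
        )
    return list(merged.values())


def collapse_by_ikfb(
    records: Sequence[CompoundRecord],
    sel: CategorySelection | None = None,
    idx: CategoryIndex | None = None,
) -> list[LiteEntry]:
    """Rule 3: one entry per InChIKey first block.

    The representative ("best") CID is the one with the most annotation —
    measured as the number of fingerprint bits within the active selection
    when a selection is given, otherwise all bits; ties go to the lowest
    CID.  Counts are summed and fingerprints unioned across the group.
    """
    sel_bits = _selection_bits(sel, idx) if sel is not None and idx is not None else None

    groups: dict[str, list[CompoundRecord]] = {}
    for rec in records:
        groups.setdefault(rec.ikfb, []).append(rec)

    entries: list[LiteEntry] = []
    for ikfb, group in groups.items():
        def annotation_size(r: CompoundRecord) -> int:
            bits = r.fingerprint.bits
            if sel_bits is not None:
                bits = bits & sel_bits
            return len(bits)

        best = min(group, key=lambda r: (-annotation_size(r), r.cid))
        fp = TocFingerprint()
        pubmed = patent = 0
        for r in group:
            fp = fp | r.fingerprint
            pubmed += r.pubmed_count
            patent += r.patent_count
        entries.append(
            LiteEntry(
                ikfb=ikfb,
                best_cid=best.cid,
                related_cids=tuple(sorted(r.cid for r in group)),
                name=best.name,
                smiles=best.smiles,
                inchi=best.inchi,
                inchikey=best.inchikey,
                formula=best.formula,
                monoisotopic_mass=best.monoisotopic_mass,
                pubmed_count=pubmed,
                patent_count=patent,
                fingerprint=fp,
            )
        )
    entries.sort(key=lambda e: e.ikfb)
    return entries


def apply_structure_filters(
    entries: Iterable[LiteEntry],
    blacklist: ElementBlacklist = DEFAULT_BLACKLIST,
) -> tuple[list[LiteEntry], list[tuple[LiteEntry, str]]]:
    """Rules 4-6: element blacklist, disconnection filter, charge stripping.

    Returns ``(kept, eliminated)`` where each eliminated entry carries a
    reason code (``element`` or ``disconnected``).  Every input entry lands
    in exactly one partition.  Charged formulas are kept, neutralized;
    structure strings are never modified.
    """
    kept: list[LiteEntry] = []
    eliminated: list[tuple[LiteEntry, str]] = []
    for entry in entries:
        if contains_excluded_element(entry.formula, blacklist):
            eliminated.append((entry, _REASON_ELEMENT))
        elif (entry.smiles or entry.inchi) and is_multicomponent(entry.smiles, entry.inchi):
            eliminated.append((entry, _REASON_DISCONNECTED))
        elif entry.formula.charge != 0:
            kept.append(replace(entry, formula=neutralize_formula(entry.formula)))
        else:
            kept.append(entry)
    return kept, eliminated


def _with_scores(
    entry: LiteEntry, sel: CategorySelection, idx: CategoryIndex
) -> LiteEntry:
    fp = idx.normalize(entry.fingerprint)
    scores = {name: category_score(fp, name, idx) for name in sel.top_categories}
    return replace(
        entry,
        fingerprint=fp,
        category_scores=scores,
        anno_total_count=anno_total_count(fp, sel, idx),
    )


def build(
    records: Sequence[CompoundRecord],
    sel: CategorySelection,
    idx: CategoryIndex,
    blacklist: ElementBlacklist = DEFAULT_BLACKLIST,
) -> tuple[list[LiteEntry], BuildReport, list[tuple[LiteEntry, str]]]:
    """Run the full six-rule pipeline and produce the accounting report.

    Returns ``(entries, report, eliminated)``; ``eliminated`` carries the
    per-entry reason codes for auditability.  Deterministic for fixed input.
    """
    annotated = filter_annotated(records, sel, idx)
    parents = map_to_parent(annotated)
    collapsed = collapse_by_ikfb(parents, sel, idx)
    kept, eliminated = apply_structure_filters(collapsed, blacklist)
    kept = [_with_scores(e, sel, idx) for e in kept]

    reasons: dict[str, int] = {}
    for _, reason in eliminated:
        reasons[reason] = reasons.get(reason, 0) + 1
    report = BuildReport(
        kept_ikfb=len(kept),
        eliminated_ikfb=len(eliminated),
        total_ikfb=len(collapsed),
        parent_cids=len(parents),
        annotated_cids=len(annotated),
        eliminated_reasons=reasons,
    )
    assert report.kept_ikfb + report.eliminated_ikfb == report.total_ikfb
    return kept, report, eliminated


def category_summary(entries: Iterable[LiteEntry], idx: CategoryIndex):
    """Per (top category, subcategory) CID and IKFB tallies.

    A compound annotated in k subcategories contributes to k rows, so the
    column totals deliberately include this duplication (the counts describe
    annotation volume, not unique compounds).  Related-CID counts use the
    whole collapsed group, since annotation was imputed to the group.
    Returns a pandas DataFrame with columns top, sub, cid_count, ikfb_count.
    """
    import pandas as pd

    rows: dict[tuple[str, str], dict[str, int]] = {}
    for entry in entries:
        n_cids = len(entry.related_cids)
        for bit in sorted(entry.fingerprint.bits):
            e = idx.entry(bit)
            key = (e.short_name, e.sub_name or "(top)")
            slot = rows.setdefault(key, {"cid_count": 0, "ikfb_count": 0})
            slot["cid_count"] += n_cids
            slot["ikfb_count"] += 1
    return pd.DataFrame(
        [
            {"top": top, "sub": sub, **counts}
            for (top, sub), counts in sorted(rows.items())
        ],
        columns=["top", "sub", "cid_count", "ikfb_count"],
    )
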