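"""Annotation-category tree, per-compound fingerprints, and category scores.

Large compound knowledge bases classify the annotation attached to each
record into a hierarchical table of contents (e.g. "Agrochemical
Information" with subcategories like "Agrochemical Category").  This module
models that tree as a flat bit index (:class:`CategoryIndex`), per-compound
presence/absence bitsets (:class:`TocFingerprint`), named selections of
top-level categories (:class:`CategorySelection`), and the two annotation
scores derived from them:

* :func:`category_score` — per top category, 1 for the category itself plus
  1 per subcategory present (0 if the category is absent entirely);
* :func:`anno_total_count` — the number of *selected* top categories
  present, the total-annotation-count column of the built database.

The index is an input, never hard-coded logic: real classification trees
change over time, so the package ships one frozen reference index
(``data/category_index.tsv``) and accepts any file in the same dialect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

__all__ = [
    "CategoryIndex",
    "TocFingerprint",
    "CategorySelection",
    "CategoryIndexError",
    "load_category_index",
    "reference_index",
    "builtin_selection",
    "BUILTIN_SELECTIONS",
    "category_score",
    "anno_total_count",
]


class CategoryIndexError(ValueError):
    """Raised for malformed category-index files or unresolvable names."""


@dataclass(frozen=True)
class CategoryEntry:
    bit: int
    top_name: str
    short_name: str
    sub_name: str = ""  # empty for top-category rows

    @property
    def is_top(self) -> bool:
        return not self.sub_name


class CategoryIndex:
    """Ordered bit → category mapping governing every fingerprint.

    Bits are unique and contiguous from 0.  Each top category owns one top
    bit and zero or more subcategory bits; only one level of nesting is
    modeled (deeper trees are flattened onto their first-level
    subcategory).
    """

    def __init__(self, entries: Iterable[CategoryEntry], version: str = "") -> None:
        self.entries: tuple[CategoryEntry, ...] = tuple(entries)
        self.version = version
        bits = [e.bit for e in self.entries]
        if sorted(bits) != list(range(len(bits))):
            dupes = {b for b in bits if bits.count(b) > 1}
            if dupes:
                raise CategoryIndexError(f"duplicate bit positions: {sorted(dupes)}")
            raise CategoryIndexError("bit positions must be contiguous from 0")
        self._by_bit = {e.bit: e for e in self.entries}
        self._top_bit: dict[str, int] = {}
        self._sub_bits: dict[str, list[int]] = {}
        self._full_to_short: dict[str, str] = {}
        for e in self.entries:
            if e.is_top:
                if e.short_name in self._top_bit:
                    raise CategoryIndexError(f"duplicate top category {e.short_name!r}")
                self._top_bit[e.short_name] = e.bit
                self._sub_bits[e.short_name] = []
                self._full_to_short[e.top_name] = e.short_name
        for e in self.entries:
            if not e.is_top:
                if e.short_name not in self._top_bit:
                    raise CategoryIndexError(
                        f"subcategory {e.sub_name!r} (bit {e.bit}) references "
                        f"unknown top category {e.short_name!r}"
                    )
                self._sub_bits[e.short_name].append(e.bit)

    # -- lookups -----------------------------------------------------------

    @property
    def width(self) -> int:
        """Number of bits in the fingerprint."""
        return len(self.entries)

    @property
    def top_categories(self) -> tuple[str, ...]:
        """Short names of all top categories, in bit order."""
        return tuple(self._top_bit)

    def resolve(self, name: str) -> str:
        """Map a short or full top-category name to its short name."""
        if name in self._top_bit:
            return name
        if name in self._full_to_short:
            return self._full_to_short[name]
        raise CategoryIndexError(
            f"unknown top category {name!r}; known: {sorted(self._top_bit)}"
        )

    def top_bit(self, name: str) -> int:
        return self._top_bit[self.resolve(name)]

    def sub_bits(self, name: str) -> frozenset[int]:
        return frozenset(self._sub_bits[self.resolve(name)])

    def category_bits(self, name: str) -> frozenset[int]:
        """Top bit plus all subcategory bits of one top category."""
        short = self.resolve(name)
        return frozenset({self._top_bit[short], *self._sub_bits[short]})

    def entry(self, bit: int) -> CategoryEntry:
        return self._by_bit[bit]

    def normalize(self, fp: "TocFingerprint") -> "TocFingerprint":
        """Add the top bit for every subcategory bit present.

        Annotation recorded only at subcategory level still implies that the
        top category has content, so fingerprints are normalized this way on
        ingest before any counting.
        """
        bits = set(fp.bits)
        for e in self.entries:
            if not e.is_top and e.bit in bits:
                bits.add(self._top_bit[e.short_name])
        return TocFingerprint(frozenset(bits))

    def validate(self, fp: "TocFingerprint") -> None:
        bad = [b for b in fp.bits if b not in self._by_bit]
        if bad:
            raise CategoryIndexError(f"fingerprint bits outside index: {sorted(bad)}")


@dataclass(frozen=True)
class TocFingerprint:
    """Set of category bits present for one compound record."""

    bits: frozenset[int] = frozenset()

    def __or__(self, other: "TocFingerprint") -> "TocFingerprint":
        return TocFingerprint(self.bits | other.bits)

    def __bool__(self) -> bool:
        return bool(self.bits)

    def to_hex(self, idx: CategoryIndex) -> str:
        """Serialize as a hex string, least-significant bit = position 0."""
        idx.validate(self)
        value = 0
        for b in self.bits:
            value |= 1 << b
        return format(value, "x")

    @classmethod
    def from_hex(cls, text: str, idx: CategoryIndex) -> "TocFingerprint":
        text = text.strip()
        max_digits = (idx.width + 3) // 4
        if len(text) > max_digits:
            raise CategoryIndexError(
                f"hex fingerprint {text!r} is wider than the index ({idx.width} bits)"
            )
        value = int(text or "0", 16)
        fp = cls(frozenset(b for b in range(value.bit_length()) if value >> b & 1))
        idx.validate(fp)
        return fp


@dataclass(frozen=True)
class CategorySelection:
    """A named, ordered choice of top categories defining one database tier."""

    name: str
    top_categories: tuple[str, ...]


_TIER0 = (
    "AgroChemInfo",
    "DrugMedicInfo",
    "FoodRelated",
    "PharmacoInfo",
    "SafetyInfo",
    "ToxicityInfo",
    "KnownUse",
)

BUILTIN_SELECTIONS: dict[str, CategorySelection] = {
    # environmental selection: seven use/hazard-oriented categories
    "tier0": CategorySelection("tier0", _TIER0),
    # exposomics tier: adds biological pathway/interaction content
    "tier1": CategorySelection("tier1", _TIER0 + ("BioPathway",)),
    # final exposomics selection: tier1 plus identification methods and
    # disease-association content
    "exposomics": CategorySelection(
        "exposomics", _TIER0 + ("BioPathway", "Identification", "DisorderDisease")
    ),
}


def builtin_selection(name: str) -> CategorySelection:
    """Return one of the built-in selections: tier0, tier1 or exposomics."""
    try:
        return BUILTIN_SELECTIONS[name]
    except KeyError:
        raise CategoryIndexError(
            f"unknown selection {name!r}; valid names: {sorted(BUILTIN_SELECTIONS)}"
        ) from None


def load_category_index(path) -> CategoryIndex:
    """Load a category index from its TSV dialect (bit, top, short, sub)."""
    if hasattr(path, "read"):
        text = path.read()
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    return _parse_index(text, version=str(path))


def _parse_index(text: str, version: str = "") -> CategoryIndex:
    entries: list[CategoryEntry] = []
    saw_header = False
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if not saw_header:
            saw_header = True
            if line.split("\t")[0].strip() == "bit":
                continue  # header row
        cols = line.split("\t")
        if len(cols) < 3:
            raise CategoryIndexError(f"line {lineno}: expected >=3 tab-separated columns")
        try:
            bit = int(cols[0])
        except ValueError:
            raise CategoryIndexError(f"line {lineno}: bad bit position {cols[0]!r}") from None
        sub = cols[3].strip() if len(cols) > 3 else ""
        entries.append(CategoryEntry(bit, cols[1].strip(), cols[2].strip(), sub))
    if not entries:
        raise CategoryIndexError("empty category index file")
    return CategoryIndex(entries, version=version)


def reference_index() -> CategoryIndex:
    """The frozen reference index shipped with the package."""
    text = (
        resources.files("chemlite")
        .joinpath("data/category_index.tsv")
        .read_text(encoding="utf-8")
    )
    return _parse_index(text, version="chemlite-reference")


def category_score(fp: TocFingerprint, top: str, idx: CategoryIndex) -> int:
    """1 + number of subcategories present, or 0 if the category is absent.

    The top-category bit gates the score: a fingerprint carrying only
    subcategory bits of a category scores 0 unless normalized first (see
    :meth:`CategoryIndex.normalize`).
    """
    short = idx.resolve(top)
    if idx.top_bit(short) not in fp.bits:
        return 0
    return 1 + len(idx.sub_bits(short) & fp.bits)


def anno_total_count(fp: TocFingerprint, sel: CategorySelection, idx: CategoryIndex) -> int:
    """Number of selected top categories whose top bit is present."""
    return sum(1 for name in sel.top_categories if idx.top_bit(name) in fp.bits)
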