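"""Molecular formulas: parsing, monoisotopic mass, charge handling, filters.

This module backs the structure-level filtering rules of the database
builder: element-blacklist screening, detection of multi-component
(disconnected) structures, and neutralization of charged formulas.

Masses are computed from a frozen table of most-abundant-isotope masses
shipped with the package (``data/isotope_masses.tsv``), so results are
reproducible across environments and library versions.  The electron mass
is neglected: at the 5 ppm retrieval windows used downstream the ~0.5 mDa
electron contribution of a singly charged species is irrelevant, and
formulas are neutralized before any mass query anyway.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

__all__ = [
    "MolecularFormula",
    "ElementBlacklist",
    "FormulaError",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "neutralize_formula",
    "contains_excluded_element",
    "is_multicomponent",
    "ELEMENT_MASSES",
    "DEFAULT_BLACKLIST",
]


class FormulaError(ValueError):
    """Raised for malformed formula strings or untabulated elements."""


def _load_isotope_masses() -> dict[str, float]:
    text = (
        resources.files("chemlite")
        .joinpath("data/isotope_masses.tsv")
        .read_text(encoding="utf-8")
    )
    masses: dict[str, float] = {}
    for line in text.splitlines():
        if not line or line.startswith("#") or line.startswith("atomic_number"):
            continue
        _, symbol, mass = line.split("\t")
        masses[symbol] = float(mass)
    return masses


#: Monoisotopic mass (Da) of the most abundant isotope, per element symbol.
ELEMENT_MASSES: Mapping[str, float] = _load_isotope_masses()

_VALID_SYMBOLS = frozenset(ELEMENT_MASSES)

# Default element exclusion list for the structure filters: rare-earth,
# platinum-group, radioactive and other elements whose compounds are not
# candidates in small-molecule HR-MS screening.
_DEFAULT_BLACKLIST_SYMBOLS = frozenset(
    "Kr Dy Ir La Lu Nd Nb Os Pd Pt Pu Pr Re Rh Ru Sm Sc Ag Ta Tc Tb Th Tm "
    "Ti W Ac Am Er Eu Gd Hf Ho Xe Yb Rn Sr Be Cm Cf Cs Md Pm Fr Pa Np Bk "
    "Es Fm No Lr Rf Db Sg Bh Hs Mt Ds Rg Cn Nh Fl Mc Lv Ts Og".split()
)


@dataclass(frozen=True)
class MolecularFormula:
    """Element composition plus net charge (elementary charges).

    ``element_counts`` maps element symbols to positive counts; the empty
    mapping is the empty formula (mass 0).
    """

    element_counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        for sym, n in self.element_counts.items():
            if sym not in _VALID_SYMBOLS:
                raise FormulaError(f"unknown element symbol: {sym!r}")
            if not isinstance(n, int) or n < 1:
                raise FormulaError(f"count for {sym} must be a positive integer, got {n!r}")
        # freeze the mapping so the dataclass is hashable-by-value in spirit
        object.__setattr__(self, "element_counts", dict(self.element_counts))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return (
            dict(self.element_counts) == dict(other.element_counts)
            and self.charge == other.charge
        )

    def __hash__(self) -> int:
        return hash((frozenset(self.element_counts.items()), self.charge))


@dataclass(frozen=True)
class ElementBlacklist:
    """Set of element symbols whose compounds are excluded from the database."""

    symbols: frozenset[str] = _DEFAULT_BLACKLIST_SYMBOLS

    def __post_init__(self) -> None:
        unknown = set(self.symbols) - _VALID_SYMBOLS
        if unknown:
            raise FormulaError(f"blacklist contains unknown symbols: {sorted(unknown)}")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


DEFAULT_BLACKLIST = ElementBlacklist()

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")
_CHARGE_RE = re.compile(r"([+-])(\d*)$")


def parse_formula(text: str) -> MolecularFormula:
    """Parse a Hill-style formula string, e.g. ``C10H14N2`` or ``C6H5O-``.

    A trailing charge token of sign-then-magnitude form (``+``, ``-``,
    ``+2``, ``-2``) is accepted; embedded charges are rejected.  The
    digits-before-sign form (``2+``) is deliberately not treated as a
    charge magnitude because it is ambiguous with a trailing element count
    (``C9H13N2+`` means two nitrogens and charge +1).  Raises
    :class:`FormulaError` on empty input or unknown element symbols.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula string")
    body = text.strip()

    charge = 0
    m = _CHARGE_RE.search(body)
    if m:
        magnitude = int(m.group(2)) if m.group(2) else 1
        charge = magnitude if m.group(1) == "+" else -magnitude
        body = body[: m.start()]
        if not body:
            raise FormulaError(f"formula {text!r} has a charge token but no elements")

    counts: dict[str, int] = {}
    pos = 0
    while pos < len(body):
        m = _TOKEN_RE.match(body, pos)
        if not m or m.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}: {body[pos:]!r}")
        sym, digits = m.group(1), m.group(2)
        if sym not in _VALID_SYMBOLS:
            raise FormulaError(f"unknown element symbol {sym!r} in formula {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos = m.end()
    if not counts:
        raise FormulaError(f"no elements found in formula {text!r}")
    return MolecularFormula(counts, charge)


def format_formula(f: MolecularFormula) -> str:
    """Serialize to Hill order (C, H, then alphabetical), charge token last."""
    symbols = sorted(f.element_counts)
    ordered: list[str] = []
    if "C" in f.element_counts:
        ordered.append("C")
        if "H" in f.element_counts:
            ordered.append("H")
        ordered.extend(s for s in symbols if s not in ("C", "H"))
    else:
        ordered = symbols
    parts = [f"{s}{f.element_counts[s] if f.element_counts[s] > 1 else ''}" for s in ordered]
    if f.charge:
        mag = abs(f.charge)
        parts.append(f"{'+' if f.charge > 0 else '-'}{mag if mag > 1 else ''}")
    return "".join(parts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Sum of count x most-abundant-isotope mass, in Da.  Charge is ignored."""
    total = 0.0
    for sym, n in f.element_counts.items():
        mass = ELEMENT_MASSES.get(sym, 0.0)
        if mass == 0.0:
            raise FormulaError(f"no tabulated isotope mass for element {sym}")
        total += n * mass
    return total


def neutralize_formula(f: MolecularFormula) -> MolecularFormula:
    """Strip the charge notation; element counts are left untouched.

    This deliberately does not add or remove hydrogens: the builder's rule
    removes charges from the *formula notation* only, leaving the
    corresponding structure strings as they are.
    """
    if f.charge == 0:
        return f
    return MolecularFormula(f.element_counts, 0)


def contains_excluded_element(f: MolecularFormula, blacklist: ElementBlacklist = DEFAULT_BLACKLIST) -> bool:
    """True iff any element of ``f`` is on the blacklist."""
    return any(sym in blacklist for sym in f.element_counts)


def is_multicomponent(smiles: str = "", inchi: str = "") -> bool:
    """Detect disconnected (multi-component) structures lexically.

    A SMILES with a component-separator dot outside of brackets, or an InChI
    whose formula layer contains a ``.`` separator, denotes a salt, mixture
    or other multi-component record.  Such entries cannot be observed at the
    mass/formula of a single-component query and are filtered out by the
    builder.  At least one identifier must be non-empty.
    """
    if not smiles and not inchi:
        raise ValueError("need at least one of SMILES or InChI")
    if smiles:
        depth = 0
        for ch in smiles:
            if ch == "[":
                depth += 1
            elif ch == "]":
                depth = max(0, depth - 1)
            elif ch == "." and depth == 0:
                return True
    if inchi:
        # formula layer is the second '/'-separated segment
        parts = inchi.split("/")
        if len(parts) > 1 and "." in parts[1]:
            return True
    return False
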