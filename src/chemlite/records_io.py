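"""Readers and writers for every file format the toolkit touches.

Dump dialect (tab-separated, one header row each):

* ``compounds.tsv`` — CID, ParentCID, Name, SMILES, InChI, InChIKey,
  Formula, MonoisotopicMass (blank mass is computed from the formula);
* ``counts.tsv`` — CID, PubMedCount, PatentCount;
* ``toc.tsv`` — CID, FingerprintHex.

The compact database is written as a plain CSV consumable by downstream
identification tools: fixed identity/metadata columns, one score column per
selected top category (short name), and a semicolon-joined RelatedCIDs
column.  Suspect lists and predecessor/successor transformation lists are
simple CSVs with documented required columns.  All text is UTF-8; CSV
quoting follows RFC 4180 (pandas defaults).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .builder import CompoundRecord, LiteEntry
from .formula import MolecularFormula, monoisotopic_mass, parse_formula
from .toc import CategoryIndex, CategorySelection, TocFingerprint

logger = logging.getLogger(__name__)

__all__ = [
    "SuspectEntry",
    "TransformationMapping",
    "DumpFormatError",
    "read_dump",
    "write_lite_csv",
    "read_lite_csv",
    "lite_table",
    "read_suspect_list",
    "read_transformation_list",
]

_INCHIKEY_RE = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")

#: Fixed lite-CSV columns preceding the per-category score columns.
LITE_FIXED_COLUMNS = (
    "Identifier",
    "CompoundName",
    "MolecularFormula",
    "MonoisotopicMass",
    "SMILES",
    "InChI",
    "InChIKey",
    "InChIKeyFirstBlock",
    "PubMed_Count",
    "Patent_Count",
    "AnnoTypeCount",
)


class DumpFormatError(ValueError):
    """Raised for malformed dump / list files, with file and line context."""


@dataclass(frozen=True)
class SuspectEntry:
    """One row of a suspect list: a chemical of interest to screen for."""

    name: str
    inchikey: str = ""  # full key or bare first block, upper-cased
    formula: MolecularFormula | None = None
    neutral_mass: float | None = None

    @property
    def ikfb(self) -> str:
        return self.inchikey[:14]


@dataclass(frozen=True)
class TransformationMapping:
    """Predecessor -> successor (transformation product) relation."""

    predecessor_cid: int
    predecessor_name: str
    successor_cid: int
    successor_name: str
    source: str = ""


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _parse_cid(value: str, path, lineno: int) -> int:
    try:
        cid = int(value)
    except (TypeError, ValueError):
        raise DumpFormatError(f"{path}:{lineno}: malformed CID {value!r}") from None
    if cid <= 0:
        raise DumpFormatError(f"{path}:{lineno}: CID must be positive, got {cid}")
    return cid


def read_dump(
    compounds_path,
    counts_path,
    toc_path,
    idx: CategoryIndex,
) -> list[CompoundRecord]:
    """Assemble compound records from the three dump files, keyed by CID.

    Counts and fingerprints are joined onto the compound rows; missing
    counts default to 0 and a missing fingerprint to the empty set.  Count
    or fingerprint rows whose CID has no compound row are orphans: they are
    skipped with a logged warning.  A blank mass column is filled from the
    formula.  Fingerprints are normalized so any subcategory bit implies
    its top-category bit.
    """
    compounds = _read_tsv(compounds_path)

    counts: dict[int, tuple[int, int]] = {}
    counts_df = _read_tsv(counts_path)
    cids_seen: set[int] = set()
    for i, row in enumerate(compounds.itertuples(index=False), start=2):
        cids_seen.add(_parse_cid(row.CID, compounds_path, i))

    orphans = 0
    for i, row in enumerate(counts_df.itertuples(index=False), start=2):
        cid = _parse_cid(row.CID, counts_path, i)
        if cid not in cids_seen:
            orphans += 1
            continue
        counts[cid] = (int(row.PubMedCount or 0), int(row.PatentCount or 0))

    fingerprints: dict[int, TocFingerprint] = {}
    toc_df = _read_tsv(toc_path)
    for i, row in enumerate(toc_df.itertuples(index=False), start=2):
        cid = _parse_cid(row.CID, toc_path, i)
        if cid not in cids_seen:
            orphans += 1
            continue
        try:
            fingerprints[cid] = TocFingerprint.from_hex(row.FingerprintHex, idx)
        except ValueError as exc:
            raise DumpFormatError(f"{toc_path}:{i}: {exc}") from exc
    if orphans:
        logger.warning("skipped %d orphan count/fingerprint rows", orphans)

    records: list[CompoundRecord] = []
    for i, row in enumerate(compounds.itertuples(index=False), start=2):
        cid = _parse_cid(row.CID, compounds_path, i)
        inchikey = row.InChIKey.strip().upper()
        if inchikey and not _INCHIKEY_RE.match(inchikey):
            raise DumpFormatError(
                f"{compounds_path}:{i}: InChIKey {inchikey!r} does not match "
                "the 14-10-1 pattern"
            )
        try:
            f = parse_formula(row.Formula) if row.Formula else MolecularFormula()
        except ValueError as exc:
            raise DumpFormatError(f"{compounds_path}:{i}: {exc}") from exc
        mass = float(row.MonoisotopicMass) if row.MonoisotopicMass else (
            monoisotopic_mass(f) if f.element_counts else 0.0
        )
        parent = int(row.ParentCID) if row.ParentCID else None
        pubmed, patent = counts.get(cid, (0, 0))
        fp = idx.normalize(fingerprints.get(cid, TocFingerprint()))
        records.append(
            CompoundRecord(
                cid=cid,
                parent_cid=parent,
                name=row.Name,
                smiles=row.SMILES,
                inchi=row.InChI,
                inchikey=inchikey,
                formula=f,
                monoisotopic_mass=mass,
                pubmed_count=pubmed,
                patent_count=patent,
                fingerprint=fp,
            )
        )
    return records


def lite_table(entries: Sequence[LiteEntry], sel: CategorySelection) -> pd.DataFrame:
    """Render collapsed entries as the lite-CSV table (a DataFrame)."""
    from .formula import format_formula

    rows = []
    for e in entries:
        row = {
            "Identifier": e.best_cid,
            "CompoundName": e.name,
            "MolecularFormula": format_formula(e.formula),
            "MonoisotopicMass": round(e.monoisotopic_mass, 6),
            "SMILES": e.smiles,
            "InChI": e.inchi,
            "InChIKey": e.inchikey,
            "InChIKeyFirstBlock": e.ikfb,
            "PubMed_Count": e.pubmed_count,
            "Patent_Count": e.patent_count,
            "AnnoTypeCount": e.anno_total_count,
        }
        for name in sel.top_categories:
            row[name] = e.category_scores.get(name, 0)
        row["RelatedCIDs"] = ";".join(str(c) for c in sorted(e.related_cids))
        rows.append(row)
    columns = list(LITE_FIXED_COLUMNS) + list(sel.top_categories) + ["RelatedCIDs"]
    return pd.DataFrame(rows, columns=columns)


def write_lite_csv(entries: Sequence[LiteEntry], sel: CategorySelection, path) -> int:
    """Write the compact database CSV; returns the number of rows written."""
    table = lite_table(entries, sel)
    table.to_csv(path, index=False)
    return len(table)


def read_lite_csv(path, sel: CategorySelection) -> list[LiteEntry]:
    """Load a lite CSV back into entries.

    The CSV does not carry the raw fingerprint, only the derived category
    scores, so round-tripped entries have an empty fingerprint; everything
    visible in the table is preserved exactly (masses to 1e-6 Da).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in LITE_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise DumpFormatError(f"{path}: missing lite-CSV columns {missing}")
    entries: list[LiteEntry] = []
    for row in df.itertuples(index=False):
        related = tuple(int(c) for c in getattr(row, "RelatedCIDs").split(";") if c)
        scores = {
            name: int(getattr(row, name) or 0)
            for name in sel.top_categories
            if name in df.columns
        }
        entries.append(
            LiteEntry(
                ikfb=row.InChIKeyFirstBlock,
                best_cid=int(row.Identifier),
                related_cids=related,
                name=row.CompoundName,
                smiles=row.SMILES,
                inchi=row.InChI,
                inchikey=row.InChIKey,
                formula=parse_formula(row.MolecularFormula),
                monoisotopic_mass=float(row.MonoisotopicMass),
                pubmed_count=int(row.PubMed_Count),
                patent_count=int(row.Patent_Count),
                category_scores=scores,
                anno_total_count=int(row.AnnoTypeCount),
            )
        )
    return entries


def _pick_column(df: pd.DataFrame, *names: str) -> str | None:
    lowered = {c.lower().replace("_", "").replace(" ", ""): c for c in df.columns}
    for name in names:
        if name in lowered:
            return lowered[name]
    return None


def read_suspect_list(path) -> list[SuspectEntry]:
    """Read a suspect list CSV: a name column plus >=1 identifier column.

    Recognized identifier columns (case/underscore-insensitive): InChIKey,
    Formula / MolecularFormula, NeutralMass / MonoisotopicMass.  InChIKeys
    are upper-cased and trimmed; duplicates are preserved (de-duplication is
    the caller's choice).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    name_col = _pick_column(df, "name", "compoundname")
    if name_col is None:
        raise DumpFormatError(f"{path}: no name column")
    key_col = _pick_column(df, "inchikey")
    formula_col = _pick_column(df, "formula", "molecularformula")
    mass_col = _pick_column(df, "neutralmass", "monoisotopicmass", "mass")
    if not any((key_col, formula_col, mass_col)):
        raise DumpFormatError(f"{path}: no identifier column (InChIKey/Formula/NeutralMass)")

    entries: list[SuspectEntry] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = getattr(row, key_col).strip().upper() if key_col else ""
        formula_text = getattr(row, formula_col).strip() if formula_col else ""
        mass_text = getattr(row, mass_col).strip() if mass_col else ""
        if not key and not formula_text and not mass_text:
            raise DumpFormatError(f"{path}:{i}: row has no identifier (key/formula/mass)")
        entries.append(
            SuspectEntry(
                name=getattr(row, name_col),
                inchikey=key,
                formula=parse_formula(formula_text) if formula_text else None,
                neutral_mass=float(mass_text) if mass_text else None,
            )
        )
    return entries


def read_transformation_list(path) -> list[TransformationMapping]:
    """Read a predecessor/successor transformation-product mapping CSV.

    Required columns: PredecessorCID, PredecessorName, SuccessorCID,
    SuccessorName; optional Source (provenance, carried through).  A row
    mapping a compound to itself is an error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["PredecessorCID", "PredecessorName", "SuccessorCID", "SuccessorName"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise DumpFormatError(f"{path}: missing columns {missing}")
    mappings: list[TransformationMapping] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        pred = _parse_cid(row.PredecessorCID, path, i)
        succ = _parse_cid(row.SuccessorCID, path, i)
        if pred == succ:
            raise DumpFormatError(f"{path}:{i}: compound {pred} maps to itself")
        mappings.append(
            TransformationMapping(
                predecessor_cid=pred,
                predecessor_name=row.PredecessorName,
                successor_cid=succ,
                successor_name=row.SuccessorName,
                source=getattr(row, "Source", ""),
            )
        )
    return mappings
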