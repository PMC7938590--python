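"""Deterministic synthetic dumps, suspect lists and benchmark sets.

Real annotation dumps are hundreds of thousands of records and change
weekly; this module produces small dumps with the same statistical shape so
every other module is testable without downloads:

* stereoisomer groups sharing an InChIKey first block (group sizes follow
  a small-integer distribution over a fixed number of groups);
* isomer clusters — several groups drawn from a shared formula pool, so
  exact-mass windows contain genuine isobaric competitors;
* sparse multi-category annotation (independent per top category, with a
  random handful of subcategories when a category is present);
* heavy-tailed literature/patent counts (discretized log-normal);
* controllable fractions of disconnected, blacklisted-element, charged and
  parent-linked records.

Alongside the dump files the generator emits a :class:`FixtureTruth`
computed by a straight-line re-derivation of the six construction rules
that shares no code with :mod:`chemlite.builder` — an independent oracle
the pipeline can be checked against.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .builder import LiteEntry
from .evaluate import BenchmarkEntry
from .toc import CategoryIndex, CategorySelection, builtin_selection, reference_index

__all__ = ["FixtureConfig", "FixtureTruth", "generate_fixture", "generate_benchmark"]

_BLACKLIST_SAMPLE = ("Ti", "Pt", "Ag", "Pd", "W")  # commonly hit exclusions
_UPPER = string.ascii_uppercase


@dataclass(frozen=True)
class FixtureConfig:
    """Study conditions for one synthetic dump.

    Defaults mirror the structure of real annotation dumps at desk scale:
    ~2.5 CIDs per skeleton, ~4% of skeletons eliminated by the structure
    filters (mostly salts/mixtures), heavy-tailed counts spanning zero to
    tens of thousands.
    """

    n_compounds: int = 300
    n_ikfb_groups: int = 120
    #: groups per shared formula (isomer cluster size); pool is derived
    n_formula_pool: int | None = None
    annotation_density: float = 0.2
    #: log-normal parameters for pubmed/patent counts
    count_mu: float = 2.0
    count_sigma: float = 2.0
    fraction_disconnected: float = 0.03
    fraction_blacklisted: float = 0.01
    fraction_charged: float = 0.05
    fraction_with_parent: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "annotation_density",
            "fraction_disconnected",
            "fraction_blacklisted",
            "fraction_charged",
            "fraction_with_parent",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_ikfb_groups > self.n_compounds:
            raise ValueError("n_ikfb_groups cannot exceed n_compounds")
        if self.n_ikfb_groups < 1:
            raise ValueError("need at least one group")


@dataclass
class FixtureTruth:
    """Expected pipeline output, derived independently of the builder.

    ``kept`` maps IKFB -> dict(best_cid, related_cids, category_scores,
    anno_total_count); ``eliminated`` maps IKFB -> reason code.
    """

    selection: str
    kept: dict = field(default_factory=dict)
    eliminated: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# generation


def _random_block(rng: np.random.Generator, n: int) -> str:
    return "".join(_UPPER[i] for i in rng.integers(0, 26, size=n))


def _random_formula(rng: np.random.Generator) -> dict[str, int]:
    c = int(rng.integers(4, 26))
    h = int(rng.integers(c, 2 * c + 3))
    counts = {"C": c, "H": h}
    if rng.random() < 0.7:
        counts["N"] = int(rng.integers(1, 4))
    if rng.random() < 0.8:
        counts["O"] = int(rng.integers(1, 6))
    if rng.random() < 0.25:
        counts["Cl"] = int(rng.integers(1, 3))
    if rng.random() < 0.15:
        counts["S"] = 1
    return counts


def _hill_string(counts: dict[str, int], charge: int = 0) -> str:
    order = ["C", "H"] + sorted(k for k in counts if k not in ("C", "H"))
    s = "".join(f"{el}{counts[el] if counts[el] > 1 else ''}" for el in order if el in counts)
    if charge:
        s += ("+" if charge > 0 else "-") + (str(abs(charge)) if abs(charge) > 1 else "")
    return s


def _mass_of(counts: dict[str, int]) -> float:
    from .formula import ELEMENT_MASSES

    return sum(n * ELEMENT_MASSES[el] for el, n in counts.items())


def _simple_smiles(rng: np.random.Generator, counts: dict[str, int], disconnected: bool) -> str:
    # structure fidelity is irrelevant to the rules under test; only the
    # presence of a component-separator dot matters
    chain = "C" * max(2, min(counts.get("C", 2), 8))
    if "N" in counts:
        chain += "N"
    if "O" in counts:
        chain += "O"
    if disconnected:
        return chain + ".Cl" if "Cl" in counts else chain + ".O"
    return chain


def generate_fixture(
    cfg: FixtureConfig,
    out_dir,
    idx: CategoryIndex | None = None,
    selection: CategorySelection | str = "tier0",
) -> tuple[dict[str, Path], FixtureTruth]:
    """Write compounds/counts/toc TSVs plus the truth JSON to ``out_dir``.

    Returns the file paths and the :class:`FixtureTruth` for the given
    selection.  Identical config (including seed) produces byte-identical
    files.
    """
    idx = idx or reference_index()
    sel = builtin_selection(selection) if isinstance(selection, str) else selection
    rng = np.random.default_rng(cfg.seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # -- group-level draws -------------------------------------------------
    n_groups = cfg.n_ikfb_groups
    pool_size = cfg.n_formula_pool or max(3, n_groups // 4)
    formula_pool = [_random_formula(rng) for _ in range(pool_size)]

    blocks: set[str] = set()
    while len(blocks) < n_groups:
        blocks.add(_random_block(rng, 14))
    group_ikfb = sorted(blocks)

    # distribute compounds over groups: one each, remainder at random
    sizes = np.ones(n_groups, dtype=int)
    extra = rng.integers(0, n_groups, size=cfg.n_compounds - n_groups)
    for g in extra:
        sizes[g] += 1

    group_formula = [formula_pool[int(rng.integers(0, pool_size))] for _ in range(n_groups)]
    group_disconnected = rng.random(n_groups) < cfg.fraction_disconnected
    group_blacklisted = rng.random(n_groups) < cfg.fraction_blacklisted
    group_charged = rng.random(n_groups) < cfg.fraction_charged
    group_blackelem = [
        _BLACKLIST_SAMPLE[int(rng.integers(0, len(_BLACKLIST_SAMPLE)))] for _ in range(n_groups)
    ]

    tops = idx.top_categories
    top_bits = {t: idx.top_bit(t) for t in tops}
    sub_bits = {t: sorted(idx.sub_bits(t)) for t in tops}

    # -- member-level rows -------------------------------------------------
    rows: list[dict] = []
    cid = 0
    for g in range(n_groups):
        counts = dict(group_formula[g])
        if group_blacklisted[g]:
            counts[group_blackelem[g]] = 1
        charge = int(rng.choice([-1, 1])) if group_charged[g] else 0
        mass = _mass_of(counts)
        smiles = _simple_smiles(rng, counts, bool(group_disconnected[g]))
        primary_cid = None
        for m in range(int(sizes[g])):
            cid += int(rng.integers(1, 9))  # sparse, increasing CIDs
            bits: set[int] = set()
            for t in tops:
                if rng.random() < cfg.annotation_density:
                    bits.add(top_bits[t])
                    if sub_bits[t]:
                        k = int(rng.integers(0, len(sub_bits[t]) + 1))
                        bits.update(rng.choice(sub_bits[t], size=k, replace=False).tolist())
            parent = None
            if primary_cid is None:
                primary_cid = cid
            elif rng.random() < cfg.fraction_with_parent:
                parent = primary_cid
            rows.append(
                {
                    "cid": cid,
                    "parent": parent,
                    "name": f"Compound-{cid}",
                    "smiles": smiles,
                    "inchi": f"InChI=1S/{_hill_string(counts)}/c{cid}",
                    "inchikey": f"{group_ikfb[g]}-{_random_block(rng, 10)}-N",
                    "formula_counts": counts,
                    "charge": charge,
                    "formula": _hill_string(counts, charge),
                    "mass": mass,
                    "pubmed": int(rng.lognormal(cfg.count_mu, cfg.count_sigma)),
                    "patent": int(rng.lognormal(cfg.count_mu, cfg.count_sigma)),
                    "bits": bits,
                }
            )

    paths = _write_dump(rows, out, idx)
    truth = _expected_truth(rows, sel, idx)
    truth.to_json(out / "truth.json")
    paths["truth"] = out / "truth.json"
    return paths, truth


def _write_dump(rows: list[dict], out: Path, idx: CategoryIndex) -> dict[str, Path]:
    compounds = out / "compounds.tsv"
    counts = out / "counts.tsv"
    toc = out / "toc.tsv"
    with compounds.open("w", encoding="utf-8") as fh:
        fh.write("CID\tParentCID\tName\tSMILES\tInChI\tInChIKey\tFormula\tMonoisotopicMass\n")
        for r in rows:
            fh.write(
                f"{r['cid']}\t{r['parent'] if r['parent'] else ''}\t{r['name']}\t"
                f"{r['smiles']}\t{r['inchi']}\t{r['inchikey']}\t{r['formula']}\t"
                f"{r['mass']:.6f}\n"
            )
    with counts.open("w", encoding="utf-8") as fh:
        fh.write("CID\tPubMedCount\tPatentCount\n")
        for r in rows:
            fh.write(f"{r['cid']}\t{r['pubmed']}\t{r['patent']}\n")
    with toc.open("w", encoding="utf-8") as fh:
        fh.write("CID\tFingerprintHex\n")
        for r in rows:
            value = 0
            for b in r["bits"]:
                value |= 1 << b
            fh.write(f"{r['cid']}\t{value:x}\n")
    return {"compounds": compounds, "counts": counts, "toc": toc}


# ---------------------------------------------------------------------------
# independent truth oracle: a straight-line re-derivation of the six rules
# over the raw generated rows, sharing no code with chemlite.builder


def _expected_truth(rows: list[dict], sel: CategorySelection, idx: CategoryIndex) -> FixtureTruth:
    from .formula import DEFAULT_BLACKLIST

    tops = list(sel.top_categories)
    top_bit = {t: idx.top_bit(t) for t in tops}
    subs = {t: set(idx.sub_bits(t)) for t in tops}
    sel_bits: set[int] = set()
    for t in tops:
        sel_bits |= {top_bit[t]} | subs[t]

    def norm(bits: set[int]) -> set[int]:
        # subcategory presence implies the top category
        b = set(bits)
        for t in idx.top_categories:
            if b & set(idx.sub_bits(t)):
                b.add(idx.top_bit(t))
        return b

    # rule 1: annotated in the selection (on normalized bits)
    annotated = [r for r in rows if norm(r["bits"]) & sel_bits]

    # rule 2: fold children onto parents
    merged: dict[int, dict] = {}
    by_cid = {r["cid"]: r for r in annotated}
    for r in annotated:
        root = r["cid"]
        while by_cid.get(root, {}).get("parent"):
            root = by_cid[root]["parent"]
        slot = merged.get(root)
        if slot is None:
            proto = by_cid.get(root, r)
            slot = merged[root] = {
                "cid": root,
                "ikfb": proto["inchikey"][:14],
                "smiles": proto["smiles"],
                "formula_counts": dict(proto["formula_counts"]),
                "bits": set(norm(proto["bits"])) if root in by_cid else set(),
                "pubmed": proto["pubmed"] if root in by_cid else 0,
                "patent": proto["patent"] if root in by_cid else 0,
            }
        if r["cid"] != root:
            slot["bits"] |= norm(r["bits"])
            slot["pubmed"] += r["pubmed"]
            slot["patent"] += r["patent"]

    # rule 3: collapse by IKFB, best = most selected bits, tie lowest CID
    groups: dict[str, list[dict]] = {}
    for slot in merged.values():
        groups.setdefault(slot["ikfb"], []).append(slot)

    truth = FixtureTruth(selection=sel.name)
    for ikfb, members in groups.items():
        best = sorted(members, key=lambda s: (-len(s["bits"] & sel_bits), s["cid"]))[0]
        union_bits: set[int] = set()
        for s in members:
            union_bits |= s["bits"]
        # rules 4-5 on the best CID's structure/formula
        if any(el in DEFAULT_BLACKLIST.symbols for el in best["formula_counts"]):
            truth.eliminated[ikfb] = "element"
            continue
        if "." in best["smiles"]:
            truth.eliminated[ikfb] = "disconnected"
            continue
        scores = {
            t: (1 + len(subs[t] & union_bits)) if top_bit[t] in union_bits else 0
            for t in tops
        }
        truth.kept[ikfb] = {
            "best_cid": best["cid"],
            "related_cids": sorted(s["cid"] for s in members),
            "category_scores": scores,
            "anno_total_count": sum(1 for t in tops if top_bit[t] in union_bits),
            "pubmed_count": sum(s["pubmed"] for s in members),
            "patent_count": sum(s["patent"] for s in members),
        }
    return truth


# ---------------------------------------------------------------------------
# benchmark generation


def generate_benchmark(
    db: list[LiteEntry],
    n_queries: int,
    informativeness: float,
    seed: int,
    ppm: float = 5.0,
    term: str = "SpectralSim",
) -> list[BenchmarkEntry]:
    """Draw benchmark queries from the database with a controllable oracle.

    Each query is a database entry; its external ``term`` scores are drawn
    so the correct candidate holds the strict per-window maximum with
    probability ``informativeness``, and otherwise all window candidates
    (including the correct one) score i.i.d. — the score then carries no
    information about correctness.  Queries are preferentially drawn from
    entries with at least one isobaric competitor in the ppm window, where
    the oracle's informativeness is actually exercised.
    """
    if not db:
        raise ValueError("database is empty")
    if n_queries > len(db):
        raise ValueError(f"n_queries={n_queries} exceeds database size {len(db)}")
    if not 0.0 <= informativeness <= 1.0:
        raise ValueError("informativeness must be in [0, 1]")
    rng = np.random.default_rng(seed)

    masses = np.array([e.monoisotopic_mass for e in db])

    def window(i: int) -> list[int]:
        m = masses[i]
        return [j for j in range(len(db)) if abs(masses[j] - m) / m * 1e6 <= ppm]

    windows = {i: window(i) for i in range(len(db))}
    contested = [i for i in range(len(db)) if len(windows[i]) > 1]
    singleton = [i for i in range(len(db)) if len(windows[i]) == 1]
    if len(contested) >= n_queries:
        chosen = [int(i) for i in rng.choice(contested, size=n_queries, replace=False)]
    else:
        fill = rng.choice(singleton, size=n_queries - len(contested), replace=False)
        chosen = contested + [int(i) for i in fill]

    entries: list[BenchmarkEntry] = []
    for i in chosen:
        cands = windows[i]
        scores = {db[j].ikfb: float(rng.uniform(0.0, 0.85)) for j in cands}
        if rng.random() < informativeness:
            scores[db[i].ikfb] = float(rng.uniform(0.9, 1.0))
        entries.append(
            BenchmarkEntry(
                name=db[i].name,
                ikfb=db[i].ikfb,
                neutral_mass=db[i].monoisotopic_mass,
                external_scores={term: scores},
            )
        )
    return entries
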