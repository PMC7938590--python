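import pytest

from chemlite.builder import CompoundRecord
from chemlite.fixtures import FixtureConfig, generate_fixture
from chemlite.formula import parse_formula
from chemlite.toc import TocFingerprint, builtin_selection, reference_index


@pytest.fixture(scope="session")
def idx():
    return reference_index()


@pytest.fixture(scope="session")
def tier0():
    return builtin_selection("tier0")


@pytest.fixture(scope="session")
def dump(tmp_path_factory, idx):
    """One generated dump at the default study conditions, plus its truth."""
    out = tmp_path_factory.mktemp("dump")
    paths, truth = generate_fixture(FixtureConfig(seed=11), out)
    return paths, truth


@pytest.fixture(scope="session")
def built(dump, idx, tier0):
    """The dump run through read_dump + the full build pipeline."""
    from chemlite.builder import build
    from chemlite.records_io import read_dump

    paths, truth = dump
    records = read_dump(paths["compounds"], paths["counts"], paths["toc"], idx)
    entries, report, eliminated = build(records, tier0, idx)
    return entries, report, eliminated, truth


def make_record(
    cid,
    ikfb="AAAAAAAAAAAAAA",
    formula="C10H14N2",
    bits=(),
    parent=None,
    smiles="CCN",
    pubmed=0,
    patent=0,
    second_block=None,
    mass=None,
    name=None,
):
    """Hand-rolled compound record for targeted unit tests."""
    from chemlite.formula import monoisotopic_mass

    f = parse_formula(formula)
    block2 = second_block or f"{'UHFFFAOYS'}{chr(ord('A') + cid % 26)}"
    return CompoundRecord(
        cid=cid,
        parent_cid=parent,
        name=name or f"cmpd-{cid}",
        smiles=smiles,
        inchi=f"InChI=1S/{formula}/c{cid}",
        inchikey=f"{ikfb}-{block2}-N",
        formula=f,
        monoisotopic_mass=mass if mass is not None else monoisotopic_mass(f),
        pubmed_count=pubmed,
        patent_count=patent,
        fingerprint=TocFingerprint(frozenset(bits)),
    )
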