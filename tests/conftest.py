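import datetime as dt
from importlib.resources import files

import pytest

from faerspv.ingredients import SynonymTable
from faerspv.meddra import MeddraVocabulary
from faerspv.model import Corpus, DrugEntry, Report


@pytest.fixture(scope="session")
def fixture_quarter():
    base = files("faerspv") / "data" / "fixture_quarter"
    return {
        "demo_file": base / "DEMO.txt",
        "drug_file": base / "DRUG.txt",
        "reac_file": base / "REAC.txt",
        "indi_file": base / "INDI.txt",
        "outc_file": base / "OUTC.txt",
    }


@pytest.fixture(scope="session")
def packaged_synonyms():
    return SynonymTable.read_tsv(files("faerspv") / "data" / "synonyms.tsv")


@pytest.fixture(scope="session")
def packaged_vocabulary():
    return MeddraVocabulary.read(files("faerspv") / "data" / "vocabulary.txt")


def make_report(
    report_id="R1",
    case_id=None,
    drug="fluoxetine",
    role="PS",
    indication=None,
    ingredient_keys=(),
    reactions=("Headache",),
    event_date=dt.date(2004, 3, 1),
    receipt_date=dt.date(2004, 4, 1),
    occupation="physician",
    age=50.0,
    sex="F",
    outcomes=frozenset({"Other"}),
):
    entry = DrugEntry(verbatim_name=drug, role=role, indication=indication)
    if ingredient_keys:
        entry = entry.with_mapping(ingredient_keys, 1.0)
    return Report(
        report_id=report_id,
        case_id=case_id or report_id,
        drugs=[entry],
        reactions=list(reactions),
        event_date=event_date,
        receipt_date=receipt_date,
        reporter_occupation=occupation,
        patient_age=age,
        patient_sex=sex,
        outcomes=outcomes,
    )


@pytest.fixture
def tiny_corpus():
    return Corpus(
        reports=[
            make_report("R1", drug="fluoxetine", ingredient_keys={"ING-A"}, reactions=("Headache",)),
            make_report("R2", drug="prozac", ingredient_keys={"ING-A"}, reactions=("Nausea",)),
            make_report("R3", drug="ibuprofen", ingredient_keys={"ING-B"}, reactions=("Headache", "Nausea")),
        ]
    )
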