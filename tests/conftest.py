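import pandas as pd
import pytest
from hypothesis import settings

from atcmapper.matcher import MatchConfig, build_index
from atcmapper.ontology import ATCCode, DrugEntry, Ontology, validate_atc_code

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def _entry(label: str, *codes: str, synonyms: set[str] | None = None) -> DrugEntry:
    return DrugEntry(label, {validate_atc_code(c) for c in codes},
                     synonyms=synonyms or set())


@pytest.fixture(scope="session")
def worked_example_ontology() -> Ontology:
    """Small ontology seeded from the curated worked example (Dutch drug names)."""
    return Ontology(
        [
            _entry("omeprazole", "A02BC01"),
            _entry("acenocoumarol", "B01AA07"),
            _entry("acenocoumarolum", "B01AA07"),
            _entry("lercanidipine", "C08CA13"),
            _entry("losartan", "C09CA01"),
            _entry("acetylsalicylzuur", "N02BA01", "B01AC06"),
            _entry("acetylsalic cardio", "B01AC06"),
            _entry("acetylsalicylz cardio", "B01AC06"),
            _entry("perindopril", "C09AA04"),
            _entry("paracetamol", "N02BE01"),
            _entry("ibuprofen", "M01AE01"),
            _entry("metoprolol", "C07AB02"),
        ]
    )


@pytest.fixture(scope="session")
def worked_example_index(worked_example_ontology):
    return build_index(worked_example_ontology, MatchConfig())


@pytest.fixture()
def raw_answers() -> pd.DataFrame:
    return pd.DataFrame(
        [
            ("P001", "Q2", "acenocoumarol/omeprazol/losartan kalum/lercanidipine"),
            ("P002", "Q2", "Paracetamol 5 gram"),
            ("P003", "Q2", "Paracetamol 5 gram"),
            ("P004", "Q2", "9999"),
            ("P005", "Q2", ""),
            ("P006", "Q2", "losartan elke dag"),
        ],
        columns=["participant_id", "question_id", "answer"],
    )
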