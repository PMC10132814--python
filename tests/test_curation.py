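import pandas as pd
import pytest

from atcmapper.curation import (
    Choice,
    MatchDecision,
    PendingDecisionsError,
    REVIEW_COLUMNS,
    Status,
    assign_atc,
    decide,
    export_review,
    import_review,
    recombine,
)
from atcmapper.matcher import auto_match, suggest
from atcmapper.preprocess import TermRecord


def _term(name, synonym=None, key="k1"):
    return TermRecord(name, synonym or name, key)


class TestDecide:
    def test_accept_one(self, worked_example_index):
        t = _term("losartan")
        sugg = suggest(t, worked_example_index)
        d = decide(t, sugg, Choice(accept_labels=["losartan"]))
        assert d.status is Status.MATCHED and len(d.selected) == 1

    def test_accept_two(self, worked_example_index):
        t = _term("kalum", "acenocoumarol/omeprazol/losartan kalum/lercanidipine")
        sugg = suggest(t, worked_example_index)
        d = decide(t, sugg, Choice(accept_labels=["acenocoumarol", "lercanidipine"]))
        assert d.status is Status.MATCHED and len(d.selected) == 2

    def test_reject_with_flag(self, worked_example_index):
        t = _term("android")
        d = decide(t, suggest(t, worked_example_index), Choice(reject=True, flag=True))
        assert d.status is Status.NO_MATCH and d.review and not d.selected

    def test_accept_outside_suggestions_is_error(self, worked_example_index):
        t = _term("losartan")
        with pytest.raises(ValueError):
            decide(t, suggest(t, worked_example_index), Choice(accept_labels=["nope"]))


class TestReviewRoundtrip:
    def test_flagged_term_gets_empty_row(self):
        d = MatchDecision(_term("ace", "ace remmer"), Status.NO_MATCH, [], review=True)
        df = export_review([d])
        assert list(df.columns) == REVIEW_COLUMNS
        row = df.iloc[0]
        assert row["ontologyTermName"] == "" and row["review"] and row["validated"]

    def test_two_selections_two_rows(self, worked_example_index):
        t = _term("kalum", "acenocoumarol/omeprazol/losartan kalum/lercanidipine")
        d = decide(
            t,
            suggest(t, worked_example_index),
            Choice(accept_labels=["acenocoumarol", "lercanidipine"], flag=True),
        )
        df = export_review([d])
        assert len(df) == 2
        assert set(df["Name"]) == {"kalum"} and df["Synonym"].nunique() == 1

    def test_roundtrip_without_edits_is_identity(self, worked_example_index, worked_example_ontology):
        terms = [
            _term("losartan"),
            _term("omeprazol"),
            _term("kalum", "acenocoumarol/omeprazol/losartan kalum/lercanidipine"),
        ]
        decisions = auto_match(terms, worked_example_index)
        # resolve the pending one so the file is final
        decisions = [
            d
            if d.status is not Status.FLAGGED_PENDING
            else decide(d.term, d.suggestions, Choice(accept_labels=[d.suggestions[0].entry.label]))
            for d in decisions
        ]
        df = export_review(decisions)
        back, errors = import_review(df, worked_example_ontology, terms)
        assert not errors
        orig = {
            (d.term.name, d.term.synonym): sorted(e.label for e, _ in d.selected)
            for d in decisions
        }
        got = {
            (d.term.name, d.term.synonym): sorted(e.label for e, _ in d.selected)
            for d in back
        }
        assert got == orig

    def test_expert_override_code(self, worked_example_ontology):
        df = pd.DataFrame(
            [["spironolacton", "spironolactionomeprazol", "", 0.0, True, True,
              "C03DA01", "spironolacton"]],
            columns=REVIEW_COLUMNS,
        )
        decisions, errors = import_review(df, worked_example_ontology)
        assert not errors
        assert decisions[0].status is Status.MATCHED
        assert [c.code for c in decisions[0].override_codes] == ["C03DA01"]

    def test_expert_rejection_becomes_no_match(self, worked_example_ontology):
        df = pd.DataFrame(
            [["android", "android", "", 0.0, True, False, "", ""]],
            columns=REVIEW_COLUMNS,
        )
        decisions, _ = import_review(df, worked_example_ontology)
        assert decisions[0].status is Status.NO_MATCH

    def test_invalid_code_is_row_error(self, worked_example_ontology):
        df = pd.DataFrame(
            [["x", "x", "", 0.0, True, True, "9.0CA04", ""]],
            columns=REVIEW_COLUMNS,
        )
        decisions, errors = import_review(df, worked_example_ontology)
        assert len(errors) == 1 and "9.0CA04" in errors[0].reason


class TestAssignRecombine:
    def test_multi_code_selection_expands(self, worked_example_index, worked_example_ontology):
        t = _term("acetylsalicylzuur", key="kA")
        d = decide(
            t,
            suggest(t, worked_example_index),
            Choice(accept_labels=["acetylsalicylzuur"]),
        )
        coded = assign_atc([d], worked_example_ontology)
        assert sorted(coded["atc_code"]) == ["B01AC06", "N02BA01"]

    def test_duplicate_codes_collapse_per_answer(self, worked_example_ontology, worked_example_index):
        syn = "acenocoumarol, acenocoumarolum"
        t1 = _term("acenocoumarol", syn, key="kB")
        t2 = _term("acenocoumarolum", syn, key="kB")
        ds = [
            decide(t, suggest(t, worked_example_index), Choice(accept_labels=[t.name]))
            for t in (t1, t2)
        ]
        coded = assign_atc(ds, worked_example_ontology)
        assert list(coded["atc_code"]) == ["B01AA07"]

    def test_no_match_contributes_nothing(self, worked_example_ontology):
        d = MatchDecision(_term("android"), Status.NO_MATCH, [])
        assert assign_atc([d], worked_example_ontology).empty

    def test_pending_decisions_error(self, worked_example_ontology):
        d = MatchDecision(_term("x"), Status.FLAGGED_PENDING, [])
        with pytest.raises(PendingDecisionsError):
            assign_atc([d], worked_example_ontology)

    def test_recombine_join_arithmetic(self):
        id_map = pd.DataFrame(
            [("P1", "Q1", "k1"), ("P2", "Q1", "k1"), ("P3", "Q1", "k1")],
            columns=["participant_id", "question_id", "answer_key"],
        )
        coded = pd.DataFrame(
            [("a", "s", "k1", "N02BA01"), ("b", "s", "k1", "B01AC06")],
            columns=["Name", "Synonym", "answer_key", "atc_code"],
        )
        out = recombine(id_map, coded)
        assert len(out) == 6  # 3 participants x 2 codes

    def test_recombine_unknown_key_is_error(self):
        id_map = pd.DataFrame(
            [("P1", "Q1", "k1")], columns=["participant_id", "question_id", "answer_key"]
        )
        coded = pd.DataFrame(
            [("a", "s", "kX", "N02BA01")],
            columns=["Name", "Synonym", "answer_key", "atc_code"],
        )
        with pytest.raises(ValueError, match="kX"):
            recombine(id_map, coded)

    def test_recombine_empty(self):
        id_map = pd.DataFrame(
            [("P1", "Q1", "k1")], columns=["participant_id", "question_id", "answer_key"]
        )
        coded = pd.DataFrame(columns=["Name", "Synonym", "answer_key", "atc_code"])
        assert recombine(id_map, coded).empty
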