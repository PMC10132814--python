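import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from atcmapper.curation import Status
from atcmapper.matcher import (
    MatchConfig,
    auto_match,
    bigram_profile,
    build_index,
    ngram_score,
    normalize_for_matching,
    round_score,
    suggest,
)
from atcmapper.ontology import DrugEntry, Ontology, validate_atc_code
from atcmapper.preprocess import TermRecord


def _term(name: str, synonym: str = "") -> TermRecord:
    return TermRecord(name, synonym or name, "k0")


class TestNormalization:
    def test_trailing_e_stem_conflates_spellings(self):
        assert normalize_for_matching("Omeprazole") == ["omeprazol"]

    def test_stem_applies_to_long_tokens_only(self):
        assert normalize_for_matching("vitamine c") == ["vitamin", "c"]

    def test_diacritics_split_token_when_folding_off(self):
        cfg = MatchConfig(fold_diacritics=False)
        assert normalize_for_matching("Tretinoïne", cfg) == ["tretino", "ne"]

    def test_diacritics_folded_by_default(self):
        assert normalize_for_matching("Tretinoïne") == ["tretinoin"]

    def test_padded_bigram_count(self):
        # a token of n characters contributes n+1 padded bigrams
        assert sum(bigram_profile(["losartan"]).values()) == 9
        assert bigram_profile([""]) == {}


class TestScore:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("losartan", "losartan", 100.0),
            ("omeprazol", "omeprazole", 100.0),
            ("ab", "ac", 33.33),
            ("xyz", "qqq", 0.0),
            ("", "losartan", 0.0),
        ],
    )
    def test_worked_examples(self, a, b, expected):
        assert round_score(ngram_score(a, b)) == expected

    @given(st.text(max_size=25), st.text(max_size=25))
    def test_symmetry_and_range(self, a, b):
        s = ngram_score(a, b)
        assert s == ngram_score(b, a)
        assert 0.0 <= s <= 100.0

    @given(st.text(alphabet="abcdef ", min_size=1, max_size=20))
    def test_self_score_is_100(self, a):
        if normalize_for_matching(a):
            assert ngram_score(a, a) == 100.0


def _random_ontology(rng: random.Random, n: int) -> Ontology:
    alphabet = "abcdehlmnoprst"
    entries = []
    seen = set()
    while len(entries) < n:
        label = "".join(rng.choice(alphabet) for _ in range(rng.randint(4, 14)))
        if label in seen:
            continue
        seen.add(label)
        syns = (
            {"".join(rng.choice(alphabet) for _ in range(6))}
            if rng.random() < 0.3
            else set()
        )
        entries.append(
            DrugEntry(label, {validate_atc_code("A02BC01")}, synonyms=syns)
        )
    return Ontology(entries)


def _brute_force_topk(term, ontology, cfg):
    scored = []
    for e in ontology.entries:
        fields = [e.label] + sorted(e.synonyms)
        best = max(
            max(ngram_score(q, f, cfg) for f in fields)
            for q in {term.name, term.synonym}
        )
        if best > 0:
            scored.append((e.label, best))
    scored.sort(key=lambda t: (-t[1], t[0].lower()))
    return scored[: cfg.k]


class TestSuggest:
    def test_exact_label_ranks_first(self, worked_example_index):
        cands = suggest(_term("losartan"), worked_example_index)
        assert cands[0].entry.label == "losartan"
        assert cands[0].score == 100.0

    def test_returns_at_most_k(self, worked_example_index):
        cfg = MatchConfig(k=3)
        assert len(suggest(_term("acetylsalicylzuur"), worked_example_index, cfg)) <= 3

    def test_k_candidates_when_enough_share_bigrams(self):
        onto = Ontology(
            [
                DrugEntry(f"drugmaker{c}", {validate_atc_code("A02BC01")})
                for c in "abcdefghijkl"
            ]
        )
        cands = suggest(_term("drugmaker"), build_index(onto))
        assert len(cands) == 10

    def test_agrees_with_brute_force_oracle(self):
        """Exact rank and score agreement with all-pairs scoring."""
        rng = random.Random(7)
        onto = _random_ontology(rng, 80)
        index = build_index(onto)
        cfg = index.cfg
        for _ in range(100):
            name = "".join(rng.choice("abcdehlmnoprst") for _ in range(rng.randint(3, 12)))
            term = _term(name)
            got = [(c.entry.label, c.score) for c in suggest(term, index, cfg)]
            assert got == _brute_force_topk(term, onto, cfg)

    def test_synonym_context_can_surface_other_drugs(self, worked_example_index):
        term = _term("kalum", "acenocoumarol/omeprazol/losartan kalum/lercanidipine")
        labels = [c.entry.label for c in suggest(term, worked_example_index)]
        assert "acenocoumarol" in labels  # reached via the answer context

    def test_retrieval_is_superset_of_positive_scores(self, worked_example_ontology):
        index = build_index(worked_example_ontology)
        cfg = index.cfg
        prof = bigram_profile(normalize_for_matching("losartan", cfg))
        retrieved = {index._fields[i][0].label for i in index.retrieve(prof)}
        positive = {
            e.label
            for e in worked_example_ontology.entries
            if ngram_score("losartan", e.label, cfg) > 0
        }
        assert positive <= retrieved

    def test_empty_ontology_rejected(self):
        with pytest.raises(ValueError):
            build_index(Ontology())


class TestAutoMatch:
    def test_exact_term_auto_matches_at_100(self, worked_example_index):
        decisions = auto_match([_term("losartan")], worked_example_index)
        assert decisions[0].status is Status.AUTO_MATCHED
        assert decisions[0].selected[0][0].label == "losartan"

    def test_threshold_above_100_matches_nothing(self, worked_example_index):
        cfg = MatchConfig(threshold=101)
        terms = [_term("losartan"), _term("omeprazol"), _term("acenocoumarol")]
        decisions = auto_match(terms, worked_example_index, cfg)
        assert all(d.status is Status.FLAGGED_PENDING for d in decisions)

    def test_typo_matches_iff_score_reaches_threshold(self, worked_example_index):
        term = _term("losartsn")  # one substitution
        score = suggest(term, worked_example_index)[0].score
        for threshold in (score - 5, score + 5):
            cfg = MatchConfig(threshold=threshold)
            d = auto_match([term], worked_example_index, cfg)[0]
            expected = Status.AUTO_MATCHED if score >= threshold else Status.FLAGGED_PENDING
            assert d.status is expected

    def test_threshold_monotonicity(self, worked_example_index):
        terms = [_term(n) for n in ("losartan", "losartsn", "omeprazol", "xyzq")]
        accepted = {}
        for t in (0, 50, 83, 100):
            decs = auto_match(terms, worked_example_index, MatchConfig(threshold=t))
            accepted[t] = {
                d.term.name for d in decs if d.status is Status.AUTO_MATCHED
            }
        assert accepted[100] <= accepted[83] <= accepted[50] <= accepted[0]

    def test_determinism(self, worked_example_index):
        terms = [_term("acetylsalicyl"), _term("perindopril")]
        runs = [
            [
                (d.term.name, d.status, [(e.label, s) for e, s in d.selected])
                for d in auto_match(terms, worked_example_index)
            ]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]
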