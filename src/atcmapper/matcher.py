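"""Fuzzy matching of free-text terms against ontology labels and synonyms.

The similarity primitive is the Dice coefficient over padded character
bigrams.  Each normalized token is padded with start/end markers, so a token
of n characters contributes n+1 bigrams ("losartan" -> ^l lo os sa ar rt ta
an n$); the profiles of the two sides are compared as multisets:

    score = 200 * |A ∩ B| / (|A| + |B|)      (percent, 0..100)

A score of 100 means the normalized profiles are identical — this is what
the default auto-accept threshold of 100% relies on: only (normalization-)
exact matches are accepted without review.  Normalization keeps [a-z0-9],
folds diacritics by default, and applies a light stem (strip one trailing
'e' from tokens of >= 4 characters) so Dutch and international spellings of
the same substance ("omeprazol" / "omeprazole") conflate to an exact match.

Candidate retrieval uses an inverted index from bigram to posting list over
every label and synonym; any entry sharing at least one bigram with the
query is scored, so the returned top-k is exact, not approximate.
"""

from __future__ import annotations

import unicodedata
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from .curation import MatchDecision, Status
from .ontology import DrugEntry, Ontology
from .preprocess import TermRecord

__all__ = [
    "MatchConfig",
    "MatchCandidate",
    "MatchIndex",
    "normalize_for_matching",
    "bigram_profile",
    "ngram_score",
    "round_score",
    "build_index",
    "suggest",
    "auto_match",
]


@dataclass
class MatchConfig:
    threshold: float = 100.0  # auto-accept cut-off, percent; >100 accepts nothing
    k: int = 10               # suggestion-list length
    use_stemming: bool = True
    fold_diacritics: bool = True

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


@dataclass
class MatchCandidate:
    entry: DrugEntry
    score: float              # unrounded; round_score() for presentation
    matched_via: str          # e.g. "name->label" or "synonym->synonym:ascal"

    def __post_init__(self) -> None:
        assert 0.0 <= self.score <= 100.0


def _fold(s: str) -> str:
    return "".join(
        c for c in unicodedata.normalize("NFKD", s) if not unicodedata.combining(c)
    )


def normalize_for_matching(s: str, cfg: MatchConfig | None = None) -> list[str]:
    """Tokenize for scoring: lowercase, [a-z0-9] charset, optional stem/fold."""
    if cfg is None:
        cfg = MatchConfig()
    if cfg.fold_diacritics:
        s = _fold(s)
    s = s.lower()
    tokens: list[str] = []
    cur: list[str] = []
    for ch in s:
        if "a" <= ch <= "z" or "0" <= ch <= "9":
            cur.append(ch)
        elif cur:
            tokens.append("".join(cur))
            cur = []
    if cur:
        tokens.append("".join(cur))
    if cfg.use_stemming:
        tokens = [t[:-1] if len(t) >= 4 and t.endswith("e") else t for t in tokens]
    return tokens


def bigram_profile(tokens: list[str]) -> Counter[str]:
    """Multiset of padded character bigrams; a token of n chars yields n+1."""
    prof: Counter[str] = Counter()
    for t in tokens:
        if not t:
            continue
        padded = "^" + t + "$"
        prof.update(padded[i : i + 2] for i in range(len(padded) - 1))
    return prof


def _dice(a: Counter[str], b: Counter[str]) -> float:
    ta, tb = sum(a.values()), sum(b.values())
    if ta == 0 or tb == 0:
        return 0.0
    inter = sum(min(n, b[g]) for g, n in a.items())
    return 200.0 * inter / (ta + tb)


def ngram_score(a: str, b: str, cfg: MatchConfig | None = None) -> float:
    """Bigram Dice similarity of two strings after normalization, in [0, 100].

    Symmetric; exactly 100.0 iff the normalized profiles are equal and
    non-empty; 0.0 if either side normalizes to nothing.
    """
    if cfg is None:
        cfg = MatchConfig()
    return _dice(
        bigram_profile(normalize_for_matching(a, cfg)),
        bigram_profile(normalize_for_matching(b, cfg)),
    )


def round_score(score: float) -> float:
    """Half-up rounding to 2 decimals, for presentation only."""
    return float(Decimal(repr(score)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


class MatchIndex:
    """Inverted bigram index over every ontology label and synonym.

    Retrieval for a query returns every entry sharing >= 1 bigram with it, a
    superset of all entries with positive score, so top-k ranking over the
    retrieved set equals exhaustive all-pairs ranking.
    """

    def __init__(self, ontology: Ontology, cfg: MatchConfig | None = None) -> None:
        if len(ontology) == 0:
            raise ValueError("cannot index an empty ontology")
        self.cfg = cfg or MatchConfig()
        self.ontology = ontology
        self._fields: list[tuple[DrugEntry, str, Counter[str]]] = []
        self._postings: dict[str, set[int]] = {}
        for entry in ontology.entries:
            fields = [("label", entry.label)] + [
                (f"synonym:{s}", s) for s in sorted(entry.synonyms)
            ]
            for fname, text in fields:
                prof = bigram_profile(normalize_for_matching(text, self.cfg))
                idx = len(self._fields)
                self._fields.append((entry, fname, prof))
                for gram in prof:
                    self._postings.setdefault(gram, set()).add(idx)

    def retrieve(self, profile: Counter[str]) -> set[int]:
        hits: set[int] = set()
        for gram in profile:
            hits |= self._postings.get(gram, set())
        return hits


def build_index(ontology: Ontology, cfg: MatchConfig | None = None) -> MatchIndex:
    """Build the retrieval index; raises ``ValueError`` on an empty ontology."""
    return MatchIndex(ontology, cfg)


def suggest(
    term: TermRecord, index: MatchIndex, cfg: MatchConfig | None = None
) -> list[MatchCandidate]:
    """Ranked top-k candidates for one term.

    The candidate score is the max of the bigram Dice score over
    {query name, query synonym} x {entry label, entry synonyms}; scoring the
    unsplit answer too lets a single selected term surface every drug
    mentioned in the answer.  Descending by score, ties broken
    lexicographically by label; at most one candidate per entry.
    """
    cfg = cfg or index.cfg
    q_profiles = [
        ("name", bigram_profile(normalize_for_matching(term.name, cfg))),
    ]
    if term.synonym and term.synonym != term.name:
        q_profiles.append(
            ("synonym", bigram_profile(normalize_for_matching(term.synonym, cfg)))
        )
    best: dict[str, MatchCandidate] = {}
    for qname, qprof in q_profiles:
        for idx in index.retrieve(qprof):
            entry, fname, fprof = index._fields[idx]
            score = _dice(qprof, fprof)
            if score <= 0.0:
                continue
            cur = best.get(entry.label)
            if cur is None or score > cur.score:
                best[entry.label] = MatchCandidate(entry, score, f"{qname}->{fname}")
    ranked = sorted(best.values(), key=lambda c: (-c.score, c.entry.label.lower()))
    return ranked[: cfg.k]


def auto_match(
    terms: list[TermRecord], index: MatchIndex, cfg: MatchConfig | None = None
) -> list[MatchDecision]:
    """Threshold-gated automatic matching over a term list.

    A term whose best candidate scores at or above the threshold becomes an
    ``auto_matched`` decision with that single candidate; everything else is
    left ``flagged_pending`` with its suggestion list for the curator.  Since
    scores never exceed 100, a threshold above 100 auto-accepts nothing.
    """
    cfg = cfg or index.cfg
    decisions: list[MatchDecision] = []
    for term in terms:
        cands = suggest(term, index, cfg)
        if cands and cands[0].score >= cfg.threshold:
            top = cands[0]
            decisions.append(
                MatchDecision(
                    term=term,
                    status=Status.AUTO_MATCHED,
                    selected=[(top.entry, top.score)],
                    review=False,
                    suggestions=cands,
                )
            )
        else:
            decisions.append(
                MatchDecision(
                    term=term,
                    status=Status.FLAGGED_PENDING,
                    selected=[],
                    review=False,
                    suggestions=cands,
                )
            )
    return decisions
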