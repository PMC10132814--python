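"""Turn raw questionnaire answers into anonymized, deduplicated term records.

Free-text medication answers arrive as (participant, question, answer) rows.
Before any fuzzy matching the pipeline

1. strips participant identifiers and deduplicates the answer texts
   (anonymization — matching happens outside the data-owner's server),
2. normalizes the text and removes dosage information, stop words, filler
   phrases and company names,
3. splits multi-drug answers into candidate terms, keeping the filtered but
   unsplit answer attached to every term as its ``Synonym`` so that both the
   matcher and the human curator retain the full context.

Deduplication happens at the level of the *filtered* answer: lower-casing
and filler removal exist mainly to make repeated answers (including repeated
misspellings) collapse so the expert checks each one once.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from . import _wordlists as _wl

__all__ = [
    "PreprocessConfig",
    "TermRecord",
    "anonymize_split",
    "normalize_text",
    "strip_dosage",
    "remove_fillers",
    "split_terms",
    "preprocess_corpus",
]

RAW_COLUMNS = ["participant_id", "question_id", "answer"]

# placeholder joining protected multi-word phrases through the splitters
_GLUE = "\x00"


@dataclass
class PreprocessConfig:
    stop_words: frozenset[str] = _wl.DUTCH_STOP_WORDS
    fillers: Sequence[str] = _wl.FILLER_TERMS
    company_names: Sequence[str] = _wl.COMPANY_NAMES
    exception_phrases: Sequence[str] = _wl.EXCEPTION_PHRASES
    application_forms: Sequence[str] = _wl.APPLICATION_FORMS
    empty_answer_codes: Sequence[str] = _wl.EMPTY_ANSWER_CODES
    separators: str = "/,+"
    min_letters: int = 3

    def __post_init__(self) -> None:
        self.stop_words = frozenset(w.lower() for w in self.stop_words)
        self.fillers = tuple(f.lower() for f in self.fillers)
        self.company_names = tuple(c.lower() for c in self.company_names)
        self.exception_phrases = tuple(e.lower() for e in self.exception_phrases)
        self.application_forms = tuple(a.lower() for a in self.application_forms)
        if not self.separators:
            raise ValueError("separator set must be non-empty")


@dataclass(frozen=True)
class TermRecord:
    """One candidate term plus its filtered (unsplit) full answer."""

    name: str
    synonym: str
    answer_key: str


def answer_key(text: str) -> str:
    """Stable anonymous key for an answer text."""
    return "a" + hashlib.md5(text.encode("utf-8")).hexdigest()[:10]


def _is_empty_answer(s: str, cfg: PreprocessConfig) -> bool:
    stripped = s.strip()
    return not stripped or stripped in cfg.empty_answer_codes


def anonymize_split(
    raw: pd.DataFrame, cfg: PreprocessConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a raw answer table into an id map and deduplicated answers.

    Returns ``(id_map, answers)`` where ``id_map`` has columns
    (participant_id, question_id, answer_key) and ``answers`` has
    (answer_key, answer) with no participant identifiers and no duplicate
    answer texts.  Rows whose answer is empty or a sentinel "no answer" code
    (8888/9999) are dropped from both tables; joining the two tables on
    ``answer_key`` reconstructs the surviving input rows exactly.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    df = raw.copy()
    df["answer"] = df["answer"].fillna("").astype(str)
    keep = ~df["answer"].map(lambda s: _is_empty_answer(s, cfg)).astype(bool)
    df = df.loc[keep]
    df["answer_key"] = df["answer"].map(answer_key)
    id_map = df[["participant_id", "question_id", "answer_key"]].reset_index(drop=True)
    answers = (
        df[["answer_key", "answer"]].drop_duplicates("answer_key").reset_index(drop=True)
    )
    return id_map, answers


_SPECIAL_CHARS_RE = re.compile(r"[\t\"'`;()\[\]{}<>—–]")


def normalize_text(s: str) -> str:
    """Lower-case, fix missing spaces after commas, drop special characters.

    Removed characters: tabs, quotes, brackets, semicolons and dashes of the
    em/en kind; the in-word hyphen is kept because drug names contain it.
    Whitespace is collapsed and trimmed.
    """
    s = s.lower()
    s = re.sub(r",(?=\S)", ", ", s)
    s = _SPECIAL_CHARS_RE.sub(" ", s)
    return re.sub(r"\s+", " ", s).strip()


_UNIT = r"(?:microgram|milligram|mcg|mg|gram|g|ml|cl|dl|l|ie|eh|%)"
_DOSAGE_RES = [
    # unit ratio first so "1 g/ml" does not leave a dangling "/ml"
    re.compile(rf"\b\d+(?:[.,]\d+)?\s*{_UNIT}\s*/\s*{_UNIT}\b"),
    re.compile(rf"\b\d+(?:[.,]\d+)?(?:\s*-\s*\d+(?:[.,]\d+)?)?\s*{_UNIT}\b"),
    re.compile(r"\b\d+(?:[.,]\d+)?\b"),  # bare numbers carry no ATC signal
]


def strip_dosage(s: str) -> str:
    """Remove weight/volume/concentration substrings ("5 gram", "100 ml", "1 g/ml").

    Operates on normalized text; a string with no dosage pattern is returned
    unchanged apart from whitespace collapsing.
    """
    for pat in _DOSAGE_RES:
        s = pat.sub(" ", s)
    return re.sub(r"\s+", " ", s).strip()


def _protect(s: str, phrases: Sequence[str]) -> str:
    for phrase in sorted(phrases, key=len, reverse=True):
        glued = phrase.replace(" ", _GLUE)
        s = re.sub(r"(?<![\w])" + re.escape(phrase) + r"(?![\w])", glued, s)
    return s


def remove_fillers(s: str, cfg: PreprocessConfig | None = None) -> str:
    """Remove stop words, filler phrases and company names (whole words only).

    Words inside exception phrases ("vitamine c") are never touched.
    Multi-word fillers ("elke dag") are removed as phrases, longest first.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    s = _protect(s, cfg.exception_phrases)
    removable = list(cfg.fillers) + list(cfg.company_names)
    for phrase in sorted(removable, key=len, reverse=True):
        s = re.sub(r"(?<![\w])" + re.escape(phrase) + r"(?![\w])", " ", s)
    words = [
        w
        for w in s.split()
        if w.strip(",/+") == "" or w.strip(",/+") not in cfg.stop_words
    ]
    s = " ".join(words).replace(_GLUE, " ")
    return re.sub(r"\s+", " ", re.sub(r"\s*,\s*", ", ", s)).strip(" ,/+")


def _letters(s: str) -> int:
    return sum(ch.isalpha() for ch in s)


def split_terms(s: str, cfg: PreprocessConfig | None = None) -> list[str]:
    """Split a filtered answer into candidate drug-name terms.

    Splits on '/', ',', '+' and whitespace; exception phrases stay intact and
    an application-form word ("dispertablet", "neusspray", ...) stays attached
    to the drug name before it, because the form can decide the ATC code.
    Fragments with fewer than three letters are discarded, sentinel codes
    yield no terms, order is preserved, and duplicates within one answer are
    removed.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    if _is_empty_answer(s, cfg):
        return []
    s = _protect(s, cfg.exception_phrases)
    terms: list[str] = []
    for chunk in re.split(r"[" + re.escape(cfg.separators) + r"]+", s):
        tokens = chunk.split()
        merged: list[str] = []
        for tok in tokens:
            if merged and tok.replace(_GLUE, " ") in cfg.application_forms:
                merged[-1] = merged[-1] + " " + tok
            else:
                merged.append(tok)
        terms.extend(t.replace(_GLUE, " ") for t in merged)
    seen: set[str] = set()
    out: list[str] = []
    for t in terms:
        t = t.strip(" -")
        if _letters(t) < cfg.min_letters or t in seen:
            continue
        seen.add(t)
        out.append(t)
    return out


def filter_answer(s: str, cfg: PreprocessConfig | None = None) -> str:
    """The 'Synonym' view of an answer: normalized, dosage-free, filler-free, unsplit."""
    return remove_fillers(strip_dosage(normalize_text(s)), cfg)


def preprocess_corpus(
    raw: pd.DataFrame, cfg: PreprocessConfig | None = None
) -> tuple[pd.DataFrame, list[TermRecord]]:
    """Full pre-processing: anonymize, filter, split, deduplicate.

    Returns ``(id_map, terms)``.  ``id_map`` keys every surviving
    (participant, question) row by the anonymous key of its *filtered* answer,
    so answers differing only in case, dosage or filler words share one key
    and are curated once.  ``terms`` holds globally deduplicated
    :class:`TermRecord` rows; all terms from one filtered answer share its
    text as their synonym.
    """
    if cfg is None:
        cfg = PreprocessConfig()
    id_map_raw, answers = anonymize_split(raw, cfg)
    filtered = answers["answer"].map(lambda a: filter_answer(a, cfg))
    fkeys = filtered.map(answer_key)
    rekey = dict(zip(answers["answer_key"], fkeys))
    id_map = id_map_raw.assign(answer_key=id_map_raw["answer_key"].map(rekey))
    terms: list[TermRecord] = []
    seen: set[tuple[str, str]] = set()
    for synonym, fkey in zip(filtered, fkeys):
        for name in split_terms(synonym, cfg):
            if (name, synonym) not in seen:
                seen.add((name, synonym))
                terms.append(TermRecord(name, synonym, fkey))
    return id_map, terms


def terms_to_frame(terms: Iterable[TermRecord]) -> pd.DataFrame:
    """Render term records with the matcher's keyword column names."""
    return pd.DataFrame(
        [{"Name": t.name, "Synonym": t.synonym, "answer_key": t.answer_key} for t in terms],
        columns=["Name", "Synonym", "answer_key"],
    )


def frame_to_terms(df: pd.DataFrame) -> list[TermRecord]:
    df = df.fillna("")
    return [
        TermRecord(str(r.Name), str(r.Synonym), str(r.answer_key))
        for r in df.itertuples(index=False)
    ]
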