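"""Curation workflow: decisions, review-file round-trip, ATC assignment, recombination.

After automatic matching, every term carries a decision:

* ``auto_matched``    — best suggestion scored at/above the threshold;
* ``matched``         — the expert accepted one or more suggestions
                        (multi-select supports answers listing several drugs);
* ``no_match``        — the expert rejected all suggestions;
* ``flagged_pending`` — still waiting for the expert.

A "Needs Review" flag can combine with ``matched`` or ``no_match`` for terms
whose correct mapping is absent from the suggestions; those are resolved in
the exported review file (a spreadsheet-style TSV grouped by the answer
text), where the expert may also enter a literal ATC code as an override —
the escape hatch for e.g. fused drug names the splitter cannot separate.

Once decisions are final, each selected ontology term expands to all of its
ATC codes (an n:m mapping), duplicates collapse per answer, and a join with
the id map turns anonymous answer keys back into participant-level coded
records.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import pandas as pd

from .ontology import ATCCode, DrugEntry, InvalidATCCodeError, Ontology, validate_atc_code
from .preprocess import TermRecord

if TYPE_CHECKING:  # matcher imports this module at runtime
    from .matcher import MatchCandidate

__all__ = [
    "Status",
    "MatchDecision",
    "Choice",
    "decide",
    "export_review",
    "import_review",
    "assign_atc",
    "recombine",
    "REVIEW_COLUMNS",
    "PendingDecisionsError",
]

REVIEW_COLUMNS = [
    "Name",
    "Synonym",
    "ontologyTermName",
    "score",
    "validated",
    "review",
    "Atccode",
    "Atccode text",
]


class Status(str, enum.Enum):
    AUTO_MATCHED = "auto_matched"
    MATCHED = "matched"
    NO_MATCH = "no_match"
    FLAGGED_PENDING = "flagged_pending"


@dataclass
class MatchDecision:
    term: TermRecord
    status: Status
    # (selected entry, score of that selection); scores are presentation-level
    selected: list[tuple[DrugEntry, float]] = field(default_factory=list)
    review: bool = False
    suggestions: list["MatchCandidate"] = field(default_factory=list)
    # expert-entered literal codes for selections outside the ontology
    override_codes: list[ATCCode] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.status is Status.AUTO_MATCHED:
            assert len(self.selected) == 1 and not self.review
        elif self.status is Status.MATCHED:
            assert len(self.selected) >= 1 or self.override_codes
        elif self.status is Status.NO_MATCH:
            assert not self.selected


@dataclass
class Choice:
    """Curator action on one term: accept a set of suggestions, reject, or flag."""

    accept_labels: Sequence[str] = ()
    reject: bool = False
    flag: bool = False


def decide(
    term: TermRecord, suggestions: Sequence["MatchCandidate"], choice: Choice
) -> MatchDecision:
    """Apply one curator choice to a term's suggestion list.

    Accepting labels not present in the suggestions raises ``ValueError`` —
    free-form curation happens in the review file, not here.
    """
    by_label = {c.entry.label: c for c in suggestions}
    if choice.reject and choice.accept_labels:
        raise ValueError("cannot both reject and accept")
    if choice.reject or not choice.accept_labels:
        return MatchDecision(term, Status.NO_MATCH, [], review=choice.flag,
                             suggestions=list(suggestions))
    selected = []
    for label in choice.accept_labels:
        cand = by_label.get(label)
        if cand is None:
            raise ValueError(f"{label!r} is not among the suggestions for {term.name!r}")
        selected.append((cand.entry, cand.score))
    return MatchDecision(term, Status.MATCHED, selected, review=choice.flag,
                         suggestions=list(suggestions))


def export_review(decisions: Iterable[MatchDecision]) -> pd.DataFrame:
    """Render decisions as the curator-facing review table.

    One row per (decision, selection); a decision without selections yields a
    single row with an empty ontologyTermName.  Rows are grouped by Synonym
    so all parts of one answer are visible together; every group containing a
    review-flagged member is emitted intact (in fact all groups are emitted,
    which makes the no-edit round-trip the identity).
    """
    from .matcher import round_score  # local import; matcher imports this module

    rows = []
    for d in decisions:
        validated = d.status is not Status.AUTO_MATCHED
        base = {
            "Name": d.term.name,
            "Synonym": d.term.synonym,
            "validated": validated,
            "review": d.review or d.status is Status.FLAGGED_PENDING,
        }
        if d.selected:
            for entry, score in d.selected:
                codes = sorted(c.code for c in entry.atc_codes)
                rows.append(
                    base
                    | {
                        "ontologyTermName": entry.label,
                        "score": round_score(score),
                        "Atccode": ", ".join(codes),
                        "Atccode text": entry.label,
                    }
                )
        else:
            override = ", ".join(c.code for c in d.override_codes)
            rows.append(
                base | {"ontologyTermName": "", "score": 0.0, "Atccode": override,
                        "Atccode text": ""}
            )
    df = pd.DataFrame(rows, columns=REVIEW_COLUMNS)
    return df.sort_values(["Synonym", "Name", "ontologyTermName"], kind="stable").reset_index(
        drop=True
    )


@dataclass
class ReviewRowError:
    line: int
    name: str
    reason: str


def _parse_bool(v: object) -> bool:
    return str(v).strip().lower() in {"true", "1", "yes", "waar"}


def import_review(
    table: pd.DataFrame, ontology: Ontology, terms: Sequence[TermRecord] | None = None
) -> tuple[list[MatchDecision], list[ReviewRowError]]:
    """Read an (edited) review table back into decisions.

    Per (Name, Synonym) group: rows whose ontologyTermName resolves in the
    ontology become selections; rows with an empty term name but a literal
    Atccode become expert overrides; a group with neither becomes
    ``no_match`` (the expert rejected it).  Rows with an unknown term name
    and an invalid code are reported as row errors, not silently dropped.
    """
    missing = set(REVIEW_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"review table missing columns {sorted(missing)}")
    term_keys = {}
    if terms:
        term_keys = {(t.name, t.synonym): t for t in terms}
    decisions: list[MatchDecision] = []
    errors: list[ReviewRowError] = []
    df = table.fillna({"ontologyTermName": "", "Atccode": ""})
    for (name, synonym), group in df.groupby(["Name", "Synonym"], sort=False):
        term = term_keys.get((name, synonym)) or TermRecord(
            str(name), str(synonym), answer_key=""
        )
        selected: list[tuple[DrugEntry, float]] = []
        overrides: list[ATCCode] = []
        review = False
        for idx, row in group.iterrows():
            review = review or _parse_bool(row["review"])
            termname = str(row["ontologyTermName"]).strip()
            raw_codes = str(row["Atccode"]).strip()
            if raw_codes.lower() in {"nan", "y", ""}:
                raw_codes = ""
            if termname:
                entry = ontology.get(termname)
                if entry is not None:
                    try:
                        score = float(row["score"])
                    except (TypeError, ValueError):
                        score = 0.0
                    selected.append((entry, score))
                    continue
                # unknown term name: fall through to the literal code, if any
            if raw_codes:
                try:
                    overrides.extend(
                        validate_atc_code(c) for c in raw_codes.split(",") if c.strip()
                    )
                    continue
                except InvalidATCCodeError as exc:
                    errors.append(ReviewRowError(int(idx), str(name), str(exc)))
                    continue
            if termname:
                errors.append(
                    ReviewRowError(int(idx), str(name), f"unknown ontology term {termname!r}")
                )
        if selected or overrides:
            decisions.append(
                MatchDecision(term, Status.MATCHED, selected, review=review,
                              override_codes=overrides)
            )
        else:
            decisions.append(MatchDecision(term, Status.NO_MATCH, [], review=review))
    return decisions, errors


class PendingDecisionsError(RuntimeError):
    def __init__(self, pending: list[MatchDecision]):
        names = ", ".join(d.term.name for d in pending[:10])
        super().__init__(f"{len(pending)} decisions still pending: {names}")
        self.pending = pending


def assign_atc(
    decisions: Iterable[MatchDecision], ontology: Ontology
) -> pd.DataFrame:
    """Expand finalized decisions into (Name, Synonym, answer_key, atc_code) rows.

    Each selection contributes all of its ATC codes; expert override codes
    pass through directly; duplicates collapse at (answer_key, atc_code)
    level, so the same drug reached via two terms of one answer codes once.
    Raises :class:`PendingDecisionsError` if any decision is unresolved.
    """
    decisions = list(decisions)
    pending = [d for d in decisions if d.status is Status.FLAGGED_PENDING]
    if pending:
        raise PendingDecisionsError(pending)
    rows = []
    for d in decisions:
        codes: set[ATCCode] = set(d.override_codes)
        for entry, _score in d.selected:
            live = ontology.get(entry.label)
            codes |= (live.atc_codes if live is not None else entry.atc_codes)
        for code in sorted(codes):
            rows.append(
                {
                    "Name": d.term.name,
                    "Synonym": d.term.synonym,
                    "answer_key": d.term.answer_key,
                    "atc_code": code.code,
                }
            )
    df = pd.DataFrame(rows, columns=["Name", "Synonym", "answer_key", "atc_code"])
    return df.drop_duplicates(["answer_key", "atc_code"]).reset_index(drop=True)


def recombine(id_map: pd.DataFrame, coded_answers: pd.DataFrame) -> pd.DataFrame:
    """Join coded answers back onto participant rows.

    Returns unique (participant_id, question_id, atc_code) triples.  Every
    answer key in ``coded_answers`` must exist in the id map — a missing key
    means the pipeline lost track of an answer and is an integrity error.
    """
    known = set(id_map["answer_key"])
    orphans = sorted(set(coded_answers["answer_key"]) - known)
    if orphans:
        raise ValueError(f"answer keys absent from id map: {orphans[:5]}")
    merged = id_map.merge(coded_answers[["answer_key", "atc_code"]], on="answer_key")
    return (
        merged[["participant_id", "question_id", "atc_code"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )
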