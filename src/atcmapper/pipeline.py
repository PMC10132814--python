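"""End-to-end orchestration with an explicit human-review gate.

The pipeline runs preprocess -> match -> (review gate) -> assign -> recombine.
Matching is semi-automatic: terms the matcher cannot settle at the configured
threshold are exported to a review file and the run halts; after the expert
edits that file the run is resumed with it, and the curated decisions are
merged with the automatic ones before ATC assignment and participant
recombination.  Every stage reports row counts so no answer is lost silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import curation, matcher, preprocess
from .ontology import Ontology, read_ontology

__all__ = ["RunConfig", "RunReport", "run_pipeline"]

log = logging.getLogger("atcmapper")


@dataclass
class RunConfig:
    answers_path: str | Path
    ontology_path: str | Path
    out_dir: str | Path
    review_path: str | Path | None = None  # supply to resume after curation
    match: matcher.MatchConfig = field(default_factory=matcher.MatchConfig)
    prep: preprocess.PreprocessConfig = field(default_factory=preprocess.PreprocessConfig)


@dataclass
class RunReport:
    n_answers: int = 0
    n_deduplicated: int = 0
    n_terms: int = 0
    n_auto_matched: int = 0
    n_matched: int = 0
    n_no_match: int = 0
    n_flagged: int = 0
    n_coded_records: int = 0
    halted_for_review: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(k, v) for k, v in vars(self).items()], columns=["stage", "count"]
        )

    def __str__(self) -> str:
        lines = [f"{k:>22}: {v}" for k, v in vars(self).items()]
        return "\n".join(lines)


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full flow; halts at the review gate when terms are pending.

    Writes ``idmap.tsv``, ``terms.tsv``, ``review.tsv`` (first phase) and
    ``coded.tsv`` plus ``report.tsv`` (final phase) under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport()

    raw = pd.read_csv(cfg.answers_path, sep="\t", dtype=str, keep_default_na=False)
    ontology = read_ontology(cfg.ontology_path)
    report.n_answers = len(raw)

    id_map, terms = preprocess.preprocess_corpus(raw, cfg.prep)
    report.n_deduplicated = id_map["answer_key"].nunique()
    report.n_terms = len(terms)
    id_map.to_csv(out / "idmap.tsv", sep="\t", index=False)
    preprocess.terms_to_frame(terms).to_csv(out / "terms.tsv", sep="\t", index=False)
    log.info("preprocess: %d answers -> %d deduplicated -> %d terms",
             report.n_answers, report.n_deduplicated, report.n_terms)

    index = matcher.build_index(ontology, cfg.match)
    decisions = matcher.auto_match(terms, index, cfg.match)
    pending = [d for d in decisions if d.status is curation.Status.FLAGGED_PENDING]
    report.n_auto_matched = len(decisions) - len(pending)
    log.info("match: %d/%d auto-matched at threshold %s",
             report.n_auto_matched, len(decisions), cfg.match.threshold)

    if pending and cfg.review_path is None:
        curation.export_review(pending).to_csv(out / "review.tsv", sep="\t", index=False)
        report.n_flagged = len(pending)
        report.halted_for_review = True
        log.info("halted: %d terms exported for review", len(pending))
        report.to_frame().to_csv(out / "report.tsv", sep="\t", index=False)
        return report

    if cfg.review_path is not None:
        table = pd.read_csv(cfg.review_path, sep="\t", dtype=str, keep_default_na=False)
        curated, errors = curation.import_review(table, ontology, terms)
        if errors:
            raise RuntimeError(
                f"review import: {len(errors)} row errors, first: {errors[0]}"
            )
        by_key = {(d.term.name, d.term.synonym): d for d in curated}
        decisions = [
            by_key.get((d.term.name, d.term.synonym), d)
            if d.status is curation.Status.FLAGGED_PENDING
            else d
            for d in decisions
        ]

    for d in decisions:
        if d.status is curation.Status.MATCHED:
            report.n_matched += 1
        elif d.status is curation.Status.NO_MATCH:
            report.n_no_match += 1
    report.n_flagged = sum(
        1 for d in decisions if d.status is curation.Status.FLAGGED_PENDING
    )

    coded = curation.assign_atc(decisions, ontology)
    records = curation.recombine(id_map, coded)
    report.n_coded_records = len(records)
    records.to_csv(out / "coded.tsv", sep="\t", index=False)
    report.to_frame().to_csv(out / "report.tsv", sep="\t", index=False)
    log.info("done: %d coded participant records", len(records))
    return report
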