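"""Dual-regime evaluation of the matcher against an expert gold standard.

The expert's curated output serves as the gold standard: a map from each
term to the set of ontology entries the expert considered correct (an empty
set means the term should be rejected).  Because the matcher returns a
single best candidate per term while the expert may have selected several,
two bounding conventions are scored:

* **optimistic** (upper bound) — a term with a multi-entry gold set counts
  as one deduplicated slot; the prediction is a true positive if it hits
  *any* gold entry.
* **pessimistic** (lower bound) — every gold entry is its own slot; the
  single prediction can satisfy at most one, and unmet slots are penalized
  as false positives (mismatches).  A term with no surviving prediction
  misses all of its slots (false negatives).

True negatives are correct rejections only: empty gold and no prediction
above threshold.  For every dataset the optimistic F-score bounds the
pessimistic one from above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .matcher import MatchConfig, MatchIndex, suggest
from .preprocess import TermRecord

__all__ = [
    "GoldStandard",
    "EvalPoint",
    "Regime",
    "confusion_counts",
    "metrics",
    "threshold_sweep",
]

# gold: (name, synonym) -> set of correct entry labels; empty set = reject
GoldStandard = Mapping[tuple[str, str], frozenset[str] | set[str]]

OPTIMISTIC = "optimistic"
PESSIMISTIC = "pessimistic"
Regime = str


@dataclass(frozen=True)
class EvalPoint:
    threshold: float
    regime: Regime
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f_score: float
    f_undefined: bool = False


def confusion_counts(
    predictions: Mapping[tuple[str, str], str | None],
    gold: GoldStandard,
    regime: Regime,
) -> tuple[int, int, int, int]:
    """Confusion counts (TP, FP, FN, TN) for top-1 predictions at one threshold.

    ``predictions`` maps each term to its surviving best candidate label, or
    ``None`` when nothing scored above the threshold.  Every predicted term
    must be present in the gold standard.
    """
    if regime not in (OPTIMISTIC, PESSIMISTIC):
        raise ValueError(f"unknown regime {regime!r}")
    tp = fp = fn = tn = 0
    for key, pred in predictions.items():
        if key not in gold:
            raise KeyError(f"term {key!r} missing from gold standard")
        gold_set = set(gold[key])
        if not gold_set:
            if pred is None:
                tn += 1
            else:
                fp += 1
            continue
        if regime == OPTIMISTIC:
            if pred is None:
                fn += 1
            elif pred in gold_set:
                tp += 1
            else:
                fp += 1
        else:  # pessimistic: one slot per gold entry
            n_slots = len(gold_set)
            if pred is None:
                fn += n_slots
            elif pred in gold_set:
                tp += 1
                fp += n_slots - 1
            else:
                fp += n_slots
    return tp, fp, fn, tn


def metrics(
    counts: tuple[int, int, int, int],
    threshold: float = 0.0,
    regime: Regime = OPTIMISTIC,
) -> EvalPoint:
    """Accuracy, precision, recall and F-score from confusion counts.

    Accuracy = (TP+TN)/(TP+TN+FP+FN); Precision = TP/(TP+FP);
    Recall = TP/(TP+FN); F = 2PR/(P+R).  F is reported as 0 with the
    ``f_undefined`` flag when precision + recall is 0.  All-zero counts are
    an error, as is any negative count.
    """
    tp, fp, fn, tn = counts
    if min(counts) < 0:
        raise ValueError("confusion counts must be non-negative")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("all-zero confusion counts")
    accuracy = (tp + tn) / total
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    if precision + recall == 0.0:
        return EvalPoint(threshold, regime, tp, fp, fn, tn, accuracy, 0.0, 0.0, 0.0,
                         f_undefined=True)
    f = 2 * precision * recall / (precision + recall)
    return EvalPoint(threshold, regime, tp, fp, fn, tn, accuracy, precision, recall, f)


def threshold_sweep(
    terms: Sequence[TermRecord],
    gold: GoldStandard,
    index: MatchIndex,
    cfg: MatchConfig | None = None,
    thresholds: Sequence[float] = tuple(range(0, 101)),
) -> list[EvalPoint]:
    """One EvalPoint per (threshold, regime) over an inclusive threshold grid.

    Suggestions are computed once per term; at each threshold a term's
    prediction is its top candidate if that candidate's score reaches the
    threshold, else no prediction.  The set of accepted terms shrinks
    monotonically as the threshold rises.
    """
    cfg = cfg or index.cfg
    best: dict[tuple[str, str], tuple[str, float] | None] = {}
    for term in terms:
        cands = suggest(term, index, cfg)
        best[(term.name, term.synonym)] = (
            (cands[0].entry.label, cands[0].score) if cands else None
        )
    points: list[EvalPoint] = []
    for t in thresholds:
        preds = {
            key: (top[0] if top is not None and top[1] >= t else None)
            for key, top in best.items()
        }
        for regime in (OPTIMISTIC, PESSIMISTIC):
            points.append(metrics(confusion_counts(preds, gold, regime), t, regime))
    return points
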