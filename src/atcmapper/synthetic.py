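"""Synthetic lexicons and noisy questionnaire corpora with known ground truth.

Real medication answers are access-controlled, so every other module is
exercised on generated data that emulates the noise actually observed in
questionnaire free text: misspellings (one character edit per corrupted
name), brand names, appended dosages ("80 mg", "100 ml"), filler phrases
("elke dag", "forte"), several drugs joined by varying separators, repeated
answers across participants, and sentinel "no answer" codes (8888/9999).

Drug names are pronounceable CVC-syllable pseudo-labels rather than real
Dutch drug names, which keeps the package free of licensed database content;
a configurable fraction of entries carries a second ATC code and a
brand-name synonym to reproduce the n:m structure of real lexicons.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import pandas as pd

from .preprocess import PreprocessConfig, TermRecord, preprocess_corpus

__all__ = [
    "CorpusSpec",
    "generate_lexicon",
    "corrupt_name",
    "generate_corpus",
    "CORRUPTION_OPS",
]

_CONSONANTS = "bcdfghklmnprstvz"
_VOWELS = "aeiou"

CORRUPTION_OPS = ("swap_adjacent", "drop_char", "double_char", "insert_char", "drop_space")


@dataclass
class CorpusSpec:
    """Study conditions for one synthetic corpus; the seed fixes every draw."""

    n_participants: int = 500
    n_lexicon: int = 100
    duplication_rate: float = 0.3
    corruption_rate: float = 0.2
    corruption_ops: tuple[str, ...] = ("swap_adjacent", "drop_char", "double_char",
                                       "insert_char")
    multi_drug_rate: float = 0.25
    dosage_rate: float = 0.3
    filler_rate: float = 0.15
    empty_code_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duplication_rate", "corruption_rate", "multi_drug_rate",
                     "dosage_rate", "filler_rate", "empty_code_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        unknown = set(self.corruption_ops) - set(CORRUPTION_OPS)
        if unknown:
            raise ValueError(f"unknown corruption ops: {sorted(unknown)}")


def _syllable(rng: random.Random) -> str:
    return rng.choice(_CONSONANTS) + rng.choice(_VOWELS) + rng.choice(_CONSONANTS)


def _pseudo_label(rng: random.Random, n_syllables: int) -> str:
    return "".join(_syllable(rng) for _ in range(n_syllables))


def _random_atc5(rng: random.Random) -> str:
    return (
        rng.choice("ABCDGHJLMNPRSV")
        + f"{rng.randrange(100):02d}"
        + rng.choice("ABCDEFGH")
        + rng.choice("ABCDEFGH")
        + f"{rng.randrange(100):02d}"
    )


def generate_lexicon(
    n: int,
    seed: int = 0,
    second_code_fraction: float = 0.15,
    brand_fraction: float = 0.2,
) -> list[tuple[str, str]]:
    """Generate ``n`` unique (label, atc_code) rows with valid level-5 codes.

    A ``second_code_fraction`` of labels gets an extra row with a second code
    (the n:m case) and a ``brand_fraction`` gets a brand-name alias row
    sharing the same code (a synonym spelling).  Deterministic in the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    labels: list[str] = []
    seen: set[str] = set()
    while len(labels) < n:
        label = _pseudo_label(rng, rng.randint(3, 5))
        if label not in seen:
            seen.add(label)
            labels.append(label)
    rows: list[tuple[str, str]] = []
    for label in labels:
        code = _random_atc5(rng)
        rows.append((label, code))
        if rng.random() < second_code_fraction:
            rows.append((label, _random_atc5(rng)))
        if rng.random() < brand_fraction:
            brand = _pseudo_label(rng, 2) + "an"
            if brand not in seen:
                seen.add(brand)
                rows.append((brand, code))
    return rows


def corrupt_name(
    label: str, ops: tuple[str, ...], seed: int | random.Random = 0
) -> tuple[str, int]:
    """Apply exactly one sampled single-character edit; never returns the original.

    Raises ``ValueError`` for labels shorter than 4 characters.  ``drop_space``
    is only applicable to labels containing a space.
    """
    if len(label) < 4:
        raise ValueError(f"label too short to corrupt: {label!r}")
    rng = seed if isinstance(seed, random.Random) else random.Random(seed)
    usable = [op for op in ops if op != "drop_space" or " " in label]
    if not usable:
        raise ValueError("no applicable corruption op for this label")
    for _ in range(100):
        op = rng.choice(usable)
        if op == "swap_adjacent":
            i = rng.randrange(len(label) - 1)
            cand = label[:i] + label[i + 1] + label[i] + label[i + 2 :]
        elif op == "drop_char":
            i = rng.randrange(len(label))
            cand = label[:i] + label[i + 1 :]
        elif op == "double_char":
            i = rng.randrange(len(label))
            cand = label[:i] + label[i] + label[i:]
        elif op == "insert_char":
            i = rng.randrange(len(label) + 1)
            cand = label[:i] + rng.choice(_CONSONANTS + _VOWELS) + label[i:]
        else:  # drop_space
            i = label.index(" ")
            cand = label[:i] + label[i + 1 :]
        if cand != label:
            return cand, 1
    raise RuntimeError("failed to produce a distinct corruption")


_DOSAGES = ("80 mg", "100 ml", "5 gram", "0,5 mg", "20 mg", "1 g/ml")
_FILLERS = ("elke dag", "forte", "plus", "zo nodig", "dagelijks")
_SEPARATORS = ("/", ", ", " ")


def generate_corpus(
    lexicon: list[tuple[str, str]],
    spec: CorpusSpec,
    cfg: PreprocessConfig | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], frozenset[str]]]:
    """Assemble a raw answer table plus its gold standard.

    Each participant contributes one answer built from lexicon labels with
    sampled separators, optional dosage strings, filler phrases, sentinel
    codes and per-name corruption.  The gold standard maps every term the
    pre-processor extracts from the corpus to the set of source labels it
    came from; residual filler terms map to the empty set (correct
    rejection).
    """
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    if cfg is None:
        cfg = PreprocessConfig()
    rng = random.Random(spec.seed)
    labels = sorted({label for label, _ in lexicon})
    answers: list[tuple[str, list[tuple[str, str]]]] = []  # (text, [(token, label)])
    rows = []
    for p in range(spec.n_participants):
        pid = f"P{p:05d}"
        if answers and rng.random() < spec.duplication_rate:
            text, parts = rng.choice(answers)
        else:
            if rng.random() < spec.empty_code_rate:
                text, parts = rng.choice(("8888", "9999")), []
            else:
                n_drugs = 1
                if rng.random() < spec.multi_drug_rate:
                    n_drugs = rng.randint(2, 3)
                parts = []
                fragments = []
                for label in rng.sample(labels, min(n_drugs, len(labels))):
                    token = label
                    if spec.corruption_ops and rng.random() < spec.corruption_rate:
                        token, _ = corrupt_name(label, spec.corruption_ops, rng)
                    parts.append((token, label))
                    frag = token
                    if rng.random() < spec.dosage_rate:
                        frag += " " + rng.choice(_DOSAGES)
                    fragments.append(frag)
                text = rng.choice(_SEPARATORS).join(fragments)
                if rng.random() < spec.filler_rate:
                    text += " " + rng.choice(_FILLERS)
                if rng.random() < 0.3:
                    text = text.capitalize()
            answers.append((text, parts))
        rows.append({"participant_id": pid, "question_id": "Q1", "answer": text})
    raw = pd.DataFrame(rows, columns=["participant_id", "question_id", "answer"])

    # derive gold by re-running the pre-processor and matching terms to tokens
    token_sources: dict[str, set[str]] = {}
    for text, parts in answers:
        for token, label in parts:
            token_sources.setdefault(token.lower(), set()).add(label)
    _, terms = preprocess_corpus(raw, cfg)
    gold: dict[tuple[str, str], frozenset[str]] = {}
    for t in terms:
        gold[(t.name, t.synonym)] = frozenset(token_sources.get(t.name, set()))
    return raw, gold
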