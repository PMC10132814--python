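"""Drug-name -> ATC-code ontology: code model, source cleaning, lookup, serialization.

The WHO Anatomical Therapeutic Chemical (ATC) classification is a five-level
hierarchical drug code.  Level patterns (L = uppercase letter, D = digit):

    level 1  L        anatomical main group        (e.g. ``A``)
    level 2  LDD      therapeutic subgroup         (e.g. ``C02``)
    level 3  LDDL     pharmacological subgroup     (e.g. ``A02B``)
    level 4  LDDLL    chemical subgroup            (e.g. ``A02BC``)
    level 5  LDDLLDD  chemical substance           (e.g. ``A02BC01``)

An ontology here is a deduplicated collection of cleaned Dutch drug labels,
each carrying one or more ATC codes (the mapping is n:m — one name may have
several codes, one code several names) plus optional brand-name synonyms.
Each entry gets a URI built from a fixed prefix and the MD5 of its label.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "ATCCode",
    "DrugEntry",
    "Ontology",
    "CleaningRules",
    "InvalidATCCodeError",
    "validate_atc_code",
    "atc_ancestors",
    "clean_source_label",
    "build_ontology",
    "lookup_codes",
    "write_ontology",
    "read_ontology",
    "write_turtle",
    "DEFAULT_URI_PREFIX",
]

DEFAULT_URI_PREFIX = "http://www.UMCG.nl/"

# one alternation branch per ATC level; full-match only
_ATC_RE = re.compile(
    r"(?:[A-Z]|[A-Z]\d\d|[A-Z]\d\d[A-Z]|[A-Z]\d\d[A-Z]{2}|[A-Z]\d\d[A-Z]{2}\d\d)"
)
_LEN_TO_LEVEL = {1: 1, 3: 2, 4: 3, 5: 4, 7: 5}


class InvalidATCCodeError(ValueError):
    """Raised for strings that do not match any ATC level pattern."""


@dataclass(frozen=True, order=True)
class ATCCode:
    code: str
    level: int = field(compare=False)

    def __str__(self) -> str:
        return self.code


def validate_atc_code(code: str) -> ATCCode:
    """Parse and validate an ATC code at any level (1-5).

    Whitespace is stripped and the code upper-cased before validation.
    Raises :class:`InvalidATCCodeError` naming the offending string when the
    result does not match one of the five level patterns (e.g. ``9.0CA04``).
    """
    if not isinstance(code, str) or not code.strip():
        raise InvalidATCCodeError(f"empty or non-string ATC code: {code!r}")
    norm = code.strip().upper()
    if not _ATC_RE.fullmatch(norm):
        raise InvalidATCCodeError(f"invalid ATC code format: {code!r}")
    return ATCCode(norm, _LEN_TO_LEVEL[len(norm)])


def atc_ancestors(code: ATCCode) -> list[ATCCode]:
    """Ancestors of *code* from level 1 down to its direct parent.

    Obtained by prefix truncation to the shorter level lengths; a level-1
    code has no ancestors.
    """
    return [
        ATCCode(code.code[:n], _LEN_TO_LEVEL[n])
        for n in (1, 3, 4, 5)
        if n < len(code.code)
    ]


@dataclass
class CleaningRules:
    """Patterns stripping non-name content from raw lexicon labels.

    Source databases mix the drug name with application form, package size,
    concentrations, dosages and company names; these rules reduce a raw row
    to the bare (lower-case) drug name.
    """

    dosage_patterns: Sequence[str] = (
        # number + unit, incl. ranges and decimal comma: "80 mg", "0,5 ml", "5-10 gram"
        r"\b\d+(?:[.,]\d+)?(?:\s*-\s*\d+(?:[.,]\d+)?)?\s*"
        r"(?:microgram|milligram|mcg|mg|gram|g|ml|cl|dl|l|ie|e|%)\b",
        # unit ratios: "1 g/ml", "50 mg/ml"
        r"\b\d+(?:[.,]\d+)?\s*(?:mcg|mg|g|ml|l)\s*/\s*(?:mcg|mg|g|ml|l)\b",
        # package sizes: "30 st", "3 x 10", "30 stuks", "10 tabl"
        r"\b\d+\s*(?:x\s*\d+\s*)?(?:stuks|stuk|st|tabl|caps|amp|sach)\b",
        r"\b\d+(?:[.,]\d+)?\b",  # bare numbers carry no name signal
    )
    company_names: Sequence[str] = (
        "sandoz",
        "teva",
        "mylan",
        "accord",
        "aurobindo",
        "pfizer",
        "bayer",
        "ratiopharm",
        "pch",
        "cf",
    )
    abbreviations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._dosage_re = [re.compile(p) for p in self.dosage_patterns]
        self.company_names = tuple(c.lower() for c in self.company_names)
        if self.company_names:
            self._company_re = re.compile(
                r"\b(?:" + "|".join(map(re.escape, self.company_names)) + r")\b"
            )
        else:
            self._company_re = None


class LabelRejected(ValueError):
    """Signals that a source label is empty after cleaning (entry dropped)."""


def clean_source_label(raw: str, rules: CleaningRules | None = None) -> str:
    """Clean one raw lexicon label; raise :class:`LabelRejected` if nothing is left.

    Order: lower-case, abbreviation expansion, dosage/package patterns,
    company names, whitespace collapse.
    """
    if rules is None:
        rules = CleaningRules()
    s = raw.lower()
    for abbr, full in rules.abbreviations.items():
        s = re.sub(r"\b" + re.escape(abbr.lower()) + r"\b", full.lower(), s)
    for pat in rules._dosage_re:
        s = pat.sub(" ", s)
    if rules._company_re is not None:
        s = rules._company_re.sub(" ", s)
    s = re.sub(r"\s+", " ", s).strip(" -,;.")
    if not s:
        raise LabelRejected(f"label empty after cleaning: {raw!r}")
    return s


@dataclass
class DrugEntry:
    label: str
    atc_codes: set[ATCCode]
    synonyms: set[str] = field(default_factory=set)
    uri: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("DrugEntry label must be non-empty")
        if not self.uri:
            self.uri = label_uri(self.label)


def label_uri(label: str, prefix: str = DEFAULT_URI_PREFIX) -> str:
    """Deterministic URI: fixed prefix + lowercase hex MD5 of the UTF-8 label."""
    return prefix + hashlib.md5(label.encode("utf-8")).hexdigest()


class Ontology:
    """Deduplicated drug entries plus the ATC parent hierarchy they span."""

    def __init__(self, entries: Iterable[DrugEntry] = ()) -> None:
        self._by_label: dict[str, DrugEntry] = {}
        for e in entries:
            self.add(e)

    def add(self, entry: DrugEntry) -> None:
        existing = self._by_label.get(entry.label.lower())
        if existing is None:
            self._by_label[entry.label.lower()] = entry
        else:
            existing.atc_codes |= entry.atc_codes
            existing.synonyms |= entry.synonyms

    @property
    def entries(self) -> list[DrugEntry]:
        return list(self._by_label.values())

    def __len__(self) -> int:
        return len(self._by_label)

    def __contains__(self, label: str) -> bool:
        return label.lower() in self._by_label

    def get(self, label: str) -> DrugEntry | None:
        return self._by_label.get(label.lower())

    def hierarchy(self) -> dict[ATCCode, ATCCode | None]:
        """Parent map over every ATC code reachable from the entries.

        Every chain terminates at a level-1 code whose parent is ``None``.
        """
        parents: dict[ATCCode, ATCCode | None] = {}
        for e in self.entries:
            for code in e.atc_codes:
                chain = atc_ancestors(code) + [code]
                for child, parent in zip(chain, [None] + chain[:-1]):
                    parents[child] = parent
        return parents


@dataclass
class RejectedRow:
    source: str
    label: str
    atc: str
    reason: str


def build_ontology(
    sources: dict[str, Iterable[tuple[str, str]]] | Iterable[tuple[str, str]],
    rules: CleaningRules | None = None,
    uri_prefix: str = DEFAULT_URI_PREFIX,
) -> tuple[Ontology, list[RejectedRow]]:
    """Merge (label, atc) rows from one or more sources into an Ontology.

    Labels are cleaned, codes validated, and (label, code) pairs deduplicated
    across sources.  Rows with invalid codes or labels that clean to nothing
    go into the rejects report instead of aborting the build — source
    databases routinely contain malformed entries that a curator fixes later.
    """
    if rules is None:
        rules = CleaningRules()
    if not isinstance(sources, dict):
        sources = {"source": sources}
    onto = Ontology()
    rejects: list[RejectedRow] = []
    for name, rows in sources.items():
        for raw_label, raw_atc in rows:
            try:
                code = validate_atc_code(raw_atc)
            except InvalidATCCodeError as exc:
                rejects.append(RejectedRow(name, raw_label, raw_atc, str(exc)))
                continue
            try:
                label = clean_source_label(raw_label, rules)
            except LabelRejected as exc:
                rejects.append(RejectedRow(name, raw_label, raw_atc, str(exc)))
                continue
            onto.add(DrugEntry(label, {code}, uri=label_uri(label, uri_prefix)))
    return onto, rejects


def lookup_codes(ontology: Ontology, label: str) -> set[ATCCode]:
    """All ATC codes for an exact (case-insensitive) entry label; empty if unknown."""
    entry = ontology.get(label)
    return set(entry.atc_codes) if entry else set()


# ---------------------------------------------------------------- serialization

_COLUMNS = ["label", "synonyms", "atc_codes", "uri"]


def write_ontology(ontology: Ontology, path: str | Path) -> None:
    """Write the ontology as TSV (columns: label, synonyms, atc_codes, uri)."""
    import pandas as pd

    rows = [
        {
            "label": e.label,
            "synonyms": "|".join(sorted(e.synonyms)),
            "atc_codes": ",".join(sorted(c.code for c in e.atc_codes)),
            "uri": e.uri,
        }
        for e in sorted(ontology.entries, key=lambda e: e.label)
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)


def read_ontology(path: str | Path) -> Ontology:
    """Read an ontology TSV written by :func:`write_ontology`.

    Raises ``ValueError`` with the 1-based data line number for malformed rows.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    onto = Ontology()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            codes = {validate_atc_code(c) for c in row.atc_codes.split(",") if c}
            if not codes:
                raise ValueError("no ATC codes")
            syns = {s for s in row.synonyms.split("|") if s}
            onto.add(DrugEntry(row.label, codes, synonyms=syns, uri=row.uri))
        except (ValueError, InvalidATCCodeError) as exc:
            raise ValueError(f"{path}: line {i}: {exc}") from exc
    return onto


def write_turtle(ontology: Ontology, path: str | Path) -> None:
    """Export the class--subclass hierarchy as RDF Turtle.

    ATC codes become classes chained by ``rdfs:subClassOf`` up to their
    level-1 group; each drug is a subclass of its ATC code(s), so a matcher
    consuming the ontology sees both the drug names and the group names.
    """
    from rdflib import RDF, RDFS, Graph, Literal, Namespace, URIRef
    from rdflib.namespace import OWL

    g = Graph()
    atc_ns = Namespace("http://purl.bioontology.org/ontology/UATC/")
    g.bind("atc", atc_ns)
    g.bind("owl", OWL)
    for code, parent in sorted(ontology.hierarchy().items()):
        node = atc_ns[code.code]
        g.add((node, RDF.type, OWL.Class))
        g.add((node, RDFS.label, Literal(code.code)))
        if parent is not None:
            g.add((node, RDFS.subClassOf, atc_ns[parent.code]))
    for e in ontology.entries:
        node = URIRef(e.uri)
        g.add((node, RDF.type, OWL.Class))
        g.add((node, RDFS.label, Literal(e.label)))
        for syn in sorted(e.synonyms):
            g.add((node, RDFS.comment, Literal(syn)))
        for code in sorted(e.atc_codes):
            g.add((node, RDFS.subClassOf, atc_ns[code.code]))
    g.serialize(destination=str(path), format="turtle")
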