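# Methods

## Problem setting

Free-text medication answers from questionnaire cohorts must be recoded as
ATC codes before analysis. The answers are Dutch drug names with
misspellings, brand names, dosage strings, filler phrases and several drugs
per line. The package implements a semi-automatic pipeline: deterministic
pre-processing, fuzzy matching against a drug-name→ATC ontology with a
confidence threshold for automatic acceptance, a human review gate for the
remainder, and recombination of codes with participant identifiers.

## ATC-code model and ontology

ATC codes are validated at any of the five levels (patterns `L`, `LDD`,
`LDDL`, `LDDLL`, `LDDLLDD`); partial codes are accepted because grouping
and filtering typically happen at group level (e.g. `C02`,
antihypertensives). The ontology merges one or more (label, code) source
tables: labels are cleaned (lower-case → dosage/package-size patterns →
company names → whitespace collapse, in that order), codes validated, and
(label, code) pairs deduplicated across sources. Rows with invalid codes or
labels that clean to nothing go to a rejects report rather than aborting the
build — source databases contain malformed entries that are corrected
manually, and silent loss would be worse than a failed build. Each entry's
URI is a fixed prefix (`http://www.UMCG.nl/` by default) plus the lowercase
hex MD5 of the UTF-8 bytes of the exact cleaned label, which makes URIs
deterministic across runs and platforms. A Turtle export renders ATC codes
as an `rdfs:subClassOf` chain terminating at the level-1 group, with drugs
as leaf subclasses, so a consumer sees both drug names and group names.

## Pre-processing

Rule order is fixed: lower-case and punctuation normalization; dosage
stripping (`number+unit`, unit ratios like `1 g/ml`, then bare numbers —
bare numbers carry no ATC signal once units are gone); stop-word, filler
and company-name removal; then splitting. Filtering precedes splitting so
the stored Synonym is the *filtered but unsplit* answer. Splitting uses
`/`, `,`, `+` and whitespace; `+` is treated as a separator because "plus"
behaves as a joining filler in this text. In-word hyphens are kept (drug
names contain them). Two classes of multi-word units survive splitting:
explicit exception phrases (`vitamine c`) and drug + application-form
bigrams (`acetylsalicylzuur dispertablet`) — the application form can
decide the ATC code. Fragments with fewer than three letters are discarded;
sentinel codes 8888/9999 yield no terms. Fused names missing a space
(`spironolactionomeprazol`) are *not* auto-split; they score poorly, miss
the threshold and flow to review, where the expert resolves them via
override codes.

Deduplication is keyed on the filtered answer: answers differing only in
case, dosage or fillers share one anonymous key (`a` + 10 hex chars of an
MD5), so each is curated once and the id-map join restores all participant
rows afterwards. The stop-word list is a compact curated set of Dutch
function words embedded in the package; the filler/company/exception lists
are seeded from the categories observed in this text type and are
user-extensible — they are configuration, not a closed vocabulary.

## Matching

The similarity primitive is the Dice coefficient over padded character
bigrams of normalized tokens, as a percentage rounded half-up to two
decimals only for presentation (ranking uses unrounded values). A token of
n characters contributes n+1 bigrams via `^`/`$` padding, and profiles are
multisets, so repeated substrings count. The score is symmetric, bounded in
[0, 100], and exactly 100 iff the normalized profiles coincide — the
property the default 100 % threshold relies on: at 100 only
normalization-identical terms are auto-accepted, and any threshold above
100 accepts nothing.

Normalization keeps `[a-z0-9]` (everything else separates tokens), folds
diacritics by default (switchable off to reproduce the behaviour of systems
that cannot handle `ï`), and applies a deliberately minimal stem: strip one
trailing `e` from tokens of ≥ 4 characters. That single rule conflates the
Dutch/international spelling pairs (`omeprazol`/`omeprazole`) that must
score 100; a full stemmer is out of scope and would risk conflating distinct
names. Composite relevance scores from search-engine-backed matchers (the
fractional scores such as 73.17 or 47.06 that mixed retrieval weighting into
the similarity) are not reproduced by the pure bigram Dice; they are
documented as non-targets.

Candidates are retrieved through an inverted index bigram → posting list
over all labels and synonyms. Retrieval returns every entry sharing at
least one bigram with the query — a superset of all entries with positive
score — so the top-k over the retrieved set is exactly the brute-force
top-k (verified against an all-pairs oracle in the tests). The candidate
score is the max over {query term, query synonym} × {entry label, entry
synonyms}; scoring the unsplit answer as well lets one selected term surface
every drug in the answer, at the cost of some redundancy that collapses
later during code assignment. Ties break lexicographically by label and at
most one candidate per entry is kept; k = 10 by default.

## Curation

Decision states: `auto_matched` (exactly one selection, no review),
`matched` (≥ 1 selections — multi-select), `no_match` (none), and
`flagged_pending`. A review flag may combine with `matched` or `no_match`.
The expert surface is a spreadsheet-style TSV with columns
`Name, Synonym, ontologyTermName, score, validated, review, Atccode,
Atccode text`, sorted and grouped by Synonym so all parts of one answer are
visible together; exporting all decisions (not only flagged ones) makes the
no-edit round-trip the identity. On import, a row whose `ontologyTermName`
resolves in the ontology becomes a selection; a row with a literal `Atccode`
and no term name becomes an expert override (first-class, because some
answers are only resolvable by hand); a group with neither becomes
`no_match`; rows with an unknown term name *and* an invalid code are
reported as row-level errors. Assignment expands each selection to all its
codes and deduplicates per (answer, code); recombination joins on the
answer key and errors on keys missing from the id map, so no coded answer
can be silently orphaned.

## Evaluation

Predictions are top-1 candidates per term surviving a threshold. Regimes:

* optimistic — multi-entry gold deduplicates to one slot; any hit is TP;
* pessimistic — one slot per gold entry; a hit fills one slot and the
  remaining slots count as FP (mismatch penalty); a wrong prediction counts
  FP for every slot; no prediction counts FN per slot.

TN is defined only by correct rejections (empty gold, no surviving
prediction); a prediction on empty gold is FP. A term filtered out by the
threshold with non-empty gold counts FN — the convention chosen for
suggestion-absent cases, applied identically in both regimes. With TP equal
and FP/FN one-sidedly larger, pessimistic precision and recall are both
bounded by optimistic, hence optimistic F ≥ pessimistic F on every dataset
(also tested on random gold standards). F is reported as 0 with an explicit
flag when precision + recall = 0; all-zero confusion counts are an error.
The threshold sweep uses step 1 over the inclusive grid 0..100, computing
suggestions once per term.

## Synthetic data

The generator defines the study conditions for all tests. Defaults: 500
participants, 100-entry lexicon, duplication rate 0.3 (answers repeated
across participants), corruption rate 0.2 with exactly one character edit
per corrupted name (swap/drop/double/insert; high-confidence matches
correspond to single-letter errors, so one edit is the canonical noise
unit), multi-drug rate 0.25, dosage rate 0.3, filler rate 0.15, sentinel
rate 0.05. Labels are pronounceable CVC-syllable pseudo-names (no licensed
drug-database content); a fraction carries a second ATC code and a
brand-name alias to reproduce the n:m structure. The gold standard is
derived by re-running the pre-processor on the generated corpus and mapping
each emitted term to its source labels, so gold completeness holds by
construction. The generator does not model real Dutch morphology, real
brand-name frequency, spelling-error distributions conditioned on keyboard
layout, or answer-length distributions of real cohorts — passing tests
demonstrate the mechanics and contracts of the pipeline, not field accuracy
on clinical text.

## Numerical and reproducibility choices

Scores are compared unrounded; only the review file and reports show
half-up 2-decimal rounding. Exact-100 detection is safe in floating point
because equal profiles give 200·n/(2n). All randomness flows through
explicit seeds (`random.Random(seed)`); identical inputs and configuration
produce byte-identical outputs, enforced by a determinism test. Test and
acceptance problem sizes (lexicons of 30–200 entries, corpora of 80–1000
answers, 1000 oracle queries against a 100-entry ontology) were chosen as
the smallest sizes at which the properties under test are non-trivial.

## Known limitations

* No spell correction and no auto-splitting of fused names; both route to
  the human reviewer by design.
* The bigram Dice score is length-sensitive: a short term against a long
  label scores low even when the term is a perfect substring; the query
  Synonym channel mitigates this for multi-drug answers.
* Non-Latin scripts are unsupported (the `[a-z0-9]` charset is structural).
* Cohort-scale performance figures depend on access-controlled data and are
  outside what the test suite can establish.
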