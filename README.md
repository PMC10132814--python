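# atcmapper

Semi-automatic translation of noisy free-text medication answers into WHO
ATC (Anatomical Therapeutic Chemical) codes.

Questionnaire studies that ask participants which drugs they take receive
answers like `acenocoumarol/omeprazol/losartan kalum/lercanidipine`,
`Paracetamol 5 gram` or `aspirine (merk)` — misspellings, brand names,
dosages, several drugs per line, varying separators. Epidemiologists need
those answers as standard ATC codes so drugs can be grouped, counted and
filtered. Fully manual coding is slow expert work; `atcmapper` automates
most of it and routes only the genuinely ambiguous cases to a human
reviewer.

## Method

The pipeline has five stages:

1. **Anonymize & deduplicate.** Participant IDs are split off into a private
   id map; only unique, anonymous answer texts move on. Lower-casing and
   filler removal make repeated answers (including repeated misspellings)
   collapse, so the expert checks each one once.
2. **Pre-process.** Normalize text, strip dosage/volume/concentration
   patterns (`5 gram`, `100 ml`, `1 g/ml`), remove Dutch stop words, filler
   phrases (`elke dag`, `forte`) and company names, and split multi-drug
   answers on `/`, `,`, `+` and whitespace. Fragments with fewer than three
   letters and sentinel "no answer" codes (8888/9999) are dropped. Each
   extracted term keeps the filtered-but-unsplit answer as its *Synonym* —
   context for both the matcher and the curator.
3. **Match.** Each term is scored against every drug label and synonym in a
   curated name→ATC ontology using the Dice coefficient over padded
   character bigrams of normalized tokens:

   `score = 200 · |A ∩ B| / (|A| + |B|)`  (percent),

   where A and B are bigram multisets. Normalization keeps `[a-z0-9]`,
   folds diacritics and strips one trailing `e` from tokens of ≥ 4
   characters, so `omeprazol` and `omeprazole` score exactly 100. Terms
   whose best candidate reaches the threshold (default 100 %) are accepted
   automatically; the rest get a ranked top-10 suggestion list.
4. **Curate.** Unresolved terms are exported as a review TSV grouped by
   answer, where the expert selects suggestions, rejects terms, or enters a
   literal ATC code as an override. Multi-select per term is supported, and
   the review file round-trips losslessly.
5. **Assign & recombine.** Selected ontology terms expand to all their ATC
   codes (an n:m mapping), duplicates collapse per answer, and a join with
   the id map yields unique (participant, question, ATC code) records.

An evaluation harness sweeps the acceptance threshold from 0 to 100 against
an expert gold standard under two bounding conventions: *optimistic* (a term
with several correct codes counts once, any hit is a true positive) and
*pessimistic* (every correct code is a slot; slots the single prediction
cannot fill are penalized). The optimistic F-score is an upper bound and the
pessimistic one a lower bound; note the pessimistic penalty counts unmet
slots as false *positives*, a deliberate divergence from the conventional
false-negative bookkeeping.

Because real cohort data are access-controlled, the package ships a
synthetic generator producing pseudo-drug lexicons and noisy corpora
(misspellings, dosages, fillers, multi-drug lines, duplicated answers) with
a known gold standard, which powers the test suite end to end.

## Worked example

```bash
atcmapper synth --out-dir fx --n-participants 80 --n-lexicon 30 --seed 7
atcmapper build-ontology --sources fx/lexicon.tsv --out onto.tsv --ttl onto.ttl
atcmapper run --answers fx/answers.tsv --ontology onto.tsv --out-dir out --threshold 100
```

prints the stage report of the first phase:

```
             n_answers: 80
        n_deduplicated: 51
               n_terms: 85
        n_auto_matched: 71
             n_flagged: 14
     halted_for_review: True
```

80 raw answers collapse to 51 unique filtered answers which split into 85
candidate terms; 71 are exact (normalized) ontology matches at the 100 %
threshold and 14 corrupted names await review in `out/review.tsv`. After the
expert edits that file, resuming with `--review` completes the run:

```bash
atcmapper run --answers fx/answers.tsv --ontology onto.tsv \
              --out-dir out2 --threshold 100 --review curated.tsv
```

```
            n_no_match: 14
       n_coded_records: 128
     halted_for_review: False
```

(here the expert rejected all 14) and writes `out2/coded.tsv` with one row
per unique participant × question × ATC code.

The library mirrors the CLI: `preprocess_corpus`, `build_index` /
`suggest` / `auto_match`, `export_review` / `import_review`, `assign_atc`,
`recombine`, `threshold_sweep`.

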