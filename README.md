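# readcoder

Rule-based extraction of coded clinical information from the free text
of UK primary-care records.  Given a record's free text and its
associated Read/OXMIS term, `readcoder` emits structured value-attribute
pairs: terminology codes for diagnoses (with negation, past-history,
family-history, suspected or death-certificate context), blood pressure,
pulse, laboratory results, dates and durations.  A companion algorithm
selects a single underlying cause of death from prioritised sources in a
patient's record.  It is aimed at epidemiologists working with GP
databases where causes of death and test results are often recorded only
in text, and at anyone who needs transparent, auditable (non-ML) clinical
text coding.

## How it works

Text is cleaned, tokenised (words, numbers, UK dates, times, fractions,
durations) and resolved against a medical lexicon and a general
British-English word list, with spelling correction restricted to a
single letter insertion or substitution.  Phrase patterns assign context
attributes — e.g. *no* starts a negative scope that runs along a list
and stops at *but* or the sentence end.  Sequences of up to five words
are matched to terminology records through a synonym table and scored
with a closeness measure:

    readscore = 1 − 0.10·n_synonym − 0.05·n_unmatched_ignorable − 0.05·n_laterality

A match needs every positive term word (after synonym substitution),
ignores word order, and is accepted at readscore ≥ 0.70.  The analysis
mode (standard, death, pregnancy, labtest, normal, date, sicknote) is
chosen from the associated code and switches interpretation rules, e.g.
`1a`/`1b`/`1c` before diagnoses in a death note become Medical
Certificate of Cause of Death (MCCD) categories.  For cause-of-death
resolution the underlying cause is the single recorded cause, or the
lowest-lettered MCCD Part I entry, with manual review flagged otherwise.
See `docs/methods.md` for the full model.

## Worked example

```sh
printf 'r1\tG20..00\t176/100 but only taking doxaz 4mg od, pn recheck 4w please. recent diagnosis ca prostate\n' > records.tsv
readcoder analyze records.tsv --out out.jsonl
cat out.jsonl
```

prints one JSON block:

```json
{"items": [{"attribute": "systolic_bp", "kind": "number", "value": 176.0},
           {"attribute": "diastolic_bp", "kind": "number", "value": 100.0},
           {"attribute": "follow_up", "kind": "duration", "value": {"unit": "week", "value": 4.0}},
           {"dictionary": "READ", "kind": "term", "term_text": "Malignant neoplasm of prostate", "value": "B46..00"}],
 "mode": "standard", "record_id": "r1"}
```

The blood-pressure pair 176/100 mmHg was recognised from the fraction,
the follow-up interval of 4 weeks from the `recheck 4w` cue, and the
abbreviation `ca prostate` was coded to Read B46..00 *Malignant neoplasm
of prostate* through the synonym table (readscore 0.85).  Dose numbers
(`4mg`) are dropped: values without an attribute are never emitted.

Other subcommands: `readcoder cod` (cause-of-death decisions over
patient bundles), `readcoder make-fixtures` (fixture terminology and
gold-annotated synthetic corpora), `readcoder evaluate`
(precision/recall/F against gold annotations, Wilson 95% CIs).

## Layout

- `src/readcoder/` — terminology, preprocess, context, matcher, modes,
  pipeline, cause_of_death, fixtures, evaluate, io, cli
- `src/readcoder/tables/` — editable CSV lookup tables and word lists
- `tests/` — unit, property (hypothesis) and acceptance tests
- `docs/methods.md` — model, parameters, design choices, limitations
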