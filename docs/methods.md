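# Methods

## Problem and approach

UK primary-care records attach free text to coded entries (Read or OXMIS
terms).  Diagnoses, causes of death, test results and dates frequently
live only in that text.  `readcoder` is a deterministic, table-driven
extractor: every behaviour that is likely to need local tuning —
word categories, abbreviations, synonyms, attribute phrase patterns,
mode triggers, cleaning rules, code-class exclusions — is an editable
CSV, not code.  There is no statistical model; the design trades recall
for precision, preferring to emit nothing over emitting a doubtful code.

## Terminology standardisation

Term wordings are lowercased; dictionary-only qualifiers (`NOS`, `NEC`,
`[D]`, `[X]`, `[M]`) are stripped; abbreviations (`a/n` → antenatal,
`h/o` → history of) are expanded.  Each word gets a match category:

* **positive** — must be present in the text (default),
* **optional** — may be absent at a small penalty (laterality words,
  common modifiers such as *acute*, *chronic*, *heart*),
* **ignorable** — stop-words,
* **negative** — words following an in-term negation marker
  (*without*, *no*); the text must not assert them positively.

Words joined by *or* form a group of which at least one member must
match, with no penalty for the unmatched members.  Terms with more than
five non-ignorable words, or in excluded code classes (administration,
procedures, tests, detailed injury causes), are flagged non-matchable.
The shipped category table is a reconstruction: it covers the behaviour
needed by the worked examples and the fixture terminology, and is meant
to be extended for a real dictionary.

## Tokenisation and lexicons

Sentences split at `.`, `;` and newline, with decimal points and
personal-title stops protected.  Tokens are classified as words,
numbers, UK day-first dates (`09/01/2007`, `9-Jan-2007`, bare years
1900–2100), times (`14:15`, `1415hrs`), fractions (`22/40`, `176/100`)
and number+unit durations (`4w`, `1 month`).  Words are resolved against
a medical lexicon (every word of the terminology plus the synonym and
pattern tables) and a general British-English list (a curated stand-in
for a public word list; one word per line, editable).

Spelling correction permits exactly one letter **insertion or
substitution** — never a deletion — and only when the edit neighbourhood
contains exactly one lexicon word (medical preferred over general).
Tokens shorter than four letters or containing digits are never
corrected: in clinical text these are almost always abbreviations, and
"correcting" them is the dominant error mode.  Unresolved words are
ignored downstream; they may be names, so they also break candidate
phrases.

## Context attributes

A phrase-pattern table maps triggers (*no*, *did not show*, *h/o*,
*family history*, *?*, *cd*, *hb*, *recheck*, ...) to attributes with a
direction and scope rule.  A **list** scope runs forward across
comma/*and*/*or* joined items and stops at *but*, other punctuation, a
newer trigger or the sentence end; scopes never cross sentences.  A
**next-value** scope claims the nearest value token (used for pulse,
haemoglobin, follow-up intervals, time of death).  Titles (*mr*, *dr*,
...) followed by a capitalised or out-of-lexicon word, and masked runs
(`XXX`, `###`), get an *anonymised* attribute and are excluded from
matching.

Quantities: a plausible blood-pressure fraction (systolic 60–300,
diastolic 30–200, systolic > diastolic) yields systolic/diastolic
findings; in pregnancy mode a denominator-40 fraction is claimed first
as gestational age (weeks).  Only one attribute may apply to a value;
conflicting claims are resolved by a fixed precedence (explicit unit >
named cue > positional) and logged.

## Matching and readscore

All contiguous runs of 1–5 resolved words are candidate phrases, tried
longest first.  Sub-phrases may be replaced through the synonym table
(up to two substitutions).  The readscore of a phrase against a term is

    score = 1 − 0.10·(synonym substitutions)
              − 0.05·(unmatched ignorable/optional/negative term words)
              − 0.05·(laterality words in the phrase but not the term)

and is 0 outright if a positive term word (or a whole *or*-group) is
unmatched, if the text positively asserts a negative term word, or if
the phrase contains a content word the term cannot account for.  That
last rule is stricter than a pure-deduction scheme; without it every
superstring phrase would match, which is incompatible with the
precision-first stance.  Word order is ignored.  The acceptance
threshold is 0.70.  All four numbers are configuration keys
(`MatcherConfig`), not constants; the shipped values make a
one-substitution or one-optional-word match (0.85–0.95) clear the
threshold and a two-failure match (≤0.65 with a substitution plus
several unmatched words) miss it.

Ties at equal score break by longer phrase, then READ over OXMIS over
CUSTOM, then lexicographic code — output must be a total order to be
reproducible.  Each token is consumed by at most one accepted match.
If the record's associated term plus a modifier word present in the text
exactly covers a more specific matchable term (left ventricular failure
+ *acute* → acute left ventricular failure), the refined term is
emitted.

## Analysis modes

The associated code's class selects the mode (first hit in priority
order death, pregnancy, labtest, normal, date, sicknote; default
standard; the word *pregnant* in the text also triggers pregnancy mode).
Death mode extracts the time/date of death, suppresses laboratory
results, and reads `1a/1b/1c/2` (or roman `Ia..II`) markers before
diagnoses as death-certificate categories.  Labtest mode takes the first
number (or *normal*/*abnormal* where the trigger allows) as the result;
normal mode accepts only *normal*/*abnormal*; date mode expects exactly
one date and flags ambiguity rather than guessing; sicknote mode reads
dates as certificate start/end and durations as the certificate
duration.

## Underlying cause of death

Candidates are gathered per patient from, in decreasing priority: the
structured MCCD area; free text stating MCCD categories or "cause of
death" (analysed in death mode); coded diagnoses on or after the date of
death; other free text attached to death records.  Coded diagnoses up to
90 days before death are collected only to support manual review.  A
single recorded cause resolves immediately; otherwise the top non-empty
tier must yield a single diagnosis or carry Part I categories (pick the
lowest letter: Ic below Ib below Ia; Part II is never the underlying
cause); anything else is flagged for manual review.  The full WHO
ICD-10 selection rules are deliberately out of scope; Read→ICD-10
mapping is a plain lookup that flags unmapped codes rather than
guessing.

## Synthetic data and what passing proves

The licensed dictionaries and the source database are confidential, so
the fixture terminology contains every code the published worked
examples use, plus seed entries for common causes of death (entries
whose official code is not printed use project-assigned placeholder
codes in the same style) and, on demand, generated distractor terms
under a reserved `ZZ` prefix.  The corpus generator emulates GP text:
short diagnosis statements, negated symptom lists, past-history notes,
BP pairs, pulse rates, follow-up intervals, certificate-style death
notes with `1a/1b/1c` markers, and single-deletion typos at a default
rate of 0.05 per record (chosen once as a realistic order of magnitude;
typos may cost recall, never gold correctness).  The generator writes
its own gold annotations from the template, sharing no code with the
matcher.

What it does **not** emulate: long narrative letters, clinician-specific
abbreviation habits, ambiguous acronyms, mixed-topic texts, OCR noise.
Perfect scores on clean synthetic corpora therefore demonstrate internal
consistency of the pipeline (the generator and matcher agree through two
independent routes), not expected performance on real records, which the
published figures put far below 100% recall.

## Numerical and edge-case choices

* Evaluation CIs: Wilson score intervals (default), switchable to exact
  binomial; Wilson behaves well at the small counts a local validation
  sample produces.
* Evaluation granularity: items match on (kind, value, negation,
  attribute family); duplicate codes collapse per record; suspected and
  family-history items are excluded by default, mirroring the original
  review protocol.
* Degenerate inputs: empty text yields an empty output block; a
  per-record exception is caught by the CLI, logged, and flagged on that
  record without aborting the run; a trigger with an empty scope is
  discarded; an ambiguous spelling correction is abandoned.
* Problem sizes: the test suite and the acceptance script run the nine
  worked examples, synthetic corpora of 120–240 records, and
  brute-force matcher cross-checks over the ≤50-term fixture store.

## Known limitations

UK English only; the category/synonym/pattern tables shipped here are
fixture-scale reconstructions, not the full production tables; one text
phrase never yields two accepted terms over the same tokens (a
conservative reading); recall on real text depends almost entirely on
the breadth of the synonym table.
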