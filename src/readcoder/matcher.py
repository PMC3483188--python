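"""Phrase-to-term matching with the readscore closeness measure.

Sequences of up to five resolved words are matched against the
terminology.  A candidate phrase may have sub-phrases replaced via a
synonym table (at a score penalty).  The readscore of a (phrase, term)
pair is 1 minus deductions: each synonym substitution, each unmatched
ignorable/optional/negative term word and each ignored laterality word
('right'/'left' in the text but not the term) costs points; any unmatched
positive term word (or wholly unmatched "or" group), any disagreement on
a negative term word, or any phrase word that matches nothing and is not
a stop/laterality word, scores 0.  Word order never matters.  The
highest-scoring term at or above the acceptance threshold wins; each
token is consumed by at most one accepted match.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .context import AttributedSpan, CONTEXT_FAMILIES
from .preprocess import LexiconStatus, Token, TokenKind
from .terminology import (
    DICTIONARY_ORDER,
    Dictionary,
    TermRecord,
    TermStore,
    WordCategory,
)

__all__ = [
    "MatcherConfig",
    "SynonymRule",
    "SynonymTable",
    "Phrase",
    "MatchCandidate",
    "candidate_phrases",
    "readscore",
    "best_match",
    "refine_term",
]

MAX_PHRASE_WORDS = 5
LATERALITY_WORDS = frozenset({"right", "left"})

_ELIGIBLE_STATUS = {
    LexiconStatus.MEDICAL,
    LexiconStatus.GENERAL,
    LexiconStatus.CORRECTED,
}


@dataclass(frozen=True)
class MatcherConfig:
    threshold: float = 0.70
    penalty_synonym: float = 0.10
    penalty_ignorable: float = 0.05
    penalty_laterality: float = 0.05
    max_substitutions: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.threshold <= 1:
            raise ValueError("threshold must be in (0, 1]")


@dataclass(frozen=True)
class SynonymRule:
    source: tuple[str, ...]  # 1-3 words
    replacement: tuple[str, ...]
    penalty: float

    def __post_init__(self) -> None:
        if self.source == self.replacement:
            raise ValueError("synonym source equals replacement")
        if self.penalty <= 0:
            raise ValueError("synonym penalty must be positive")


@dataclass
class SynonymTable:
    rules: list[SynonymRule] = field(default_factory=list)

    def applicable(self, words: tuple[str, ...]) -> Iterable[tuple[int, SynonymRule]]:
        """(start index, rule) pairs whose source occurs contiguously in words."""
        for rule in self.rules:
            k = len(rule.source)
            for i in range(len(words) - k + 1):
                if words[i : i + k] == rule.source:
                    yield i, rule

    def replacement_words(self) -> set[str]:
        return {w for rule in self.rules for w in rule.replacement}


def load_synonyms(path: Union[str, Path]) -> SynonymTable:
    table = SynonymTable()
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            table.rules.append(
                SynonymRule(
                    source=tuple(row["source"].strip().lower().split()),
                    replacement=tuple(row["replacement"].strip().lower().split()),
                    penalty=float(row["penalty"]),
                )
            )
    return table


@dataclass(frozen=True)
class Phrase:
    sentence_index: int
    start: int  # token index of first word, half-open span over the sentence
    end: int
    words: tuple[str, ...]
    token_indices: tuple[int, ...]


@dataclass
class MatchCandidate:
    code: str
    dictionary: Dictionary
    phrase: Phrase
    readscore: float
    n_synonym_substitutions: int = 0
    unmatched_ignorable_count: int = 0
    negated: bool = False
    attribute: Optional[str] = None

    @property
    def sort_key(self):
        # total order: score desc, longer phrase, READ < OXMIS < CUSTOM, code
        return (
            -self.readscore,
            -len(self.phrase.words),
            DICTIONARY_ORDER[self.dictionary],
            self.code,
        )


def candidate_phrases(
    tokens: Sequence[Token],
    excluded: Optional[set[tuple[int, int]]] = None,
) -> list[Phrase]:
    """All contiguous word sequences of 1-5 resolved words, longest first.

    Runs break at non-word tokens, unresolved (UNKNOWN) words and
    excluded positions (anonymised tokens).
    """
    excluded = excluded or set()
    runs: list[list[Token]] = []
    current: list[Token] = []
    for tok in tokens:
        ok = (
            tok.kind is TokenKind.WORD
            and tok.lexicon_status in _ELIGIBLE_STATUS
            and (tok.sentence_index, tok.token_index) not in excluded
        )
        if ok:
            if current and current[-1].sentence_index != tok.sentence_index:
                runs.append(current)
                current = []
            current.append(tok)
        elif current:
            runs.append(current)
            current = []
    if current:
        runs.append(current)

    phrases: list[Phrase] = []
    for run in runs:
        n = len(run)
        for length in range(min(n, MAX_PHRASE_WORDS), 0, -1):
            for i in range(n - length + 1):
                window = run[i : i + length]
                phrases.append(
                    Phrase(
                        window[0].sentence_index,
                        window[0].token_index,
                        window[-1].token_index + 1,
                        tuple(t.norm for t in window),
                        tuple(t.token_index for t in window),
                    )
                )
    phrases.sort(key=lambda p: (-len(p.words), p.sentence_index, p.start))
    return phrases


# ---------------------------------------------------------------------------
# scoring

def _variants(
    words: tuple[str, ...], synonyms: SynonymTable, max_subs: int
) -> Iterable[tuple[tuple[str, ...], int]]:
    """Phrase variants under 0..max_subs synonym substitutions."""
    seen = {words}
    frontier = [(words, 0)]
    yield words, 0
    for _ in range(max_subs):
        next_frontier = []
        for current, n in frontier:
            for i, rule in synonyms.applicable(current):
                k = len(rule.source)
                variant = current[:i] + rule.replacement + current[i + k :]
                if variant not in seen:
                    seen.add(variant)
                    next_frontier.append((variant, n + 1))
                    yield variant, n + 1
        frontier = next_frontier


def _score_variant(
    variant: set[str],
    n_subs: int,
    term: TermRecord,
    stopwords: set[str],
    config: MatcherConfig,
) -> Optional[tuple[float, int]]:
    term_words = set(term.words)
    grouped = {i for g in term.or_groups for i in g}

    deductions = 0.0
    unmatched_ignorable = 0
    for i, (word, cat) in enumerate(zip(term.words, term.categories)):
        present = word in variant
        if cat is WordCategory.POSITIVE and i not in grouped:
            if not present:
                return None
        elif cat is WordCategory.NEGATIVE:
            if present:
                return None  # text asserts what the term negates
            deductions += config.penalty_ignorable
            unmatched_ignorable += 1
        elif i in grouped:
            continue  # group members scored as a unit below
        elif not present:  # OPTIONAL or IGNORABLE
            deductions += config.penalty_ignorable
            unmatched_ignorable += 1
    for group in term.or_groups:
        if not any(term.words[i] in variant for i in group):
            return None

    for word in variant:
        if word in term_words:
            continue
        if word in stopwords:
            continue
        if word in LATERALITY_WORDS:
            deductions += config.penalty_laterality
            continue
        return None  # a content word the term cannot account for

    score = 1.0 - deductions - n_subs * config.penalty_synonym
    return max(score, 0.0), unmatched_ignorable


def readscore(
    phrase_words: Sequence[str],
    term: TermRecord,
    synonyms: SynonymTable,
    config: MatcherConfig = MatcherConfig(),
    stopwords: Optional[set[str]] = None,
) -> tuple[float, int, int]:
    """Best (score, n_substitutions, unmatched_ignorable) over synonym variants.

    Returns score 0.0 when no variant matches.  *stopwords* are globally
    ignorable words (the IGNORABLE rows of the category table).
    """
    if not term.matchable:
        raise ValueError(f"term {term.code} is not matchable")
    stopwords = stopwords or set()
    best: Optional[tuple[float, int, int]] = None
    for variant, n_subs in _variants(tuple(phrase_words), synonyms,
                                     config.max_substitutions):
        scored = _score_variant(set(variant), n_subs, term, stopwords, config)
        if scored is None:
            continue
        score, unmatched = scored
        if best is None or score > best[0]:
            best = (score, n_subs, unmatched)
    return best if best is not None else (0.0, 0, 0)


# ---------------------------------------------------------------------------
# selection

def _candidate_terms(
    phrase: Phrase, store: TermStore, synonyms: SynonymTable
) -> set[tuple[Dictionary, str]]:
    lookup_words = set(phrase.words)
    for i, rule in synonyms.applicable(phrase.words):
        lookup_words.update(rule.replacement)
    keys: set[tuple[Dictionary, str]] = set()
    for word in lookup_words:
        keys.update(store.lookup_word(word))
    return keys


def _span_attributes(
    phrase: Phrase, spans: Sequence[AttributedSpan]
) -> tuple[bool, Optional[str]]:
    negated = False
    attribute: Optional[str] = None
    for span in spans:
        if span.attribute not in CONTEXT_FAMILIES:
            continue
        overlap = any(span.covers(phrase.sentence_index, i)
                      for i in phrase.token_indices)
        if not overlap:
            continue
        if span.attribute == "negative":
            negated = True
        elif span.attribute != "anonymised" and attribute is None:
            attribute = span.attribute
    return negated, attribute


def best_match(
    phrases: Sequence[Phrase],
    store: TermStore,
    synonyms: SynonymTable,
    config: MatcherConfig = MatcherConfig(),
    stopwords: Optional[set[str]] = None,
    spans: Sequence[AttributedSpan] = (),
) -> list[MatchCandidate]:
    """Accept the highest-readscore term per phrase, longest phrase first.

    Each token is consumed by at most one accepted match; phrases
    overlapping consumed tokens are skipped.
    """
    accepted: list[MatchCandidate] = []
    consumed: set[tuple[int, int]] = set()
    for phrase in phrases:
        positions = {(phrase.sentence_index, i) for i in phrase.token_indices}
        if positions & consumed:
            continue
        best: Optional[MatchCandidate] = None
        for key in _candidate_terms(phrase, store, synonyms):
            term = store.records[key]
            if not term.matchable:
                continue
            score, n_subs, unmatched = readscore(
                phrase.words, term, synonyms, config, stopwords
            )
            if score < config.threshold:
                continue
            candidate = MatchCandidate(
                code=term.code,
                dictionary=term.dictionary,
                phrase=phrase,
                readscore=score,
                n_synonym_substitutions=n_subs,
                unmatched_ignorable_count=unmatched,
            )
            if best is None or candidate.sort_key < best.sort_key:
                best = candidate
        if best is not None:
            best.negated, best.attribute = _span_attributes(phrase, spans)
            accepted.append(best)
            consumed.update(positions)
    accepted.sort(key=lambda c: (c.phrase.sentence_index, c.phrase.start))
    return accepted


def refine_term(
    original_code: str,
    store: TermStore,
    text_words: set[str],
) -> Optional[TermRecord]:
    """Combine the record's associated term with modifier words in the text.

    If the text supplies modifier words that, together with the associated
    term's non-ignorable words, exactly cover a more specific matchable
    term, that term is returned (e.g. a failure term plus the word 'acute'
    refines to the acute-failure term).
    """
    original = store.get(original_code)
    if original is None:
        return None
    base = set(original.non_ignorable_words)
    best: Optional[TermRecord] = None
    best_key = None
    for record in store.matchable_records():
        if record.code == original.code and record.dictionary is original.dictionary:
            continue
        specific = set(record.non_ignorable_words)
        extra = specific - base
        if not extra or not specific > base:
            continue
        if not extra <= text_words:
            continue
        key = (len(extra), DICTIONARY_ORDER[record.dictionary], record.code)
        if best is None or key < best_key:
            best, best_key = record, key
    return best
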