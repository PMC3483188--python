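"""Terminology handling: loading, standardising and indexing Read/OXMIS terms.

Free text is coded against a table of clinical terms.  Each term's wording is
standardised (lowercased, abbreviations expanded, dictionary-only qualifiers
such as ``NOS``/``NEC``/``[D]`` stripped) and every word is categorised as
POSITIVE (must be present in the text), NEGATIVE (must not be asserted
positively), OPTIONAL (may be absent at a small score penalty) or IGNORABLE
(stop-words).  Words joined by "or" form an alternative group of which at
least one member must match.  Terms that are too long (more than five
non-ignorable words) or that belong to excluded code classes (administration,
procedures, injury-cause descriptions) are flagged non-matchable.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "Dictionary",
    "WordCategory",
    "TermRecord",
    "TermStore",
    "TerminologyError",
    "load_term_table",
    "standardise_term_text",
    "categorise_term_words",
    "select_matchable_subset",
    "add_custom_term",
]

MAX_NON_IGNORABLE_WORDS = 5

#: markers inside a term wording that negate the words that follow them
NEGATION_MARKERS = frozenset({"without", "no", "not"})

#: bracketed qualifiers and suffix codes that never occur in clinical text
_QUALIFIER_RE = re.compile(r"\[[dxmv]\]|\bNOS\b|\bNEC\b", re.IGNORECASE)
_WORD_RE = re.compile(r"[a-z0-9]+(?:[/'][a-z0-9]+)*")


class TerminologyError(ValueError):
    """Raised for malformed or inconsistent terminology input."""


class Dictionary(str, Enum):
    READ = "READ"
    OXMIS = "OXMIS"
    CUSTOM = "CUSTOM"


#: tie-break order between dictionaries when scores are equal
DICTIONARY_ORDER = {Dictionary.READ: 0, Dictionary.OXMIS: 1, Dictionary.CUSTOM: 2}


class WordCategory(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    OPTIONAL = "OPTIONAL"
    IGNORABLE = "IGNORABLE"


@dataclass
class TermRecord:
    code: str
    dictionary: Dictionary
    raw_text: str
    words: list[str]
    categories: list[WordCategory]
    or_groups: list[frozenset[int]] = field(default_factory=list)
    matchable: bool = True

    def __post_init__(self) -> None:
        if len(self.words) != len(self.categories):
            raise TerminologyError(
                f"{self.code}: {len(self.words)} words but {len(self.categories)} categories"
            )

    @property
    def key(self) -> tuple[Dictionary, str]:
        return (self.dictionary, self.code)

    @property
    def non_ignorable_words(self) -> list[str]:
        return [
            w
            for w, c in zip(self.words, self.categories)
            if c is not WordCategory.IGNORABLE
        ]

    @property
    def positive_words(self) -> set[str]:
        grouped = {i for g in self.or_groups for i in g}
        return {
            w
            for i, (w, c) in enumerate(zip(self.words, self.categories))
            if c is WordCategory.POSITIVE and i not in grouped
        }

    def words_in_category(self, category: WordCategory) -> set[str]:
        return {w for w, c in zip(self.words, self.categories) if c is category}


@dataclass
class TermStore:
    """Term records keyed by (dictionary, code) plus an inverted word index."""

    records: dict[tuple[Dictionary, str], TermRecord] = field(default_factory=dict)
    word_index: dict[str, set[tuple[Dictionary, str]]] = field(default_factory=dict)
    load_errors: list[str] = field(default_factory=list)

    def add(self, record: TermRecord) -> None:
        if record.key in self.records:
            raise TerminologyError(
                f"duplicate code {record.code!r} in dictionary {record.dictionary.value}"
            )
        self.records[record.key] = record
        self._index(record)

    def _index(self, record: TermRecord) -> None:
        for word, cat in zip(record.words, record.categories):
            if cat is not WordCategory.IGNORABLE:
                self.word_index.setdefault(word, set()).add(record.key)

    def reindex(self) -> None:
        self.word_index.clear()
        for record in self.records.values():
            self._index(record)

    def get(
        self, code: str, dictionary: Optional[Dictionary] = None
    ) -> Optional[TermRecord]:
        if dictionary is not None:
            return self.records.get((dictionary, code))
        for d in (Dictionary.READ, Dictionary.OXMIS, Dictionary.CUSTOM):
            rec = self.records.get((d, code))
            if rec is not None:
                return rec
        return None

    def lookup_word(self, word: str) -> set[tuple[Dictionary, str]]:
        return self.word_index.get(word, set())

    def matchable_records(self) -> Iterable[TermRecord]:
        return (r for r in self.records.values() if r.matchable)

    def all_words(self) -> set[str]:
        """Every standardised word of every record (the 'medical' lexicon)."""
        out: set[str] = set()
        for record in self.records.values():
            out.update(record.words)
        return out

    def __len__(self) -> int:
        return len(self.records)


def standardise_term_text(
    raw: str, abbreviations: Optional[Mapping[str, str]] = None
) -> list[str]:
    """Standardise a term wording into a list of lowercase words.

    Bracketed qualifiers ([D], [X], [M], [V]) and the terminology-only
    phrases NOS/NEC are removed; abbreviations listed in *abbreviations*
    are expanded to their full wording.  Idempotent.
    """
    abbreviations = abbreviations or {}
    text = _QUALIFIER_RE.sub(" ", raw).lower()
    words: list[str] = []
    for token in _WORD_RE.findall(text):
        token = token.replace("'", "")
        if token in abbreviations:
            words.extend(abbreviations[token].split())
        else:
            words.append(token)
    return words


def categorise_term_words(
    words: Sequence[str], pattern_table: Mapping[str, WordCategory]
) -> tuple[list[WordCategory], list[frozenset[int]]]:
    """Assign a match category to each term word and build "or" groups.

    Default category is POSITIVE; the pattern table overrides by word
    (stop-words IGNORABLE, laterality and common modifiers OPTIONAL).
    A negation marker ("without", "no", "not") is itself IGNORABLE and
    switches the following words to NEGATIVE.  Non-ignorable words joined
    by "or" form one alternative group (members become OPTIONAL; at least
    one must match).
    """
    categories: list[WordCategory] = []
    negated = False
    for word in words:
        if word in NEGATION_MARKERS:
            categories.append(WordCategory.IGNORABLE)
            negated = True
            continue
        cat = pattern_table.get(word, WordCategory.POSITIVE)
        if negated and cat is WordCategory.POSITIVE:
            cat = WordCategory.NEGATIVE
        categories.append(cat)

    or_groups: list[frozenset[int]] = []
    group: set[int] = set()
    for i, word in enumerate(words):
        if word != "or":
            continue
        prev = _nearest_member(categories, i, step=-1)
        nxt = _nearest_member(categories, i, step=+1)
        if prev is None or nxt is None:
            continue
        group.update((prev, nxt))
    if group:
        for i in group:
            categories[i] = WordCategory.OPTIONAL
        or_groups.append(frozenset(group))
    return categories, or_groups


def _nearest_member(
    categories: Sequence[WordCategory], start: int, step: int
) -> Optional[int]:
    i = start + step
    while 0 <= i < len(categories):
        if categories[i] is not WordCategory.IGNORABLE:
            return i
        i += step
    return None


def _make_record(
    code: str,
    dictionary: Dictionary,
    raw_text: str,
    abbreviations: Mapping[str, str],
    pattern_table: Mapping[str, WordCategory],
) -> TermRecord:
    words = standardise_term_text(raw_text, abbreviations)
    categories, or_groups = categorise_term_words(words, pattern_table)
    record = TermRecord(code, dictionary, raw_text, words, categories, or_groups)
    record.matchable = _is_matchable(record)
    return record


def _is_matchable(record: TermRecord) -> bool:
    n_non_ignorable = len(record.non_ignorable_words)
    if n_non_ignorable == 0 or n_non_ignorable > MAX_NON_IGNORABLE_WORDS:
        return False
    return bool(record.positive_words) or bool(record.or_groups)


def load_term_table(
    path: Union[str, Path],
    abbreviations: Optional[Mapping[str, str]] = None,
    pattern_table: Optional[Mapping[str, WordCategory]] = None,
) -> TermStore:
    """Load a terminology CSV (columns code, dictionary, term_text).

    Rows failing validation are recorded in ``store.load_errors`` rather
    than silently dropped; duplicate (dictionary, code) pairs raise.
    """
    abbreviations = abbreviations or {}
    pattern_table = pattern_table or {}
    store = TermStore()
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        required = {"code", "dictionary", "term_text"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise TerminologyError(
                f"terminology CSV must have columns {sorted(required)}; "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                dictionary = Dictionary(row["dictionary"].strip().upper())
                record = _make_record(
                    row["code"].strip(),
                    dictionary,
                    row["term_text"].strip(),
                    abbreviations,
                    pattern_table,
                )
                store.add(record)
            except TerminologyError as exc:
                if "duplicate" in str(exc):
                    raise
                store.load_errors.append(f"line {lineno}: {exc}")
            except ValueError as exc:
                store.load_errors.append(f"line {lineno}: {exc}")
    return store


def select_matchable_subset(
    store: TermStore, exclusion_prefixes: Iterable[str]
) -> TermStore:
    """Flag terms in excluded code classes as non-matchable (in place).

    Exclusions are code-prefix classes (administration, procedures,
    detailed injury causes).  The length bound is applied at load time;
    this re-applies it defensively.
    """
    prefixes = tuple(exclusion_prefixes)
    for record in store.records.values():
        if record.code.startswith(prefixes):
            record.matchable = False
        elif record.matchable:
            record.matchable = _is_matchable(record)
    store.reindex()
    return store


def add_custom_term(
    store: TermStore,
    code: str,
    text: str,
    abbreviations: Optional[Mapping[str, str]] = None,
    pattern_table: Optional[Mapping[str, WordCategory]] = None,
) -> TermStore:
    """Register a locally defined term under the CUSTOM dictionary."""
    record = _make_record(
        code, Dictionary.CUSTOM, text, abbreviations or {}, pattern_table or {}
    )
    store.add(record)
    return store


def load_word_categories(path: Union[str, Path]) -> dict[str, WordCategory]:
    """Load the word → default-category pattern table (CSV word,category)."""
    table: dict[str, WordCategory] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            table[row["word"].strip().lower()] = WordCategory(row["category"].strip())
    return table


def load_abbreviations(path: Union[str, Path]) -> dict[str, str]:
    """Load abbreviation → expansion table (CSV abbreviation,expansion)."""
    table: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            table[row["abbreviation"].strip().lower()] = row["expansion"].strip().lower()
    return table


def load_excluded_prefixes(path: Union[str, Path]) -> list[str]:
    with open(path, newline="", encoding="utf-8") as handle:
        return [row["prefix"].strip() for row in csv.DictReader(handle)]
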