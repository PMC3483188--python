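"""End-to-end analysis of one free-text record and its lookup tables.

The processing chain mirrors the tool's design: select the analysis mode
from the associated coded term, clean the text, tokenise, resolve words
against the lexicons (with single-edit spelling correction), assign
context attributes and quantities, match phrases to terminology, attempt
term refinement from the associated code, assemble value-attribute
output items and finally apply mode-specific rules.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Optional, Sequence, Union

from . import context as ctx
from . import matcher as m
from . import modes as md
from . import preprocess as pp
from . import terminology as tm

logger = logging.getLogger(__name__)

__all__ = ["Tables", "OutputItem", "RecordOutput", "load_tables",
           "assemble_output", "analyze_record", "default_table_dir"]

#: custom local codes registered on top of the terminology table
CUSTOM_TERMS = [
    ("RC0001", "Rhabdomyolysis"),
    ("RC0002", "Recently in hospital"),
]


@dataclass
class OutputItem:
    """One value-attribute pair of structured output."""

    kind: str  # term | number | duration | date | time | result
    value: Any
    attribute: Optional[str] = None
    negated: bool = False
    dictionary: Optional[str] = None
    term_text: Optional[str] = None
    date: Optional[dict] = None  # event date attached to a term
    position: tuple[int, int] = (0, 0)

    def to_dict(self) -> dict:
        out = {"kind": self.kind, "value": self.value}
        if self.attribute:
            out["attribute"] = self.attribute
        if self.negated:
            out["negated"] = True
        if self.dictionary:
            out["dictionary"] = self.dictionary
        if self.term_text:
            out["term_text"] = self.term_text
        if self.date:
            out["date"] = self.date
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "OutputItem":
        value = data["value"]
        if isinstance(value, list):  # JSON round-trip of tuples
            value = tuple(value)
        return cls(
            kind=data["kind"],
            value=value,
            attribute=data.get("attribute"),
            negated=data.get("negated", False),
            dictionary=data.get("dictionary"),
            term_text=data.get("term_text"),
            date=data.get("date"),
        )


@dataclass
class RecordOutput:
    record_id: str
    mode: str
    items: list[OutputItem] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)
    error: Optional[str] = None

    def to_dict(self) -> dict:
        out = {
            "record_id": self.record_id,
            "mode": self.mode,
            "items": [item.to_dict() for item in self.items],
        }
        if self.flags:
            out["flags"] = self.flags
        if self.error:
            out["error"] = self.error
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "RecordOutput":
        return cls(
            record_id=data["record_id"],
            mode=data["mode"],
            items=[OutputItem.from_dict(d) for d in data.get("items", [])],
            flags=data.get("flags", []),
            error=data.get("error"),
        )


@dataclass
class Tables:
    """All lookup tables and derived indexes needed to analyse records."""

    store: tm.TermStore
    lexicons: pp.Lexicons
    synonyms: m.SynonymTable
    patterns: list[ctx.AttributePattern]
    mode_triggers: list[md.ModeTrigger]
    category_table: dict[str, tm.WordCategory]
    abbreviations: dict[str, str]
    cleaning_rules: list[tuple[str, str]]
    config: m.MatcherConfig = field(default_factory=m.MatcherConfig)

    @property
    def stopwords(self) -> set[str]:
        return {
            w
            for w, c in self.category_table.items()
            if c is tm.WordCategory.IGNORABLE
        }


def default_table_dir() -> Path:
    return Path(resources.files("readcoder") / "tables")


def _load_cleaning_rules(path: Path) -> list[tuple[str, str]]:
    with open(path, newline="", encoding="utf-8") as handle:
        return [(row["pattern"], row["action"].strip())
                for row in csv.DictReader(handle)]


def load_tables(
    table_dir: Optional[Union[str, Path]] = None,
    config: Optional[m.MatcherConfig] = None,
    terms_path: Optional[Union[str, Path]] = None,
) -> Tables:
    """Load every lookup table from *table_dir* (default: packaged tables).

    *terms_path* overrides the terminology CSV, e.g. for a generated
    fixture terminology.
    """
    table_dir = Path(table_dir) if table_dir else default_table_dir()
    abbreviations = tm.load_abbreviations(table_dir / "abbreviations.csv")
    category_table = tm.load_word_categories(table_dir / "word_categories.csv")
    store = tm.load_term_table(
        terms_path or table_dir / "terms.csv", abbreviations, category_table
    )
    for code, text in CUSTOM_TERMS:
        if store.get(code, tm.Dictionary.CUSTOM) is None:
            tm.add_custom_term(store, code, text, abbreviations, category_table)
    tm.select_matchable_subset(
        store, tm.load_excluded_prefixes(table_dir / "excluded_prefixes.csv")
    )
    synonyms = m.load_synonyms(table_dir / "synonyms.csv")
    patterns = ctx.load_attribute_patterns(table_dir / "attrib_patterns.csv")
    medical = store.all_words()
    # synonym and attribute-pattern entries are part of the tool's vocabulary
    medical.update(
        w for rule in synonyms.rules
        for w in (*rule.source, *rule.replacement)
        if w.isalpha()
    )
    medical.update(
        w for p in patterns for w in p.trigger if w.isalpha()
    )
    lexicons = pp.Lexicons(
        medical=medical,
        general=pp.load_general_words(table_dir / "general_words.txt"),
    )
    return Tables(
        store=store,
        lexicons=lexicons,
        synonyms=synonyms,
        patterns=patterns,
        mode_triggers=md.load_mode_triggers(table_dir / "mode_triggers.csv"),
        category_table=category_table,
        abbreviations=abbreviations,
        cleaning_rules=_load_cleaning_rules(table_dir / "cleaning_rules.csv"),
        config=config or m.MatcherConfig(),
    )


# ---------------------------------------------------------------------------
# output assembly

_QUANTITY_ITEM_KINDS = {
    "systolic_bp": "number",
    "diastolic_bp": "number",
    "pulse": "number",
    "haemoglobin": "number",
    "lab_result": "number",
    "gestational_age": "duration",
    "follow_up": "duration",
    "time_of_death": "time",
    "admission_date": "date",
    "lmp_date": "date",
}


def assemble_output(
    candidates: Sequence[m.MatchCandidate],
    quantities: Sequence[ctx.QuantityFinding],
    tokens: Sequence[pp.Token],
    store: tm.TermStore,
) -> list[OutputItem]:
    """Order matched terms and quantity findings into output items.

    Term items may carry a blank attribute (a current/past diagnosis);
    every other item kind is invalid without one — findings always carry
    an attribute, and unclaimed numbers/dates/durations never become
    items.  Duplicate term codes are collapsed, keeping the earliest and
    merging any attribute or date it lacks.
    """
    items: list[OutputItem] = []
    for cand in candidates:
        record = store.records[(cand.dictionary, cand.code)]
        item = OutputItem(
            kind="term",
            value=cand.code,
            attribute=cand.attribute,
            negated=cand.negated,
            dictionary=cand.dictionary.value,
            term_text=record.raw_text,
            position=(cand.phrase.sentence_index, cand.phrase.start),
        )
        if cand.attribute == "past_history":
            item.date = _event_date(cand, tokens)
        items.append(item)

    for finding in quantities:
        kind = _QUANTITY_ITEM_KINDS.get(finding.attribute)
        if kind is None:
            continue
        value: Any = finding.value
        if kind == "duration":
            value = {"value": finding.value, "unit": finding.unit or "week"}
        items.append(
            OutputItem(kind=kind, value=value, attribute=finding.attribute,
                       position=(finding.sentence_index, finding.start))
        )

    items = _dedupe_terms(items)
    for item in items:
        assert item.kind == "term" or item.attribute, "non-term item lacks attribute"
    items.sort(key=lambda it: it.position)
    return items


def _event_date(
    cand: m.MatchCandidate, tokens: Sequence[pp.Token]
) -> Optional[dict]:
    """Date stated alongside a past-history diagnosis in the same sentence."""
    same_sentence = [
        t for t in tokens
        if t.sentence_index == cand.phrase.sentence_index
        and t.kind is pp.TokenKind.DATE
    ]
    after = [t for t in same_sentence if t.token_index >= cand.phrase.end]
    chosen = after[0] if after else (same_sentence[0] if same_sentence else None)
    return chosen.value if chosen else None


def _dedupe_terms(items: list[OutputItem]) -> list[OutputItem]:
    seen: dict[tuple, OutputItem] = {}
    out: list[OutputItem] = []
    for item in items:
        if item.kind != "term":
            out.append(item)
            continue
        key = (item.dictionary, item.value, item.negated)
        if key in seen:
            kept = seen[key]
            kept.attribute = kept.attribute or item.attribute
            kept.date = kept.date or item.date
            continue
        seen[key] = item
        out.append(item)
    return out


# ---------------------------------------------------------------------------
# per-record driver

def analyze_record(
    record_id: str,
    associated_code: Optional[str],
    text: str,
    tables: Tables,
    mode_override: Optional[md.Mode] = None,
    ignore_associated: bool = True,
) -> RecordOutput:
    """Run the full analysis chain on one record.

    With *ignore_associated* (the default, matching how coded displays
    repeat the associated term) a matched term identical to the
    associated code is kept only if nothing else was found for its span.
    """
    mode_ctx = md.select_mode(associated_code, text, tables.mode_triggers)
    if mode_override is not None:
        mode_ctx = md.ModeContext(mode_override, associated_code, "override",
                                  mode_ctx.accepts_normal_abnormal)
    mode = mode_ctx.mode.value

    cleaned = pp.clean_text(text, tables.cleaning_rules)
    tokens = pp.tokenize(cleaned)
    pp.resolve_tokens(tokens, tables.lexicons)

    anon = ctx.mark_anonymised(tokens)
    events = ctx.apply_patterns(tokens, tables.patterns, mode)
    spans = ctx.propagate_scopes(events, tokens) + anon
    quantities = ctx.extract_quantities(tokens, spans, mode)

    excluded = {(sp.sentence_index, i)
                for sp in anon for i in range(sp.start, sp.end)}
    phrases = m.candidate_phrases(tokens, excluded)
    candidates = m.best_match(
        phrases, tables.store, tables.synonyms, tables.config,
        tables.stopwords, spans,
    )
    if ignore_associated and associated_code:
        candidates = [c for c in candidates if c.code != associated_code]

    items = assemble_output(candidates, quantities, tokens, tables.store)

    refined = None
    if associated_code:
        text_words = {t.norm for t in tokens if t.is_word}
        refined = m.refine_term(associated_code, tables.store, text_words)
    if refined is not None and not any(
        it.kind == "term" and it.value == refined.code for it in items
    ):
        extra_words = set(refined.non_ignorable_words) - {
            w for w in (tables.store.get(associated_code) or refined).non_ignorable_words
        }
        position = min(
            ((t.sentence_index, t.token_index) for t in tokens
             if t.norm in extra_words),
            default=(0, 0),
        )
        items.append(
            OutputItem(kind="term", value=refined.code,
                       dictionary=refined.dictionary.value,
                       term_text=refined.raw_text, position=position)
        )

    items, flags = md.apply_mode_rules(mode_ctx, tokens, items)
    return RecordOutput(record_id=record_id, mode=mode, items=items, flags=flags)
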