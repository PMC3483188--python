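"""Context attributes: negation, history, anonymisation and quantities.

A table of phrase patterns (the attribute table) maps trigger words or
phrases to context attributes.  Trigger scopes are propagated over nearby
tokens by simple rules: a list scope runs forward across comma/'and'/'or'
joined items until 'but', other punctuation, a new trigger or the end of
the sentence; a next-value scope claims the nearest value token.  Quantity
attributes (blood pressure, pulse, haemoglobin, follow-up interval,
gestational age, laboratory result) convert classified tokens into typed
findings; only a single attribute can apply to each value.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .preprocess import LexiconStatus, Token, TokenKind

logger = logging.getLogger(__name__)

__all__ = [
    "Direction",
    "ScopeRule",
    "AttributePattern",
    "AttributedSpan",
    "QuantityFinding",
    "load_attribute_patterns",
    "apply_patterns",
    "propagate_scopes",
    "mark_anonymised",
    "extract_quantities",
]

#: controlled vocabulary of context and value attributes
ATTRIBUTE_VOCABULARY = frozenset(
    {
        "negative",
        "past_history",
        "family_history",
        "suspected",
        "anonymised",
        "cause_of_death",
        "mccd_1a",
        "mccd_1b",
        "mccd_1c",
        "mccd_2",
        "admission_date",
        "follow_up",
        "date_of_event",
        "date_of_death",
        "lmp_date",
        "sick_start",
        "sick_end",
        "sick_duration",
        "time_of_death",
        "systolic_bp",
        "diastolic_bp",
        "pulse",
        "haemoglobin",
        "lab_result",
        "gestational_age",
    }
)

#: attribute families: at most one attribute of a family applies to a token
CONTEXT_FAMILIES = {
    "negative": "negation",
    "past_history": "history",
    "family_history": "history",
    "suspected": "certainty",
    "anonymised": "anonymised",
    "cause_of_death": "death",
    "mccd_1a": "death",
    "mccd_1b": "death",
    "mccd_1c": "death",
    "mccd_2": "death",
}

_VALUE_KINDS = {
    TokenKind.NUMBER,
    TokenKind.DURATION,
    TokenKind.DATE,
    TokenKind.TIME,
    TokenKind.FRACTION,
}

_TITLES = {"mr", "mrs", "ms", "dr", "miss", "prof"}
_LIST_JOINERS = {"and", "or"}
_LIST_TERMINATOR = "but"

#: cue precedence when two findings claim one value token
_QUANTITY_PRECEDENCE = [
    "systolic_bp",
    "diastolic_bp",
    "gestational_age",
    "pulse",
    "haemoglobin",
    "follow_up",
    "time_of_death",
    "lab_result",
]


class Direction(str, Enum):
    FORWARD = "FORWARD"
    BACKWARD = "BACKWARD"
    SELF = "SELF"


class ScopeRule(str, Enum):
    LIST = "LIST"
    SENTENCE = "SENTENCE"
    NEXT_VALUE = "NEXT_VALUE"
    WINDOW_K = "WINDOW_K"


@dataclass(frozen=True)
class AttributePattern:
    pattern_id: str
    trigger: tuple[str, ...]
    attribute: str
    direction: Direction
    scope_rule: ScopeRule
    modes: frozenset[str]  # {"all"} or explicit mode names
    window: int = 1

    def __post_init__(self) -> None:
        if self.attribute not in ATTRIBUTE_VOCABULARY:
            raise ValueError(f"unknown attribute {self.attribute!r}")
        if self.scope_rule is ScopeRule.WINDOW_K and self.window < 1:
            raise ValueError("WINDOW_K requires k >= 1")

    def active_in(self, mode: str) -> bool:
        return "all" in self.modes or mode in self.modes


@dataclass(frozen=True)
class TriggerEvent:
    pattern: AttributePattern
    sentence_index: int
    start: int  # token index of first trigger token
    end: int  # half-open


@dataclass(frozen=True)
class AttributedSpan:
    sentence_index: int
    start: int
    end: int  # half-open, within one sentence
    attribute: str
    pattern_id: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("span must be non-empty")

    def covers(self, sentence_index: int, token_index: int) -> bool:
        return (
            sentence_index == self.sentence_index
            and self.start <= token_index < self.end
        )


@dataclass(frozen=True)
class QuantityFinding:
    attribute: str
    value: float | str
    sentence_index: int
    start: int
    end: int
    unit: Optional[str] = None


def load_attribute_patterns(path: Union[str, Path]) -> list[AttributePattern]:
    patterns: list[AttributePattern] = []
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            patterns.append(
                AttributePattern(
                    pattern_id=row["pattern_id"].strip(),
                    trigger=tuple(row["trigger"].strip().lower().split()),
                    attribute=row["attribute"].strip(),
                    direction=Direction(row["direction"].strip()),
                    scope_rule=ScopeRule(row["scope_rule"].strip()),
                    modes=frozenset(row["modes"].strip().lower().split("|")),
                    window=int(row.get("window") or 1),
                )
            )
    return patterns


# ---------------------------------------------------------------------------
# trigger detection and scope propagation

def _sentences(tokens: Sequence[Token]) -> dict[int, list[Token]]:
    out: dict[int, list[Token]] = {}
    for tok in tokens:
        out.setdefault(tok.sentence_index, []).append(tok)
    return out


def apply_patterns(
    tokens: Sequence[Token],
    patterns: Sequence[AttributePattern],
    mode: str = "standard",
) -> list[TriggerEvent]:
    """Find every pattern occurrence; longer triggers shadow shorter ones."""
    active = [p for p in patterns if p.active_in(mode)]
    events: list[TriggerEvent] = []
    for s_index, sent in sorted(_sentences(tokens).items()):
        norms = [t.norm for t in sent]
        taken: set[int] = set()
        i = 0
        while i < len(norms):
            best: Optional[AttributePattern] = None
            for pattern in active:
                k = len(pattern.trigger)
                if tuple(norms[i : i + k]) == pattern.trigger:
                    if best is None or k > len(best.trigger):
                        best = pattern
            if best is not None and i not in taken:
                k = len(best.trigger)
                events.append(TriggerEvent(best, s_index, i, i + k))
                taken.update(range(i, i + k))
                i += k
            else:
                i += 1
    return events


def propagate_scopes(
    events: Sequence[TriggerEvent], tokens: Sequence[Token]
) -> list[AttributedSpan]:
    """Extend each trigger to its scope; degenerate (empty) scopes are dropped."""
    by_sentence = _sentences(tokens)
    trigger_starts = {(e.sentence_index, e.start) for e in events}
    spans: list[AttributedSpan] = []
    for event in events:
        sent = by_sentence.get(event.sentence_index, [])
        span = _scope_for(event, sent, trigger_starts)
        if span is not None:
            spans.append(span)
    return spans


def _scope_for(
    event: TriggerEvent,
    sent: Sequence[Token],
    trigger_starts: set[tuple[int, int]],
) -> Optional[AttributedSpan]:
    pattern = event.pattern
    s = event.sentence_index
    if pattern.direction is Direction.SELF:
        return AttributedSpan(s, event.start, event.end, pattern.attribute,
                              pattern.pattern_id)

    if pattern.scope_rule is ScopeRule.NEXT_VALUE:
        indices = (
            range(event.end, len(sent))
            if pattern.direction is Direction.FORWARD
            else range(event.start - 1, -1, -1)
        )
        for i in indices:
            if sent[i].kind in _VALUE_KINDS:
                return AttributedSpan(s, i, i + 1, pattern.attribute,
                                      pattern.pattern_id)
        return None

    if pattern.scope_rule is ScopeRule.SENTENCE:
        if event.end >= len(sent):
            return None
        return AttributedSpan(s, event.end, len(sent), pattern.attribute,
                              pattern.pattern_id)

    if pattern.scope_rule is ScopeRule.WINDOW_K:
        end = min(event.end + pattern.window, len(sent))
        if end <= event.end:
            return None
        return AttributedSpan(s, event.end, end, pattern.attribute,
                              pattern.pattern_id)

    # LIST: forward across a comma/'and'/'or' joined list
    end = event.end
    while end < len(sent):
        tok = sent[end]
        if (s, end) in trigger_starts:
            break  # nearest trigger wins from here on
        if tok.norm == _LIST_TERMINATOR:
            break
        if tok.kind is TokenKind.PUNCT and tok.norm != ",":
            break
        end += 1
    if end <= event.end:
        return None
    return AttributedSpan(s, event.end, end, pattern.attribute, pattern.pattern_id)


def mark_anonymised(tokens: Sequence[Token]) -> list[AttributedSpan]:
    """Mark masked runs and probable names after personal titles."""
    spans: list[AttributedSpan] = []
    by_sentence = _sentences(tokens)
    for s_index, sent in sorted(by_sentence.items()):
        for i, tok in enumerate(sent):
            if tok.kind is TokenKind.WORD and set(tok.norm) == {"x"} and len(tok.norm) >= 2:
                spans.append(AttributedSpan(s_index, i, i + 1, "anonymised", "mask"))
                continue
            if tok.norm in _TITLES and i + 1 < len(sent):
                nxt = sent[i + 1]
                if nxt.kind is TokenKind.WORD and (
                    nxt.surface[:1].isupper()
                    or nxt.lexicon_status
                    in (LexiconStatus.UNKNOWN, LexiconStatus.NOT_A_WORD)
                    or set(nxt.norm) == {"x"}
                    or nxt.lexicon_status is LexiconStatus.GENERAL
                ):
                    spans.append(
                        AttributedSpan(s_index, i + 1, i + 2, "anonymised", "title")
                    )
    return spans


# ---------------------------------------------------------------------------
# quantity extraction

_BP_SYSTOLIC = (60, 300)
_BP_DIASTOLIC = (30, 200)
_PULSE_RANGE = (20, 300)


def _plausible_bp(num: int, den: int) -> bool:
    return (
        _BP_SYSTOLIC[0] <= num <= _BP_SYSTOLIC[1]
        and _BP_DIASTOLIC[0] <= den <= _BP_DIASTOLIC[1]
        and num > den
    )


def extract_quantities(
    tokens: Sequence[Token],
    spans: Sequence[AttributedSpan],
    mode: str = "standard",
) -> list[QuantityFinding]:
    """Convert value tokens with quantity cues into typed findings.

    Cue spans come from the attribute table (pulse, haemoglobin,
    follow-up, time of death); blood-pressure pairs and pregnancy-mode
    gestational ages are recognised from fraction tokens directly.  The
    first claim on a value token wins by attribute precedence; losing
    claims are logged.
    """
    findings: list[QuantityFinding] = []
    claimed: dict[tuple[int, int], str] = {}

    def claim(finding: QuantityFinding) -> None:
        key = (finding.sentence_index, finding.start)
        if key in claimed:
            logger.info(
                "value at %s already %s; dropping %s claim",
                key, claimed[key], finding.attribute,
            )
            return
        claimed[key] = finding.attribute
        findings.append(finding)

    span_map: dict[tuple[int, int], list[AttributedSpan]] = {}
    for span in spans:
        for i in range(span.start, span.end):
            span_map.setdefault((span.sentence_index, i), []).append(span)

    by_sentence = _sentences(tokens)

    # pass 1: fraction tokens (gestational age claims denominator-40 first)
    for s_index, sent in sorted(by_sentence.items()):
        for i, tok in enumerate(sent):
            if tok.kind is not TokenKind.FRACTION or tok.value is None:
                continue
            num, den = tok.value
            if mode == "pregnancy" and den == 40:
                claim(QuantityFinding("gestational_age", float(num), s_index, i, i + 1,
                                      unit="week"))
            elif _plausible_bp(num, den):
                tok.kind = TokenKind.BP_PAIR
                claim(QuantityFinding("systolic_bp", float(num), s_index, i, i + 1,
                                      unit="mmHg"))
                findings.append(
                    QuantityFinding("diastolic_bp", float(den), s_index, i, i + 1,
                                    unit="mmHg")
                )

    # pass 2: cue-driven findings in precedence order
    cue_order = {a: k for k, a in enumerate(_QUANTITY_PRECEDENCE)}
    cue_spans = sorted(
        (sp for sp in spans if sp.attribute in cue_order),
        key=lambda sp: (cue_order[sp.attribute], sp.sentence_index, sp.start),
    )
    for span in cue_spans:
        sent = by_sentence.get(span.sentence_index, [])
        for i in range(span.start, min(span.end, len(sent))):
            tok = sent[i]
            finding = _finding_from(span.attribute, tok, span.sentence_index, i)
            if finding is not None:
                claim(finding)

    # pass 3: bare pulse 'NUMBER bpm' handled via pattern table; labtest result
    if mode == "labtest":
        for s_index, sent in sorted(by_sentence.items()):
            for i, tok in enumerate(sent):
                if tok.kind is TokenKind.NUMBER and (s_index, i) not in claimed:
                    claim(QuantityFinding("lab_result", float(tok.value), s_index,
                                          i, i + 1))
                    break
            else:
                continue
            break

    return findings


def _finding_from(
    attribute: str, tok: Token, s_index: int, i: int
) -> Optional[QuantityFinding]:
    if attribute == "pulse" and tok.kind is TokenKind.NUMBER:
        if _PULSE_RANGE[0] <= tok.value <= _PULSE_RANGE[1]:
            return QuantityFinding("pulse", float(tok.value), s_index, i, i + 1,
                                   unit="beats/min")
    if attribute == "haemoglobin" and tok.kind is TokenKind.NUMBER:
        return QuantityFinding("haemoglobin", float(tok.value), s_index, i, i + 1,
                               unit="g/dL")
    if attribute == "follow_up" and tok.kind is TokenKind.DURATION:
        value, unit = tok.value
        return QuantityFinding("follow_up", _to_weeks(value, unit), s_index, i, i + 1,
                               unit="week")
    if attribute == "time_of_death" and tok.kind is TokenKind.TIME:
        return QuantityFinding("time_of_death", tok.value, s_index, i, i + 1)
    if attribute in ("admission_date", "lmp_date") and tok.kind is TokenKind.DATE:
        return QuantityFinding(attribute, tok.value, s_index, i, i + 1)
    return None


def _to_weeks(value: float, unit: str) -> float:
    factor = {"week": 1.0, "day": 1 / 7, "month": 52 / 12, "year": 52.0}[unit]
    return value * factor
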