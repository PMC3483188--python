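"""Analysis modes: record-level interpretation regimes.

Every free-text entry in UK primary-care records is attached to a coded
(associated) term; the class of that term selects how the text is read.
A death term switches on death-certificate parsing, a test term switches
on result capture, a sickness-certificate term turns dates into
certificate start/end dates, and so on.  Triggers are configured as code
prefixes (or exact codes, or a text cue) in a CSV table, checked in a
fixed priority order: death, pregnancy, labtest, normal, date, sicknote,
then standard as the default.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence, Union

from .preprocess import Token, TokenKind

logger = logging.getLogger(__name__)

__all__ = ["Mode", "ModeTrigger", "ModeContext", "load_mode_triggers",
           "select_mode", "apply_mode_rules"]


class Mode(str, Enum):
    STANDARD = "standard"
    DEATH = "death"
    PREGNANCY = "pregnancy"
    LABTEST = "labtest"
    NORMAL = "normal"
    DATE = "date"
    SICKNOTE = "sicknote"


_MODE_PRIORITY = [
    Mode.DEATH,
    Mode.PREGNANCY,
    Mode.LABTEST,
    Mode.NORMAL,
    Mode.DATE,
    Mode.SICKNOTE,
]


@dataclass(frozen=True)
class ModeTrigger:
    trigger: str
    kind: str  # prefix | code | text
    mode: Mode
    accepts_normal_abnormal: bool = False


@dataclass(frozen=True)
class ModeContext:
    mode: Mode
    associated_code: Optional[str] = None
    trigger_rule: Optional[str] = None
    accepts_normal_abnormal: bool = False


def load_mode_triggers(path: Union[str, Path]) -> list[ModeTrigger]:
    triggers: list[ModeTrigger] = []
    with open(path, newline="", encoding="utf-8") as handle:
        for row in csv.DictReader(handle):
            triggers.append(
                ModeTrigger(
                    trigger=row["trigger"].strip(),
                    kind=row["kind"].strip(),
                    mode=Mode(row["mode"].strip().lower()),
                    accepts_normal_abnormal=row.get("accepts_normal_abnormal", "0").strip()
                    in ("1", "true", "yes"),
                )
            )
    return triggers


def select_mode(
    associated_code: Optional[str],
    text: str,
    trigger_table: Sequence[ModeTrigger],
) -> ModeContext:
    """Pick the analysis mode; first matching trigger in priority order wins."""
    lowered = text.lower()
    for mode in _MODE_PRIORITY:
        for trig in trigger_table:
            if trig.mode is not mode:
                continue
            hit = (
                (trig.kind == "prefix" and associated_code is not None
                 and associated_code.startswith(trig.trigger))
                or (trig.kind == "code" and associated_code == trig.trigger)
                or (trig.kind == "text" and trig.trigger in lowered)
            )
            if hit:
                return ModeContext(mode, associated_code, f"{trig.kind}:{trig.trigger}",
                                   trig.accepts_normal_abnormal)
    return ModeContext(Mode.STANDARD, associated_code, None)


# ---------------------------------------------------------------------------
# mode-specific output rules (applied to assembled output items)

_MCCD_NORMS = {"1a": "mccd_1a", "ia": "mccd_1a",
               "1b": "mccd_1b", "ib": "mccd_1b",
               "1c": "mccd_1c", "ic": "mccd_1c",
               "ii": "mccd_2"}


def mccd_category_positions(
    tokens: Sequence[Token], mode: Mode
) -> list[tuple[int, int, str]]:
    """(sentence, token, attribute) for each death-certificate category marker.

    '1a'/'1b'/'1c' (or roman 'Ia'...'II') are markers wherever they occur;
    a bare number 2 counts only immediately before a word, to avoid
    swallowing ordinary quantities.
    """
    if mode is not Mode.DEATH:
        return []
    out: list[tuple[int, int, str]] = []
    toks = list(tokens)
    for i, tok in enumerate(toks):
        if tok.kind is TokenKind.WORD and tok.norm in _MCCD_NORMS:
            out.append((tok.sentence_index, tok.token_index, _MCCD_NORMS[tok.norm]))
        elif (
            tok.kind is TokenKind.NUMBER
            and tok.value == 2
            and i + 1 < len(toks)
            and toks[i + 1].kind is TokenKind.WORD
            and toks[i + 1].sentence_index == tok.sentence_index
        ):
            out.append((tok.sentence_index, tok.token_index, "mccd_2"))
    return out


def apply_mode_rules(
    mode_ctx: ModeContext,
    tokens: Sequence[Token],
    items: list,
) -> tuple[list, list[str]]:
    """Amend assembled output items per the active mode; returns (items, flags).

    Imports OutputItem lazily to avoid a module cycle; *items* is a list of
    ``pipeline.OutputItem``.
    """
    from .pipeline import OutputItem  # local import; modes amend pipeline output

    mode = mode_ctx.mode
    flags: list[str] = []

    if mode is Mode.DEATH:
        items = [it for it in items if it.attribute != "lab_result"]
        markers = mccd_category_positions(tokens, mode)
        for item in items:
            if item.kind != "term" or item.attribute:
                continue
            last = None
            for s, t, attr in markers:
                if (s, t) < item.position:
                    last = attr
            if last is not None:
                item.attribute = last
        for tok in tokens:
            if tok.kind is TokenKind.TIME and not any(
                it.kind == "time" for it in items
            ):
                items.append(OutputItem("time", tok.value, "time_of_death",
                                        position=(tok.sentence_index, tok.token_index)))
        dates = [t for t in tokens if t.kind is TokenKind.DATE
                 and t.value and t.value.get("day")]
        if dates and not any(it.attribute == "date_of_death" for it in items):
            tok = dates[0]
            items.append(OutputItem("date", tok.value, "date_of_death",
                                    position=(tok.sentence_index, tok.token_index)))

    elif mode in (Mode.LABTEST, Mode.NORMAL):
        has_numeric = any(it.attribute == "lab_result" for it in items)
        if mode is Mode.NORMAL:
            items = [it for it in items if it.attribute != "lab_result"]
            has_numeric = False
        if mode_ctx.accepts_normal_abnormal and not has_numeric:
            for tok in tokens:
                if tok.kind is TokenKind.WORD and tok.norm in ("normal", "abnormal"):
                    items.append(OutputItem("result", tok.norm, "lab_result",
                                            position=(tok.sentence_index,
                                                      tok.token_index)))
                    break

    elif mode is Mode.DATE:
        dates = [t for t in tokens if t.kind is TokenKind.DATE]
        items = [it for it in items if it.kind != "date"]
        if len(dates) == 1:
            tok = dates[0]
            items.append(OutputItem("date", tok.value, "date_of_event",
                                    position=(tok.sentence_index, tok.token_index)))
        elif len(dates) > 1:
            flags.append("ambiguous_date")
            logger.warning("date mode: %d dates found, none emitted", len(dates))

    elif mode is Mode.SICKNOTE:
        dates = [t for t in tokens if t.kind is TokenKind.DATE
                 and t.value and t.value.get("month")]
        attrs = ["sick_start", "sick_end"]
        for tok, attr in zip(dates, attrs):
            items.append(OutputItem("date", tok.value, attr,
                                    position=(tok.sentence_index, tok.token_index)))
        for tok in tokens:
            if tok.kind is TokenKind.DURATION:
                value, unit = tok.value
                items.append(OutputItem("duration", {"value": value, "unit": unit},
                                        "sick_duration",
                                        position=(tok.sentence_index, tok.token_index)))

    items.sort(key=lambda it: it.position)
    return items, flags
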