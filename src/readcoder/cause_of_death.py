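"""Underlying cause-of-death selection from prioritised record sources.

A death certificate (MCCD) Part I holds a causal sequence — Ia directly
leading to death, due to Ib, due to Ic — and the underlying cause is
conventionally the lowest lettered Part I entry; Part II lists
contributory conditions that are never the underlying cause.  For each
deceased patient, candidate causes are gathered from sources in
decreasing order of reliability: the structured MCCD area, free text that
states MCCD categories or 'cause of death', coded diagnoses on or after
the date of death, then any other free text attached to death records.
A single candidate resolves immediately; otherwise the highest-priority
non-empty source must either yield a single diagnosis or carry MCCD
categories (pick the lowest Part I letter); anything else is flagged for
manual review.  Coded diagnoses up to 90 days before death are gathered
only to assist that review.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from . import pipeline as pl
from .modes import Mode

__all__ = [
    "Source",
    "MccdCategory",
    "CauseCandidate",
    "CauseDecision",
    "PatientBundle",
    "BundleEvent",
    "gather_candidates",
    "select_underlying",
    "map_to_icd10",
    "load_icd10_map",
]

PRE_DEATH_WINDOW_DAYS = 90


class Source(str, Enum):
    MCCD_STRUCTURED = "mccd_structured"
    FREETEXT_MCCD = "freetext_mccd"
    FREETEXT_COD_STATED = "freetext_cod_stated"
    READ_ON_AFTER_DEATH = "read_on_after_death"
    FREETEXT_OTHER = "freetext_other"
    READ_BEFORE_DEATH = "read_before_death"


#: decreasing priority; FREETEXT_MCCD and FREETEXT_COD_STATED share a tier
SOURCE_TIER = {
    Source.MCCD_STRUCTURED: 1,
    Source.FREETEXT_MCCD: 2,
    Source.FREETEXT_COD_STATED: 2,
    Source.READ_ON_AFTER_DEATH: 3,
    Source.FREETEXT_OTHER: 4,
}


class MccdCategory(str, Enum):
    IA = "1a"
    IB = "1b"
    IC = "1c"
    II = "2"


#: Part I depth: the lowest lettered entry is the underlying cause
_PART_I_DEPTH = {MccdCategory.IA: 0, MccdCategory.IB: 1, MccdCategory.IC: 2}


@dataclass(frozen=True)
class CauseCandidate:
    source: Source
    code: str
    mccd_category: Optional[MccdCategory] = None
    icd10: Optional[str] = None
    event_date: Optional[dt.date] = None

    def __post_init__(self) -> None:
        if self.mccd_category is not None and self.source not in (
            Source.MCCD_STRUCTURED, Source.FREETEXT_MCCD
        ):
            raise ValueError(
                f"{self.source.value} candidates cannot carry an MCCD category"
            )


class DecisionStatus(str, Enum):
    RESOLVED = "resolved"
    MANUAL_REVIEW = "manual_review"
    NO_CAUSE = "no_cause"


@dataclass(frozen=True)
class CauseDecision:
    status: DecisionStatus
    underlying: Optional[CauseCandidate] = None
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.status is DecisionStatus.RESOLVED and self.underlying is None:
            raise ValueError("resolved decision requires an underlying cause")


@dataclass(frozen=True)
class BundleEvent:
    date: Optional[dt.date]
    code: Optional[str] = None
    text: Optional[str] = None
    mccd_category: Optional[MccdCategory] = None
    structured_mccd: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "BundleEvent":
        date = data.get("date")
        return cls(
            date=dt.date.fromisoformat(date) if date else None,
            code=data.get("code"),
            text=data.get("text"),
            mccd_category=(
                MccdCategory(data["mccd_category"]) if data.get("mccd_category") else None
            ),
            structured_mccd=bool(data.get("structured_mccd")),
        )


@dataclass(frozen=True)
class PatientBundle:
    patient_id: str
    death_date: Optional[dt.date]
    events: tuple[BundleEvent, ...]

    @classmethod
    def from_dict(cls, data: dict) -> "PatientBundle":
        return cls(
            patient_id=str(data["patient_id"]),
            death_date=(
                dt.date.fromisoformat(data["death_date"])
                if data.get("death_date")
                else None
            ),
            events=tuple(BundleEvent.from_dict(e) for e in data.get("events", [])),
        )


_MCCD_ATTRS = {
    "mccd_1a": MccdCategory.IA,
    "mccd_1b": MccdCategory.IB,
    "mccd_1c": MccdCategory.IC,
    "mccd_2": MccdCategory.II,
}


def gather_candidates(
    bundle: PatientBundle,
    tables: pl.Tables,
    icd10_map: Optional[Mapping[str, str]] = None,
) -> list[CauseCandidate]:
    """Label candidate causes by source; free text is analysed in death mode."""
    if bundle.death_date is None:
        raise ValueError(f"bundle {bundle.patient_id} has no death date")
    icd10_map = icd10_map or {}
    candidates: list[CauseCandidate] = []

    def add(source: Source, code: str, category=None, date=None) -> None:
        candidates.append(
            CauseCandidate(
                source=source,
                code=code,
                mccd_category=category,
                icd10=icd10_map.get(code),
                event_date=date,
            )
        )

    for i, event in enumerate(bundle.events):
        if event.structured_mccd and event.code:
            add(Source.MCCD_STRUCTURED, event.code, event.mccd_category, event.date)
            continue
        if event.text:
            output = pl.analyze_record(
                f"{bundle.patient_id}:{i}", event.code, event.text, tables,
                mode_override=Mode.DEATH,
            )
            for item in output.items:
                if item.kind != "term" or item.negated:
                    continue
                if item.attribute in _MCCD_ATTRS:
                    add(Source.FREETEXT_MCCD, item.value,
                        _MCCD_ATTRS[item.attribute], event.date)
                elif item.attribute == "cause_of_death":
                    add(Source.FREETEXT_COD_STATED, item.value, date=event.date)
                elif not item.attribute:
                    add(Source.FREETEXT_OTHER, item.value, date=event.date)
        elif event.code:
            if event.date is None:
                continue
            if event.date >= bundle.death_date:
                add(Source.READ_ON_AFTER_DEATH, event.code, date=event.date)
            elif (bundle.death_date - event.date).days <= PRE_DEATH_WINDOW_DAYS:
                add(Source.READ_BEFORE_DEATH, event.code, date=event.date)
    return candidates


def _mccd_part_ii_ok(cand: CauseCandidate) -> bool:
    return cand.mccd_category is not MccdCategory.II


def select_underlying(candidates: Sequence[CauseCandidate]) -> CauseDecision:
    """Apply the prioritised selection rules to the gathered candidates.

    READ_BEFORE_DEATH candidates only support manual review and are never
    auto-selected.
    """
    eligible = [c for c in candidates if c.source in SOURCE_TIER
                and _mccd_part_ii_ok(c)]
    support_only = [c for c in candidates if c.source is Source.READ_BEFORE_DEATH]
    if not eligible:
        if support_only:
            return CauseDecision(DecisionStatus.MANUAL_REVIEW,
                                 rationale="only pre-death coded diagnoses")
        return CauseDecision(DecisionStatus.NO_CAUSE, rationale="no candidates")

    distinct = {c.code for c in eligible}
    if len(distinct) == 1:
        return CauseDecision(DecisionStatus.RESOLVED, eligible[0],
                             rationale="single recorded cause")

    best_tier = min(SOURCE_TIER[c.source] for c in eligible)
    tier = [c for c in eligible if SOURCE_TIER[c.source] == best_tier]
    tier_codes = {c.code for c in tier}
    if len(tier_codes) == 1:
        return CauseDecision(DecisionStatus.RESOLVED, tier[0],
                             rationale="single diagnosis in top source")

    categorised = [c for c in tier if c.mccd_category in _PART_I_DEPTH]
    if categorised:
        deepest = max(categorised,
                      key=lambda c: _PART_I_DEPTH[c.mccd_category])
        return CauseDecision(DecisionStatus.RESOLVED, deepest,
                             rationale="lowest lettered Part I entry")

    return CauseDecision(DecisionStatus.MANUAL_REVIEW,
                         rationale="multiple uncategorised candidates")


def load_icd10_map(path: Union[str, Path]) -> dict[str, str]:
    with open(path, newline="", encoding="utf-8") as handle:
        return {
            row["read_code"].strip(): row["icd10_code"].strip()
            for row in csv.DictReader(handle)
        }


def map_to_icd10(
    code: str, icd10_map: Mapping[str, str]
) -> tuple[Optional[str], bool]:
    """Direct table lookup; (icd10 or None, mapped?).  Never guesses."""
    mapped = icd10_map.get(code)
    return mapped, mapped is not None
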