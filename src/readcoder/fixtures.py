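"""Fixture terminology and synthetic gold-annotated corpora.

Real UK primary-care free text cannot be redistributed, and the full
licensed Read/OXMIS dictionaries cannot be shipped.  This module builds a
fixture terminology (the curated seed table plus generated distractor
terms) and generates synthetic GP-style corpora — short texts with
diagnoses, negated symptom lists, single-edit misspellings, blood
pressures, pulse rates, lab values, UK dates and death-certificate
notes — each carrying its own gold-standard structured annotation.
Where a seed entry has no official published code, the code is a
synthetic project-assigned placeholder in the same style.
"""

from __future__ import annotations

import csv
import io
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

from .pipeline import OutputItem, Tables, default_table_dir, load_tables

__all__ = [
    "GoldAnnotation",
    "SyntheticRecord",
    "build_fixture_terminology",
    "generate_synthetic_corpus",
    "WORKED_EXAMPLES",
]

#: word pool for generated distractor terms (medical-flavoured vocabulary)
_FILLER_WORD_POOL = [
    "gastritis", "dermatitis", "nephritis", "colitis", "hepatitis",
    "bronchitis", "sinusitis", "cellulitis", "phlebitis", "tonsillitis",
    "anaemia", "asthma", "eczema", "gout", "migraine", "psoriasis",
    "ulcer", "polyp", "cyst", "abscess", "hernia", "fistula",
    "acute", "chronic", "recurrent", "benign", "malignant", "mild",
    "gastric", "duodenal", "renal", "hepatic", "cardiac", "pulmonary",
    "cervical", "lumbar", "femoral", "radial", "cranial", "pelvic",
]

#: diseases safe for text generation: standardised wordings are pairwise
#: distinct and match their own term at full score
_GENERATION_CODES = [
    ("G30..00", "mi"),
    ("G573000", None),
    ("G580.00", None),
    ("G801.00", None),
    ("H262.00", None),
    ("486B", None),
    ("A38..00", None),
    ("B902.00", None),
    ("H3z..00", None),
    ("Eu02z00", None),
    ("B576.00", None),
    ("G674.00", None),
]

#: symptom-style single-word negatables drawn from the seed terminology
_NEGATABLE_TERMS = [("486", "pneumonia"), ("G573000", "atrial fibrillation"),
                    ("G801.00", "deep vein thrombosis")]


@dataclass(frozen=True)
class GoldAnnotation:
    record_id: str
    items: tuple[OutputItem, ...]
    note: str = ""


@dataclass(frozen=True)
class SyntheticRecord:
    record_id: str
    associated_code: Optional[str]
    text: str
    gold: GoldAnnotation


def _seed_rows() -> list[dict[str, str]]:
    with open(default_table_dir() / "terms.csv", newline="", encoding="utf-8") as f:
        return list(csv.DictReader(f))


def build_fixture_terminology(
    seed: int, n_filler: int, out_path: Optional[Union[str, Path]] = None
) -> str:
    """Seed terminology plus *n_filler* deterministic distractor terms.

    Returns the CSV text; optionally also writes it to *out_path*.
    Filler codes use a reserved ``ZZ`` prefix and never collide with the
    seed codes.
    """
    rng = random.Random(seed)
    rows = _seed_rows()
    taken = {row["code"] for row in rows}
    for i in range(n_filler):
        code = f"ZZ{i:04d}0"
        assert code not in taken
        n_words = rng.choice([1, 2, 2, 3])
        words = rng.sample(_FILLER_WORD_POOL, n_words)
        rows.append(
            {"code": code, "dictionary": "READ",
             "term_text": " ".join(words).capitalize()}
        )
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=["code", "dictionary", "term_text"])
    writer.writeheader()
    writer.writerows(rows)
    text = buf.getvalue()
    if out_path is not None:
        Path(out_path).write_text(text, encoding="utf-8", newline="")
    return text


# ---------------------------------------------------------------------------
# synthetic corpora

def _term_item(code: str, tables: Tables, negated: bool = False,
               attribute: Optional[str] = None) -> OutputItem:
    record = tables.store.get(code)
    assert record is not None, code
    return OutputItem(kind="term", value=code, negated=negated,
                      attribute=attribute, dictionary=record.dictionary.value,
                      term_text=record.raw_text)


def _term_phrase(code: str, tables: Tables) -> str:
    record = tables.store.get(code)
    return " ".join(record.words)


def _misspell(word: str, rng: random.Random) -> str:
    """Drop one interior letter (recoverable by a single insertion)."""
    if len(word) < 5:
        return word
    i = rng.randrange(1, len(word) - 1)
    return word[:i] + word[i + 1:]


def generate_synthetic_corpus(
    seed: int,
    n_records: int,
    profile: str = "general",
    misspelling_rate: float = 0.05,
    tables: Optional[Tables] = None,
) -> list[SyntheticRecord]:
    """Generate *n_records* gold-annotated GP-style texts.

    *profile* is ``general`` (diagnoses, negation lists, quantities) or
    ``death`` (certificate-style notes).  The misspelling rate is the
    per-record probability of injecting one single-deletion typo into a
    diagnosis word; gold annotations are unaffected (a typo may therefore
    cost recall, as in real text).
    """
    if profile not in ("general", "death"):
        raise ValueError(f"unknown profile {profile!r}")
    tables = tables or load_tables()
    rng = random.Random(seed)
    records: list[SyntheticRecord] = []
    for i in range(n_records):
        rid = f"{profile[0]}{i:05d}"
        if profile == "death":
            rec = _death_record(rid, rng, tables)
        else:
            rec = _general_record(rid, rng, tables)
        if misspelling_rate > 0 and rng.random() < misspelling_rate:
            rec = _inject_typo(rec, rng)
        records.append(rec)
    return records


def _pick_codes(rng: random.Random, k: int) -> list[str]:
    return [c for c, _ in rng.sample(_GENERATION_CODES, k)]


def _general_record(rid: str, rng: random.Random, tables: Tables) -> SyntheticRecord:
    template = rng.randrange(6)
    if template == 0:  # plain diagnosis
        (code,) = _pick_codes(rng, 1)
        text = _term_phrase(code, tables)
        items = (_term_item(code, tables),)
    elif template == 1:  # negated list
        k = rng.choice([1, 2, 3])
        codes = [c for c, w in rng.sample(_NEGATABLE_TERMS, k)]
        names = [_term_phrase(c, tables) for c in codes]
        if k == 1:
            text = f"no {names[0]}"
        else:
            text = "no " + ", ".join(names[:-1]) + " or " + names[-1]
        items = tuple(_term_item(c, tables, negated=True) for c in codes)
    elif template == 2:  # past history
        (code,) = _pick_codes(rng, 1)
        text = f"h/o {_term_phrase(code, tables)}"
        items = (_term_item(code, tables, attribute="past_history"),)
    elif template == 3:  # blood pressure + diagnosis
        sys = rng.randrange(110, 220)
        dia = rng.randrange(55, min(sys - 10, 115))
        (code,) = _pick_codes(rng, 1)
        text = f"bp {sys}/{dia}, {_term_phrase(code, tables)}"
        items = (
            OutputItem(kind="number", value=float(sys), attribute="systolic_bp"),
            OutputItem(kind="number", value=float(dia), attribute="diastolic_bp"),
            _term_item(code, tables),
        )
    elif template == 4:  # pulse
        pulse = rng.randrange(40, 140)
        text = f"pulse {pulse} regular"
        items = (OutputItem(kind="number", value=float(pulse), attribute="pulse"),)
    else:  # follow-up interval
        weeks = rng.choice([1, 2, 4, 6, 8, 12])
        (code,) = _pick_codes(rng, 1)
        text = f"{_term_phrase(code, tables)} recheck {weeks}w"
        items = (
            _term_item(code, tables),
            OutputItem(kind="duration", value={"value": float(weeks), "unit": "week"},
                       attribute="follow_up"),
        )
    return SyntheticRecord(rid, "55...11", text, GoldAnnotation(rid, items))


def _death_record(rid: str, rng: random.Random, tables: Tables) -> SyntheticRecord:
    template = rng.randrange(3)
    if template == 0:  # MCCD category note
        k = rng.choice([1, 2, 3])
        codes = _pick_codes(rng, k)
        labels = ["1a", "1b", "1c"][:k]
        parts = [f"{lab} {_term_phrase(c, tables)}"
                 for lab, c in zip(labels, codes)]
        text = ", ".join(parts)
        items = tuple(
            _term_item(c, tables, attribute=f"mccd_{lab}")
            for lab, c in zip(labels, codes)
        )
    elif template == 1:  # time of death note
        hh, mm = rng.randrange(24), rng.randrange(60)
        (code,) = _pick_codes(rng, 1)
        text = f"cd {hh:02d}{mm:02d}hrs, {_term_phrase(code, tables)}"
        items = (
            OutputItem(kind="time", value=f"{hh:02d}:{mm:02d}",
                       attribute="time_of_death"),
            _term_item(code, tables),
        )
    else:  # sudden death
        (code,) = _pick_codes(rng, 1)
        text = f"{_term_phrase(code, tables)}, sudden death"
        items = (
            _term_item(code, tables),
            _term_item("T4002", tables),
        )
    return SyntheticRecord(rid, "22J..12", text, GoldAnnotation(rid, items))


def _inject_typo(rec: SyntheticRecord, rng: random.Random) -> SyntheticRecord:
    words = rec.text.split()
    long_idx = [i for i, w in enumerate(words) if len(w) >= 5 and w.isalpha()]
    if not long_idx:
        return rec
    i = rng.choice(long_idx)
    words[i] = _misspell(words[i], rng)
    return SyntheticRecord(rec.record_id, rec.associated_code,
                           " ".join(words), rec.gold)


# ---------------------------------------------------------------------------
# worked examples: published rows of GP free text with known structured output

WORKED_EXAMPLES = [
    {
        "record_id": "wx_angio",
        "associated_code": "55...11",
        "text": "coronary severe triple vessel disease + impaired function",
    },
    {
        "record_id": "wx_htn",
        "associated_code": "G20..00",
        "text": (
            "176/100 but only taking doxaz 4mg od not bd as pw intended - "
            "increase to 4mg bd, pn recheck 4w please. otherwise isq but "
            "recent diagnosis ca prostate - seeing urol 1w - reassured re "
            "treatablility of this nowadays"
        ),
    },
    {
        "record_id": "wx_ecg",
        "associated_code": "32...00",
        "text": "sinus bradycardia (58 bpm) nonspecific intraventricular conduction delay",
    },
    {
        "record_id": "wx_angiogram",
        "associated_code": "55...12",
        "text": "ct did not show renal artery stenosis.",
    },
    {
        "record_id": "wx_lvf",
        "associated_code": "G581.00",
        "text": "acute give lasix and o2 and admitted",
    },
    {
        "record_id": "wx_mi",
        "associated_code": "14A4.00",
        "text": "had an mi in 1996",
    },
    {
        "record_id": "wx_death",
        "associated_code": "22J..12",
        "text": (
            "found dead by family this afternoon, called ambulance, "
            "cd 1415hrs, sudden death, rpt to coroner"
        ),
    },
    {
        "record_id": "wx_labtest",
        "associated_code": "42J..00",
        "text": "original result: 'neutrophil count' = 4.17 x109 / l (1. 5 - 7. 5)",
    },
    {
        "record_id": "wx_sicknote",
        "associated_code": "9D2..00",
        "text": "### 09/01/2007 1 month heart problems, ###",
    },
]
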