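"""Underlying cause-of-death selection over per-patient bundles."""

import pytest

from readcoder.cause_of_death import (
    CauseCandidate,
    DecisionStatus,
    MccdCategory,
    PatientBundle,
    Source,
    gather_candidates,
    load_icd10_map,
    map_to_icd10,
    select_underlying,
)
from readcoder.pipeline import default_table_dir


def cand(source, code, category=None):
    return CauseCandidate(source=source, code=code, mccd_category=category)


def bundle(events, pid="p1", death="2001-06-01"):
    return PatientBundle.from_dict(
        {"patient_id": pid, "death_date": death, "events": events}
    )


def test_lowest_part_i_entry_selected():
    """Ia pneumonia / Ib stroke / Ic AF resolves to the Ic entry."""
    candidates = [
        cand(Source.FREETEXT_MCCD, "H262.00", MccdCategory.IA),
        cand(Source.FREETEXT_MCCD, "G66..00", MccdCategory.IB),
        cand(Source.FREETEXT_MCCD, "G573000", MccdCategory.IC),
    ]
    decision = select_underlying(candidates)
    assert decision.status is DecisionStatus.RESOLVED
    assert decision.underlying.code == "G573000"


def test_single_candidate_resolves():
    decision = select_underlying([cand(Source.FREETEXT_OTHER, "486B")])
    assert decision.status is DecisionStatus.RESOLVED
    assert decision.underlying.code == "486B"


def test_multiple_uncategorised_flag_manual_review():
    decision = select_underlying(
        [cand(Source.FREETEXT_OTHER, "486B"), cand(Source.FREETEXT_OTHER, "G66..00")]
    )
    assert decision.status is DecisionStatus.MANUAL_REVIEW


def test_no_candidates_is_no_cause():
    assert select_underlying([]).status is DecisionStatus.NO_CAUSE


def test_part_ii_never_underlying():
    candidates = [
        cand(Source.FREETEXT_MCCD, "Eu02z00", MccdCategory.II),
        cand(Source.FREETEXT_MCCD, "H262.00", MccdCategory.IA),
    ]
    decision = select_underlying(candidates)
    assert decision.underlying.code == "H262.00"
    only_ii = select_underlying([cand(Source.FREETEXT_MCCD, "Eu02z00",
                                      MccdCategory.II)])
    assert only_ii.status is not DecisionStatus.RESOLVED


def test_priority_respected_when_lower_sources_added():
    top = [cand(Source.MCCD_STRUCTURED, "G30..00", MccdCategory.IA)]
    base = select_underlying(top)
    widened = select_underlying(
        top + [cand(Source.FREETEXT_OTHER, "486B"),
               cand(Source.READ_ON_AFTER_DEATH, "G66..00")]
    )
    assert base.status is widened.status is DecisionStatus.RESOLVED
    assert base.underlying.code == widened.underlying.code == "G30..00"


def test_decision_deterministic():
    candidates = [
        cand(Source.FREETEXT_MCCD, "H262.00", MccdCategory.IA),
        cand(Source.FREETEXT_MCCD, "G573000", MccdCategory.IC),
        cand(Source.FREETEXT_OTHER, "486B"),
    ]
    results = {select_underlying(list(reversed(candidates))).underlying.code
               for _ in range(3)} | {select_underlying(candidates).underlying.code}
    assert results == {"G573000"}


def test_gather_candidates_sources(tables):
    b = bundle(
        [
            {"date": "2001-06-01", "structured_mccd": True, "code": "G30..00",
             "mccd_category": "1a"},
            {"date": "2001-06-01", "code": "22J..12",
             "text": "1a aspiration pneumonia 1b stroke"},
            {"date": "2001-06-02", "code": "G66..00"},
            {"date": "2001-05-01", "code": "B902.00"},
            {"date": "2000-01-01", "code": "G20..00"},  # outside 90-day window
        ]
    )
    candidates = gather_candidates(b, tables)
    by_source = {}
    for c in candidates:
        by_source.setdefault(c.source, []).append(c)
    assert [c.code for c in by_source[Source.MCCD_STRUCTURED]] == ["G30..00"]
    assert {(c.code, c.mccd_category) for c in by_source[Source.FREETEXT_MCCD]} == {
        ("H262.00", MccdCategory.IA), ("G66..00", MccdCategory.IB)
    }
    assert [c.code for c in by_source[Source.READ_ON_AFTER_DEATH]] == ["G66..00"]
    assert [c.code for c in by_source[Source.READ_BEFORE_DEATH]] == ["B902.00"]
    assert "G20..00" not in {c.code for c in candidates}


def test_gather_requires_death_date(tables):
    with pytest.raises(ValueError, match="death date"):
        gather_candidates(bundle([], death=None), tables)


def test_cod_stated_free_text(tables):
    b = bundle([{"date": "2001-06-01", "code": "22J..12",
                 "text": "cause of death bronchopneumonia"}])
    candidates = gather_candidates(b, tables)
    assert [(c.source, c.code) for c in candidates] == [
        (Source.FREETEXT_COD_STATED, "486B")
    ]


def test_map_to_icd10():
    icd10_map = load_icd10_map(default_table_dir() / "read_icd10_map.csv")
    assert map_to_icd10("G30..00", icd10_map) == ("I21.9", True)
    assert map_to_icd10("ABSENT", icd10_map) == (None, False)
    assert map_to_icd10("G30..00", {}) == (None, False)
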