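"""Attribute triggers, scope propagation, anonymisation and quantities."""

import pytest
from hypothesis import given, settings, strategies as st

from readcoder import preprocess as pp
from readcoder.context import (
    apply_patterns,
    extract_quantities,
    mark_anonymised,
    propagate_scopes,
)


def prep(text, tables, mode="standard"):
    tokens = pp.tokenize(pp.clean_text(text, tables.cleaning_rules))
    pp.resolve_tokens(tokens, tables.lexicons)
    events = apply_patterns(tokens, tables.patterns, mode)
    spans = propagate_scopes(events, tokens)
    return tokens, events, spans


def covered_norms(tokens, spans, attribute):
    out = set()
    for span in spans:
        if span.attribute != attribute:
            continue
        for t in tokens:
            if span.covers(t.sentence_index, t.token_index):
                out.add(t.norm)
    return out


def test_negative_list_scope(tables):
    tokens, events, spans = prep("no pneumonia, stroke or dementia", tables)
    assert len([e for e in events if e.pattern.attribute == "negative"]) == 1
    neg = covered_norms(tokens, spans, "negative")
    assert {"pneumonia", "stroke", "dementia"} <= neg


def test_negative_scope_terminated_by_but(tables):
    tokens, _, spans = prep("no chest pain but breathless", tables)
    neg = covered_norms(tokens, spans, "negative")
    assert "chest" in neg and "breathless" not in neg


def test_longer_trigger_shadows_shorter(tables):
    _, events, _ = prep("ct did not show renal artery stenosis.", tables)
    negs = [e for e in events if e.pattern.attribute == "negative"]
    assert [e.pattern.pattern_id for e in negs] == ["neg_did_not_show"]


def test_scope_never_crosses_sentence(tables):
    tokens, _, spans = prep("no pneumonia. dementia present", tables)
    neg = covered_norms(tokens, spans, "negative")
    assert "dementia" not in neg


def test_trigger_at_sentence_end_discarded(tables):
    _, _, spans = prep("pneumonia excluded? no", tables)
    assert all(s.attribute != "negative" for s in spans)


def test_no_triggers_no_spans(tables):
    _, events, spans = prep("mitral valve disease", tables)
    assert events == [] and spans == []


def test_mode_gating_of_patterns(tables):
    _, events, _ = prep("cd 1415hrs", tables, mode="standard")
    assert all(e.pattern.attribute != "time_of_death" for e in events)
    _, events, _ = prep("cd 1415hrs", tables, mode="death")
    assert any(e.pattern.attribute == "time_of_death" for e in events)


def test_mark_anonymised_title_and_mask(tables):
    for text, expected_norm in [("Mr. XXX seen", "xxx"), ("dr jones reviewed", "jones")]:
        tokens = pp.tokenize(pp.clean_text(text, tables.cleaning_rules))
        pp.resolve_tokens(tokens, tables.lexicons)
        spans = mark_anonymised(tokens)
        marked = {t.norm for s in spans for t in tokens
                  if s.covers(t.sentence_index, t.token_index)}
        assert expected_norm in marked
    tokens = pp.tokenize("mitral valve")
    assert mark_anonymised(tokens) == []


@pytest.mark.parametrize(
    "text, mode, expected",
    [
        ("176/100 today", "standard",
         {("systolic_bp", 176.0), ("diastolic_bp", 100.0)}),
        ("sinus bradycardia (58 bpm)", "standard", {("pulse", 58.0)}),
        ("hb 14.3", "standard", {("haemoglobin", 14.3)}),
        ("recheck 4w", "standard", {("follow_up", 4.0)}),
        ("22/40 today", "pregnancy", {("gestational_age", 22.0)}),
        ("22/40 today", "standard", set()),  # not BP-plausible, not pregnant
    ],
)
def test_extract_quantities(tables, text, mode, expected):
    tokens, _, spans = prep(text, tables, mode)
    findings = extract_quantities(tokens, spans, mode)
    assert {(f.attribute, f.value) for f in findings} == expected


def test_single_attribute_per_value(tables):
    # pulse cue and bpm suffix both point at 72: one finding only
    tokens, _, spans = prep("pulse 72 bpm", tables)
    findings = extract_quantities(tokens, spans, "standard")
    assert [f.attribute for f in findings] == ["pulse"]


@given(st.lists(st.sampled_from(["pneumonia", "stroke", "dementia", "valve",
                                 "mitral", "fracture", "femur"]),
                min_size=1, max_size=8))
@settings(derandomize=True, max_examples=50, deadline=None)
def test_no_spontaneous_attributes(tables, words):
    """Texts without trigger words never produce attribute spans."""
    _, events, spans = prep(" ".join(words), tables)
    assert events == [] and spans == []
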