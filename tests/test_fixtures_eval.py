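"""Fixture generation determinism and evaluation arithmetic."""

import csv
import io

import pytest

from readcoder import analyze_record
from readcoder.evaluate import EvalOptions, EvalResult, item_key, score_outputs
from readcoder.fixtures import build_fixture_terminology, generate_synthetic_corpus
from readcoder.pipeline import OutputItem, RecordOutput


def test_fixture_terminology_deterministic_and_collision_free():
    a = build_fixture_terminology(seed=1, n_filler=100)
    b = build_fixture_terminology(seed=1, n_filler=100)
    assert a == b
    rows = list(csv.DictReader(io.StringIO(a)))
    codes = [r["code"] for r in rows]
    assert len(codes) == len(set(codes))
    filler = {c for c in codes if c.startswith("ZZ")}
    assert len(filler) == 100
    base = list(csv.DictReader(io.StringIO(build_fixture_terminology(1, 0))))
    assert not filler & {r["code"] for r in base}
    assert {r["code"] for r in base} == set(codes) - filler


def test_corpus_determinism_and_empty():
    a = generate_synthetic_corpus(3, 25, "general")
    b = generate_synthetic_corpus(3, 25, "general")
    assert [(r.record_id, r.text) for r in a] == [(r.record_id, r.text) for r in b]
    assert generate_synthetic_corpus(3, 0, "general") == []
    with pytest.raises(ValueError):
        generate_synthetic_corpus(3, 1, "bogus")


def test_death_profile_records_look_like_certificates(tables):
    recs = generate_synthetic_corpus(5, 30, "death", 0.0, tables)
    assert any("1a" in r.text for r in recs)
    assert all(r.associated_code == "22J..12" for r in recs)
    for rec in recs:
        assert rec.gold.items  # every record carries complete gold output


def test_eval_arithmetic_from_published_counts():
    death = EvalResult.from_counts(tp=683, fp=11, fn=52)
    assert round(death.precision * 100, 1) == 98.4
    assert round(death.recall * 100, 1) == 92.9
    assert round(death.f_score, 2) == 0.96
    general = EvalResult.from_counts(tp=346, fp=32, fn=101)
    assert round(general.precision * 100, 1) == 91.5
    assert round(general.recall * 100, 1) == 77.4
    assert round(general.f_score, 2) == 0.84


def test_wilson_intervals_are_sane():
    res = EvalResult.from_counts(tp=683, fp=11, fn=52)
    lo, hi = res.precision_ci
    assert lo < res.precision < hi and 0.96 < lo and hi < 1.0


def test_perfect_agreement_scores_one(tables):
    recs = generate_synthetic_corpus(9, 20, "general", 0.0, tables)
    outs = [analyze_record(r.record_id, r.associated_code, r.text, tables)
            for r in recs]
    gold = {r.record_id: list(r.gold.items) for r in recs}
    res = score_outputs(outs, gold)
    assert res.precision == res.recall == 1.0 and res.f_score == 1.0


def test_score_outputs_matches_brute_force(tables):
    recs = generate_synthetic_corpus(13, 20, "general", 0.3, tables)
    outs = [analyze_record(r.record_id, r.associated_code, r.text, tables)
            for r in recs]
    gold = {r.record_id: list(r.gold.items) for r in recs}
    res = score_outputs(outs, gold)
    # independent recount: explicit per-record set comparison
    tp = fp = fn = 0
    for out in outs:
        got = {item_key(i) for i in out.items}
        want = {item_key(i) for i in gold[out.record_id]}
        tp += sum(1 for k in got if k in want)
        fp += sum(1 for k in got if k not in want)
        fn += sum(1 for k in want if k not in got)
    assert (res.true_positives, res.false_positives, res.false_negatives) == (tp, fp, fn)


def test_suspected_and_family_history_items_ignored():
    out = RecordOutput("r1", "standard", [
        OutputItem("term", "G30..00", attribute="family_history"),
        OutputItem("term", "486B"),
    ])
    gold = {"r1": [OutputItem("term", "486B")]}
    res = score_outputs([out], gold)
    assert (res.true_positives, res.false_positives) == (1, 0)
    strict = score_outputs([out], gold,
                           EvalOptions(ignore_suspected_family=False))
    assert strict.false_positives == 1


def test_record_id_mismatch_raises(tables):
    out = RecordOutput("missing", "standard", [])
    with pytest.raises(KeyError):
        score_outputs([out], {"other": []})


def test_noise_never_improves_recall(tables):
    """Appending unknown-word noise can only lose items, never gain recall."""
    recs = generate_synthetic_corpus(17, 40, "general", 0.0, tables)
    gold = {r.record_id: list(r.gold.items) for r in recs}
    clean = [analyze_record(r.record_id, r.associated_code, r.text, tables)
             for r in recs]
    noisy = [analyze_record(r.record_id, r.associated_code,
                            r.text + " zxqv qwfp blorx", tables)
             for r in recs]
    res_clean = score_outputs(clean, gold)
    res_noisy = score_outputs(noisy, gold)
    assert res_noisy.recall <= res_clean.recall
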