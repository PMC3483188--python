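"""Phrase generation, readscore and best-match selection."""

import pytest
from hypothesis import given, settings, strategies as st

from readcoder import preprocess as pp
from readcoder.context import apply_patterns, propagate_scopes
from readcoder.matcher import (
    MatcherConfig,
    SynonymRule,
    SynonymTable,
    best_match,
    candidate_phrases,
    readscore,
    refine_term,
)
from readcoder.terminology import TermStore, add_custom_term


def prepared(text, tables, mode="standard"):
    tokens = pp.tokenize(pp.clean_text(text, tables.cleaning_rules))
    pp.resolve_tokens(tokens, tables.lexicons)
    events = apply_patterns(tokens, tables.patterns, mode)
    spans = propagate_scopes(events, tokens)
    return tokens, spans


def run_matcher(text, tables, mode="standard"):
    tokens, spans = prepared(text, tables, mode)
    phrases = candidate_phrases(tokens)
    return best_match(phrases, tables.store, tables.synonyms, tables.config,
                      tables.stopwords, spans)


def test_phrase_counts(tables):
    tokens, _ = prepared("found dead by family this afternoon", tables)
    phrases = candidate_phrases(tokens)
    assert len(phrases) == 6 + 5 + 4 + 3 + 2  # n-k+1 windows for k=1..5
    lengths = [len(p.words) for p in phrases]
    assert lengths == sorted(lengths, reverse=True)  # longest first
    tokens, _ = prepared("sepsis", tables)
    assert len(candidate_phrases(tokens)) == 1


def test_anonymised_tokens_excluded_from_phrases(tables):
    tokens, _ = prepared("found dead today", tables)
    middle = {(0, 1)}
    phrases = candidate_phrases(tokens, excluded=middle)
    assert all(1 not in p.token_indices for p in phrases)


def test_readscore_identity_is_one(tables):
    term = tables.store.get("P769000")  # renal artery stenosis
    score, subs, unmatched = readscore(
        ["renal", "artery", "stenosis"], term, tables.synonyms,
        tables.config, tables.stopwords)
    assert score == 1.0 and subs == 0 and unmatched == 0


def test_readscore_laterality_ignored_at_penalty(tables):
    term = tables.store.get("N821")  # FRACTURE FEMUR
    score, *_ = readscore(["fracture", "right", "femur"], term, tables.synonyms,
                          tables.config, tables.stopwords)
    assert score == pytest.approx(1.0 - tables.config.penalty_laterality)
    assert score >= tables.config.threshold


def test_readscore_synonym_penalty():
    """One substitution and no other deductions scores 1 - penalty."""
    store = TermStore()
    add_custom_term(store, "C1", "myocardial infarction")
    synonyms = SynonymTable([SynonymRule(("mi",), ("myocardial", "infarction"), 0.10)])
    score, subs, _ = readscore(["mi"], store.get("C1"), synonyms, MatcherConfig())
    assert score == pytest.approx(0.9) and subs == 1


def test_readscore_zero_when_positive_word_missing(tables):
    term = tables.store.get("P769000")
    score, *_ = readscore(["renal", "artery"], term, tables.synonyms,
                          tables.config, tables.stopwords)
    assert score == 0.0


def test_readscore_unknown_content_word_blocks_match(tables):
    term = tables.store.get("213100")  # found dead
    score, *_ = readscore(["found", "dead", "coroner"], term, tables.synonyms,
                          tables.config, tables.stopwords)
    assert score == 0.0


def test_best_match_worked_phrases(tables):
    cands = run_matcher("coronary severe triple vessel disease + impaired function",
                        tables)
    assert [c.code for c in cands] == ["G340.11"]
    cands = run_matcher("ct did not show renal artery stenosis.", tables)
    assert [(c.code, c.negated) for c in cands] == [("P769000", True)]
    cands = run_matcher("zxqv gleep", tables)
    assert cands == []


def test_each_token_consumed_once(tables):
    cands = run_matcher("aspiration pneumonia", tables)
    assert [c.code for c in cands] == ["H262.00"]  # not also bare PNEUMONIA


def test_brute_force_oracle_equivalence(tables):
    """Index-driven selection equals scoring every (phrase, term) pair."""
    texts = [
        "coronary severe triple vessel disease",
        "no pneumonia, stroke or dementia",
        "ca prostate seen today",
        "fracture right femur and deep vein thrombosis",
        "had an mi in 1996",
        "aspiration pneumonia, sudden death",
    ]
    records = [r for r in tables.store.matchable_records()]
    assert len(records) <= 50
    for text in texts:
        tokens, spans = prepared(text, tables)
        phrases = candidate_phrases(tokens)
        fast = best_match(phrases, tables.store, tables.synonyms, tables.config,
                          tables.stopwords, spans)
        # oracle: no word index, enumerate everything, same tie-break
        consumed = set()
        slow = []
        for phrase in phrases:
            positions = {(phrase.sentence_index, i) for i in phrase.token_indices}
            if positions & consumed:
                continue
            scored = []
            for record in records:
                s, *_ = readscore(phrase.words, record, tables.synonyms,
                                  tables.config, tables.stopwords)
                if s >= tables.config.threshold:
                    scored.append((s, record))
            if not scored:
                continue
            from readcoder.terminology import DICTIONARY_ORDER
            s, record = min(scored, key=lambda p: (-p[0],
                                                   DICTIONARY_ORDER[p[1].dictionary],
                                                   p[1].code))
            slow.append((record.code, phrase.start))
            consumed |= positions
        assert [(c.code, c.phrase.start) for c in fast] == sorted(
            slow, key=lambda p: p[1]
        ), text


@given(st.permutations(["triple", "vessel", "disease"]))
@settings(derandomize=True, max_examples=6, deadline=None)
def test_word_order_invariance(tables, words):
    term = tables.store.get("G340.11")
    score, *_ = readscore(list(words), term, tables.synonyms,
                          tables.config, tables.stopwords)
    assert score == pytest.approx(0.85)


def test_exact_match_never_scores_below_synonym_route(tables):
    term = tables.store.get("G30..00")
    exact, *_ = readscore(["acute", "myocardial", "infarction"], term,
                          tables.synonyms, tables.config, tables.stopwords)
    via_syn, *_ = readscore(["mi"], term, tables.synonyms, tables.config,
                            tables.stopwords)
    assert exact >= via_syn


def test_threshold_monotonicity(tables):
    text = "ca prostate and fracture right femur"
    counts = []
    for threshold in (0.5, 0.7, 0.9, 0.99):
        config = MatcherConfig(threshold=threshold)
        tokens, spans = prepared(text, tables)
        cands = best_match(candidate_phrases(tokens), tables.store,
                           tables.synonyms, config, tables.stopwords, spans)
        counts.append(len(cands))
    assert counts == sorted(counts, reverse=True)


def test_refine_term(tables):
    refined = refine_term("G581.00", tables.store,
                          {"acute", "give", "lasix", "admitted"})
    assert refined is not None and refined.code == "G581000"
    assert refine_term("G581.00", tables.store, {"give", "lasix"}) is None
    assert refine_term("NOPE", tables.store, {"acute"}) is None
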