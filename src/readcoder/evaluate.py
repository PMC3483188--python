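"""Precision/recall evaluation of structured output against gold annotations.

Items are matched per record on (kind, value, negation status, attribute
family).  Following the original testing protocol, duplicate term codes
within a record are collapsed and terms attributed to suspected
conditions or family members are excluded before counting, and the
record's own associated code can be ignored.  95% confidence intervals
use the Wilson score method by default (stable at small counts), with an
exact (Clopper-Pearson) alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

from statsmodels.stats.proportion import proportion_confint

from .context import CONTEXT_FAMILIES
from .pipeline import OutputItem, RecordOutput

__all__ = ["EvalOptions", "EvalResult", "score_outputs", "item_key"]

_EXCLUDED_ATTRIBUTES = {"suspected", "family_history"}


@dataclass(frozen=True)
class EvalOptions:
    ignore_suspected_family: bool = True
    ignore_associated: bool = True
    ci_method: str = "wilson"  # or "beta" for exact binomial
    relaxed_codes: bool = False  # credit ancestor/descendant codes


@dataclass(frozen=True)
class EvalResult:
    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float
    recall: float
    f_score: float
    precision_ci: tuple[float, float]
    recall_ci: tuple[float, float]

    @classmethod
    def from_counts(
        cls, tp: int, fp: int, fn: int, ci_method: str = "wilson"
    ) -> "EvalResult":
        precision = tp / (tp + fp) if tp + fp else float("nan")
        recall = tp / (tp + fn) if tp + fn else float("nan")
        if precision + recall > 0:
            f_score = 2 * precision * recall / (precision + recall)
        else:
            f_score = 0.0
        return cls(
            true_positives=tp,
            false_positives=fp,
            false_negatives=fn,
            precision=precision,
            recall=recall,
            f_score=f_score,
            precision_ci=_ci(tp, tp + fp, ci_method),
            recall_ci=_ci(tp, tp + fn, ci_method),
        )

    def to_dict(self) -> dict:
        return {
            "true_positives": self.true_positives,
            "false_positives": self.false_positives,
            "false_negatives": self.false_negatives,
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "precision_ci": list(self.precision_ci),
            "recall_ci": list(self.recall_ci),
        }


def _ci(successes: int, trials: int, method: str) -> tuple[float, float]:
    if trials == 0:
        return (float("nan"), float("nan"))
    low, high = proportion_confint(successes, trials, alpha=0.05, method=method)
    return (float(low), float(high))


def item_key(item: OutputItem, relaxed: bool = False) -> tuple:
    """Comparison key: kind, value, negation, attribute family."""
    family = CONTEXT_FAMILIES.get(item.attribute or "", item.attribute)
    value = item.value
    if isinstance(value, dict):
        value = tuple(sorted(value.items()))
    if item.kind == "term" and relaxed:
        value = str(value)[:3]  # code class prefix
    return (item.kind, value, item.negated, family)


def _countable(item: OutputItem, options: EvalOptions,
               associated: Optional[str]) -> bool:
    if options.ignore_suspected_family and item.attribute in _EXCLUDED_ATTRIBUTES:
        return False
    if (
        options.ignore_associated
        and associated is not None
        and item.kind == "term"
        and item.value == associated
    ):
        return False
    return True


def score_outputs(
    outputs: Sequence[RecordOutput],
    gold: Mapping[str, Sequence[OutputItem]],
    options: EvalOptions = EvalOptions(),
    associated_codes: Optional[Mapping[str, str]] = None,
) -> EvalResult:
    """Item-level comparison of analysis output with gold annotations.

    *gold* maps record id to expected items; every output record id must
    be present in *gold*.
    """
    associated_codes = associated_codes or {}
    tp = fp = fn = 0
    for output in outputs:
        if output.record_id not in gold:
            raise KeyError(f"record {output.record_id!r} missing from gold standard")
        associated = associated_codes.get(output.record_id)
        got = {
            item_key(item, options.relaxed_codes)
            for item in output.items
            if _countable(item, options, associated)
        }
        want = {
            item_key(item, options.relaxed_codes)
            for item in gold[output.record_id]
            if _countable(item, options, associated)
        }
        tp += len(got & want)
        fp += len(got - want)
        fn += len(want - got)
    return EvalResult.from_counts(tp, fp, fn, options.ci_method)
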