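"""Accuracy / macro-F1 evaluation with bootstrap confidence intervals,
approach comparison, and challenging-subset construction.

Macro F1 is the unweighted mean of the per-class F1 scores over the
positive (stigmatizing) and negative classes, so performance on the rare
class counts as much as on the common one.  Uncertainty comes from
note-level bootstrap resampling (B resamples with replacement, percentile
95% CI); two approaches are compared with a two-sample Student t-test on
their bootstrap score vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .corpus_model import Note, PredictionRecord, TermLexicon
from .errors import ValidationError
from .keyword_engine import keyword_classify

LabelMap = Mapping[str, int]


def _as_label_map(
    source: Union[LabelMap, Sequence[PredictionRecord], Sequence[Note]]
) -> dict[str, int]:
    if isinstance(source, Mapping):
        return dict(source)
    out: dict[str, int] = {}
    for item in source:
        if isinstance(item, PredictionRecord):
            out[item.note_id] = item.label
        elif isinstance(item, Note):
            if item.gold_binary is None:
                raise ValidationError(f"note {item.note_id!r} has no gold label")
            out[item.note_id] = item.gold_binary
        else:
            raise ValidationError(f"cannot extract labels from {type(item)!r}")
    return out


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n


def confusion_counts(
    predictions: Union[LabelMap, Sequence[PredictionRecord]],
    gold: Union[LabelMap, Sequence[Note]],
) -> ConfusionCounts:
    """Standard 2x2 counts over predictions aligned to gold by note_id."""
    pred_map = _as_label_map(predictions)
    gold_map = _as_label_map(gold)
    missing = set(pred_map) ^ set(gold_map)
    if missing:
        raise ValidationError(
            f"predictions and gold are not aligned; unmatched ids: "
            f"{sorted(missing)[:5]}..."
        )
    tp = fp = fn = tn = 0
    for nid, p in pred_map.items():
        g = gold_map[nid]
        if p not in (0, 1) or g not in (0, 1):
            raise ValidationError(f"non-binary label for note {nid!r}")
        if p == 1 and g == 1:
            tp += 1
        elif p == 1:
            fp += 1
        elif g == 1:
            fn += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _f1(two_tp: int, denom: int) -> float:
    return two_tp / denom if denom else 0.0


def macro_f1(counts: ConfusionCounts) -> float:
    """Mean of per-class F1 (positive and negative class), 0-denominator
    F1 defined as 0."""
    if counts.n == 0:
        raise ValidationError("macro F1 undefined on an empty sample")
    f1_pos = _f1(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn)
    f1_neg = _f1(2 * counts.tn, 2 * counts.tn + counts.fn + counts.fp)
    return (f1_pos + f1_neg) / 2.0


def _metric_from_arrays(pred: np.ndarray, gold: np.ndarray, metric: str) -> np.ndarray:
    """Vectorized metric over resample matrices of shape (B, n)."""
    tp = ((pred == 1) & (gold == 1)).sum(axis=-1)
    fp = ((pred == 1) & (gold == 0)).sum(axis=-1)
    fn = ((pred == 0) & (gold == 1)).sum(axis=-1)
    tn = ((pred == 0) & (gold == 0)).sum(axis=-1)
    if metric == "accuracy":
        return (tp + tn) / (tp + fp + fn + tn)
    with np.errstate(invalid="ignore"):
        f1_pos = np.where(2 * tp + fp + fn > 0, 2 * tp / np.maximum(2 * tp + fp + fn, 1), 0.0)
        f1_neg = np.where(2 * tn + fn + fp > 0, 2 * tn / np.maximum(2 * tn + fn + fp, 1), 0.0)
    return (f1_pos + f1_neg) / 2.0


def resample_indices(n: int, B: int, seed: int) -> np.ndarray:
    """The (B, n) bootstrap index matrix used by :func:`bootstrap_ci`."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, n, size=(B, n))


@dataclass
class EvalReport:
    """Point metrics plus bootstrap distribution for one approach."""

    approach: str
    n_notes: int
    accuracy: float
    macro_f1: float
    ci_low: float
    ci_high: float
    bootstrap_scores: list[float]
    B: int
    seed: int
    metric: str = "macro_f1"
    ci_method: str = "percentile"  # normal-approximation not implemented

    def to_json(self) -> str:
        payload = {
            "schema_version": 1,
            "approach": self.approach,
            "n_notes": self.n_notes,
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "B": self.B,
            "seed": self.seed,
            "metric": self.metric,
            "ci_method": self.ci_method,
            "bootstrap_scores": self.bootstrap_scores,
        }
        return json.dumps(payload, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        payload = json.loads(text)
        payload.pop("schema_version", None)
        return cls(**payload)


def bootstrap_ci(
    predictions: Union[LabelMap, Sequence[PredictionRecord]],
    gold: Union[LabelMap, Sequence[Note]],
    metric: str = "macro_f1",
    B: int = 1000,
    seed: int = 0,
    approach: str = "",
) -> EvalReport:
    """Note-level bootstrap of a metric with a percentile 95% CI.

    Draws B resamples of size n with replacement, evaluates the metric on
    each, and takes the 2.5/97.5 percentiles of the resulting scores.
    """
    if B < 1:
        raise ValidationError("B must be >= 1")
    if metric not in ("macro_f1", "accuracy"):
        raise ValidationError(f"unknown metric {metric!r}")
    pred_map = _as_label_map(predictions)
    gold_map = _as_label_map(gold)
    counts = confusion_counts(pred_map, gold_map)
    ids = sorted(pred_map)
    pred = np.array([pred_map[i] for i in ids])
    gold_arr = np.array([gold_map[i] for i in ids])
    idx = resample_indices(len(ids), B, seed)
    scores = _metric_from_arrays(pred[idx], gold_arr[idx], metric)
    ci_low, ci_high = np.percentile(scores, [2.5, 97.5])
    return EvalReport(
        approach=approach,
        n_notes=len(ids),
        accuracy=counts.accuracy,
        macro_f1=macro_f1(counts),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        bootstrap_scores=[float(s) for s in scores],
        B=B,
        seed=seed,
        metric=metric,
    )


def compare_approaches(
    report_a: EvalReport,
    report_b: EvalReport,
    equal_var: bool = True,
) -> dict[str, float]:
    """Two-sample t-test on two bootstrap score vectors.

    Student's (equal-variance) test by default, matching the named
    procedure; pass ``equal_var=False`` for Welch's variant.
    """
    if report_a.B != report_b.B:
        raise ValidationError("reports must have equal bootstrap counts")
    a = np.asarray(report_a.bootstrap_scores)
    b = np.asarray(report_b.bootstrap_scores)
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        raise ValidationError("both score vectors have zero variance")
    t_stat, p_value = stats.ttest_ind(a, b, equal_var=equal_var)
    return {"t_stat": float(t_stat), "p_value": float(p_value)}


def challenging_subset(notes: Sequence[Note], lexicon: TermLexicon) -> list[Note]:
    """Notes containing at least one lexicon term, regardless of gold
    category — the subset where context, not keywords, decides the label."""
    if len(lexicon) == 0:
        raise ValidationError("lexicon must be non-empty")
    return [n for n in notes if keyword_classify(n, lexicon) == 1]
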