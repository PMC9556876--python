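"""Precision/recall/F-score and Fmax against held-out truth.

The evaluation protocol is leave-out: a target's own annotations are hidden
from every predictor and used only as truth. Per-target precision, recall
and F are macro-averaged over evaluable targets (those with non-empty
truth). Fmax follows the CAFA convention: scan score thresholds 0.00..1.00
in steps of 0.01, average precision over targets with at least one
prediction at the threshold and recall over all targets, and take the
maximum harmonic mean.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.0, 1.01, 0.01), 2))


def prf(predicted: set[str], truth: set[str]) -> tuple[float, float, float]:
    """Per-target precision, recall, F1. Truth must be non-empty."""
    if not truth:
        raise ValueError("truth set is empty; exclude such targets upstream")
    hits = len(set(predicted) & truth)
    precision = hits / len(predicted) if predicted else 0.0
    recall = hits / len(truth)
    f = (2 * precision * recall / (precision + recall)
         if precision + recall > 0 else 0.0)
    return precision, recall, f


def macro_prf(
    per_target: Iterable[tuple[float, float, float]]
) -> tuple[float, float, float]:
    """Unweighted mean of per-target (P, R, F)."""
    rows = np.asarray(list(per_target), dtype=float)
    if rows.size == 0:
        raise ValueError("no per-target results to average")
    means = rows.mean(axis=0)
    return float(means[0]), float(means[1]), float(means[2])


def fmax(
    predictions: Mapping[str, Mapping[str, float]],
    truths: Mapping[str, set[str]],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> float:
    """CAFA-style Fmax over a threshold grid.

    ``predictions[target]`` maps terms to scores in [0, 1];
    ``truths[target]`` is the held-out term set. Targets with empty truth
    are excluded (logged).
    """
    evaluable = [t for t, truth in truths.items() if truth]
    skipped = len(truths) - len(evaluable)
    if skipped:
        logger.info("fmax: excluded %d target(s) with empty truth", skipped)
    if not evaluable:
        raise ValueError("no target with non-empty truth")

    best = 0.0
    for tau in thresholds:
        precisions = []
        recalls = []
        for target in evaluable:
            pred = {
                term for term, score in predictions.get(target, {}).items()
                if score >= tau
            }
            truth = truths[target]
            hits = len(pred & truth)
            if pred:
                precisions.append(hits / len(pred))
            recalls.append(hits / len(truth))
        precision = float(np.mean(precisions)) if precisions else 0.0
        recall = float(np.mean(recalls))
        if precision + recall > 0:
            best = max(best, 2 * precision * recall / (precision + recall))
    return best


def micro_prf(
    predictions: Mapping[str, set[str]], truths: Mapping[str, set[str]]
) -> tuple[float, float, float]:
    """Micro-averaged P/R/F: counts pooled across targets before dividing."""
    hits = n_pred = n_truth = 0
    for target, truth in truths.items():
        pred = set(predictions.get(target, set()))
        hits += len(pred & truth)
        n_pred += len(pred)
        n_truth += len(truth)
    if n_truth == 0:
        raise ValueError("no truth terms to evaluate against")
    precision = hits / n_pred if n_pred else 0.0
    recall = hits / n_truth
    f = (2 * precision * recall / (precision + recall)
         if precision + recall > 0 else 0.0)
    return precision, recall, f


def evaluate_run(
    predictions: Mapping[str, Mapping[str, float]],
    truths: Mapping[str, set[str]],
    term_aspect: Mapping[str, str] | None = None,
    aspects: Sequence[str] = ("BP", "MF", "CC"),
    average: str = "macro",
) -> dict:
    """P/R/F and Fmax, pooled and (when an aspect map is given) per aspect.

    ``average`` selects macro (unweighted per-target mean, the default) or
    micro (counts pooled across targets) P/R/F aggregation.
    """
    if average not in ("macro", "micro"):
        raise ValueError("average must be 'macro' or 'micro'")

    def _metrics(preds, trs) -> dict | None:
        evaluable = {t: truth for t, truth in trs.items() if truth}
        if not evaluable:
            return None
        if average == "macro":
            per_target = [
                prf(set(preds.get(t, {})), truth) for t, truth in evaluable.items()
            ]
            p, r, f = macro_prf(per_target)
        else:
            p, r, f = micro_prf(
                {t: set(preds.get(t, {})) for t in evaluable}, evaluable)
        return {
            "precision": p,
            "recall": r,
            "f": f,
            "fmax": fmax(preds, evaluable),
            "n_targets": len(evaluable),
        }

    report = {"pooled": _metrics(predictions, truths), "per_aspect": {}}
    if term_aspect is not None:
        for aspect in aspects:
            keep = {t for t, a in term_aspect.items() if a == aspect}
            preds_a = {
                target: {t: s for t, s in scores.items() if t in keep}
                for target, scores in predictions.items()
            }
            truths_a = {target: truth & keep for target, truth in truths.items()}
            metrics = _metrics(preds_a, truths_a)
            if metrics is not None:
                report["per_aspect"][aspect] = metrics
    return report
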