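"""n-star consensus over the three predictors.

A GO term reaches the n-star level when at least n of the component
predictors (sequence, domain, topology) propose it. 1-star is the union,
3-star the unanimous intersection; the n-star sets are nested. The combined
score is the mean of the contributing predictors' scores; the support count
(how many predictors agreed) is carried along as a categorical confidence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

logger = logging.getLogger(__name__)

PREDICTOR_LABELS = ("seq", "domain", "topo")


class ConsensusTerm(NamedTuple):
    term: str
    score: float
    support: int


@dataclass
class PredictionSet:
    """Per-predictor, per-target scored GO term predictions.

    ``predictions[label][target]`` is a dict term -> score in [0, 1]; within
    a target and predictor, terms are unique by construction.
    """

    predictions: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)

    def add(self, label: str, target: str,
            ranked: Iterable[tuple[str, float]]) -> None:
        if label not in PREDICTOR_LABELS:
            raise ValueError(f"unknown predictor label {label!r}")
        scores: dict[str, float] = {}
        for term, score in ranked:
            if not 0.0 <= score <= 1.0:
                raise ValueError(f"score {score} for {term!r} outside [0, 1]")
            scores[term] = score
        self.predictions.setdefault(label, {})[target] = scores

    def for_target(self, target: str) -> dict[str, dict[str, float]]:
        return {
            label: self.predictions.get(label, {}).get(target, {})
            for label in PREDICTOR_LABELS
        }

    def targets(self) -> set[str]:
        return {t for per in self.predictions.values() for t in per}


def n_star(preds: PredictionSet, target: str, n: int) -> list[ConsensusTerm]:
    """Terms predicted by >= n predictors, scored by mean contributing score.

    A predictor with no output for the target contributes nothing (so a
    3-star consensus is then impossible; logged). Result sorted by combined
    score descending, term id ascending.
    """
    if not 1 <= n <= len(PREDICTOR_LABELS):
        raise ValueError(f"n must be in 1..{len(PREDICTOR_LABELS)}")
    per_predictor = preds.for_target(target)
    empty = [label for label, scores in per_predictor.items() if not scores]
    if empty and n > len(PREDICTOR_LABELS) - len(empty):
        logger.info(
            "n_star(%s, n=%d): predictor(s) %s empty; %d-star unreachable",
            target, n, empty, n,
        )
    combined: dict[str, list[float]] = {}
    for scores in per_predictor.values():
        for term, score in scores.items():
            combined.setdefault(term, []).append(score)
    out = [
        ConsensusTerm(term, sum(scores) / len(scores), len(scores))
        for term, scores in combined.items()
        if len(scores) >= n
    ]
    out.sort(key=lambda c: (-c.score, c.term))
    return out
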