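"""Output-side measures: accuracy, maximum probability, predictive entropy.

Entropy is reported in bits (base-2) since the word lexicon is the natural
alphabet; a one-hot prediction has 0 bits and a fully uncertain prediction
log2(K) bits.  Uncertainty summaries are computed both over accurate
responses only (high max-probability / low entropy on correct responses is
the proxy for rapid retrieval; the reverse for word-finding delay) and over
all responses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cnn_model import PredictiveDistribution, TrainedModel, predict_batch
from .errors import EmptySubsetError, InvalidInputError
from .synthetic_speech import MelSpectrogram

__all__ = [
    "PredictionRecord",
    "UncertaintySummary",
    "classify",
    "entropy_bits",
    "evaluate",
    "summarize_uncertainty",
    "accuracy_percent",
]


@dataclass(frozen=True)
class PredictionRecord:
    exemplar_id: str
    true_label: int
    predicted_label: int
    max_prob: float
    entropy_bits: float
    correct: bool


@dataclass(frozen=True)
class UncertaintySummary:
    n: int
    entropy_mean: float
    entropy_sd: float
    max_prob_mean: float
    max_prob_sd: float
    accuracy: float  # percent correct over the unfiltered records


def _probs(dist) -> np.ndarray:
    p = dist.probs if isinstance(dist, PredictiveDistribution) else np.asarray(dist, dtype=float)
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidInputError("distribution must be a non-empty vector")
    if np.any(p < 0):
        raise InvalidInputError("distribution has negative components")
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise InvalidInputError(f"distribution sums to {p.sum()}, not 1")
    return p


def classify(dist) -> int:
    """Argmax selection; ties broken toward the lowest index."""
    return int(np.argmax(_probs(dist)))


def entropy_bits(dist) -> float:
    """Shannon entropy -sum p log2 p with 0 log 0 := 0, in [0, log2 K]."""
    p = _probs(dist)
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def evaluate(model: TrainedModel, test_set: list[MelSpectrogram]) -> list[PredictionRecord]:
    """One PredictionRecord per test exemplar."""
    if not test_set:
        raise InvalidInputError("test set is empty")
    probs = predict_batch(model, test_set)
    records = []
    for spec, p in zip(test_set, probs):
        pred = int(np.argmax(p))
        records.append(
            PredictionRecord(
                exemplar_id=spec.exemplar_id,
                true_label=int(spec.label),
                predicted_label=pred,
                max_prob=float(p[pred]),
                entropy_bits=entropy_bits(p),
                correct=pred == int(spec.label),
            )
        )
    return records


def accuracy_percent(records: list[PredictionRecord]) -> float:
    if not records:
        raise InvalidInputError("no records")
    return 100.0 * sum(r.correct for r in records) / len(records)


def summarize_uncertainty(
    records: list[PredictionRecord], correct_only: bool = True
) -> UncertaintySummary:
    """Mean and sample SD (n-1 denominator) of entropy and max probability.

    With ``correct_only`` the statistics describe accurate responses only;
    ``accuracy`` always refers to the full record list.  An empty subset
    after filtering is an explicit error, never a silent zero.
    """
    if not records:
        raise InvalidInputError("no records")
    subset = [r for r in records if r.correct] if correct_only else records
    if not subset:
        raise EmptySubsetError("no records remain after the correct-only filter")
    ent = np.array([r.entropy_bits for r in subset])
    mp = np.array([r.max_prob for r in subset])
    sd = lambda v: float(v.std(ddof=1)) if len(v) > 1 else 0.0
    return UncertaintySummary(
        n=len(subset),
        entropy_mean=float(ent.mean()),
        entropy_sd=sd(ent),
        max_prob_mean=float(mp.mean()),
        max_prob_sd=sd(mp),
        accuracy=accuracy_percent(records),
    )
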