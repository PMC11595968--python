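"""Few-shot classification and consistency-weighted temporal voting.

Chunks are classified by nearest class prototype (the arithmetic mean of
the support chunks' joint embeddings, one prototype per class) under
Euclidean distance.  A recording's chunk-level predictions are then fused
into one sequence-level label by weighted voting: a chunk whose neighbors
in time agree with it gets a higher weight, operationalizing the idea
that temporally consistent predictions are more trustworthy than isolated
flips.

Ties break deterministically: first by smaller mean chunk distance, then
by the fixed class ordinal (CP < UCLP < BCLP).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .io import CleftLabel

__all__ = [
    "PrototypeSet",
    "ChunkPrediction",
    "SequencePrediction",
    "class_prototypes",
    "predict_chunk",
    "temporal_weights",
    "vote_sequence",
]


@dataclass
class PrototypeSet:
    prototypes: dict[CleftLabel, np.ndarray]  # class -> mean joint embedding
    support_counts: dict[CleftLabel, int]

    def __post_init__(self) -> None:
        if not self.prototypes:
            raise ValueError("empty prototype set")
        dims = {v.shape for v in self.prototypes.values()}
        if len(dims) != 1:
            raise ValueError("prototypes must share dimensionality")
        for c, n in self.support_counts.items():
            if n < 1:
                raise ValueError(f"support count for {c.name} must be >= 1")

    @property
    def dim(self) -> int:
        return next(iter(self.prototypes.values())).size

    @property
    def classes(self) -> list[CleftLabel]:
        return sorted(self.prototypes, key=int)


@dataclass
class ChunkPrediction:
    chunk_index: int
    label: CleftLabel
    distances: dict[CleftLabel, float]


@dataclass
class SequencePrediction:
    label: CleftLabel
    tally: dict[CleftLabel, float]
    chunk_predictions: list[ChunkPrediction]
    weights: np.ndarray


def class_prototypes(
    embeddings: np.ndarray | Sequence[np.ndarray],
    labels: Sequence[CleftLabel | int],
    require_all: bool = True,
) -> PrototypeSet:
    """Mean joint embedding per class over the support set.

    With ``require_all`` (default) every cleft class must be represented;
    the error names the missing class.
    """
    E = np.asarray([np.asarray(e, dtype=np.float64) for e in embeddings])
    labs = [CleftLabel(int(l)) for l in labels]
    if E.shape[0] != len(labs):
        raise ValueError("one label per support embedding required")
    present = set(labs)
    if require_all:
        missing = [c.name for c in CleftLabel if c not in present]
        if missing:
            raise ValueError(f"support set missing class(es): {missing}")
    protos: dict[CleftLabel, np.ndarray] = {}
    counts: dict[CleftLabel, int] = {}
    for c in sorted(present, key=int):
        mask = np.array([l == c for l in labs])
        protos[c] = E[mask].mean(axis=0)
        counts[c] = int(mask.sum())
    return PrototypeSet(prototypes=protos, support_counts=counts)


def predict_chunk(
    embedding: np.ndarray, protos: PrototypeSet, chunk_index: int = 0
) -> ChunkPrediction:
    """Nearest-prototype classification; exact ties go to the lowest ordinal."""
    e = np.asarray(embedding, dtype=np.float64).ravel()
    if e.size != protos.dim:
        raise ValueError(
            f"embedding dim {e.size} does not match prototype dim {protos.dim}"
        )
    distances = {
        c: float(np.linalg.norm(e - protos.prototypes[c])) for c in protos.classes
    }
    best = min(distances, key=lambda c: (distances[c], int(c)))
    return ChunkPrediction(chunk_index=chunk_index, label=best, distances=distances)


def temporal_weights(
    labels: Sequence[CleftLabel | int], window: int = 1, alpha: float = 1.0
) -> np.ndarray:
    """Consistency weights over an ordered chunk label sequence.

    For chunk i let c_i be the fraction of chunks at positions
    [i-window, i+window] (excluding i, clipped to the sequence bounds)
    that share chunk i's label; a chunk with no neighbors has c_i = 0.
    The weight is 1 + alpha * c_i, so weights live in [1, 1 + alpha] and
    alpha = 0 recovers plain majority voting.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    labs = [int(l) for l in labels]
    if not labs:
        raise ValueError("empty label sequence")
    n = len(labs)
    weights = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - window), min(n - 1, i + window)
        neighbors = [labs[k] for k in range(lo, hi + 1) if k != i]
        c_i = (
            sum(1 for l in neighbors if l == labs[i]) / len(neighbors)
            if neighbors
            else 0.0
        )
        weights[i] = 1.0 + alpha * c_i
    return weights


def vote_sequence(
    chunk_predictions: Sequence[ChunkPrediction],
    weights: Sequence[float] | np.ndarray,
) -> SequencePrediction:
    """Weighted ensemble vote over chunk predictions.

    tally[c] = sum of weights of chunks predicting c; the largest tally
    wins.  A tied tally goes to the class with the smallest mean chunk
    distance among the tied classes, then to the lowest class ordinal.
    """
    preds = list(chunk_predictions)
    w = np.asarray(weights, dtype=np.float64)
    if not preds:
        raise ValueError("empty prediction list")
    if w.size != len(preds):
        raise ValueError("one weight per chunk prediction required")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    tally: dict[CleftLabel, float] = {}
    for pred, wi in zip(preds, w):
        tally[pred.label] = tally.get(pred.label, 0.0) + float(wi)
    best_score = max(tally.values())
    tied = [c for c, s in tally.items() if s == best_score]
    if len(tied) > 1:
        mean_dist = {
            c: float(np.mean([p.distances[c] for p in preds if p.label == c]))
            for c in tied
        }
        tied.sort(key=lambda c: (mean_dist[c], int(c)))
    winner = tied[0]
    return SequencePrediction(
        label=winner, tally=tally, chunk_predictions=preds, weights=w
    )
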