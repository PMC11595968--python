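"""Leakage-safe cross-validation and the classification metric suite.

Cross-validation is grouped at the participant level: every recording of
a child stays in one fold, so a model is never scored on a speaker it has
seen during training.  Within each class, participants are shuffled by
the run seed, interleaved by sex, and dealt round-robin to folds, which
keeps both class and sex proportions as even as an integer deal allows.

Metrics follow the one-vs-rest convention: per-class precision, recall
and F1 (2PR/(P+R)) from the pooled confusion matrix, plus accuracy and
macro / support-weighted averages.  A zero denominator yields 0 with a
warning, matching common tooling conventions.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .encoder import EncoderSpec, SiameseEncoder
from .errors import CleftusError
from .fewshot import (
    ChunkPrediction,
    class_prototypes,
    predict_chunk,
    temporal_weights,
    vote_sequence,
)
from .io import CleftLabel, Manifest
from .pipeline import ChunkRecord, load_chunk_dataset
from .preprocess import PreprocessConfig
from .siamese import TrainConfig, _batched_features, train_siamese

__all__ = [
    "FoldAssignment",
    "ConfusionMatrix",
    "ClassMetrics",
    "MetricsReport",
    "UnitPrediction",
    "CVResult",
    "stratified_group_kfold",
    "confusion_matrix",
    "precision_recall_f1",
    "aggregate_metrics",
    "compute_metrics",
    "run_cross_validation",
]

_CLASSES = list(CleftLabel)


@dataclass
class FoldAssignment:
    n_folds: int
    fold_of_participant: dict[str, int]
    seed: int

    def __post_init__(self) -> None:
        for pid, f in self.fold_of_participant.items():
            if not 0 <= f < self.n_folds:
                raise ValueError(f"participant {pid!r} assigned to invalid fold {f}")

    def participants_in_fold(self, fold: int) -> list[str]:
        return [p for p, f in self.fold_of_participant.items() if f == fold]


@dataclass
class ConfusionMatrix:
    """3x3 counts, rows = true class, columns = predicted, order CP/UCLP/BCLP."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 3) or np.any(self.counts < 0):
            raise ValueError("confusion matrix must be 3x3 nonnegative counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)


@dataclass
class ClassMetrics:
    precision: float
    recall: float
    f1: float
    support: int
    degenerate: bool = False  # a zero denominator forced a 0 metric


@dataclass
class MetricsReport:
    accuracy: float
    per_class: dict[CleftLabel, ClassMetrics]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "per_class": {
                c.name: dataclasses.asdict(m) for c, m in self.per_class.items()
            },
            "macro": {
                "precision": self.macro_precision,
                "recall": self.macro_recall,
                "f1": self.macro_f1,
            },
            "weighted": {
                "precision": self.weighted_precision,
                "recall": self.weighted_recall,
                "f1": self.weighted_f1,
            },
        }


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 by convention when both are 0."""
    if precision + recall <= 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def stratified_group_kfold(
    manifest: Manifest, n_folds: int, seed: int = 0
) -> FoldAssignment:
    """Participant-level stratified fold assignment.

    Within each class the participants are shuffled by the seed, ordered
    by interleaving the two sexes, and dealt round-robin to folds (the
    deal position carries over between classes so fold sizes stay even).
    Each fold's per-class count is within one participant of every other
    fold's.  A class with fewer participants than folds still deals
    best-effort, with a warning.
    """
    participants = manifest.participants
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    if n_folds > len(participants):
        raise ValueError(
            f"cannot make {n_folds} folds from {len(participants)} participants"
        )
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    offset = 0
    for c in _CLASSES:
        members = [p for p in participants if p.label == c]
        if not members:
            continue
        if len(members) < n_folds:
            warnings.warn(
                f"class {c.name} has {len(members)} participants for "
                f"{n_folds} folds; stratification is best-effort",
                stacklevel=2,
            )
        by_sex: dict[str, list] = {}
        for p in members:
            by_sex.setdefault(p.sex.value, []).append(p)
        groups = []
        for key in sorted(by_sex):
            grp = by_sex[key]
            order = rng.permutation(len(grp))
            groups.append([grp[i] for i in order])
        groups.sort(key=len, reverse=True)
        # deal sex blocks consecutively: the carried round-robin position then
        # spreads each sex as evenly over the folds as integers allow
        ordered = [p for grp in groups for p in grp]
        for p in ordered:
            assignment[p.id] = offset % n_folds
            offset += 1
    return FoldAssignment(n_folds=n_folds, fold_of_participant=assignment, seed=seed)


def confusion_matrix(
    true: Sequence[CleftLabel | int], pred: Sequence[CleftLabel | int]
) -> ConfusionMatrix:
    t = [int(x) for x in true]
    p = [int(x) for x in pred]
    if len(t) != len(p):
        raise ValueError("true and predicted label lists differ in length")
    counts = np.zeros((3, 3), dtype=np.int64)
    for ti, pi in zip(t, p):
        counts[ti, pi] += 1
    return ConfusionMatrix(counts=counts)


def precision_recall_f1(cm: ConfusionMatrix, c: CleftLabel | int) -> ClassMetrics:
    """One-vs-rest precision/recall/F1 for one class from the matrix."""
    k = int(c)
    tp = int(cm.counts[k, k])
    fp = int(cm.counts[:, k].sum() - tp)
    fn = int(cm.counts[k, :].sum() - tp)
    degenerate = False
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision, degenerate = 0.0, True
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall, degenerate = 0.0, True
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1 = 0.0
        degenerate = degenerate or True
    if degenerate:
        warnings.warn(
            f"zero denominator for class {CleftLabel(k).name}; metric set to 0",
            stacklevel=2,
        )
    return ClassMetrics(
        precision=precision,
        recall=recall,
        f1=f1,
        support=tp + fn,
        degenerate=degenerate,
    )


def aggregate_metrics(
    per_class: dict[CleftLabel, ClassMetrics], cm: ConfusionMatrix
) -> MetricsReport:
    """Accuracy plus macro (unweighted) and support-weighted averages.

    A class with zero support contributes its 0 metrics to the macro
    average (with a warning) and is ignored by the weighted average.
    """
    if cm.total == 0:
        raise ValueError("cannot aggregate metrics over zero evaluated units")
    accuracy = float(np.trace(cm.counts) / cm.total)
    classes = sorted(per_class, key=int)
    for c in classes:
        if per_class[c].support == 0:
            warnings.warn(
                f"class {c.name} has zero support; macro average includes its 0",
                stacklevel=2,
            )
    P = np.array([per_class[c].precision for c in classes])
    R = np.array([per_class[c].recall for c in classes])
    F = np.array([per_class[c].f1 for c in classes])
    S = np.array([per_class[c].support for c in classes], dtype=np.float64)
    w = S / S.sum()
    return MetricsReport(
        accuracy=accuracy,
        per_class=dict(per_class),
        macro_precision=float(P.mean()),
        macro_recall=float(R.mean()),
        macro_f1=float(F.mean()),
        weighted_precision=float((P * w).sum()),
        weighted_recall=float((R * w).sum()),
        weighted_f1=float((F * w).sum()),
    )


def compute_metrics(
    true: Sequence[CleftLabel | int], pred: Sequence[CleftLabel | int]
) -> MetricsReport:
    """Full metric report from parallel true/predicted label lists."""
    cm = confusion_matrix(true, pred)
    per_class = {c: precision_recall_f1(cm, c) for c in _CLASSES}
    return aggregate_metrics(per_class, cm)


# ----------------------------------------------------------------------
# cross-validation


@dataclass
class UnitPrediction:
    participant_id: str
    utterance_id: str | None  # None when the unit is the participant
    true_label: CleftLabel
    predicted_label: CleftLabel
    tally: dict[CleftLabel, float]
    fold: int


@dataclass
class CVResult:
    fold_assignment: FoldAssignment
    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    predictions: list[UnitPrediction]
    loss_histories: list[list[float]] = field(default_factory=list)


def _units(
    chunks: Sequence[ChunkRecord], idx: np.ndarray, unit: str
) -> list[tuple[str, str | None, np.ndarray]]:
    """Group chunk indices into voting units, preserving temporal order."""
    groups: dict[tuple, list[int]] = {}
    for k in idx:
        c = chunks[k]
        key = (c.participant_id,) if unit == "participant" else (
            c.participant_id,
            c.utterance_id,
        )
        groups.setdefault(key, []).append(int(k))
    out = []
    for key, members in groups.items():
        pid = key[0]
        uid = key[1] if unit == "utterance" else None
        out.append((pid, uid, np.array(members)))
    return out


def run_cross_validation(
    manifest: Manifest,
    preprocess_config: PreprocessConfig | None = None,
    encoder_spec: EncoderSpec | None = None,
    train_config: TrainConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
    unit: Literal["participant", "utterance"] = "participant",
    vote_window: int = 1,
    vote_alpha: float = 1.0,
    chunks: Sequence[ChunkRecord] | None = None,
) -> CVResult:
    """Grouped stratified K-fold evaluation of the full pipeline.

    For every fold: a Siamese encoder is trained on the other K-1 folds'
    chunks, class prototypes are built from those same training chunks,
    each held-out chunk is classified by nearest prototype, and chunk
    votes are fused per unit (participant by default, utterance
    optionally) with consistency weights.  The pooled report scores the
    concatenated out-of-fold predictions.

    With a frozen backbone the penultimate features of every chunk are
    computed once and shared across folds (the backbone never trains, so
    this leaks nothing); only the projection head is retrained per fold.
    """
    preprocess_config = preprocess_config or PreprocessConfig()
    encoder_spec = encoder_spec or EncoderSpec(freeze_backbone=True)
    train_config = train_config or TrainConfig()
    if not manifest.trainable:
        raise ValueError("manifest is not trainable (missing classes or utterances)")
    if chunks is None:
        chunks = load_chunk_dataset(manifest, preprocess_config)
    labels = np.array([int(c.label) for c in chunks])
    pids = np.array([c.participant_id for c in chunks])

    assignment = stratified_group_kfold(manifest, n_folds, seed)
    ss = np.random.SeedSequence(seed)
    run_seeds = ss.generate_state(n_folds + 1, dtype=np.uint32)

    spec = dataclasses.replace(encoder_spec, projection_dim=train_config.embedding_dim)
    frozen = spec.freeze_backbone or spec.backbone == "biomedclip_frozen"
    encoder = SiameseEncoder(spec, seed=int(run_seeds[0]))
    if frozen:
        us_feats = _batched_features(encoder, [c.ultrasound_image for c in chunks])
        sp_feats = _batched_features(encoder, [c.spectrogram_image for c in chunks])

    predictions: list[UnitPrediction] = []
    fold_reports: list[MetricsReport] = []
    loss_histories: list[list[float]] = []
    part_label = {p.id: p.label for p in manifest.participants}

    for fold in range(n_folds):
        test_pids = set(assignment.participants_in_fold(fold))
        train_pids = {
            p for p, f in assignment.fold_of_participant.items() if f != fold
        }
        # leakage guard: a participant must never appear on both sides
        assert not (test_pids & train_pids), "participant leakage across folds"
        train_idx = np.nonzero(~np.isin(pids, list(test_pids)))[0]
        test_idx = np.nonzero(np.isin(pids, list(test_pids)))[0]
        if test_idx.size == 0:
            raise CleftusError(f"fold {fold}: no held-out chunks")
        fold_seed = int(run_seeds[fold + 1])
        cfg = dataclasses.replace(train_config, seed=fold_seed)
        train_chunks = [chunks[k] for k in train_idx]
        try:
            if frozen:
                # fresh projection head per fold on the shared frozen backbone
                from .nn import Linear

                encoder.head = Linear(
                    encoder.feature_dim,
                    spec.projection_dim,
                    np.random.default_rng(fold_seed),
                )
                trained = train_siamese(
                    train_chunks,
                    encoder,
                    cfg,
                    features=(us_feats[train_idx], sp_feats[train_idx]),
                )
                emb_all = np.concatenate(
                    [encoder.head.forward(us_feats), encoder.head.forward(sp_feats)],
                    axis=1,
                )
            else:
                fold_encoder = SiameseEncoder(spec, seed=fold_seed)
                trained = train_siamese(train_chunks, fold_encoder, cfg)
                from .pipeline import joint_embeddings

                emb_all = joint_embeddings(chunks, fold_encoder)
        except CleftusError as exc:
            raise type(exc)(f"fold {fold}: {exc}") from exc
        loss_histories.append(trained.loss_history)

        protos = class_prototypes(emb_all[train_idx], labels[train_idx])
        fold_true, fold_pred = [], []
        for pid, uid, members in _units(chunks, test_idx, unit):
            chunk_preds: list[ChunkPrediction] = [
                predict_chunk(emb_all[k], protos, chunk_index=chunks[k].chunk_index)
                for k in members
            ]
            w = temporal_weights(
                [cp.label for cp in chunk_preds], vote_window, vote_alpha
            )
            seq = vote_sequence(chunk_preds, w)
            truth = part_label[pid]
            predictions.append(
                UnitPrediction(
                    participant_id=pid,
                    utterance_id=uid,
                    true_label=truth,
                    predicted_label=seq.label,
                    tally=seq.tally,
                    fold=fold,
                )
            )
            fold_true.append(truth)
            fold_pred.append(seq.label)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # single folds often miss a class
            fold_reports.append(compute_metrics(fold_true, fold_pred))

    pooled = compute_metrics(
        [p.true_label for p in predictions], [p.predicted_label for p in predictions]
    )
    return CVResult(
        fold_assignment=assignment,
        fold_reports=fold_reports,
        pooled=pooled,
        predictions=predictions,
        loss_histories=loss_histories,
    )
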