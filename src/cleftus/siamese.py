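"""Pair construction and contrastive training of the shared-weight encoder.

The training signal is the classic contrastive loss over pairs of chunk
embeddings: for a pair with Euclidean distance D and binary label y
(1 = same cleft class, 0 = different),

    loss = y * D^2 + (1 - y) * max(0, m - D)^2

summed over the batch, with margin m.  Minimizing it pulls same-class
chunks together and pushes different-class chunks at least m apart, which
is what makes nearest-prototype classification work from a handful of
support examples.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .encoder import EncoderSpec, SiameseEncoder, ViTConfig
from .errors import SamplingError, TrainingError

__all__ = [
    "PairedExample",
    "TrainConfig",
    "TrainedSiamese",
    "sample_pairs",
    "contrastive_loss",
    "contrastive_loss_and_grad",
    "train_siamese",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class PairedExample:
    """Indices of two distinct chunks plus the same-class indicator."""

    i: int
    j: int
    y: int  # 1 same class, 0 different

    def __post_init__(self) -> None:
        if self.i == self.j:
            raise ValueError("a pair must reference two distinct chunks")
        if self.y not in (0, 1):
            raise ValueError("y must be binary")


@dataclass
class TrainConfig:
    """Optimization settings for the Siamese objective.

    Defaults follow the contrastive-training configuration: Adam at 1e-4,
    batch 32, 20 epochs, margin 1.0, embedding dimension 128.  The
    alternative encoder-pretraining preset (AdamW, 3e-5, weight decay
    0.01, batch 16, 30 epochs) is available via :meth:`vit_preset`.
    """

    learning_rate: float = 1e-4
    optimizer: Literal["adam", "adamw"] = "adam"
    weight_decay: float = 0.0
    batch_size: int = 32
    n_epochs: int = 20
    margin: float = 1.0
    embedding_dim: int = 128
    seed: int = 0
    pairs_per_epoch: int = 2048
    pos_fraction: float = 0.5
    reduction: Literal["sum", "mean"] = "sum"

    def __post_init__(self) -> None:
        if self.margin <= 0:
            raise ValueError("margin must be positive")
        if not 0.0 < self.pos_fraction < 1.0:
            raise ValueError("pos_fraction must lie strictly in (0, 1)")
        if self.batch_size < 1 or self.n_epochs < 1 or self.pairs_per_epoch < 1:
            raise ValueError("batch_size, n_epochs, pairs_per_epoch must be >= 1")

    @classmethod
    def vit_preset(cls, **overrides) -> "TrainConfig":
        base = dict(
            learning_rate=3e-5,
            optimizer="adamw",
            weight_decay=0.01,
            batch_size=16,
            n_epochs=30,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class TrainedSiamese:
    encoder: SiameseEncoder
    train_config: TrainConfig
    loss_history: list[float]  # mean per-pair loss per epoch

    def __post_init__(self) -> None:
        if len(self.loss_history) != self.train_config.n_epochs:
            raise ValueError("loss_history length must equal n_epochs")


def _labels_and_participants(chunks) -> tuple[np.ndarray, np.ndarray]:
    labels = np.array([int(c.label) for c in chunks])
    pids = np.array([c.participant_id for c in chunks])
    return labels, pids


def sample_pairs(
    chunks: Sequence,
    n_pairs: int,
    pos_fraction: float = 0.5,
    seed: int = 0,
) -> list[PairedExample]:
    """Draw a balanced list of same/different-class chunk pairs.

    Exactly ``round(n_pairs * pos_fraction)`` positives.  Positive pairs
    are drawn across different participants of the same class whenever the
    class has more than one participant, so the encoder must learn
    class-level rather than speaker-level similarity.  Deterministic for a
    fixed seed.
    """
    labels, pids = _labels_and_participants(chunks)
    classes = np.unique(labels)
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    n_pos = int(round(n_pairs * pos_fraction))
    n_neg = n_pairs - n_pos
    if n_neg > 0 and classes.size < 2:
        raise SamplingError("negative pairs need at least two classes present")
    rng = np.random.default_rng(seed)
    by_class = {int(c): np.nonzero(labels == c)[0] for c in classes}
    pairs: list[PairedExample] = []
    for _ in range(n_pos):
        c = int(rng.choice(classes))
        idx = by_class[c]
        if idx.size < 2:
            raise SamplingError(
                f"class {c} has fewer than 2 chunks; cannot form a positive pair"
            )
        class_pids = np.unique(pids[idx])
        if class_pids.size >= 2:
            pa, pb = rng.choice(class_pids, size=2, replace=False)
            i = int(rng.choice(idx[pids[idx] == pa]))
            j = int(rng.choice(idx[pids[idx] == pb]))
        else:
            i, j = (int(v) for v in rng.choice(idx, size=2, replace=False))
        pairs.append(PairedExample(i=i, j=j, y=1))
    for _ in range(n_neg):
        ca, cb = (int(v) for v in rng.choice(classes, size=2, replace=False))
        i = int(rng.choice(by_class[ca]))
        j = int(rng.choice(by_class[cb]))
        pairs.append(PairedExample(i=i, j=j, y=0))
    # interleave positives and negatives so minibatches stay mixed
    order = rng.permutation(len(pairs))
    return [pairs[k] for k in order]


def _as_batch(e: np.ndarray) -> np.ndarray:
    e = np.asarray(e, dtype=np.float64)
    return e[None] if e.ndim == 1 else e


def contrastive_loss(
    e1: np.ndarray,
    e2: np.ndarray,
    y: np.ndarray | int,
    margin: float = 1.0,
    reduction: Literal["sum", "mean"] = "sum",
) -> float:
    """Contrastive loss y*D^2 + (1-y)*max(0, m-D)^2, summed over the batch."""
    loss, _, _ = contrastive_loss_and_grad(e1, e2, y, margin, reduction)
    return loss


def contrastive_loss_and_grad(
    e1: np.ndarray,
    e2: np.ndarray,
    y: np.ndarray | int,
    margin: float = 1.0,
    reduction: Literal["sum", "mean"] = "sum",
) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss plus analytic gradients with respect to both embedding batches."""
    if margin <= 0:
        raise ValueError("margin must be positive")
    E1, E2 = _as_batch(e1), _as_batch(e2)
    if E1.shape != E2.shape:
        raise ValueError(f"embedding shapes differ: {E1.shape} vs {E2.shape}")
    yv = np.atleast_1d(np.asarray(y, dtype=np.float64))
    if yv.shape[0] != E1.shape[0]:
        raise ValueError("y must have one entry per pair")
    diff = E1 - E2
    d = np.sqrt((diff**2).sum(axis=1))
    hinge = np.maximum(0.0, margin - d)
    per_pair = yv * d**2 + (1.0 - yv) * hinge**2
    # d(D^2)/de1 = 2*diff ; d(hinge^2)/de1 = -2*hinge*diff/D (0 at D=0)
    safe_d = np.where(d > 0, d, 1.0)
    coeff = 2.0 * yv - 2.0 * (1.0 - yv) * np.where(d > 0, hinge / safe_d, 0.0)
    g1 = coeff[:, None] * diff
    scale = 1.0
    if reduction == "mean":
        scale = 1.0 / yv.shape[0]
    loss = float(per_pair.sum() * scale)
    g1 = g1 * scale
    if np.asarray(e1).ndim == 1:
        return loss, g1[0], -g1[0]
    return loss, g1, -g1


def _joint_from_head_output(out: np.ndarray, n: int, p: int) -> tuple[np.ndarray, np.ndarray]:
    """Reassemble head outputs stacked as [us_a, sp_a, us_b, sp_b] blocks."""
    e_a = np.concatenate([out[0:n], out[n : 2 * n]], axis=1)
    e_b = np.concatenate([out[2 * n : 3 * n], out[3 * n : 4 * n]], axis=1)
    return e_a, e_b


def _head_grad_from_joint(g_a: np.ndarray, g_b: np.ndarray, p: int) -> np.ndarray:
    return np.concatenate(
        [g_a[:, :p], g_a[:, p:], g_b[:, :p], g_b[:, p:]], axis=0
    )


def train_siamese(
    chunks: Sequence,
    encoder_spec: EncoderSpec | SiameseEncoder,
    config: TrainConfig | None = None,
    features: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedSiamese:
    """Contrastive training of the shared-weight encoder on a chunk set.

    ``chunks`` is any sequence of records exposing ``label``,
    ``participant_id``, ``ultrasound_image`` and ``spectrogram_image``
    (see :class:`cleftus.pipeline.ChunkRecord`).  Each epoch draws a fresh
    balanced pair sample and runs minibatch Adam.  With a frozen backbone
    the penultimate features are computed once and only the projection
    head is optimized — the published zero-shot-features reading — which
    also makes training orders of magnitude faster.

    Returns the trained model with its per-epoch mean pair loss.  For a
    fixed seed the loss history is bitwise reproducible.
    """
    config = config or TrainConfig()
    if len(chunks) == 0:
        raise ValueError("cannot train on an empty chunk set")
    if isinstance(encoder_spec, SiameseEncoder):
        encoder = encoder_spec
    else:
        spec = dataclasses.replace(
            encoder_spec, projection_dim=config.embedding_dim
        ) if encoder_spec.projection_dim != config.embedding_dim else encoder_spec
        encoder = SiameseEncoder(spec, seed=config.seed)
    params = encoder.trainable_parameters()
    if not params:
        raise ValueError("encoder has no trainable parameters")
    from .nn import Adam

    opt = Adam(
        params,
        lr=config.learning_rate,
        weight_decay=config.weight_decay if config.optimizer == "adamw" else 0.0,
    )
    p = encoder.spec.projection_dim

    frozen = encoder.backbone_frozen
    if frozen:
        if features is not None:
            us_feats, sp_feats = features
            if len(us_feats) != len(chunks) or len(sp_feats) != len(chunks):
                raise ValueError("precomputed features must align with chunks")
        else:
            us_feats = _batched_features(encoder, [c.ultrasound_image for c in chunks])
            sp_feats = _batched_features(encoder, [c.spectrogram_image for c in chunks])

    ss = np.random.SeedSequence(config.seed)
    epoch_seeds = ss.generate_state(2 * config.n_epochs, dtype=np.uint32)
    loss_history: list[float] = []
    for epoch in range(config.n_epochs):
        pairs = sample_pairs(
            chunks,
            config.pairs_per_epoch,
            config.pos_fraction,
            seed=int(epoch_seeds[2 * epoch]),
        )
        drop_rng = np.random.default_rng(int(epoch_seeds[2 * epoch + 1]))
        epoch_loss = 0.0
        for lo in range(0, len(pairs), config.batch_size):
            batch = pairs[lo : lo + config.batch_size]
            n = len(batch)
            ia = np.array([pr.i for pr in batch])
            ib = np.array([pr.j for pr in batch])
            yv = np.array([pr.y for pr in batch], dtype=np.float64)
            if frozen:
                feats = np.concatenate(
                    [us_feats[ia], sp_feats[ia], us_feats[ib], sp_feats[ib]], axis=0
                )
                out = encoder.head.forward(feats)
            else:
                imgs = np.concatenate(
                    [
                        np.stack([chunks[k].ultrasound_image for k in ia]),
                        np.stack([chunks[k].spectrogram_image for k in ia]),
                        np.stack([chunks[k].ultrasound_image for k in ib]),
                        np.stack([chunks[k].spectrogram_image for k in ib]),
                    ]
                )
                out = encoder.encode_batch(imgs, train=True, rng=drop_rng)
            e_a, e_b = _joint_from_head_output(out, n, p)
            loss, g_a, g_b = contrastive_loss_and_grad(
                e_a, e_b, yv, config.margin, config.reduction
            )
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            g_out = _head_grad_from_joint(g_a, g_b, p)
            if frozen:
                encoder.head.backward(g_out)
            else:
                encoder.backward(g_out)
            opt.step()
            epoch_loss += loss if config.reduction == "sum" else loss * n
        loss_history.append(epoch_loss / len(pairs))
    return TrainedSiamese(encoder=encoder, train_config=config, loss_history=loss_history)


def _batched_features(
    encoder: SiameseEncoder, images: Sequence[np.ndarray], batch: int = 64
) -> np.ndarray:
    out = []
    for lo in range(0, len(images), batch):
        out.append(encoder.features(np.stack(images[lo : lo + batch])))
    return np.concatenate(out, axis=0)


# ----------------------------------------------------------------------
# checkpointing


def _config_blob(trained: TrainedSiamese) -> str:
    payload = {
        "encoder_spec": dataclasses.asdict(trained.encoder.spec),
        "train_config": dataclasses.asdict(trained.train_config),
    }
    return json.dumps(payload, sort_keys=True)


def save_checkpoint(trained: TrainedSiamese, path: str | Path) -> None:
    """Single-file checkpoint: parameters + configs + config hash."""
    blob = _config_blob(trained)
    meta = {
        "config": blob,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "loss_history": trained.loss_history,
    }
    arrays = {f"param/{k}": v for k, v in trained.encoder.state_dict().items()}
    np.savez(path, __meta__=json.dumps(meta), **arrays)


def load_checkpoint(path: str | Path) -> TrainedSiamese:
    with np.load(path, allow_pickle=False) as data:
        meta = json.loads(str(data["__meta__"]))
        blob = meta["config"]
        if hashlib.sha256(blob.encode()).hexdigest() != meta["config_sha256"]:
            raise ValueError("checkpoint config hash mismatch")
        payload = json.loads(blob)
        vit = ViTConfig(**payload["encoder_spec"].pop("vit"))
        spec = EncoderSpec(vit=vit, **payload["encoder_spec"])
        config = TrainConfig(**payload["train_config"])
        encoder = SiameseEncoder(spec, seed=config.seed)
        state = {
            k[len("param/") :]: data[k] for k in data.files if k.startswith("param/")
        }
    encoder.load_state_dict(state)
    return TrainedSiamese(
        encoder=encoder, train_config=config, loss_history=list(meta["loss_history"])
    )
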