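"""Contrastive loss, pair sampling, and metric-learning behaviour."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from cleftus.encoder import EncoderSpec, SiameseEncoder
from cleftus.errors import SamplingError
from cleftus.io import CleftLabel
from cleftus.siamese import (
    PairedExample,
    TrainConfig,
    contrastive_loss,
    contrastive_loss_and_grad,
    load_checkpoint,
    sample_pairs,
    save_checkpoint,
    train_siamese,
)


@dataclass
class FakeChunk:
    label: CleftLabel
    participant_id: str


class TestContrastiveLoss:
    @pytest.mark.parametrize(
        "e1, e2, y, expected",
        [
            ([1.0, 2.0], [1.0, 2.0], 1, 0.0),  # same point, same class
            ([0.0, 0.0], [1.2, 0.0], 0, 0.0),  # beyond margin
            ([0.0, 0.0], [0.4, 0.0], 0, 0.36),  # (1 - 0.4)^2
            ([0.0, 0.0], [0.5, 0.0], 1, 0.25),  # D^2
        ],
    )
    def test_closed_form_values(self, e1, e2, y, expected):
        loss = contrastive_loss(np.array(e1), np.array(e2), y, margin=1.0)
        assert loss == pytest.approx(expected, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            contrastive_loss(np.zeros(3), np.zeros(4), 1)

    def test_nonpositive_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            contrastive_loss(np.zeros(2), np.ones(2), 0, margin=0.0)

    def test_nonnegative_and_zero_conditions(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            e1, e2 = rng.normal(size=(2, 4))
            y = int(rng.integers(2))
            assert contrastive_loss(e1, e2, y) >= 0.0
        # zero iff positives coincide and negatives are >= m apart
        assert contrastive_loss(np.ones(3), np.ones(3), 1) == 0.0
        far = np.zeros(3)
        far[0] = 2.0
        assert contrastive_loss(np.zeros(3), far, 0, margin=1.0) == 0.0

    def test_gradient_matches_finite_differences_on_3d_toy(self):
        rng = np.random.default_rng(7)
        for y in (0, 1):
            e1 = rng.normal(size=3)
            e2 = e1 + rng.normal(scale=0.3, size=3)  # keep D < margin
            _, g1, g2 = contrastive_loss_and_grad(e1, e2, y, margin=1.0)
            for gi, ei in ((g1, e1), (g2, e2)):
                for k in range(3):
                    old = ei[k]
                    ei[k] = old + 1e-6
                    lp = contrastive_loss(e1, e2, y)
                    ei[k] = old - 1e-6
                    lm = contrastive_loss(e1, e2, y)
                    ei[k] = old
                    assert gi[k] == pytest.approx((lp - lm) / 2e-6, abs=1e-4)


def _fake_chunks():
    chunks = []
    for c in CleftLabel:
        for p in range(2):
            for _ in range(3):
                chunks.append(FakeChunk(label=c, participant_id=f"{c.name}{p}"))
    return chunks


class TestSamplePairs:
    def test_balanced_counts(self):
        pairs = sample_pairs(_fake_chunks(), 10, 0.5, seed=0)
        assert len(pairs) == 10
        assert sum(p.y for p in pairs) == 5

    def test_same_seed_is_deterministic(self):
        a = sample_pairs(_fake_chunks(), 20, 0.5, seed=3)
        b = sample_pairs(_fake_chunks(), 20, 0.5, seed=3)
        assert a == b

    def test_positives_cross_participants_when_possible(self):
        chunks = _fake_chunks()
        pairs = sample_pairs(chunks, 40, 1.0, seed=1)
        assert all(
            chunks[p.i].participant_id != chunks[p.j].participant_id for p in pairs
        )

    def test_single_class_all_positive_is_legal(self):
        chunks = [FakeChunk(CleftLabel.CP, f"p{i}") for i in range(4)]
        pairs = sample_pairs(chunks, 6, 1.0, seed=0)
        assert all(p.y == 1 for p in pairs)

    def test_class_with_single_chunk_raises_sampling_error(self):
        chunks = [
            FakeChunk(CleftLabel.CP, "a"),
            FakeChunk(CleftLabel.UCLP, "b"),
            FakeChunk(CleftLabel.UCLP, "c"),
        ]
        with pytest.raises(SamplingError, match="positive"):
            # CP will eventually be drawn for a positive pair
            sample_pairs(chunks, 50, 1.0, seed=0)

    def test_pair_references_distinct_chunks(self):
        with pytest.raises(ValueError, match="distinct"):
            PairedExample(i=2, j=2, y=1)


@dataclass
class FeatChunk:
    label: CleftLabel
    participant_id: str
    ultrasound_image: np.ndarray = None
    spectrogram_image: np.ndarray = None


def _separable_setup(n_per_class=6, dim=16, seed=0):
    """Linearly separable per-class feature clusters + a frozen encoder."""
    rng = np.random.default_rng(seed)
    centers = {c: rng.normal(scale=2.0, size=dim) for c in CleftLabel}
    chunks, us, sp = [], [], []
    for c in CleftLabel:
        for k in range(n_per_class):
            chunks.append(FeatChunk(label=c, participant_id=f"{c.name}{k % 3}"))
            us.append(centers[c] + rng.normal(scale=0.1, size=dim))
            sp.append(centers[c] + rng.normal(scale=0.1, size=dim))
    spec = EncoderSpec(
        freeze_backbone=True, projection_dim=8
    )
    enc = SiameseEncoder(spec, seed=seed)
    # head operates directly on the synthetic features
    from cleftus.nn import Linear

    enc.head = Linear(dim, 8, np.random.default_rng(seed))
    return chunks, (np.array(us), np.array(sp)), enc


class TestTrainSiamese:
    def test_loss_decreases_on_separable_data(self):
        chunks, feats, enc = _separable_setup()
        cfg = TrainConfig(
            n_epochs=10, pairs_per_epoch=64, batch_size=16, embedding_dim=8,
            learning_rate=1e-2, seed=0,
        )
        trained = train_siamese(chunks, enc, cfg, features=feats)
        assert len(trained.loss_history) == 10
        assert trained.loss_history[-1] < trained.loss_history[0]

    def test_same_seed_gives_identical_loss_history(self):
        histories = []
        for _ in range(2):
            chunks, feats, enc = _separable_setup(seed=4)
            cfg = TrainConfig(
                n_epochs=4, pairs_per_epoch=32, batch_size=16, embedding_dim=8,
                learning_rate=1e-2, seed=11,
            )
            histories.append(train_siamese(chunks, enc, cfg, features=feats).loss_history)
        assert histories[0] == histories[1]

    def test_converged_separable_case_pushes_classes_beyond_margin(self):
        chunks, feats, enc = _separable_setup(seed=2)
        cfg = TrainConfig(
            n_epochs=80, pairs_per_epoch=96, batch_size=32, embedding_dim=8,
            learning_rate=2e-2, margin=1.0, seed=2,
        )
        train_siamese(chunks, enc, cfg, features=feats)
        us, sp = feats
        emb = np.concatenate([enc.head.forward(us), enc.head.forward(sp)], axis=1)
        labels = np.array([int(c.label) for c in chunks])
        intra, inter = [], []
        for i in range(len(chunks)):
            for j in range(i + 1, len(chunks)):
                d = np.linalg.norm(emb[i] - emb[j])
                (intra if labels[i] == labels[j] else inter).append(d)
        assert min(inter) >= cfg.margin - 0.05
        assert np.mean(intra) < np.mean(inter)

    def test_empty_chunk_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            train_siamese([], EncoderSpec(), TrainConfig(n_epochs=1))


def test_checkpoint_round_trip(tmp_path):
    chunks, feats, enc = _separable_setup(seed=5)
    cfg = TrainConfig(
        n_epochs=2, pairs_per_epoch=16, batch_size=8, embedding_dim=8,
        learning_rate=1e-2, seed=5,
    )
    # use the real image pathway so the checkpointed encoder is self-contained
    rng = np.random.default_rng(0)
    img_chunks = [
        FeatChunk(
            label=c.label,
            participant_id=c.participant_id,
            ultrasound_image=rng.normal(size=(3, 224, 224)),
            spectrogram_image=rng.normal(size=(3, 224, 224)),
        )
        for c in chunks[0:2] + chunks[6:8] + chunks[12:14]  # two per class
    ]
    trained = train_siamese(img_chunks, EncoderSpec(freeze_backbone=True), cfg)
    path = tmp_path / "ckpt.npz"
    save_checkpoint(trained, path)
    restored = load_checkpoint(path)
    img = np.random.default_rng(1).normal(size=(1, 3, 224, 224))
    assert np.allclose(
        trained.encoder.encode_batch(img), restored.encoder.encode_batch(img)
    )
    assert restored.loss_history == trained.loss_history
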