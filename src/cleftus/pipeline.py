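"""Glue between the corpus on disk and the learning modules.

Turns a validated manifest into a flat list of :class:`ChunkRecord`, each
holding one temporally aligned ultrasound/spectrogram image pair plus the
bookkeeping (participant, utterance, chunk index, label) the training and
evaluation stages need.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .encoder import SiameseEncoder
from .io import CleftLabel, Manifest, read_audio, read_frame_sequence
from .preprocess import ChunkPair, PreprocessConfig, preprocess_utterance

__all__ = ["ChunkRecord", "load_chunk_dataset", "joint_embeddings"]


@dataclass
class ChunkRecord:
    """One aligned chunk pair with its provenance."""

    participant_id: str
    utterance_id: str
    chunk_index: int
    label: CleftLabel
    time_span_s: tuple[float, float]
    ultrasound_image: np.ndarray  # (3, 224, 224) normalized
    spectrogram_image: np.ndarray  # (3, 224, 224) normalized


def load_chunk_dataset(
    manifest: Manifest, config: PreprocessConfig | None = None
) -> list[ChunkRecord]:
    """Read every utterance in the manifest and cut it into chunk records.

    Records keep manifest order: utterances in row order, chunks in
    temporal order within each utterance.
    """
    config = config or PreprocessConfig()
    by_id = {p.id: p for p in manifest.participants}
    records: list[ChunkRecord] = []
    for utt in manifest.utterances:
        seq = read_frame_sequence(utt.frames_path, utt.params_path)
        audio = read_audio(utt.audio_path)
        pairs: list[ChunkPair] = preprocess_utterance(seq, audio, config)
        label = by_id[utt.participant_id].label
        for pair in pairs:
            records.append(
                ChunkRecord(
                    participant_id=utt.participant_id,
                    utterance_id=utt.utterance_id,
                    chunk_index=pair.index,
                    label=label,
                    time_span_s=pair.time_span_s,
                    ultrasound_image=pair.ultrasound_image,
                    spectrogram_image=pair.spectrogram_image,
                )
            )
    return records


def joint_embeddings(
    chunks: Sequence[ChunkRecord],
    encoder: SiameseEncoder,
    batch_size: int = 64,
) -> np.ndarray:
    """Evaluation-mode joint embeddings, one row per chunk.

    Both modalities pass through the same shared-weight encoder; the row
    is the concatenation [ultrasound ; spectrogram] of the two projected
    embeddings (2 x projection_dim columns).
    """
    us, sp = [], []
    for lo in range(0, len(chunks), batch_size):
        batch = chunks[lo : lo + batch_size]
        us.append(encoder.encode_batch(np.stack([c.ultrasound_image for c in batch])))
        sp.append(encoder.encode_batch(np.stack([c.spectrogram_image for c in batch])))
    return np.concatenate([np.concatenate(us), np.concatenate(sp)], axis=1)
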