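"""Temporal chunking and image rendering for both modalities.

Each recording is cut into K contiguous chunks.  A chunk is represented by
a temporally aligned image pair: one ultrasound frame (or frame average)
and the power-spectrogram slice of the synchronized audio over the same
time span, both rendered as normalized 3x224x224 rasters ready for the
encoder.

Time convention: half-open [t0, t1) intervals, 0-based indices.  The K
chunk spans always partition [0, duration) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .errors import AlignmentError
from .io import AudioSignal, FrameSequence

__all__ = [
    "StftParams",
    "PreprocessConfig",
    "SpectrogramMatrix",
    "ChunkPair",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "slice_into_chunks",
    "chunk_to_image",
    "compute_spectrogram",
    "segment_spectrogram",
    "to_model_image",
    "spectrogram_to_db_image",
    "preprocess_utterance",
]

IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])


@dataclass
class StftParams:
    """Short-time Fourier transform settings for the speech spectrogram.

    Defaults are standard wide-band speech-analysis values: 25 ms Hann
    window, 10 ms hop.  The stored spectrogram matrix is linear power
    |STFT|^2; decibel compression applies only when rendering the
    spectrogram *image*.
    """

    window_length_s: float = 0.025
    hop_length_s: float = 0.010
    window: Literal["hann", "rectangular"] = "hann"
    n_fft: int | None = None  # None -> smallest power of two >= window samples
    log_compress: bool = True
    floor_db: float = -80.0

    def __post_init__(self) -> None:
        if self.window_length_s <= 0 or self.hop_length_s <= 0:
            raise ValueError("window and hop lengths must be positive")
        if self.hop_length_s > self.window_length_s:
            raise ValueError("hop length must not exceed window length")
        if self.window not in ("hann", "rectangular"):
            raise ValueError(f"unknown window {self.window!r}")

    def window_samples(self, sample_rate: int) -> int:
        return int(round(self.window_length_s * sample_rate))

    def hop_samples(self, sample_rate: int) -> int:
        return max(1, int(round(self.hop_length_s * sample_rate)))

    def fft_size(self, sample_rate: int) -> int:
        win = self.window_samples(sample_rate)
        if self.n_fft is not None:
            if self.n_fft < win:
                raise ValueError("n_fft must be >= window length in samples")
            return self.n_fft
        n = 1
        while n < win:
            n *= 2
        return n


@dataclass
class PreprocessConfig:
    """How a recording becomes K model-ready chunk pairs."""

    n_chunks: int = 8
    chunk_image_mode: Literal["middle_frame", "mean_frame"] = "middle_frame"
    image_size: int = 224
    normalize: Literal["imagenet"] = "imagenet"
    stft: StftParams = field(default_factory=StftParams)

    def __post_init__(self) -> None:
        if self.n_chunks < 1:
            raise ValueError("n_chunks must be >= 1")
        if self.image_size != 224:
            raise ValueError("image_size is fixed at 224 for the encoder")


@dataclass
class SpectrogramMatrix:
    """Linear power spectrogram: full two-sided DFT bins x frames.

    ``values[k, f]`` is the squared magnitude of bin k of the windowed DFT
    of frame f.  Frames start every ``hop`` samples at 0 (no centering), so
    frame f spans samples [f*hop, f*hop + win) and its center time is
    (f*hop + win/2) / sample_rate.
    """

    values: np.ndarray  # (n_fft, n_frames), power
    bin_hz: float
    frame_times_s: np.ndarray  # frame center times, strictly increasing

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=np.float64)
        if np.any(self.values < 0):
            raise ValueError("power spectrogram must be nonnegative")
        if self.frame_times_s.size > 1 and not np.all(
            np.diff(self.frame_times_s) > 0
        ):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class ChunkPair:
    """One temporally aligned ultrasound/spectrogram image pair."""

    index: int
    time_span_s: tuple[float, float]  # half-open [t0, t1)
    ultrasound_image: np.ndarray  # (3, 224, 224), ImageNet-normalized
    spectrogram_image: np.ndarray  # (3, 224, 224), ImageNet-normalized


def slice_into_chunks(n_frames: int, n_chunks: int) -> list[range]:
    """Partition frame indices 0..n_frames-1 into K contiguous ranges.

    Sizes differ by at most one; the first ``n_frames mod K`` chunks are
    the larger ones.  Accepts either a FrameSequence or a frame count.
    """
    if isinstance(n_frames, FrameSequence):
        n_frames = n_frames.n_frames
    if n_chunks < 1:
        raise ValueError("number of chunks must be >= 1")
    if n_chunks > n_frames:
        raise ValueError(
            f"cannot slice {n_frames} frames into {n_chunks} chunks"
        )
    base, extra = divmod(n_frames, n_chunks)
    ranges: list[range] = []
    lo = 0
    for i in range(n_chunks):
        size = base + (1 if i < extra else 0)
        ranges.append(range(lo, lo + size))
        lo += size
    return ranges


def chunk_to_image(
    seq: FrameSequence,
    frame_range: range | Sequence[int],
    mode: Literal["middle_frame", "mean_frame"] = "middle_frame",
) -> np.ndarray:
    """Reduce a chunk's frames to one 2-D raster.

    ``middle_frame`` picks the frame at floor((lo + hi) / 2) where hi is the
    last index in the range (inclusive); ``mean_frame`` is the pixel-wise
    mean across the chunk.
    """
    idx = list(frame_range)
    if not idx:
        raise ValueError("empty frame range")
    if mode == "middle_frame":
        mid = (idx[0] + idx[-1]) // 2
        return np.asarray(seq.frames[mid], dtype=np.float64)
    if mode == "mean_frame":
        return np.asarray(seq.frames[idx], dtype=np.float64).mean(axis=0)
    raise ValueError(f"unknown chunk image mode {mode!r}")


def compute_spectrogram(sig: AudioSignal, p: StftParams | None = None) -> SpectrogramMatrix:
    """Power spectrogram |STFT(s)|^2 of a mono signal.

    Frames are hop-spaced with no centering or tail padding; each frame is
    windowed and transformed with a full (two-sided) n_fft-point DFT, so
    for a rectangular window each frame satisfies Parseval's identity:
    sum_k values[k, f] == n_fft * sum_n x[n]^2 over the frame.
    """
    p = p or StftParams()
    x = np.asarray(sig.samples, dtype=np.float64)
    sr = sig.sample_rate
    win = p.window_samples(sr)
    hop = p.hop_samples(sr)
    n_fft = p.fft_size(sr)
    if x.size < win:
        raise ValueError(
            f"signal of {x.size} samples is shorter than one {win}-sample window"
        )
    n_frames = 1 + (x.size - win) // hop
    starts = np.arange(n_frames) * hop
    frames = np.lib.stride_tricks.sliding_window_view(x, win)[starts]
    if p.window == "hann":
        w = np.hanning(win)
        frames = frames * w
    spectrum = np.fft.fft(frames, n=n_fft, axis=1)
    values = np.abs(spectrum) ** 2  # (n_frames, n_fft)
    times = (starts + win / 2.0) / sr
    return SpectrogramMatrix(
        values=values.T.copy(), bin_hz=sr / n_fft, frame_times_s=times
    )


def _uniform_spans(n_chunks: int, duration_s: float) -> list[tuple[float, float]]:
    edges = np.linspace(0.0, duration_s, n_chunks + 1)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(n_chunks)]


def segment_spectrogram(
    spec: SpectrogramMatrix,
    n_chunks: int,
    duration_s: float,
    spans: Sequence[tuple[float, float]] | None = None,
) -> list[np.ndarray]:
    """Split a spectrogram into per-chunk sub-matrices.

    STFT frame f goes to the chunk whose half-open time span contains the
    frame's center time; every frame lands in exactly one chunk.  ``spans``
    overrides the default uniform partition of [0, duration_s) — the
    pipeline passes the video-derived chunk spans here so both modalities
    cut at identical times.  A chunk that captures no frame raises an
    alignment error naming the chunk.
    """
    if spans is None:
        spans = _uniform_spans(n_chunks, duration_s)
    if len(spans) != n_chunks:
        raise ValueError("spans length must equal n_chunks")
    centers = spec.frame_times_s
    # Half-open [t0, t1); the final span absorbs a center landing exactly on
    # duration_s only if it is strictly inside (it never is by construction).
    assignment = np.full(centers.size, -1, dtype=int)
    for i, (t0, t1) in enumerate(spans):
        mask = (centers >= t0) & (centers < t1)
        assignment[mask] = i
    segments: list[np.ndarray] = []
    for i in range(n_chunks):
        cols = np.nonzero(assignment == i)[0]
        if cols.size == 0:
            raise AlignmentError(
                f"chunk {i} (span [{spans[i][0]:.4f}, {spans[i][1]:.4f}) s) "
                "captures no spectrogram frames"
            )
        segments.append(spec.values[:, cols])
    return segments


def spectrogram_to_db_image(
    segment: np.ndarray, floor_db: float = -80.0
) -> np.ndarray:
    """Render a power sub-matrix as a decibel raster for the encoder.

    Only the nonnegative-frequency half is rendered (the two-sided matrix
    is conjugate-symmetric), low frequencies at the bottom row.  Power is
    expressed in dB relative to the segment maximum and clipped at
    ``floor_db``; an all-zero segment renders flat.
    """
    seg = np.asarray(segment, dtype=np.float64)
    half = seg[: seg.shape[0] // 2 + 1]
    peak = half.max()
    if peak <= 0:
        return np.zeros_like(half[::-1])
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(half / peak)
    db = np.clip(db, floor_db, 0.0)
    return db[::-1]  # flip so low frequencies sit at the image bottom


def to_model_image(raster: np.ndarray, image_size: int = 224) -> np.ndarray:
    """Turn any finite 2-D raster into an encoder-ready 3x224x224 tensor.

    Min-max scaled to [0, 1] (a constant raster maps to 0.5 everywhere),
    bilinearly resized, replicated to three channels, then standardized
    with the ImageNet channel statistics.
    """
    x = np.asarray(raster, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("raster must be 2-D")
    if not np.all(np.isfinite(x)):
        raise ValueError("raster contains non-finite values")
    lo, hi = x.min(), x.max()
    if hi > lo:
        x = (x - lo) / (hi - lo)
    else:
        x = np.full_like(x, 0.5)
    if x.shape != (image_size, image_size):
        x = _sk_resize(
            x, (image_size, image_size), order=1, mode="edge",
            anti_aliasing=False, preserve_range=True,
        )
    rgb = np.broadcast_to(x, (3, image_size, image_size)).copy()
    rgb -= IMAGENET_MEAN[:, None, None]
    rgb /= IMAGENET_STD[:, None, None]
    return rgb


def preprocess_utterance(
    seq: FrameSequence, audio: AudioSignal, config: PreprocessConfig | None = None
) -> list[ChunkPair]:
    """Cut one recording into K aligned ultrasound/spectrogram image pairs.

    Chunk boundaries are defined on the video frame grid and mapped onto
    the audio timeline proportionally, so the K spans partition both
    modalities even when the two stream durations differ by a few
    milliseconds.
    """
    config = config or PreprocessConfig()
    K = config.n_chunks
    ranges = slice_into_chunks(seq.n_frames, K)
    video_spans = [
        (r.start / seq.fps, r.stop / seq.fps) for r in ranges
    ]
    spec = compute_spectrogram(audio, config.stft)
    scale = audio.duration_s / seq.duration_s
    audio_spans = [(t0 * scale, t1 * scale) for t0, t1 in video_spans]
    segments = segment_spectrogram(spec, K, audio.duration_s, spans=audio_spans)
    pairs: list[ChunkPair] = []
    for i, (rng, span, seg) in enumerate(zip(ranges, video_spans, segments)):
        us = chunk_to_image(seq, rng, config.chunk_image_mode)
        if config.stft.log_compress:
            sp = spectrogram_to_db_image(seg, config.stft.floor_db)
        else:
            sp = seg[: seg.shape[0] // 2 + 1][::-1]
        pairs.append(
            ChunkPair(
                index=i,
                time_span_s=span,
                ultrasound_image=to_model_image(us, config.image_size),
                spectrogram_image=to_model_image(sp, config.image_size),
            )
        )
    return pairs
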