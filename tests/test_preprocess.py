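"""Chunk slicing, spectrogram computation, and image normalization."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cleftus.errors import AlignmentError
from cleftus.io import AudioSignal, FrameSequence
from cleftus.preprocess import (
    IMAGENET_MEAN,
    IMAGENET_STD,
    StftParams,
    chunk_to_image,
    compute_spectrogram,
    preprocess_utterance,
    segment_spectrogram,
    slice_into_chunks,
    to_model_image,
)


class TestSliceIntoChunks:
    @pytest.mark.parametrize(
        "n, k, sizes",
        [
            (10, 1, [10]),
            (12, 4, [3, 3, 3, 3]),
            (10, 3, [4, 3, 3]),  # remainder chunks come first
        ],
    )
    def test_examples(self, n, k, sizes):
        ranges = slice_into_chunks(n, k)
        assert [len(r) for r in ranges] == sizes

    @pytest.mark.parametrize("n, k", [(10, 11), (10, 0), (5, -1)])
    def test_invalid_k(self, n, k):
        with pytest.raises(ValueError):
            slice_into_chunks(n, k)

    @settings(deadline=None)
    @given(st.integers(1, 500), st.data())
    def test_partition_property(self, n, data):
        k = data.draw(st.integers(1, n))
        ranges = slice_into_chunks(n, k)
        flat = [i for r in ranges for i in r]
        assert flat == list(range(n))  # contiguous, disjoint, covering
        sizes = [len(r) for r in ranges]
        assert max(sizes) - min(sizes) <= 1
        assert sorted(sizes, reverse=True) == sizes


class TestChunkToImage:
    def _seq(self, frames):
        return FrameSequence(frames=np.asarray(frames, dtype=float), fps=50.0)

    def test_middle_frame_of_ten(self):
        seq = self._seq([np.full((2, 2), i) for i in range(10)])
        img = chunk_to_image(seq, range(0, 10), "middle_frame")
        assert np.all(img == 4)  # floor((0+9)/2)

    def test_mean_frame_idempotent_on_identical_frames(self):
        frame = np.arange(6.0).reshape(2, 3)
        seq = self._seq([frame, frame])
        assert np.allclose(chunk_to_image(seq, range(0, 2), "mean_frame"), frame)

    def test_mean_of_zero_and_one(self):
        seq = self._seq([np.zeros((2, 2)), np.ones((2, 2))])
        assert np.all(chunk_to_image(seq, range(0, 2), "mean_frame") == 0.5)

    def test_empty_range_rejected(self):
        seq = self._seq([np.zeros((2, 2))])
        with pytest.raises(ValueError, match="empty"):
            chunk_to_image(seq, range(0, 0))


def _brute_force_power(x, win, hop, n_fft):
    """O(N^2) reference: frame-wise rectangular-window DFT magnitudes squared."""
    n_frames = 1 + (len(x) - win) // hop
    out = np.empty((n_fft, n_frames))
    for f in range(n_frames):
        frame = x[f * hop : f * hop + win]
        for k in range(n_fft):
            acc = 0.0 + 0.0j
            for n, xn in enumerate(frame):
                acc += xn * np.exp(-2j * np.pi * k * n / n_fft)
            out[k, f] = abs(acc) ** 2
    return out


class TestComputeSpectrogram:
    def test_zero_signal_gives_zero_matrix(self):
        sig = AudioSignal(samples=np.zeros(1000), sample_rate=8000)
        spec = compute_spectrogram(sig, StftParams())
        assert np.all(spec.values == 0)

    def test_matches_brute_force_dft_oracle(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=96)
        sig = AudioSignal(samples=x, sample_rate=1000)
        p = StftParams(window_length_s=0.032, hop_length_s=0.016, window="rectangular")
        spec = compute_spectrogram(sig, p)
        oracle = _brute_force_power(x, win=32, hop=16, n_fft=32)
        assert spec.values.shape == oracle.shape
        assert np.max(np.abs(spec.values - oracle)) < 1e-9

    def test_sinusoid_at_exact_bin_has_power_n_squared_over_4(self):
        N, k, sr = 256, 8, 1000
        x = np.cos(2 * np.pi * k * np.arange(N) / N)
        sig = AudioSignal(samples=x, sample_rate=sr)
        p = StftParams(window_length_s=N / sr, hop_length_s=N / sr, window="rectangular")
        spec = compute_spectrogram(sig, p)
        assert spec.n_frames == 1
        assert spec.values[k, 0] == pytest.approx(N**2 / 4, rel=1e-10)

    def test_parseval_per_frame_for_rectangular_window(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2048)
        sig = AudioSignal(samples=x, sample_rate=8000)
        p = StftParams(window_length_s=256 / 8000, hop_length_s=128 / 8000,
                       window="rectangular")
        spec = compute_spectrogram(sig, p)
        n_fft = 256
        for f in range(spec.n_frames):
            frame = x[f * 128 : f * 128 + 256]
            lhs = spec.values[:, f].sum()
            rhs = n_fft * (frame**2).sum()
            assert abs(lhs - rhs) / rhs < 1e-6

    def test_signal_shorter_than_window_rejected(self):
        sig = AudioSignal(samples=np.zeros(10), sample_rate=8000)
        with pytest.raises(ValueError, match="shorter"):
            compute_spectrogram(sig, StftParams())


class TestSegmentSpectrogram:
    def _spec(self, duration, sr=1000, win=0.02, hop=0.01):
        t = np.arange(int(duration * sr)) / sr
        sig = AudioSignal(samples=np.sin(2 * np.pi * 100 * t), sample_rate=sr)
        return compute_spectrogram(
            sig, StftParams(window_length_s=win, hop_length_s=hop)
        )

    def test_single_chunk_is_full_matrix(self):
        spec = self._spec(1.0)
        (seg,) = segment_spectrogram(spec, 1, 1.0)
        assert np.array_equal(seg, spec.values)

    def test_half_open_interval_rule(self):
        spec = self._spec(2.0)
        segs = segment_spectrogram(spec, 2, 2.0)
        n0 = int(np.sum(spec.frame_times_s < 1.0))
        assert segs[0].shape[1] == n0
        assert segs[1].shape[1] == spec.n_frames - n0

    def test_one_frame_per_chunk_at_k_equals_n(self):
        spec = self._spec(0.5)
        segs = segment_spectrogram(spec, spec.n_frames, 0.5)
        assert all(s.shape[1] == 1 for s in segs)

    def test_empty_chunk_raises_alignment_error_naming_chunk(self):
        spec = self._spec(0.1)  # few frames
        with pytest.raises(AlignmentError, match="chunk"):
            segment_spectrogram(spec, spec.n_frames + 2, 0.1)


class TestToModelImage:
    def test_constant_input_maps_to_half_gray(self):
        out = to_model_image(np.full((30, 40), 7.0))
        for c in range(3):
            expected = (0.5 - IMAGENET_MEAN[c]) / IMAGENET_STD[c]
            assert np.allclose(out[c], expected)

    def test_already_224_ramp_resize_is_identity(self):
        ramp = np.tile(np.linspace(0, 1, 224), (224, 1))
        out = to_model_image(ramp)
        recovered = out[0] * IMAGENET_STD[0] + IMAGENET_MEAN[0]
        assert np.allclose(recovered, ramp, atol=1e-12)

    def test_round_trip_recovers_resized_unit_image(self):
        from skimage.transform import resize

        rng = np.random.default_rng(3)
        raw = rng.random((64, 48))
        scaled = (raw - raw.min()) / (raw.max() - raw.min())
        oracle = resize(scaled, (224, 224), order=1, mode="edge",
                        anti_aliasing=False, preserve_range=True)
        out = to_model_image(raw)
        for c in range(3):
            rec = out[c] * IMAGENET_STD[c] + IMAGENET_MEAN[c]
            assert np.allclose(rec, oracle, atol=1e-6)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            to_model_image(np.array([[1.0, np.inf]]))


def test_preprocess_utterance_spans_partition_recording():
    rng = np.random.default_rng(0)
    seq = FrameSequence(frames=rng.random((45, 32, 32)), fps=30.0)
    sr = 8000
    audio = AudioSignal(samples=rng.normal(size=int(1.5 * sr)), sample_rate=sr)
    pairs = preprocess_utterance(seq, audio)
    assert len(pairs) == 8
    assert pairs[0].time_span_s[0] == 0.0
    assert pairs[-1].time_span_s[1] == pytest.approx(seq.duration_s)
    for a, b in zip(pairs, pairs[1:]):
        assert a.time_span_s[1] == pytest.approx(b.time_span_s[0])
    for pr in pairs:
        assert pr.ultrasound_image.shape == (3, 224, 224)
        assert pr.spectrogram_image.shape == (3, 224, 224)
        assert np.all(np.isfinite(pr.ultrasound_image))
        assert np.all(np.isfinite(pr.spectrogram_image))
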