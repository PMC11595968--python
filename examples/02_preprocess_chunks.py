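"""Cut one recording into temporally aligned chunk pairs.

Loads the first utterance of a freshly simulated corpus, slices it into
K = 8 chunks, and shows how the video spans and the spectrogram frames
line up.  Each chunk becomes a 3x224x224 ultrasound image and a matching
3x224x224 spectrogram image, both ImageNet-normalized for the encoder.
"""

import tempfile

from cleftus import load_manifest, read_audio, read_frame_sequence
from cleftus.preprocess import PreprocessConfig, compute_spectrogram, preprocess_utterance
from cleftus.synthdata import SynthConfig, generate_dataset

out = tempfile.mkdtemp(prefix="cleftus_prep_")
manifest = generate_dataset(SynthConfig(n_per_class=1, seed=3), out)

utt = manifest.utterances[0]
seq = read_frame_sequence(utt.frames_path, utt.params_path)
audio = read_audio(utt.audio_path)
print(f"{utt.participant_id}/{utt.utterance_id}: "
      f"{seq.n_frames} frames at {seq.fps} fps ({seq.duration_s:.2f} s), "
      f"{audio.samples.size} audio samples at {audio.sample_rate} Hz")

spec = compute_spectrogram(audio)
print(f"spectrogram: {spec.values.shape[0]} DFT bins x {spec.n_frames} frames, "
      f"bin width {spec.bin_hz:.1f} Hz")

pairs = preprocess_utterance(seq, audio, PreprocessConfig(n_chunks=8))
for p in pairs:
    t0, t1 = p.time_span_s
    print(f"  chunk {p.index}: [{t0:.3f}, {t1:.3f}) s  "
          f"us {p.ultrasound_image.shape}  sp {p.spectrogram_image.shape}")
# The 8 half-open spans partition [0, 1.5) exactly; every STFT frame is
# assigned to the single chunk containing its center time.
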