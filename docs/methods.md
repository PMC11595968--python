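# Methods

This note records the modelling choices, default parameters and known
limitations of the cleftus pipeline, in the order data flows through it.

## Data model and I/O

A corpus is a manifest (CSV or JSON, one row per utterance) referencing,
per utterance, a directory of lexicographically ordered PNG ultrasound
frames with a `key=value` sidecar (`fps`, `width`, `height`, `n_frames`)
and a mono PCM WAV. Proprietary raw ultrasound formats and video codecs
are deliberately out of scope: the directory-of-PNG layout is trivially
inspectable and is what the synthetic generator writes. Stereo WAVs are
averaged to mono; integer PCM is scaled by the magnitude of the most
negative representable value, so full scale maps to ±1 within one
quantization step. Missing sex/age are permitted and recorded as missing;
sex is only used as a secondary stratification key.

The three class labels carry fixed ordinals (CP = 0, UCLP = 1, BCLP = 2)
used for every deterministic tie-break in the pipeline.

## Chunking and alignment

A recording is cut into K contiguous chunks on the video frame grid;
sizes differ by at most one frame and the larger chunks come first.
K defaults to 8 so a typical 1–3 s utterance yields roughly 0.2–0.4 s
chunks — long enough to hold an articulatory gesture, short enough that
several chunks vote per utterance. All intervals are half-open [t0, t1)
with 0-based indices; the K spans partition [0, duration) exactly, and
slicing depends only on the frame count, never on content.

A chunk's ultrasound image is its middle frame by default (the sharpest
single articulatory posture); a pixel-wise mean across the chunk is an
option. The video-derived spans are mapped proportionally onto the audio
timeline, and each STFT frame goes to the unique chunk containing its
center time, so both modalities cut at identical relative positions even
when stream durations differ by a few milliseconds.

## Spectrogram

The spectrogram is linear power |STFT|², computed with hop-spaced,
uncentered frames and a full two-sided DFT, which makes the per-frame
Parseval identity hold exactly for rectangular windows (a property test
checks it to 1e−6 relative). Defaults are standard wide-band speech
analysis settings: 25 ms Hann window, 10 ms hop, FFT size the next power
of two. The matrix itself stays linear; only the rendered image is
compressed to decibels relative to the segment peak, clipped at −80 dB
(the nonnegative-frequency half, low frequencies at the bottom).

Both chunk images are min-max scaled to [0, 1] (a constant raster maps to
0.5), bilinearly resized to 224×224, replicated to three channels, and
standardized with the ImageNet channel statistics — the preprocessing
contract of the pretrained vision backbones this pipeline is built
around.

## Encoder

One encoder instance serves both modalities, so the Siamese shared-weight
property holds by construction rather than by weight-copying. Two
backbones exist:

* **`vit_trainable`** — a vision transformer implemented in numpy with
  hand-derived backward passes (patch embedding, class token, learned
  positional embeddings, pre-norm blocks with multi-head attention and
  GELU MLPs, final LayerNorm). The desk-scale default is 2 layers /
  4 heads / 64 hidden so CPU tests run in seconds; the full-size
  configuration (12/12/768, patch 16, dropout 0.1) is available as
  `VIT_FULL`. Everything trainable runs in float64; analytic gradients
  are verified against central finite differences in the test suite.
  With `freeze_backbone=True` the backbone keeps its random
  initialization, is cast to float32 (it never sees a gradient), and only
  the linear projection head trains — penultimate features are then
  computed once and cached, which makes cross-validation fast.
* **`biomedclip_frozen`** — an adapter for a pretrained biomedical CLIP
  vision tower used zero-shot. It requires the optional torch/open_clip
  stack plus downloadable weights and raises a dependency error with an
  actionable message otherwise; nothing in this package ever fine-tunes
  such a backbone.

The default readout pools patch tokens by mean; class-token readout is an
option. Mean pooling is the more informative readout of an untrained
backbone, which matters for the frozen-at-initialization configuration.
Per-modality embeddings (projection dimension 128) are fused by plain
concatenation — no renormalization — giving a 256-dimensional joint
embedding whose squared norm is the sum of the modality squared norms.

## Contrastive training

Pairs are sampled fresh each epoch: 2048 pairs, half positive, with
positives drawn across *different participants* of the same class
whenever possible so the encoder cannot shortcut through speaker
identity. The loss is y·D² + (1−y)·max(0, m−D)² on joint-embedding
Euclidean distance, summed over the batch (mean reduction is a config
option for learning-rate stability). Defaults: Adam, learning rate 1e−4,
batch 32, 20 epochs, margin 1.0. An alternative preset (AdamW, 3e−5,
weight decay 0.01, batch 16, 30 epochs) matches the encoder-pretraining
configuration; the Adam preset governs the Siamese objective by default.
At D = 0 the hinge term's subgradient is taken as 0. A non-finite loss
aborts with the epoch index. For a fixed seed, training is bitwise
reproducible (all randomness flows through seeded numpy generators;
single-threaded CPU arithmetic).

## Few-shot classification and voting

Prototypes are arithmetic means of support-chunk joint embeddings, one
per class; a query chunk takes the nearest prototype under Euclidean
distance, exact ties going to the lowest class ordinal. Within each CV
training fold, *all* training-participant chunks form the support set;
episodic N-way-k-shot sampling is not the default because the evaluation
protocol scores a single model per fold.

Temporal voting operationalizes "trust consistent chunks more": for chunk
i, c_i is the fraction of chunks within w positions (excluding i, clipped
at the sequence ends; c_i = 0 with no neighbors) sharing i's label, and
its vote weighs 1 + α·c_i. Defaults w = 1, α = 1, so weights live in
[1, 2] and α = 0 recovers exact unweighted majority voting (tested
against a brute-force oracle). Sequence ties break by smaller mean chunk
distance, then class ordinal. The voting unit defaults to the
participant — all of a child's chunks pooled in utterance order — with
per-utterance voting as an option; participant-level outcomes are what a
per-child diagnostic evaluation measures.

## Cross-validation and metrics

Folds are assigned at the participant level: within each class,
participants are shuffled by the run seed, grouped by sex, and dealt
round-robin with a deal position carried across blocks, which keeps both
class and sex proportions within one participant of even. Grouping by
participant is non-negotiable for honest few-shot evaluation — the
no-leakage condition (train and test participant sets disjoint) is
asserted on every run. K defaults to 5; K = number of participants gives
leave-one-participant-out. With a frozen backbone the cached penultimate
features are shared across folds (the backbone never trains, so nothing
leaks); the projection head is freshly initialized and retrained per
fold.

Metrics are one-vs-rest from the confusion matrix (rows true, columns
predicted, class order CP/UCLP/BCLP): precision TP/(TP+FP), recall
TP/(TP+FN), F1 = 2PR/(P+R), accuracy = trace/total, plus unweighted
macro and support-weighted averages. Zero denominators yield 0 with a
warning, matching common tooling; the implementation is cross-checked
against scikit-learn to 1e−12 on random inputs. Reports display at two
decimals on the percent scale.

## Synthetic corpus

The generator emulates the *structure* of a pediatric cleft corpus, not
its physics. Class identity is encoded twice: frames carry a Gaussian
ridge whose curvature/slope differ by class (CP: 0.8/−0.5, UCLP: −0.8/0,
BCLP: 0/0.7 on a [−1,1]² grid — pairwise template correlations are far
below 0.9), smoothly displaced by a 1.5 Hz sinusoid over time; audio
carries two class-specific spectral bands (CP 500/1500 Hz, UCLP 900/2200,
BCLP 1400/3000, each with a weaker 1.15× sideband) under a syllable-like
3 Hz amplitude envelope. Small per-participant jitter (5% geometry, 2%
pitch) makes speakers distinguishable without overwhelming the class
signal. Gaussian noise enters both modalities at a configurable SNR
(default 20 dB; +inf disables noise; −40 dB drowns the signal to chance).

Defaults: 5 participants per class, 3 utterances each, 1.5 s at 60 fps,
64×64 frames, 16 kHz audio. Sex is assigned by deterministic quota —
round(n × male fraction) males per class with seed-shuffled order, the
fractions 6/11, 8/11 and 4/7 mirroring the demographic composition of
the clinical corpus this generator stands in for; a quota keeps the
composition exact at small n, where Bernoulli draws would routinely
produce degenerate strata. All randomness derives from one root seed:
participant seed = SeedSequence(root, spawn_key=(class, index)),
utterance rng = SeedSequence(participant_seed, spawn_key=(utterance,)).
Identical seeds produce byte-identical files.

What passing tests on this corpus do and do not show: they certify the
pipeline's mechanics — alignment, leakage-safety, metric learning on a
recoverable signal, graceful collapse to chance when no signal exists
(accuracy is non-increasing in noise over {20, 0, −20} dB, and sits in
the 95% binomial band of chance at −40 dB). They say nothing about real
ultrasound speckle, articulatory variability, disordered speech
acoustics, or clinical class overlap, all of which are absent by design.

## Problem sizes and numerical choices

Development and acceptance runs use the desk-scale configuration: the
2-layer/64-hidden encoder with frozen backbone, 5 participants per class,
5-fold grouped CV — a full run takes well under a minute on one CPU, and
the package's own acceptance script completes in about a minute. The
full-size encoder configuration is selectable but training it end to end
in pure numpy is slow and intended for small experiments only.

Other numerical conventions: min-max scaling maps constant images to 0.5;
softmax rows are max-subtracted before exponentiation; LayerNorm uses
eps = 1e−6; Adam uses the standard bias-corrected step with eps = 1e−8;
checkpoints embed a SHA-256 hash of their configuration and refuse to
load on mismatch.

## Known limitations

* The `biomedclip_frozen` backbone is an adapter only; without the
  optional dependency stack it reports how to proceed but cannot run.
* The chunk-to-image reduction discards within-chunk motion; optical-flow
  or spatiotemporal encodings are out of scope.
* No voice-activity detection or denoising precedes the STFT.
* Calibrated probabilities and learned attention over chunks are not
  provided; the voting weights are a fixed, interpretable rule.
* Whether the strongest published configuration feeds pretrained CLIP
  features into a *second* trainable transformer cannot be settled from
  the available description; both compositions are expressible here
  (frozen backbone + trainable head, or end-to-end ViT) and neither is
  claimed as canonical.
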