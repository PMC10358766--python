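# Methods

This note documents the modeling and numerical choices behind `stt_eeg`:
what the pipeline computes, what the synthetic data does and does not
emulate, and where the design was genuinely open.

## Data model and epoching

A `Recording` is one subject × clip segment of 32-channel EEG, time-major
(samples × channels) in microvolts, at the protocol's preprocessed rate
of 128 Hz.  Labels are per clip: −1 negative, 0 neutral, +1 positive, and
every epoch cut from a clip inherits its label.

Epoching uses 4-s windows (512 samples) on a fixed grid every
`stride = window × (1 − overlap)` seconds over `[0, T)`, with 50%
overlap (stride 2 s) by default.  Windows whose end runs past the
recording wrap circularly to its start, so a T-second recording yields
exactly `floor(T / stride)` epochs.  This convention is what makes the
protocol arithmetic exact: 8 minutes of per-class signal → 240 epochs,
12 minutes → 360.  An end-clamped rule (`(T − w)/s + 1` epochs) cannot
produce those counts, which is why the wrapped grid was chosen.  Epoch
offsets are 0-based, half-open `[start, start + window)`.

Groups of G = 8 epochs are formed within each (label, subject) partition,
ordered by (clip, start time), in consecutive non-overlapping runs;
leftovers are dropped.  A group may span the boundary between two clips
of the same label — the alternative (grouping within clips) discards a
quarter of each clip and breaks the 120-epochs → 15-groups arithmetic.
The group-shuffling seed affects order only, never membership.

The montage constant reproduces the acquisition list verbatim, including
its idiosyncratic "FC" label where the standard 10-20 name is "FC2";
"FC2" is accepted as an alias on input, and channel matching is
case-insensitive (the source list mixes "CP5" and "Cp6" spellings).

## Synthetic corpus

The generator emulates the structure of the music-listening corpus:
32 subjects × 12 one-minute clips (4 per class), 32 channels, 128 Hz.
Each channel is unit-RMS 1/f Gaussian background noise (exponent 1.0, the
standard resting-EEG spectrum) scaled to 10 µV RMS, plus class-conditional
band-limited oscillations: the positive class adds theta (4–8 Hz) on the
frontal-midline group Fz, Cz, AF3, AF4; the negative class adds beta
(13–30 Hz) on the frontal channels Fp1, Fp2, F3, F4, F7, F8; neutral adds
nothing.  These topographies follow the literature on liked/disliked
music; the exact channel sets are this package's choice.  Each oscillation
is a sum of three sinusoids with frequencies drawn uniformly in the band
and independent random phases per subject × clip, normalized to unit RMS.

The effect amplitude is `gain × snr × background RMS`, with `snr = 6` by
default — a deliberately *strongly separated* regime (oscillation RMS six
times the background on target channels) in which desk-scale parameter
recovery is well-posed.  Real affective EEG effects are far weaker and
far less stationary; passing recovery tests on this corpus demonstrates
that the pipeline extracts class-conditional band-power topography when
it is present, not that the architecture would reach similar accuracy on
physiological recordings.  Also not emulated: ocular/muscle artifacts
(the protocol's subjects kept their eyes closed), inter-subject
variability in background spectra, volume conduction between channels,
and non-stationarity within a clip.

Generation is a pure function of the spec: every subject × clip gets its
own child seed (`SeedSequence(seed, spawn_key=(subject, label, clip))`),
so corpora are bit-identical across runs and insensitive to iteration
order.  `band_power` (Welch, 256-sample Hann segments, 50% overlap,
band-integrated, channel-averaged) is the validation statistic used by
the generator's own tests.

## Model

Tokenization: each epoch's 32 electrodes are cut into ceil(32/5) = 7
slabs of H = 5 consecutive montage rows × W = 512 samples (C = 1); the
last slab is zero-padded from 2 rows (an overlap-last mode is available).
A flattened slab is one token, so a group gives 7 × 8 = 56 tokens.  The
spatial stream orders them slab-fastest, the temporal stream
epoch-fastest; both streams see identical data, realizing the two axes
with one shared tokenizer.  Before tokenization each epoch is z-scored by
its global mean/std (across samples and channels), which fixes the input
scale for optimization while preserving the between-channel amplitude
ratios that carry the class signal.

Each stream is an independent pre-norm encoder (no parameter sharing):
affine patch embedding to D, learnable class token, learned position
embeddings, L blocks of multi-head self-attention + GELU MLP
(width 4·D), dropout 0.1, final layer norm, affine head on the class
token.  Defaults D = 64, n_heads = 4, L = 8.  Fusion layer-normalizes the
concatenated stream logits and maps them affinely to the classes — the
reading we adopt of the (ambiguous) published fusion formula.

Initialization is truncated normal (σ = 0.02, clipped at 2σ) for weights.
The patch-embedding *bias* is initialized as a truncated-normal anchor of
unit scale rather than zero: pre-norm layer normalization discards each
token's overall magnitude, but with a non-zero bias the normalized
direction rotates away from the anchor as patch energy grows, so slab
amplitude — exactly the band-power statistic separating the classes —
stays linearly decodable.  Empirically this init roughly halves the
training budget needed for parameter recovery at desk scale; it does not
change the architecture.

The autodiff engine (`stt_eeg.autograd`) is a minimal tape-free
reverse-mode implementation over numpy (float32) with the primitives the
model needs; every backward rule is tested against float64 central
differences, and the whole model against float32 finite differences.

## Training and evaluation

The objective is `α·CE(Y_spatial) + (1 − α)·CE(Y_temporal)` with α = 0.3,
plus a unit-weight cross-entropy on the fused logits.  The published
objective contains only the two stream terms, but the fused output is
the quantity evaluated, and without its own loss term the fusion layer
would be untrained; `fused_loss_weight = 0` restores the literal
two-term objective.  Optimization is AMSGrad at a constant learning rate
of 0.001 (a cosine decay was piloted and discarded — it slowed
convergence at these problem sizes), batch size 24, fixed epoch budget
(default 25).  Optional best-validation checkpointing (`val_fraction`)
holds out part of the training fold, scores the fused head each epoch
and restores the best parameters; there is no early stopping.

Cross-validation is label-stratified at the group level (scikit-learn
`StratifiedKFold`), mirroring the sample-wise protocol.  Note that
group-level splitting of 50%-overlapped epochs leaks information between
train and test — neighboring epochs share half their samples — which is
a property of the protocol being reproduced, not a bug; a subject-wise
mode (`subject_wise=True`, whole subjects per fold) is provided for
leakage-free estimates.  Each fold trains a fresh model with a
fold-derived seed.  Multiclass sensitivity/specificity are macro
one-vs-rest averages; zero-denominator metrics are reported as NaN with
a warning, never as 0.

The channel ablation trains three variants on shared splits: spatial-only
(α = 1, no fused term, spatial logits evaluated), temporal-only (α = 0),
and combined.  The heads × layers grid sweeps the cross-product with
shared splits and seeds and can resume from completed cells.

## Evaluation scale

The bundled evaluation (tests and `scripts/acceptance.py`) runs the
study at a reduced scale chosen for single-core reproducibility: an
8-subject corpus (360 groups), a D = 32 / L = 2 / 2-head model, and
3-fold CV; the determinism check uses a 2-subject corpus and 2 folds.
Under these conditions the fused head reaches ≈95% ternary accuracy,
the combined model matches or beats the better single stream, and
shuffled labels fall to chance.  The full 32-subject, 10-fold, D = 64 /
L = 8 configuration is expressible through the CLI but is a
multi-hour computation with the numpy engine.

## Known limitations

* The two streams consume identical tokens (by design); on data whose
  class signal is purely topographic the temporal stream is not
  handicapped, so spatial-vs-temporal ablation differences on the default
  synthetic corpus reflect token *ordering* and seed noise, not distinct
  information.
* Circular wrapping of the final epochs joins the recording's end to its
  start; for stationary synthetic clips this is harmless, but on real
  data the wrapped epochs straddle a discontinuity.
* Accuracy of the fused head, not calibration, is the target; logits are
  not temperature-calibrated.
* The EDF writer is minimal (16-bit, 1-s records, single physical range
  across channels) — sufficient for round-tripping this pipeline's data,
  not a general-purpose exporter.
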