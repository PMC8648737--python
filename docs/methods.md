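# Methods

## Problem and model

`vocalsep` addresses single-channel separation of overlapping animal
vocalizations.  Given a mixture `x = Σᵢ sⁱ` of `N` fixed-length sources
produced by distinct individuals, a separator `f` estimates
`ŝⁱ = fⁱ(x)`.  The model is a masking network in time–frequency space:

- **Encoder.**  Centered STFT magnitude with a periodic Hann window
  (reflect padding of `nfft/2` on the left; the frame count is
  `1 + ceil(len/hop)`).  Variants: dB-scaled magnitude
  (`20·log10(m + 1e-8)`), or a learnable Conv1d filterbank (kernel `nfft`,
  stride `hop`, ReLU so masking acts on nonnegative activations).
- **U-Net core.**  `B` downsampling blocks (two 3×3 "same" convolutions,
  leaky ReLU with slope 0.01, BatchNorm after the activation, then max
  pooling), a middle block, and `B` upsampling blocks (bilinear upsampling
  at the pool scale, skip concatenation, two convolutions).  A final
  convolution emits `N` channels passed through a sigmoid, giving masks in
  `[0, 1]`; each separated magnitude is therefore bounded by the mixture's.
  Filter counts start at `base_channels` (default 16; 8 in the toy
  experiments) and double per level.  All trainable weights use Xavier
  uniform initialization.
- **Decoder.**  The masked magnitude is inverted with an iSTFT that reuses
  the mixture phase (the default is phase-unaware), with weighted
  overlap-add and division by the accumulated squared window — exact
  reconstruction for any hop ≤ nfft/2.  The dB variant converts back to
  linear magnitude first; the free variant uses a transposed convolution.

Since the representation grid is generally not divisible by `pool^B`
(e.g. 513 frequency bins with pool 6), the representation is zero-padded up
to the next multiple per axis before the U-Net and cropped after masking.

Species presets (rate, segment length `T`, `nfft`/`hop`, U-Net depth/pool,
class count): macaque 24 414 Hz / 23 156 / 1024 / 64 / (4, 2) / 8;
dolphin 96 kHz / 290 680 / 1024 / 256 / (3, 6) / 8 with a 4.7 kHz high-pass;
bat 250 kHz / 250 000 / 2048 / 512 / (4, 3) / 12.  The `toy` preset
(8 kHz, `T = 2048`, nfft 128, hop 64, depth 2, pool 2, 6 classes) keeps the
whole pipeline in CPU-minutes; its smaller `nfft` halves the frequency grid
relative to a naive scaling while retaining 62.5 Hz resolution, ample for
the synthetic F0 bands.

## Training objective

The loss is permutation invariant: the exact minimum over all `N!`
assignments of outputs to targets of the mean per-channel loss (`N ≤ 4` by
default; the search is brute force and is verified against an independent
enumeration in the tests).  The per-channel loss combines

- time-domain L1,
- L1 between STFT magnitudes,
- spectral convergence `‖|Ŝ|−|Ŝₜ|‖_F / ‖|Sₜ|‖_F`,

with default weights (1, 1, 1); both L1 terms are means rather than sums so
the weights remain comparable across segment lengths and grid sizes.
Log-magnitude L1 and negative SI-SDR terms are implemented but default to
weight 0, reflecting that they brought no empirical benefit.  An optional
decoupled penalty `λ Σ βⱼ²` is available (`λ = 0` by default).

Two optimizer recipes: plain AdamW (lr 3e-4, weight decay 0.01 — the
library-conventional default, as only the optimizer name and learning rate
are prescribed) used for the free-encoder model, and a warm start of 3
epochs of SGD with Nesterov momentum 0.6 at lr 1e-3 before switching to
AdamW, which stabilizes the STFT-masking models.  PIT is computed
per example, and gradients flow only through the winning assignment.
Models checkpoint every epoch; the lowest-validation-loss state is restored.

Training runs in float32 (halving memory traffic on CPU); the autodiff
engine defaults to float64 elsewhere so that gradient audits against central
finite differences hold to < 1e-4 relative error.

## Identity classifier

The downstream probe is a CNN: optional frozen windowed-sinc high-pass →
non-dB STFT magnitude → convolutional blocks (two 3×3 convolutions + leaky
ReLU, max pool 4; 4 blocks for the field presets, 2 for the toy preset) →
mean over time frames → dense layer with leaky ReLU and dropout (0.25
macaque, 0.5 dolphin/bat) → linear + log-softmax over the `V` individuals.
Time-average pooling before the dense layer makes features onset invariant,
complementing the random onset-shift augmentation applied to training and
evaluation calls.  Training minimizes the NLL with Adam at lr 3e-4; the
epoch with the highest validation accuracy is kept.  Inputs are not
peak-normalized (nothing in the pipeline assumes normalization).

## Evaluation

SI-SDR uses the scale-invariant form `10 log₁₀(|αs|²/|ŝ−αs|²)` with
`α = ŝᵀs/|s|²`.  (A strict mode computes the non-scale-invariant variant
`−10 log₁₀|ŝ−s|² + 10 log₁₀|αs|²` for comparison; the scale-invariant form
is the package default since it is the one consistent with "searching over
gains".)  Values are capped at 60 dB when the residual reaches machine
noise; an estimate orthogonal to the target returns `−inf`.  Set metrics are
maximized over output permutations; the mixture baseline is the mean of
`si_sdr(x, sⁱ)` over sources, and ΔSI-SDR is the improvement over it.
Downstream accuracy takes, per mixture, the permutation of outputs that
maximizes the fraction of correct identity predictions; it is omitted for
open-regime sets whose labels the classifier was never trained on.

## Synthetic data

Real corpora are large and partly access-restricted, so all tests and
reference experiments run on synthetic calls.  A call is a harmonic stack
`a(t) · Σ_h w_h sin(2π h ∫f₀)` with a raised-cosine attack/release envelope,
a quadratic relative-F0 contour, geometric harmonic-weight decay
(0.4–0.8), and slow multiplicative F0 jitter (0.5 %).  Individuals receive
disjoint sub-bands of the preset F0 band; profile construction rejects any
configuration whose highest harmonic reaches the Nyquist frequency.  The
generator realizes the statistical assumptions the separation approach rests
on — individual distinctiveness, nonstationarity, and approximate disjoint
time–frequency support — and nothing more: no formants, reverberation,
background interference, call-type repertoires, or echolocation click
trains.  Passing tests therefore demonstrate the machinery is correct and
the method works when its assumptions hold, not field-recording performance.

Mixtures follow the reference-dataset recipe: draw `N` distinct individuals,
one call each, fix durations (truncation keeps call onsets, which carry
identity cues), place each call at a uniform random onset, and sum — the
mixture equals the sample-wise sum of the shifted sources exactly, with no
gain normalization (a relative-gain jitter flag exists, default off).  An
`overlap_required` flag (default on) redraws onsets jointly until every pair
of sources shares at least one sample, matching how discrete-call mixtures
are constructed; for stream-like data it can be disabled.  Calls are split
80/20 per individual before mixing so validation mixtures contain only
held-out calls; the open-speaker regime holds out whole individuals.  The
dolphin denoising variant high-pass filters the *targets* while leaving the
mixture input unfiltered, so the model must also learn to denoise; the
additivity invariant then applies pre-filtering.

## Reference experiment conditions

The scaled-down two-speaker closed-regime experiment uses two individuals at
8 kHz with sub-bands tiling 300–800 Hz and two harmonics — chosen so the
low voice's second harmonics (750–950 Hz) clear the high voice's
fundamentals (625–725 Hz), realizing structurally disjoint supports — with
25 calls per individual, 200 training and 40 validation mixtures, a base-8
U-Net, and 12 epochs (3 SGD warm-up + AdamW, batch 16).  The identity probe
trains for 20 epochs at batch 8: the 50-call corpus needs the extra gradient
steps at lr 3e-4.  The ideal-mask harness uses single-harmonic ("two-tone")
individuals over 300–1800 Hz, where a ground-truth binary mask plus
mixture-phase inversion is near-lossless; with two harmonics, colliding
partials bound binary-mask performance near 8 dB while trained soft masks
reach 20–40 dB.  The classifier sanity run uses six individuals with 50
calls each for 8 epochs.

## Numerical choices and edge cases

- dB scaling adds ε = 1e-8 before the log; the inverse subtracts it and
  clamps at zero.
- The differentiable STFT floors cell magnitudes at 1e-12 inside the square
  root so gradients stay finite on silent cells; spectral convergence
  rejects targets whose total magnitude is below 1e-8 as undefined.
- The sinc high-pass uses the classic design rule
  `taps = 2·ceil(2/tb) + 1` with a Blackman taper and explicit spectral
  inversion (`δ − lowpass`), which nulls DC exactly; the kernel is
  symmetrized to be bit-exact linear phase.  Filtering uses "same"-mode FFT
  convolution.
- `mean + 3σ` segment sizing uses the population (ddof = 0) standard
  deviation and rounds up.
- Max pooling breaks ties toward the first element; bilinear upsampling
  uses the half-pixel (align-corners-false) convention with edge clamping.
- SGD/AdamW states are kept separately across the optimizer switch; the
  switch happens after 3 warm-up epochs.
- WAV I/O accepts PCM16/PCM32/float mono; sampling-rate mismatches are
  rejected unless resampling is requested explicitly (polyphase).

## Limitations

- The autodiff engine is minimal and CPU-bound; field-preset training at
  native rates is out of reach here, and the printed parameter counts of the
  original-scale architectures are therefore reference points, not targets.
- Phase is never estimated: reconstruction reuses mixture phase, which caps
  achievable SI-SDR when sources overlap in time–frequency.
- The permutation search is exact and factorial; `N ≤ 4` is enforced.
- Synthetic calls omit most acoustic complexity of real recordings (see
  above), and the open-speaker regime is exercised structurally (label
  disjointness) rather than at realistic difficulty.
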