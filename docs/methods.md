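# Methods

## Problem

Isolated-word speech assessment for acquired language impairment: given
short recordings of single words from healthy speakers and from speakers
with impaired speech, (a) recognize the word, (b) score how "healthy" each
utterance sounds, and (c) discriminate healthy from impaired speech. The
package implements the full chain — signal conditioning, a high-resolution
quadratic time-frequency transform, image/feature classifiers, severity
scoring, and a three-scenario evaluation protocol — and ships a synthetic
corpus generator so the chain is testable without clinical recordings.

## Hyperbolic T-distribution (HTD)

The transform is a Cohen-class quadratic TFD, i.e. a smoothed Wigner–Ville
distribution (WVD):

    rho(t, f) = F_{tau->f} [ G(t, tau) *_t  z(t + tau/2) z*(t - tau/2) ]

with z the analytic signal of the input. The HTD's time–lag kernel is
lag-independent:

    G(t, tau) = R_sigma(t) = k_sigma / cosh^(2 sigma)(t),
    k_sigma   = Gamma(2 sigma) / (2^(2 sigma - 1) Gamma(sigma)^2),

so it smooths the WVD along time only. Because
`integral cosh^(-2 sigma)(t) dt = 1/k_sigma`, the kernel has unit mass: the
WVD's frequency marginal is preserved (up to boundary effects) while
cross-terms — which oscillate along time at the beat frequency of the
interfering components — are strongly attenuated. As sigma grows the kernel
narrows and the HTD converges to the (lag-windowed) WVD; `wvd_reference`
implements that limit on the identical grid and serves as the oracle in the
property tests.

One typographic wrinkle: the kernel is sometimes typeset as if k_sigma
*equals* the integral of cosh^(-2 sigma). A normalization factor must be the
reciprocal for unit mass, and the closed form above is that reciprocal. The
discrete weights are renormalized to unit sum after truncation in any case,
so either reading produces identical kernels here.

### Discrete conventions

* Analytic signal via the FFT construction (positive frequencies doubled,
  DC/Nyquist kept) — `scipy.signal.hilbert`.
* Half-lags on the integer grid: `K[n, m] = z[n+m] conj(z[n-m])`, lag
  `tau = 2m/rate`, no half-sample interpolation. An FFT of length `nfft`
  over lags gives bins `f_k = k rate / (2 nfft)` on `[0, rate/2)`.
* A symmetric Hann taper over lags (unity at lag 0) suppresses
  lag-truncation ripple; it multiplies both the HTD and the WVD reference,
  so the sigma-limit comparison is between identically windowed surfaces.
* The kernel is sampled at the signal's time step. Its dimensionless
  argument maps to seconds through `kernel_time_scale` (default 5 ms per
  unit): sigma and the scale jointly set the smoothing width. Default
  sigma = 1; both are configuration fields. Truncation at 1e-4 of the peak
  weight, followed by renormalization to unit discrete mass.
* Near the signal boundary only part of the kernel mass overlaps the data;
  the convolution is renormalized by the overlapping mass so tones keep
  constant energy per frame up to the edges. With that correction the
  discrete surface satisfies, within 2 % for tones and chirps:
  sum(rho) * (hop/rate) * (rate/(2 nfft)) = analytic-signal energy.
* The assembled spectrum must be real up to rounding: if the imaginary
  residue exceeds 1e-6 of the real peak the transform raises rather than
  silently truncating.

### TF images

Grids are clipped at zero (quadratic-TFD interference residue), log
compressed over a 60 dB dynamic range, min–max normalized, mapped through a
fixed perceptual colormap (viridis) and bilinearly resized; rows are
frequency with the highest frequency on top. Rendering is deterministic, an
all-zero grid renders as a uniform background, and the colormap name and
dynamic range are stored with the image.

## Synthetic corpus

Words are acoustic stand-ins built by source–filter synthesis: a glottal
impulse train following a linear per-syllable pitch contour (a lexical-tone
surrogate) drives a cascade of three formant resonators under a rise/fall
envelope. Class templates live on a (7 formant sets x 3 tone directions)
grid, so any two classes differ by >= 150 Hz in some formant or in contour
direction; odd classes carry a second syllable. Speaker identity is a
consistent multiplicative formant/pitch perturbation (<= 3-4 %), with
smaller per-repetition jitter.

Impairment is modeled as severity-scaled effects applied in a fixed order —
tempo warp, formant drift (resynthesis), tone flattening, pitch
jitter/amplitude shimmer, syllable deletion, additive noise with SNR falling
from 40 dB toward 15 dB at severity 1. Severity 0 is a bit-exact identity.
Patient severities default to a uniform draw over {0.2, 0.4, 0.6, 0.8}.

What the generator does *not* emulate: coarticulation, phonetic structure
within syllables, room acoustics, channel variation, and the great
between-patient diversity of real impaired speech. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that its
qualitative orderings (degradation lowers accuracy and true-class
activation) hold on controllable data — not that clinical accuracy levels
transfer.

Generator defaults mirror the clinical corpus shape (20 classes, 34 healthy
speakers x 5 repetitions, 12 patients x 3 repetitions, recorded at a high
rate in stereo). The package's standard test-scale corpus
(`desk_scale_dataset`) is 20 classes x (10 healthy speakers x 3 reps + 5
patients x 2 reps) = 800 utterances at 8 kHz: 8 kHz covers the synthesized
formant range (<= 3.4 kHz), and ten healthy speakers give exactly two
speakers per fold under speaker-grouped five-fold cross-validation.

## Preprocessing

Endpoint silence removal uses 20 ms frame RMS with a -40 dB threshold
relative to the loudest frame; trimming is idempotent and never touches
interior frames; an all-silent utterance raises and is excluded. The
noisy-sample exclusion uses a spectral SNR proxy: broadband noise lifts the
median of the power spectral density, so noise power is the median density
integrated over the band and signal power the remainder; utterances below a
5 dB floor are discarded. (A frame-energy noise floor fails on steady tonal
signals, where the quietest frames are pure signal — the spectral floor
handles that case; both criteria are documented stand-ins for what was a
manual screening step in the original corpus.)

## Classifiers

**LDA.** The TFD grid is log-compressed, mean-pooled to 32 x 32 tiles
(1024 dims), projected by PCA (fitted on training data only) to
min(C-1, 64) dims, then classified by LDA with Ledoit–Wolf shrinkage of the
within-class covariance; posteriors come from the Gaussian class model. The
projection keeps the covariance estimate well-conditioned at a few hundred
training samples.

**CNN.** A small convolutional network in plain numpy (im2col GEMM forward
and backward, all layer gradients verified against finite differences):
three 3x3 conv blocks of 16/32/64 channels, each with batch normalization,
ReLU and 2x2 max-pool, then a linear head on the 8 x 8 x 64 map — roughly
100k parameters on 64 x 64 RGB inputs. Training follows the fixed protocol:
cross-entropy, Adam (beta1 0.9, beta2 0.999), decoupled weight decay 0.01
on weight matrices (not biases or batch-norm parameters), batch size 128,
15 epochs, cyclical learning rate with peak 3e-3 realized as one cycle over
the whole run (linear warmup for the first 45 % of steps, cosine annealing
to ~0 after) — the schedule the cyclical-LR practice converged on for short
fine-tuning runs. Training is bit-reproducible from the seed. Larger
pretrained backbones are named in the configuration for completeness but
require externally downloaded weights and are not bundled.

**Severity score.** TCOA (true-class output activation) is the model's
posterior probability at the utterance's true word class, in [0, 1]. It is
taken as the raw posterior — no renormalization across repetitions. A
cut-off threshold (default 0.7) yields the binary healthy/impaired
decision; the tie goes to healthy, so the threshold itself is the lowest
activation still accepted as healthy.

## Evaluation

* Stratified five-fold cross-validation; speaker-grouped (speaker-disjoint
  folds) by default to prevent identity leakage. Exact per-fold class
  balance (within one sample) is guaranteed in ungrouped mode; in grouped
  mode balance is best-effort because group disjointness constrains the
  assignment.
* Metrics: accuracy and macro-averaged precision/recall/F1 over word
  classes, per fold with mean and sd; classes absent from a fold contribute
  zero to the macro numerator and stay in the denominator. Macro was chosen
  because the corpus is class-balanced (macro ~ micro) and it removes
  averaging ambiguity.
* Exact Wilcoxon signed-rank test for paired model comparisons: zero
  differences discarded, mid-ranks for ties, and the two-sided p computed
  from the full null distribution of the positive-rank sum (dynamic
  programming over doubled mid-ranks; limited to 25 non-zero pairs).
* Scenarios: (1) five-fold CV within healthy; (2) train on all healthy,
  test on all impaired — dispersion from repeated training seeds (3 for the
  CNN at desk scale; the LDA fit is deterministic, so it is reported once);
  (3) five-fold CV within impaired, customized models only.

## Numerical and design notes

* All randomness flows through explicitly passed seeded generators; there
  is no global RNG state, and repeated seeded runs produce byte-identical
  manifests, audio, TF images and metric reports.
* The CNN trains in float32 (GEMM throughput); the TFD engine is float64.
* Optional train-time augmentation (off by default) applies small random
  zero-filled translations to half of each batch; on the synthetic corpus
  it did not improve speaker generalization and plain training is used.
* Degenerate inputs: empty signals, all-silent utterances, and grids
  shorter than the lag window raise informative errors; an all-zero grid
  renders as a uniform image rather than NaNs.
* Problem sizes used by the test suite and the acceptance script: TFD
  properties on 0.5 s signals at 8 kHz; scenario evaluation on the 800
  utterance desk-scale corpus described above. These sizes keep a full run
  on a single CPU core in the tens of minutes while leaving every
  qualitative comparison intact.

## Known limitations

* The synthetic corpus is far more regular than clinical speech; absolute
  accuracies on it (near-perfect in scenario 1) say nothing about absolute
  clinical accuracy.
* The LDA input representation and several analysis constants (sigma,
  window, hop, colormap) are package choices exposed in the configuration,
  not reproductions of unpublished settings.
* The noisy-sample rule is an automatic proxy for a manual judgment; the
  4 % exclusion rate of the original corpus is not a calibration target.
* Only the self-contained CNN backbone ships; transfer learning from
  large pretrained networks is out of scope without a weights download.
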