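# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `eegsr`, in the spirit of a model-description appendix.

## Problem setting

Super-resolution is posed as learning `f_θ : X_LR → X_HR` for two
degradation families on z-scored, 2-s EEG windows:

* **spatial** — a fixed electrode subset is observed (factors ×2/×4/×8,
  e.g. 8 of 64 channels).  The subset is chosen once per montage by greedy
  farthest-point sampling on the unit sphere, seeded at the vertex electrode
  with ties broken by canonical rank.  This is a deterministic,
  montage-agnostic stand-in for "low-density acquisition" masking protocols
  whose exact electrode lists are rarely published; it maximizes spatial
  coverage and is reproducible by construction.
* **temporal** — decimation by keeping every k-th sample from phase 0,
  relying on the pipeline's prior bandpass for anti-aliasing.  The naive
  inverse operators are zero-padding at HR ranks (spatial) and per-channel
  linear interpolation with hold-last (temporal; output length is exactly
  factor × LR length so that degrade∘upsample∘degrade = degrade).

The probabilistic variant models `p(X_HR | X_LR, positions, label)` with a
conditional denoising diffusion process whose denoiser is the same trunk as
the regression model.

## Electrode geometry

Montages carry unit-sphere positions (head frame: x right, y front, z up),
obtained from the 10-05 template positions re-centred by a least-squares
sphere fit and normalized.  Spherical-spline interpolation, the synthetic
leadfield and the topographic metrics need only this angular geometry; no
BEM/FEM head modelling is attempted.  Built-in channel sets: 64 (BCI2000
motor-imagery cap), 62 (SEED-style; PO9/PO10 stand in for cerebellar leads
absent from the template), and nested 32/16/8 low-density caps.  Arbitrary
channel counts fall back to a Fibonacci grid on the upper hemisphere.

## Synthetic data generator

Each window is a sum of S band-limited sources (flat-spectrum noise
confined to one of δ 1–4, θ 4–8, α 8–13, β 13–30, γ 30–50 Hz by Fourier
masking) mixed onto electrodes with gains `exp(−d²/σ_lf²)` (`d` =
great-circle distance from source to electrode), plus per-channel
`1/f^a` noise at a configured SNR, then per-channel z-scored.  Class labels
switch which sources are active (`s mod n_classes == label`), giving each
class a stable topography so label conditioning is learnable.

Defaults: 64 channels, 160 Hz, 2-s windows, 8 sources, two classes,
`a = 1`, SNR 10 dB, `σ_lf = 1.0` rad.  The leadfield width was set so that
neighbouring-electrode correlations land in the 0.7–0.9 range typical of
volume-conducted scalp EEG (≈0.83 on the 64-channel montage); narrower
decays produce unrealistically focal fields on which classical spherical
splines cannot beat zero-padding, contrary to their well-documented
real-data behaviour.  Reproducibility: one root seed; window w draws from
`default_rng([seed, w])`, source geometry from `default_rng([seed, 0xEE6])`.

What the generator does *not* emulate: realistic volume conduction
(a Gaussian-in-angle gain is not a physical leadfield), artifacts (blinks,
EMG, line noise), non-stationarity across windows, inter-subject
variability.  Tests passing on this corpus therefore demonstrate mechanism
correctness and learnability orderings, not clinical performance.

Note one consequence of per-channel z-scoring (the standard normalization,
`(x − μ_c)/(σ_c + 1e-8)`): every channel has unit variance, so a source's
spatial profile survives only in cross-channel correlations and band
*fractions*, not absolute amplitudes.  Band-power comparisons across
channels tie within a few percent near a source.

## Preprocessing conventions

* Bad channels: *flatline* = variance < 1e-10 with the signal at numerically
  zero level (dead channel); *saturation* = max |consecutive difference| <
  1e-8 at a non-zero level (stuck amplifier, level threshold 1e-5).  The
  level term disambiguates cases that satisfy both variance and difference
  thresholds.  Trials with > 30% bad channels are rejected; survivors are
  repaired by spherical splines.
* Spherical splines: Perrin-style kernel
  `g(x) = Σ_{n=1..50} (2n+1)/(n(n+1))^4 · P_n(x)/(4π)` (order m=4), solved
  per time sample through the bordered system with ridge λ = 1e-5 and an
  enforced constant term; one factorization serves all time samples.
  Verified against MNE's interpolation matrix to ~1e-13.
* Filtering: optional IIR notch (Q=30, zero-phase) followed by a
  windowed-sinc FIR bandpass (Hamming, ~3 × rate / band_lo taps rounded odd,
  capped at a third of the signal length), applied forward–backward for zero
  phase.
* Z-scoring uses the population σ with the 1e-8 stabilizer, so constant
  channels map to exactly zero.
* Windows: non-overlapping 2-s segments, seeded shuffle, fractional
  80/10/10 split by default.

## Backbone

The selective-SSM discretization is zero-order hold on A (`exp(ΔA)`) and
Euler on B (`ΔB`) — the canonical choice.  Δ is `softplus` of a learned
projection whose bias is initialized so Δ ∈ [1e-3, 0.1].  Mamba-1 blocks
use `A = −exp(A_log)` with `A_log` initialized to `log(1..N)` per channel;
Mamba-2 blocks use one scalar decay per head (init `log U(1,16)`) and an
RMS normalization between the scan and the SiLU gate.  Fixed per the
published configuration: conv kernel 3 (causal, depthwise), expansion 2.
The scan is a sequential numpy loop with an analytic backward pass —
correctness over speed; no parallel-scan or fused kernels.

Bidirectional layers keep separate parameters per direction (a tied mode
exists and is used only to test the time-reversal equivariance the
architecture should have when tied).  Directional convolutions are
depthwise, causal in each stream's own direction; the inter-layer skip
projection is a full k=3 convolution.

## Trunk and conditioning

Encoder: stem k=3 conv, then `depth` stages of stride-2 k=4 convs doubling
the width; decoder mirrors with zero-insertion upsampling + k=3 convs; SiLU
activations; linear k=3 head.  Defaults `base_width=64, depth=2`; the desk
study uses `base_width=32`.  The bottleneck is either the BiMamba stack
(projected to `d_model` and back) or, for the ablation variant, two rounds
of conv/norm/LeakyReLU/dropout (dropout 0.1; the normalization is a
channel LayerNorm — running-statistics batch norm is deliberately avoided
to keep training bit-reproducible on any batch order).

Conditioning streams are individually switchable: the upsampled LR signal
is channel-concatenated with the noisy input (diffusion) or *is* the input
(regression); electrode-position embeddings (learned rank table + linear map
of the 3-D coordinate, reduced to a per-channel bias) are added to the
LR-shaped stream; label embeddings (with a reserved null id for
unconditional use) are added at the bottleneck; sinusoidal timestep
embeddings pass through a small MLP and are added per encoder stage.  The
network output adds the upsampled LR signal back (residual guidance), so
the trunk learns corrections; the head convolution is standard-initialized,
so the untrained network is genuinely untrained.

## Diffusion

Schedule: T=1000; β follows the squared-cosine cumulative-decay profile
affinely rescaled so min β = 1e-4 and max β = 0.015 exactly.  Rescaling the
raw capped per-step cosine betas instead would let the near-1 terminal
values dominate the affine map and leave ᾱ_T ≈ 0.75; the profile rescaling
keeps the cosine shape, the exact endpoints, monotone betas and
ᾱ_999 ≈ 5e-4.  Prediction type defaults to "sample" (the denoiser outputs
the clean signal); "epsilon" is available.  Sample clipping is disabled.
Training timesteps are uniform over [0, T); an optional high-t-biased mode
(density ∝ t³) exists and is off by default.  One-step sampling initializes
at `σ·ε` (+ upsampled LR when configured, σ = 1.0 by default), presents
t = T−1 = 999, and is contractually limited to a single denoiser call
(instrumented).  Multi-step DDPM/DDIM use the standard η-parameterized
recursion over a strided timestep subsequence.

## Training

AdamW (lr 1e-3 default, cosine decay to 1e-5, weight decay 1e-4, gradient
norm clip 1.0), batch 32, early stopping on validation NMSE with patience
10 when a validation split is supplied, best-validation parameters
restored.  Non-finite losses abort the epoch and keep the last good
parameters.  All randomness (parameter init, batch order, diffusion
timesteps/noise, dropout, sampler init) derives from the estimator seed, so
fits are bit-reproducible on one CPU thread.

## Metrics

Welch spectra use Hann windows of `min(L, 256)` samples with 50% overlap
everywhere (PSD, band powers, cross-spectra).  The 1-D SSIM uses a
length-11 Gaussian window (σ=1.5) with `c1=(0.01R)², c2=(0.03R)²` on the
reference's dynamic range; it matches the image-domain implementation
applied per channel to ~1e-6.  PSNR fixes MAX=1 (signals are z-scored) and
reports +inf as a sentinel for exact reconstruction.  Topographic
smoothness is the mean squared residual of each channel against the mean of
its k=4 nearest neighbours (great-circle graph).  Band edges: δ 1–4, θ 4–8,
α 8–13, β 13–30, γ 30–50 Hz, clipped to the analysis passband.  The Fréchet
distance computes the cross square root as `S1^{1/2} S2 S1^{1/2}` via
symmetric eigendecomposition with negative eigenvalues clipped at zero.
The default feature extractor behind the Fréchet-distance-on-windows
utility is a fixed-seed random convolutional encoder — a synthetic
stand-in embedding, deterministic and content-sensitive but *not* a trained
EEG representation; any callable with the same signature can replace it.

## Desk-scale study conditions

All learning checks (tests and `scripts/acceptance.py`) run one frozen
configuration sized for a single CPU: 16-channel montage at 32 Hz, 2-s
windows (64 samples), generator defaults otherwise (8 sources across the
δ/θ/α bands feasible under the 16 Hz Nyquist, two classes, 10 dB SNR),
spatial ×2 task (8 observed channels by farthest-point sampling), 200
training / 50 test windows, model `base_width=32, d_model=64, d_state=8`,
one bidirectional layer with one block per direction, AdamW lr 1e-2,
batch 8, 10 epochs.  Geometry-probing fixtures (single-source spline
comparisons) use 20 dB SNR to isolate the spatial property from noise.

## Known limitations

* The sequential numpy scan is orders of magnitude slower than fused GPU
  kernels; the package targets desk-scale experiments, not benchmark-scale
  training (parameter counts at the published scale are reported by
  `model_summary`, not asserted).
* One-step diffusion at desk scale stays close to its LR-guided
  initialization; the conditioned-vs-unconditioned ordering is robust, but
  absolute diffusion NMSE trails the regression model, consistent with the
  published observation that diffusion needs longer training.
* The spherical-spline baseline and leadfield share the same spherical
  geometry; real heads are not spheres, and neither are the template
  positions exactly.
* EDF/FIF ingestion matches channels by name only; no resampling,
  re-referencing (beyond optional common average) or artifact subspace
  removal is provided.
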