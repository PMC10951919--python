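# Methods

This note documents the models, defaults and design choices behind
`cryosr`, and what the synthetic studies do and do not demonstrate.

## Forward model and simulator

Each synthetic movie frame is generated in the Fourier domain as
`f_i = D(C · E_i · T_i x) + n_i`:

* **Scene `x`** — `n_particles` copies (default 40 on a 192² grid) of a
  single blob-cluster template (a 4-component isotropic Gaussian
  mixture, randomly positioned and rotated) over a smooth low-order
  background. Repeating one template emulates the natural repetition of
  identical particle projections across a micrograph; it is not a
  protein density projection.
* **Drift `T_i`** — a seeded Gaussian random walk of cumulative
  sub-pixel shifts (step σ 0.6 HR px by default), applied as Fourier
  phase ramps; boundaries are therefore periodic. Frame 0 defines the
  reference position.
* **CTF `C`** — single defocus (no astigmatism), underfocus positive,
  `CTF(k) = −√(1−A²)·sin γ(k) − A·cos γ(k)` with
  `γ(k) = πλΔf k² − (π/2)Cs λ³k⁴ + φ` and λ the relativistic electron
  wavelength. Defaults: Δf 15000 Å, 300 kV, Cs 2.7 mm, A 0.07, pixel
  1.5 Å. `CTF(0) = −A` and the output is bounded in [−1, 1].
* **Radiation damage `E_i`** — a dose-proportional B-factor envelope
  `exp(−β d k²/4)` with `d` the exposure accumulated to the frame
  midpoint (default 2 e⁻/Å² per frame) and β = 8 Å²/(e⁻/Å²). One
  parameter, monotone in dose and frequency; it reproduces the
  early-vs-late spectral asymmetry that self-supervision exploits, not
  any measured damage curve.
* **Downsampling `D`** — Fourier cropping (ideal low-pass, mean
  preserved exactly) or 2×2 binning. Fourier cropping makes band limits
  exact and is the default for oracle tests; **binning is the
  acquisition model for the end-to-end studies**, because real binned
  movies alias super-Nyquist signal into the LR band — the physical
  channel MISR exploits — whereas ideal cropping destroys it
  irreversibly.
* **Noise** — additive white Gaussian, applied after downsampling, with
  per-frame σ = `noise_sigma` × the clean frame's σ. The default
  `noise_sigma = 4` puts the per-frame power SNR at 0.0625, inside the
  realistic 0.05–0.1 window for dose-fractionated frames. Gaussian
  rather than Poisson noise keeps every oracle analytic; at cryo-EM
  doses the difference is immaterial for these tests.

The simulator returns the noise-free scene, the CTF-modulated scene
(the method's recovery target), the true shift track and the observable
movie, so every processing stage has an oracle.

## Preprocessing

Registration is global rigid translation by phase correlation on the
*unnormalised* cross-power spectrum, low-pass weighted by
`exp(−|k|²/2σ²)` with σ = 0.1 cycles/px, with upsampled-DFT sub-pixel
refinement. The unnormalised spectrum is a matched filter; the low-pass
weighting reflects that cryo-EM signal concentrates at low frequency
while the noise is white — without it, registration fails completely at
per-frame SNR ≈ 0.05. Measured accuracy against the simulator's true
shifts: ≤ 0.01 px noiseless, ≲ 0.2 px for an SNR-0.05 frame against a
clean reference (the regime of the averaging loop, which registers each
frame against the running mean accumulated outward from the reference
frame).

Moving averages `A(f_m..f_n; r)` visit frames outward from reference
`r`, align each to the running mean, and average. The exposure is split
at ⌈M/2⌉ (the extra frame goes to the early half, which carries more
signal). K = 4 reference frames are drawn uniformly without replacement
from the late half for training inputs; the same references (as global
frame indices) are reused for the all-frame inference averages.

## Network

Encode–fuse–decode over bilinearly pre-upsampled inputs:

* Encoder (weights shared across frames): each upsampled frame is
  concatenated with the pixel-wise **median** of all upsampled frames
  (the alignment anchor), embedded by one convolution and
  `n_encoder_layers` residual blocks.
* Fusion: states are merged pairwise and recursively — concatenate two
  states, project back to one with a single *shared* convolution —
  ⌈log₂ N⌉ times; odd counts duplicate the last state.
* Decoder: `n_decoder_layers` convolutions ending in one channel; the
  output is this residual plus the median reference.

All operators are local and shared, so the parameter count is
independent of N and of image size: the network trains on 64-px crops
and runs on full micrographs. Convolutions are float32 im2col matmuls
with hand-derived backward passes; leaky rectifier (slope 0.1) and no
normalisation layers, in the tradition of small image-specific networks.
Package defaults are 64 channels and 2 residual blocks; the synthetic
studies use 16 channels and 1 block, which the measurements below showed
to be capacity-sufficient at the 96² study scale while keeping a full
400-iteration training run under a minute on one CPU core.

## Loss and training

Per iteration, one random crop (64 px on the acquisition grid) is taken
from the K late-half averages and the pseudo-HR; the average-crops are
further downsampled by s = 2 with the same operator family as the
acquisition downsampling (so the self-supervision degradation matches
the real one), and a random vertical/horizontal mirror is applied
jointly. Patches are standardized by the pseudo-HR crop's mean/σ.

The loss is `MAE + λ·L_freq` (λ = 1) with
`L_freq = mean_k w_k · ‖(Re,Im) difference of Fourier coefficients‖₂`
and `w = exp(−|k|²/2σ_f²)`, σ_f = 0.125 cycles/px — half the LR Nyquist
on the output grid, down-weighting the band where both prediction and
target are noise-dominated. Its gradient is computed analytically:
`∇ = Re F(w · conj(D)/|D|)/n` for `D` the coefficient difference (zero
sub-gradient at D = 0), verified against finite differences.

Optimisation is Adam from 10⁻³. The learning rate decays by 10 when the
projected loss decrease over a sliding window (|slope| × window, from a
linear fit) falls below 0.3 × the residual noise of the fit; training
stops at the 10⁻⁶ floor or a 400-iteration cap. The window (80) and
factor (0.3) are deliberately patient: with single-crop sampling the
total loss is dominated by noise variance and flattens long before the
signal term converges — an impatient detector halts at ~100 iterations
and measurably degrades output quality, because the network has not yet
learned to co-register the K mutually shifted averages.

## Inference and back-projection

The trained network runs on the all-frame averages (tiled with feathered
overlap and trimmed interior seams when configured). The output is then
corrected toward data consistency by back-projection,
`sr ← sr + step · U(anchor − D(sr))`, with U bilinear upsampling. The
default is a **single damped pass (step 0.5) against the mean of the K
averages**: iterating to full consistency with a single noisy reference
average re-injects that average's noise into the denoised estimate
(measured: Pearson to ground truth drops from ≈0.65 to ≈0.34, below the
bilinear baseline). The classical full iteration (any count, step up to
1, single-reference anchor) remains available through the config; the
residual norm is monitored and never allowed to increase. The output
header carries pixel size divided by s.

## What the synthetic study shows — and does not

The canonical study: ten seeded movies, 96×96 LR, 16 frames, per-frame
SNR 0.0625, binned 2× from a CTF-modulated 192² scene; pipeline at 16
channels, crop 64, ≤ 400 iterations; scored against the CTF-modulated
ground truth with bilinear upsampling of the aligned all-frame average
as baseline. `scripts/acceptance.py` recomputes it.

* **Pearson correlation to ground truth** improves for the zero-shot
  output in most seeds (9/10 in the frozen seed batch, mean ≈ 0.66 vs
  0.61) — the fusion/denoising channel of the method is effective.
* **High-band FRC gain** (above 0.25 cycles/HR-px, the super-resolved
  band proper) is at the measurement-noise floor (mean ≈ −0.005,
  positive in a minority of seeds), and this did not change with network
  width, depth, training length or back-projection strength. The reason
  is informational, not algorithmic: at a 96² field with 16 frames and
  power SNR 0.06, the only genuine super-Nyquist channel is the aliased
  fold introduced by binning, and after drift-averaging its amplitude
  sits below the FRC noise floor of a 192² comparison; the L1-optimal
  response of the network to a noise-dominated supervision band is
  suppression. Real micrographs are ~4000² with thousands of particles,
  i.e. three orders of magnitude more internal evidence per frequency
  band; the desk-scale study is a functional test of the machinery, not
  a demonstration of super-Nyquist recovery.

Other deliberate limitations: the simulator is not an electron-optical
simulation (no detector MTF/DQE, no Poisson counting, no 3-D density
projection); the aligner is global and rigid (no local motion, no dose
weighting — the averaging stage treats all frames equally); upscale
factors are integral; boundaries are periodic throughout. Degenerate
inputs are rejected explicitly (constant images for registration,
constant movies for training); ties and guards use documented epsilons
(standardization floor 10⁻⁸, loss sub-gradient 10⁻¹², plateau atol
10⁻¹², lr-floor comparison tolerance 10⁻⁹).
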