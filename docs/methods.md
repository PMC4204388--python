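# Methods

This note records the model, the numerical choices, and the design decisions
behind `nchr`, in the spirit of a solver's methods appendix.

## Reconstruction model

A spectral-domain OCT B-scan `f(x)` (rows = axial depth, columns = A-scan
index, intensities normalized to [0, 1]) is related to the camera's k-space
measurements `F(k)` by a unitary Fourier transform.  The package default is
the full 2-D unitary DFT of the B-scan; a per-column (axial) 1-D mode is
available via `transform_mode="axial"`, closer to how an SD-OCT spectrometer
samples, but the generic whole-lattice operator is the default because the
regularizer and the consistency constraint are defined on the whole lattice.
Unitarity means Parseval holds to round-off, so noise variances are the same
in both domains.

The estimate solves a homotopic continuation problem: minimize the non-local
functional ρ(f, σ) subject to per-coefficient data consistency
`|F̂(k) − F(k)| ≤ δ`, with the kernel bandwidth σ driven toward zero.  Large
σ gives a heavily smoothed, easy problem whose solution initializes the next,
sharper one.

### Non-local regularizer

ρ(f, σ) = Σ_x Σ_{i∈N(x)} w(x,i,σ) ‖R(x) − R(i)‖², with:

- `R(x)`: square patch extractor (default 9×9), symmetric-reflection padding
  at the borders (for neighborhoods too);
- `N(x)`: square search window (default 21×21);
- patch differences are plain Frobenius sums of squared per-pixel
  differences — no Gaussian taper, and the weights are used unnormalized,
  exactly as the functional is written;
- ρ's patches are taken from the *variable* image `f`; the patches inside
  the weights come from the frozen current estimate `f̂`.

The modified James-Stein weight multiplies the usual Gaussian
patch-similarity kernel by a positive-part shrinkage factor
`max(0, 1 − (m−2)σ²/‖r(x)‖²)`, where `r(x)` is the residual patch
(noisy input minus current estimate) at `x` and `m` is the pixel count the
norm runs over.  Reading `m` as the patch pixel count (81) keeps the factor
dimensionally consistent with the residual norm; the literal
neighborhood-count reading (441) is available via `js_norm="neighborhood"`.
The raw factor can go negative for small residuals; it is clipped at zero
(the standard positive-part James-Stein estimator), which keeps all weights
and ρ nonnegative.  The self-weight w(x,x) is always zero.

Interpretation: the factor is an evidence gate.  Where the current estimate
sits close to the data (residual below ~(m−2)σ²), there is no evidence of
removable noise at bandwidth σ and the non-local pull is switched off,
protecting converged structure from over-smoothing.  The conventional
non-local weight (no factor) is retained as a comparison arm; modified
weights are *not* symmetric in (x, i) — the factor depends on x only —
whereas conventional weights are.

### k-space noise compensation

The clamp replaces each deviation `d = F̂(k) − F(k)` by `d·min(1, δ/|d|)` — a
radial projection of the deviation onto the δ-disc, the rotation-invariant
complex generalization of the scalar three-branch clamp (whose branches
partition on |F̂ − F| vs δ).  A `component` mode clips real and imaginary
parts independently instead.  The radial clamp is an exact Euclidean
projection: idempotent, monotone in δ, identity inside the ball, and hard
data consistency (output = measurements) at δ = 0.

δ is κ times the per-coefficient complex noise standard deviation (κ default
3, covering ~99.9% of circular Gaussian noise deviations).  The noise std
comes either from calibration (the simulator knows its ground truth) or from
a user-marked signal-free spectral band, estimated robustly as
`median(|F|)/√(ln 2)` (the Rayleigh-median relation), which tolerates stray
signal coefficients.  Note that speckle is broadband: on speckled images a
"signal-free" band does not exist, and the band estimator then reports
speckle-plus-noise power rather than the detector floor.

### Solver loop

Per σ level (geometric schedule `σ_1·decay^t`, defaults σ_1 = 0.3,
decay = 0.9, floored at 10⁻³, capped at 50 levels):

1. recompute the weight field at the current estimate, freeze it;
2. `inner_iters` (default 5) steepest-descent steps on ρ.  With frozen
   weights ρ is an exact quadratic form, so the value along a descent ray
   follows from two gradient evaluations in closed form; the initial step is
   `λ / max|∇ρ|` (λ = 0.7, i.e. a maximum per-pixel change of λ), then
   halved until ρ does not increase.  λ's role is genuinely underdetermined
   in the method description; the step-scale interpretation is isolated in
   the single `lambda_step` constant.
3. forward transform, radial clamp into the δ-ball, inverse transform (the
   real part; the imaginary residual is round-off and available as a
   diagnostic).

Convergence: relative L2 image change below `conv_tol` (default 10⁻⁴) or
schedule exhausted.  Two refinements around the James-Stein gate were needed
to make the reference iteration well-posed:

- **Bootstrap level.**  At the warm start (estimate = naive inverse
  transform) the residual is identically zero, so every modified weight
  vanishes and the loop would be a fixed point.  The first σ level therefore
  runs with conventional weights; the gate takes over from level 2.
- **Gated levels don't convergence-test.**  A level whose weight field is
  identically zero changes nothing by construction; counting it would stop
  the continuation before σ becomes small enough for the gate to open.

The loop contains no randomness: identical configuration and measurement give
a bit-identical result.  Non-finite intermediates raise a numerical-failure
error carrying the trace collected so far.

### Implementation of the heavy operators

Weights, ρ and ∇ρ are organized as one vectorized pass per neighborhood
offset: patch-difference maps are box-filter sums of squared shifted
differences, and the frozen-weight gradient accumulates, per offset,
`B_t = 2·A_t·(box-sum of W_t)` at positive and shifted-negative positions,
with contributions landing on reflection-padded pixels folded back onto
their interior sources.  This makes central finite differences of ρ agree
with the analytic gradient including at the borders.  Per-pixel scalar
versions of every operation are kept as the readable reference surface, and
nested-loop brute-force implementations in the test suite pin both down on
≤16×16 instances to 10⁻⁸ relative.

## Synthetic phantom and acquisition model

The phantom emulates a retinal cross-section: a zero-reflectivity band at
the top (vitreous), five layers with reflectivities spanning 10:1
(0.9, 0.3, 0.7, 0.09, 0.5), boundaries undulating sinusoidally with ≤3 px
amplitude, optional disc inclusions for vessels.  ROI masks for scoring are
the background band and the layer interiors, eroded by the 9×9 patch radius
so metrics never straddle an interface; every mask must keep ≥50 px.

Speckle is fully developed: the amplitude image is multiplied by the
magnitude of a unit-power circular complex Gaussian field, so speckled
intensity is unit-mean (E[out²] = clean²).  Detector noise is additive
circular complex white Gaussian in k-space — where the SD-OCT camera
samples — with per-coefficient variance `speed_factor × base_noise_std²`,
encoding that SNR is inversely proportional to the A-scan rate
(speed_factor 1 ↔ 47 kHz, 4 ↔ 188 kHz, 8 ↔ 376 kHz).  The Gaussian-in-k-space
choice is a stand-in; the distribution of real high-speed acquisitions is
instrument-specific.  Speckle and detector noise use independent child
streams of one seed, so disabling either leaves the other's realization
untouched.

`base_noise_std = 0.05` was chosen once so that the naive reconstruction of
the default phantom spans a realistic working range — about 37 dB SNR at the
baseline rate falling to about 28 dB at 8× — degraded but recoverable, as in
practical SD-OCT.

What the phantom does *not* emulate: spectrometer λ→k resampling, dispersion,
motion, axial PSF structure, depth-dependent attenuation — and, importantly,
any background texture: the band above the first layer is exactly zero
reflectivity, so its only content is detector noise.  Consequently nearly all
background noise lies within the δ-ball and both weight modes can flatten the
background almost completely; reconstructed SNR then saturates far above
anything attainable on real tomograms, and differences *between* well-
converged variants reflect where the continuation stopped rather than
fidelity.  Passing direction tests on this phantom show the pipeline denoises
and preserves contrast; they do not predict margins on in-vivo data.

## Metrics

SNR = 10·log₁₀(max|f|² / σ²_b) in dB; CNR = mean over regions of
(μ_r − μ_b)/√(σ²_r + σ²_b).  Variances are unbiased (n−1) sample variances
(immaterial at the ≥50 px mask floor).  Metrics are computed on the
linear-magnitude image by default; a log-compressed (display-scale) variant
sits behind `log_scale=True`, since published figures are sometimes scored on
display images.  Degenerate inputs (zero background variance, zero pooled
variance, empty masks) raise an undefined-metric error rather than returning
infinities.

## Problem sizes used in the shipped studies

The test suite's end-to-end study runs the default 128×128 phantom at speed
factors {1, 4, 8} with five noise seeds each (reference operating point:
σ_1 = 0.3, λ = 0.7, 9×9/21×21); `scripts/acceptance.py` repeats it with three
seeds derived from its `--seed` plus the speed-4 weight-mode comparison.
Oracle-equivalence instances are ≤16×16 with 3×3 patches in 5×5
neighborhoods.  These sizes keep a full run at minutes on a single CPU while
exercising every code path at the reference parameter values.

## Known limitations

- The reconstruction operates on real-valued B-scans (real part after the
  inverse transform); complex/magnitude processing of raw interferograms is
  out of scope, as are λ→k resampling and dispersion compensation.
- B-scans only; no 3-D volumes, no GPU path.
- The weight computation is O(|N| · H · W) per σ level with dense search
  windows; desk-scale images (≤ a few hundred pixels square) are the target.
- On the synthetic phantom the weight-mode comparison is direction-unstable
  for the saturation reason above; treat modified-vs-conventional margins
  measured there as phantom artifacts, not method properties.
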