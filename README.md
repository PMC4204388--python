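# nchr — noise-compensated homotopic non-local OCT reconstruction

Rapid spectral-domain OCT acquisitions trade signal for speed: the SNR of an
SD-OCT tomogram is proportional to the detector integration time, so pushing
the A-scan rate from 47 kHz to 188 or 376 kHz buries retinal microstructure
in speckle and detector noise.  `nchr` reconstructs such low-SNR B-scans by
**noise-compensated homotopic modified James-Stein non-local regularized
reconstruction (NCHR)**: instead of denoising the inverse-transformed image
alone, it couples spatial-domain non-local regularization to the spectral
(k-space) measurements the camera actually recorded.

The package is aimed at OCT image-analysis researchers.  It contains the full
method plus everything needed to exercise it without any real data: a layered
retina-like phantom simulator with fully developed speckle and speed-scaled
detector noise, and the SNR/CNR metrics used for scoring.

## The method

With `f(x)` the B-scan and `F(k)` its k-space measurements (unitary DFT,
`f = F⁻¹F(k)`), the reconstruction solves

    f̂(x) = lim_{σ→0}  argmin_f  ρ(f, σ)
    subject to  |F̂(k) − F(k)| ≤ δ  for every k,

where the regularizer is a weighted non-local patch penalty

    ρ(f, σ) = Σ_x Σ_{i∈N(x)} w(x, i, σ) · ‖R(x) − R(i)‖²,

`R(x)` extracts a 9×9 patch, `N(x)` is a 21×21 search neighborhood, and the
modified James-Stein weight

    w(x, i, σ) = α(x,i) · max(0, 1 − (m−2)σ² / ‖f(x) − f̂(x)‖²)
                 · exp(−‖R̂(x) − R̂(i)‖² / 2σ²)

carries a positive-part shrinkage factor that gates the non-local pull off
wherever the current estimate already explains the data (small residual
relative to σ).  Dropping the factor gives the conventional non-local weight,
available as a baseline (`weight_mode="conventional"`).

The solver alternates (1) frozen-weight steepest descent on ρ in the spatial
domain and (2) a k-space projection that clamps every reconstructed
coefficient back into the δ-ball around its measurement, while σ is continued
geometrically toward zero.  δ is the empirically determined noise floor of
the system at the operating speed, scaled by κ (default 3).  Quality is
scored with

    SNR = 10 log₁₀( max|f|² / σ²_b ),      CNR = (1/R) Σ_r (μ_r − μ_b) / √(σ²_r + σ²_b),

computed over a background-noise mask and R homogeneous regions of interest.

## Worked example

```python
import nchr

scene = nchr.generate_phantom(nchr.default_phantom_spec(seed=0))
acq = nchr.AcquisitionModel(speed_factor=8, base_noise_std=0.05, seed=0)  # 8x = 376 kHz
meas = nchr.simulate_acquisition(scene, acq)
meas = meas.with_delta(nchr.estimate_delta(meas, noise_std=acq.noise_std))

rois = scene.roi_set()
naive = nchr.inverse_transform(meas.coefficients)
before = nchr.quality_report(naive, rois)
result = nchr.reconstruct(meas)
after = nchr.quality_report(result.image, rois)

print(f"delta = {meas.delta:.3f}")
print(f"naive reconstruction : SNR {before.snr_db:6.2f} dB   CNR {before.cnr:.3f}")
print(f"NCHR reconstruction  : SNR {after.snr_db:6.2f} dB   CNR {after.cnr:.3f}")
print(f"outer iterations = {result.iterations}, converged = {result.converged}")
```

prints

```
delta = 0.424
naive reconstruction : SNR  28.54 dB   CNR 1.402
NCHR reconstruction  : SNR  41.84 dB   CNR 1.560
outer iterations = 26, converged = True
```

The naive reconstruction is the plain inverse transform of the noisy
measurements; at 8× the baseline scan rate the phantom's background band is
dominated by detector noise.  NCHR lifts the peak-signal-to-background-noise
ratio by 13 dB and improves layer-versus-background contrast (CNR) while the
k-space clamp guarantees every spectral coefficient stays within δ = 0.424 of
what was measured.

The same pipeline is available from the shell:

```sh
nchr simulate --out scene.h5 --seed 0 --speed-factor 8
nchr reconstruct --input scene.h5 --output recon.tif --trace trace.jsonl
nchr compare --seeds 3 --speed-factor 4 --size 64
```

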