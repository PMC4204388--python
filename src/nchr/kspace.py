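"""Spatial <-> k-space transforms, noise-floor tolerance and the data-consistency clamp.

In SD-OCT the camera samples interferometric data in the spectral (k-space)
domain; the B-scan is its inverse Fourier transform.  The reconstruction
framework alternates spatial-domain regularization with a k-space projection
that keeps every reconstructed coefficient within a tolerance ``delta`` of the
measured one, ``delta`` being derived from the detector noise floor.

All transforms are unitary so that energy (and therefore noise variance) is
preserved between domains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import log, sqrt

import numpy as np

from .errors import CannotEstimateDeltaError

__all__ = [
    "KSpaceMeasurement",
    "forward_transform",
    "inverse_transform",
    "estimate_delta",
    "estimate_noise_std",
    "highfreq_band_mask",
    "project_to_tolerance",
]


@dataclass
class KSpaceMeasurement:
    """Complex spectral coefficients F(k) plus the consistency tolerance.

    Parameters
    ----------
    coefficients
        Complex 2-D array on the same lattice as the spatial image.
    delta
        Per-coefficient deviation tolerance (same units as ``|coefficients|``);
        ``None`` until estimated or supplied.
    speed_factor, base_noise_std, seed
        Optional acquisition metadata carried along for provenance.
    """

    coefficients: np.ndarray
    delta: float | None = None
    speed_factor: float = 1.0
    base_noise_std: float | None = None
    seed: int | None = None
    transform_mode: str = "2d"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=complex)
        if self.coefficients.ndim != 2:
            raise ValueError("coefficients must be a 2-D array")
        if self.delta is not None and self.delta < 0:
            raise ValueError("delta must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.coefficients.shape

    def with_delta(self, delta: float) -> "KSpaceMeasurement":
        return replace(self, delta=float(delta))


def _axes(mode: str):
    if mode == "2d":
        return (0, 1)
    if mode == "axial":
        # one 1-D transform per A-scan (column), along depth
        return (0,)
    raise ValueError(f"unknown transform mode {mode!r}")


def forward_transform(image: np.ndarray, mode: str = "2d") -> np.ndarray:
    """Unitary DFT of a B-scan (whole-image 2-D by default, per-column if ``axial``)."""
    image = np.asarray(image)
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return np.fft.fftn(image, axes=_axes(mode), norm="ortho")


def inverse_transform(
    coefficients: np.ndarray, mode: str = "2d", return_imag_residual: bool = False
):
    """Real part of the inverse unitary DFT.

    The imaginary residual (zero for coefficients of a real image, tiny
    round-off otherwise) is available as a diagnostic.
    """
    coefficients = np.asarray(coefficients, dtype=complex)
    if not np.all(np.isfinite(coefficients)):
        raise ValueError("coefficients contain non-finite values")
    full = np.fft.ifftn(coefficients, axes=_axes(mode), norm="ortho")
    image = full.real
    if return_imag_residual:
        return image, float(np.abs(full.imag).max(initial=0.0))
    return image


def highfreq_band_mask(shape: tuple[int, int], cutoff: float = 0.25) -> np.ndarray:
    """Boolean mask of the high-frequency corner band of a 2-D spectrum.

    Selects coefficients whose normalized frequency exceeds ``cutoff``
    (Nyquist = 0.5) along *both* axes.  For structured B-scans, whose energy
    concentrates near the zero-lateral-frequency strip, this band is
    effectively signal-free and usable for noise-floor estimation.
    """
    fy = np.abs(np.fft.fftfreq(shape[0]))
    fx = np.abs(np.fft.fftfreq(shape[1]))
    return (fy[:, None] >= cutoff) & (fx[None, :] >= cutoff)


# median of |n| for circular complex Gaussian noise with E|n|^2 = sigma^2
_RAYLEIGH_MEDIAN = sqrt(log(2.0))


def estimate_noise_std(
    coefficients: np.ndarray, band_mask: np.ndarray
) -> float:
    """Robust per-coefficient complex noise std from a signal-free band.

    Uses the median of the coefficient magnitudes: for circular complex
    Gaussian noise the magnitude is Rayleigh and ``median(|n|) = sigma *
    sqrt(ln 2)``, which is insensitive to a few stray signal coefficients.
    """
    band = np.asarray(coefficients)[np.asarray(band_mask, dtype=bool)]
    if band.size == 0:
        raise CannotEstimateDeltaError("signal-free band mask selects no coefficients")
    return float(np.median(np.abs(band)) / _RAYLEIGH_MEDIAN)


def estimate_delta(
    measurement: KSpaceMeasurement,
    noise_std: float | None = None,
    kappa: float = 3.0,
    band_mask: np.ndarray | None = None,
) -> float:
    """Noise-floor-derived tolerance ``delta = kappa * noise_std``.

    ``noise_std`` is the per-coefficient complex noise standard deviation,
    either supplied from calibration or estimated from a user-marked
    signal-free spectral band.
    """
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    if noise_std is None:
        if band_mask is None:
            raise CannotEstimateDeltaError(
                "provide noise_std from calibration or mark a signal-free band"
            )
        noise_std = estimate_noise_std(measurement.coefficients, band_mask)
    if noise_std < 0:
        raise ValueError("noise_std must be nonnegative")
    return float(kappa * noise_std)


def project_to_tolerance(
    estimate_coeffs: np.ndarray,
    measurement: KSpaceMeasurement,
    mode: str = "radial",
) -> np.ndarray:
    """Clamp reconstructed coefficients into the delta-ball around the measurements.

    Per coefficient the deviation ``d = Fhat - F`` is replaced by
    ``d * min(1, delta / |d|)`` (``radial`` mode, the rotation-invariant
    complex generalization of the scalar three-branch rule), or its real and
    imaginary parts are clipped independently to ``[-delta, delta]``
    (``component`` mode).  Coefficients already within tolerance are returned
    unchanged; ``delta = 0`` reduces to hard data consistency.
    """
    est = np.asarray(estimate_coeffs, dtype=complex)
    meas = measurement.coefficients
    if est.shape != meas.shape:
        raise ValueError(
            f"shape mismatch: estimate {est.shape} vs measurement {meas.shape}"
        )
    delta = measurement.delta
    if delta is None:
        raise ValueError("measurement.delta is unset; call estimate_delta first")
    if delta == 0:
        return meas.copy()
    d = est - meas
    if mode == "radial":
        mag = np.abs(d)
        scale = np.ones_like(mag)
        np.divide(delta, mag, out=scale, where=mag > delta)
        return meas + d * scale
    if mode == "component":
        return meas + np.clip(d.real, -delta, delta) + 1j * np.clip(
            d.imag, -delta, delta
        )
    raise ValueError(f"unknown projection mode {mode!r}")
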