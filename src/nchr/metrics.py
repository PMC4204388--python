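"""SNR and CNR image-quality metrics.

SNR = 10 log10( max|f|^2 / var_background )   [dB]

CNR = (1/R) sum_r (mu_r - mu_b) / sqrt(sigma_r^2 + sigma_b^2)

with mu_b, sigma_b^2 the mean/variance over a background (signal-free) mask
and mu_r, sigma_r^2 over the r-th homogeneous region of interest.  Variances
are unbiased (n-1) sample variances; metrics are computed on the
linear-magnitude image by default, with an optional log-compressed (display
scale) variant behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UndefinedMetricError

__all__ = ["ROISet", "QualityReport", "snr", "cnr", "quality_report"]


@dataclass
class ROISet:
    """A background-noise mask plus R >= 1 homogeneous region-of-interest masks."""

    background_mask: np.ndarray
    region_masks: list

    def __post_init__(self) -> None:
        self.background_mask = np.asarray(self.background_mask, dtype=bool)
        self.region_masks = [np.asarray(m, dtype=bool) for m in self.region_masks]
        if len(self.region_masks) < 1:
            raise ValueError("need at least one region mask")
        if self.background_mask.sum() == 0:
            raise ValueError("background mask is empty")
        for k, m in enumerate(self.region_masks):
            if m.shape != self.background_mask.shape:
                raise ValueError(f"region mask {k} shape differs from background")
            if m.sum() == 0:
                raise ValueError(f"region mask {k} is empty")
            if np.any(m & self.background_mask):
                raise ValueError(f"region mask {k} overlaps the background mask")


@dataclass
class QualityReport:
    """SNR (dB), mean CNR and the per-region CNR values it averages."""

    snr_db: float
    cnr: float
    per_region_cnr: list

    def to_dict(self) -> dict:
        return {
            "snr_db": self.snr_db,
            "cnr": self.cnr,
            "per_region_cnr": list(self.per_region_cnr),
        }


def _log_compress(image: np.ndarray) -> np.ndarray:
    mag = np.abs(image)
    peak = mag.max()
    if peak == 0:
        raise UndefinedMetricError("log-scale metrics undefined on an all-zero image")
    floor = peak * 1e-6  # -120 dB display floor
    return 20.0 * np.log10(np.maximum(mag, floor))


def snr(image: np.ndarray, rois: ROISet, log_scale: bool = False, ddof: int = 1) -> float:
    """Peak-signal-to-background-noise ratio in decibels."""
    image = np.asarray(image, dtype=float)
    if log_scale:
        image = _log_compress(image)
    bg = image[rois.background_mask]
    if bg.size < 2:
        raise UndefinedMetricError("background mask needs at least 2 pixels")
    var_b = float(np.var(bg, ddof=ddof))
    if var_b == 0:
        raise UndefinedMetricError("background variance is zero; SNR undefined")
    peak = float(np.abs(image).max())
    if peak == 0:
        raise UndefinedMetricError("image is identically zero; SNR undefined")
    return float(10.0 * np.log10(peak**2 / var_b))


def quality_report(
    image: np.ndarray, rois: ROISet, log_scale: bool = False, ddof: int = 1
) -> QualityReport:
    """SNR plus per-region and mean CNR in one pass."""
    raw = np.asarray(image, dtype=float)
    img = _log_compress(raw) if log_scale else raw
    bg = img[rois.background_mask]
    if bg.size < 2:
        raise UndefinedMetricError("background mask needs at least 2 pixels")
    mu_b = float(bg.mean())
    var_b = float(np.var(bg, ddof=ddof))
    per_region = []
    for k, mask in enumerate(rois.region_masks):
        vals = img[mask]
        if vals.size < 2:
            raise UndefinedMetricError(f"region mask {k} needs at least 2 pixels")
        var_r = float(np.var(vals, ddof=ddof))
        denom = var_r + var_b
        if denom == 0:
            raise UndefinedMetricError(
                f"region {k} and background both have zero variance; CNR undefined"
            )
        per_region.append((float(vals.mean()) - mu_b) / np.sqrt(denom))
    return QualityReport(
        snr_db=snr(image, rois, log_scale=log_scale, ddof=ddof),
        cnr=float(np.mean(per_region)),
        per_region_cnr=per_region,
    )


def cnr(image: np.ndarray, rois: ROISet, log_scale: bool = False, ddof: int = 1) -> QualityReport:
    """Contrast-to-noise report (alias of :func:`quality_report`)."""
    return quality_report(image, rois, log_scale=log_scale, ddof=ddof)
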