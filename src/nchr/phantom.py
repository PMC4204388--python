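"""Layered retina-like phantom generator with speckle and speed-scaled detector noise.

A phantom is a piecewise-constant reflectivity map: a dark (zero-reflectivity)
band at the top standing in for the vitreous, followed by a stack of layers of
contrasting reflectivity whose boundaries undulate gently across the B-scan,
optionally with disc inclusions emulating vessel cross-sections.  Fully
developed speckle multiplies the amplitude (magnitude of a unit-power circular
complex Gaussian field, so speckled intensity has unit mean), and detector
noise is additive circular complex Gaussian in k-space with variance
proportional to the simulated A-scan rate: doubling the line rate halves the
integration time, halving the collected signal energy relative to the noise.
The generator also emits the ROI masks (background band + eroded layer
interiors) that the SNR/CNR metrics score against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_erosion

from . import kspace
from .errors import InvalidAcquisitionError, InvalidSpecError
from .metrics import ROISet

__all__ = [
    "PhantomSpec",
    "PhantomScene",
    "AcquisitionModel",
    "default_phantom_spec",
    "generate_phantom",
    "apply_speckle",
    "simulate_acquisition",
]

_MIN_ROI_PIXELS = 50


@dataclass
class PhantomSpec:
    """Geometry and reflectivities of a layered phantom.

    ``layer_boundaries`` is an (n_layers, width) array of row positions, one
    curve per boundary; layer k occupies rows [boundary k, boundary k+1) and
    the last layer extends to the bottom of the image.  ``erosion_radius``
    controls how far ROI masks retreat from layer boundaries (default = the
    9x9 patch radius, so metrics never straddle an interface).
    """

    height: int = 128
    width: int = 128
    layer_boundaries: np.ndarray = None
    layer_reflectivities: np.ndarray = None
    background_reflectivity: float = 0.0
    inclusions: list = field(default_factory=list)  # (center(y,x), radius, reflectivity)
    erosion_radius: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layer_boundaries is None or self.layer_reflectivities is None:
            raise InvalidSpecError("layer_boundaries and layer_reflectivities required")
        self.layer_boundaries = np.atleast_2d(np.asarray(self.layer_boundaries, dtype=float))
        self.layer_reflectivities = np.asarray(self.layer_reflectivities, dtype=float)
        nb = self.layer_boundaries.shape[0]
        if self.layer_boundaries.shape[1] == 1:
            self.layer_boundaries = np.repeat(self.layer_boundaries, self.width, axis=1)
        if self.layer_boundaries.shape != (nb, self.width):
            raise InvalidSpecError("layer_boundaries must be (n_layers, width)")
        if self.layer_reflectivities.shape != (nb,):
            raise InvalidSpecError("one reflectivity per layer required")
        if np.any(self.layer_boundaries < 0) or np.any(self.layer_boundaries >= self.height):
            raise InvalidSpecError("layer boundaries must lie within [0, height)")
        if np.any(np.diff(self.layer_boundaries, axis=0) <= 0):
            raise InvalidSpecError("layer boundaries must be strictly increasing per column")
        if np.any(self.layer_reflectivities < 0) or self.background_reflectivity < 0:
            raise InvalidSpecError("reflectivities must be nonnegative")
        if self.background_reflectivity >= self.layer_reflectivities.min():
            raise InvalidSpecError(
                "background reflectivity must be strictly below every layer reflectivity"
            )
        for center, radius, refl in self.inclusions:
            if radius <= 0 or refl < 0:
                raise InvalidSpecError("inclusions need positive radius, nonnegative reflectivity")

    @property
    def n_layers(self) -> int:
        return self.layer_boundaries.shape[0]


@dataclass
class PhantomScene:
    """Noise-free reflectivity map plus the masks the metrics module needs."""

    clean_image: np.ndarray
    background_mask: np.ndarray
    region_masks: list
    truth_labels: np.ndarray

    def roi_set(self) -> ROISet:
        return ROISet(self.background_mask, list(self.region_masks))


@dataclass
class AcquisitionModel:
    """Detector-noise model tied to the simulated A-scan rate.

    ``speed_factor`` is the line rate relative to the 47 kHz baseline (4 for
    188 kHz, 8 for 376 kHz); the per-coefficient complex noise variance is
    ``speed_factor * base_noise_std**2``.
    """

    speed_factor: float = 1.0
    base_noise_std: float = 0.05
    speckle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_factor < 1:
            raise InvalidAcquisitionError("speed_factor must be >= 1")
        if self.base_noise_std < 0:
            raise InvalidAcquisitionError("base_noise_std must be nonnegative")

    @property
    def noise_std(self) -> float:
        """Effective per-coefficient complex noise std at this speed."""
        return float(self.base_noise_std * np.sqrt(self.speed_factor))


def default_phantom_spec(seed: int = 0, height: int = 128, width: int = 128) -> PhantomSpec:
    """Five-layer phantom with gently curved boundaries.

    Boundaries undulate sinusoidally (amplitude <= 3 px, 1-2 periods across
    the scan, randomized phase per seed); reflectivities span a 10:1 range so
    CNR has both strong and weak contrasts to work with.
    """
    rng = np.random.default_rng(seed)
    base_rows = np.linspace(0.22, 0.85, 5) * height
    cols = np.arange(width)
    boundaries = np.empty((5, width))
    # undulation amplitude capped so adjacent boundaries can never cross
    gap = base_rows[1] - base_rows[0]
    amp_cap = min(3.0, 0.25 * gap)
    for k, b in enumerate(base_rows):
        amp = rng.uniform(min(1.0, amp_cap), amp_cap) if amp_cap > 0 else 0.0
        freq = rng.uniform(1.0, 2.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        boundaries[k] = b + amp * np.sin(2.0 * np.pi * freq * cols / width + phase)
    reflectivities = np.array([0.9, 0.3, 0.7, 0.09, 0.5])
    return PhantomSpec(
        height=height,
        width=width,
        layer_boundaries=boundaries,
        layer_reflectivities=reflectivities,
        seed=seed,
    )


def generate_phantom(spec: PhantomSpec) -> PhantomScene:
    """Rasterize a spec into a clean image, label map and disjoint ROI masks."""
    H, W = spec.height, spec.width
    rows = np.arange(H)[:, None]
    # label 0 = background band, 1..n = layers
    labels = np.sum(rows >= spec.layer_boundaries[:, None, :], axis=0).astype(int)
    reflect = np.concatenate(([spec.background_reflectivity], spec.layer_reflectivities))
    clean = reflect[labels]

    n = spec.n_layers
    for j, (center, radius, refl) in enumerate(spec.inclusions):
        cy, cx = center
        yy, xx = np.ogrid[:H, :W]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        clean = np.where(disc, refl, clean)
        labels = np.where(disc, n + 1 + j, labels)

    er = spec.erosion_radius
    struct = np.ones((2 * er + 1, 2 * er + 1), dtype=bool)

    def _erode(mask: np.ndarray) -> np.ndarray:
        # border_value=1 so the image edge itself does not eat into the mask
        return binary_erosion(mask, structure=struct, border_value=1)

    background = _erode(labels == 0)
    regions = [_erode(labels == k + 1) for k in range(n)]
    for name, mask in [("background", background)] + [
        (f"layer {k}", m) for k, m in enumerate(regions)
    ]:
        if mask.sum() < _MIN_ROI_PIXELS:
            raise InvalidSpecError(
                f"{name} ROI has {int(mask.sum())} px after erosion; "
                f"need >= {_MIN_ROI_PIXELS} for stable metrics"
            )
    return PhantomScene(clean, background, regions, labels)


def apply_speckle(clean: np.ndarray, seed) -> np.ndarray:
    """Fully developed speckle: amplitude times |unit-power circular Gaussian|.

    The speckled intensity has unit mean (E[out^2] = clean^2 pixelwise).
    ``seed`` may be an int, a SeedSequence or a Generator.
    """
    clean = np.asarray(clean, dtype=float)
    if np.any(clean < 0):
        raise ValueError("apply_speckle requires a nonnegative amplitude image")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    u = (rng.standard_normal(clean.shape) + 1j * rng.standard_normal(clean.shape)) / np.sqrt(2.0)
    return clean * np.abs(u)


def simulate_acquisition(
    scene: PhantomScene, acq: AcquisitionModel, transform_mode: str = "2d"
) -> kspace.KSpaceMeasurement:
    """Forward-simulate a k-space acquisition of a phantom scene.

    Speckle (if enabled) multiplies the clean amplitude, the unitary forward
    transform maps it to k-space, and circular complex white Gaussian detector
    noise of variance ``speed_factor * base_noise_std**2`` per coefficient is
    added.  Speckle and detector noise draw from independent child streams of
    ``acq.seed``, so disabling one never perturbs the other.
    """
    ss = np.random.SeedSequence(acq.seed)
    speckle_seq, noise_seq = ss.spawn(2)
    img = apply_speckle(scene.clean_image, speckle_seq) if acq.speckle else scene.clean_image
    coeffs = kspace.forward_transform(img, mode=transform_mode)
    sigma = acq.noise_std
    noise_rng = np.random.default_rng(noise_seq)
    noise = (sigma / np.sqrt(2.0)) * (
        noise_rng.standard_normal(coeffs.shape) + 1j * noise_rng.standard_normal(coeffs.shape)
    )
    return kspace.KSpaceMeasurement(
        coeffs + noise,
        speed_factor=acq.speed_factor,
        base_noise_std=acq.base_noise_std,
        seed=acq.seed,
        transform_mode=transform_mode,
    )
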