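"""Modified James-Stein non-local regularization functional, weights and gradient.

The regularization functional is

    rho(f, sigma) = sum_x sum_{i in N(x)} w(x, i, sigma) * ||R(x) - R(i)||^2

where ``R(x)`` extracts a square patch centered at ``x``, ``N(x)`` is a square
search neighborhood around ``x``, and ``||.||`` is the Frobenius norm over
patch pixels.  The modified weight is

    w(x, i, sigma) = alpha(x, i)
                     * max(0, 1 - (m - 2) sigma^2 / ||r(x)||^2)
                     * exp(-||Rhat(x) - Rhat(i)||^2 / (2 sigma^2))

with ``alpha`` the self-exclusion indicator, ``r(x)`` the residual patch
(noisy image minus current estimate) at ``x``, and ``m`` the number of pixels
the residual norm runs over.  The middle term is a positive-part James-Stein
shrinkage factor: where the current estimate already explains the data
(small residual relative to the noise level ``sigma``) the non-local pull is
switched off, which protects already-converged structure from over-smoothing.
Dropping that factor gives the conventional non-local weight, kept here as a
baseline.

Weights are used unnormalized, exactly as the functional is written.  Patches
and neighborhoods are completed by symmetric reflection past the image border.
The per-pixel operations (``nl_weight`` etc.) are the readable reference
surface; ``compute_weights`` / ``rho`` / ``rho_gradient`` are the vectorized
forms the solver uses, organized as one pass per neighborhood offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = [
    "PatchConfig",
    "WeightField",
    "extract_patch",
    "alpha",
    "js_shrinkage_factor",
    "nl_weight",
    "conventional_nl_weight",
    "compute_weights",
    "rho",
    "rho_gradient",
]

_PAD_MODE = "symmetric"


@dataclass(frozen=True)
class PatchConfig:
    """Patch / search-neighborhood geometry.

    Defaults (9x9 patch inside a 21x21 neighborhood) are the operating point
    used for retinal B-scans; small odd sizes (3/5) are used for the
    brute-force test instances.
    """

    patch_size: int = 9
    neighborhood_size: int = 21
    boundary_mode: str = _PAD_MODE

    def __post_init__(self) -> None:
        if self.patch_size % 2 == 0 or self.neighborhood_size % 2 == 0:
            raise ValueError("patch_size and neighborhood_size must be odd")
        if self.patch_size < 1 or self.patch_size > self.neighborhood_size:
            raise ValueError("require 1 <= patch_size <= neighborhood_size")
        if self.boundary_mode != _PAD_MODE:
            raise ValueError("only symmetric reflection padding is supported")

    @property
    def patch_radius(self) -> int:
        return self.patch_size // 2

    @property
    def neighborhood_radius(self) -> int:
        return self.neighborhood_size // 2

    @property
    def n_patch_px(self) -> int:
        return self.patch_size**2

    @property
    def n_neigh_px(self) -> int:
        return self.neighborhood_size**2


@dataclass
class WeightField:
    """Non-local weights for every (center pixel, neighborhood offset) pair.

    ``weights[dy + Rn, dx + Rn, y, x]`` is w(x=(y,x), i=(y+dy, x+dx), sigma);
    the zero-offset slice is identically zero (self-exclusion).  ``is_zero``
    short-circuits the solver when the shrinkage factor gates everything off.
    """

    weights: np.ndarray  # (ns, ns, H, W)
    sigma: float
    cfg: PatchConfig
    mode: str = "js"
    is_zero: bool = False


def extract_patch(image: np.ndarray, center: tuple[int, int], cfg: PatchConfig) -> np.ndarray:
    """Patch of size ``patch_size`` centered at ``center``, reflection-padded."""
    image = np.asarray(image)
    y, x = center
    if not (0 <= y < image.shape[0] and 0 <= x < image.shape[1]):
        raise IndexError(f"center {center} outside image of shape {image.shape}")
    r = cfg.patch_radius
    padded = np.pad(image, r, mode=_PAD_MODE)
    return padded[y : y + cfg.patch_size, x : x + cfg.patch_size].copy()


def alpha(x: tuple[int, int], i: tuple[int, int]) -> int:
    """Self-exclusion indicator: 0 when the neighbor is the center pixel itself."""
    return 0 if tuple(x) == tuple(i) else 1


def js_shrinkage_factor(residual_sq_norm: float, sigma: float, n_size: int) -> float:
    """Positive-part James-Stein factor ``max(0, 1 - (n-2) sigma^2 / ||r||^2)``.

    Returns 0 for a zero residual: with no evidence that the estimate deviates
    from the data, the non-local pull is fully gated off.
    """
    if residual_sq_norm < 0:
        raise ValueError("residual_sq_norm must be nonnegative")
    if n_size < 3:
        raise ValueError("n_size must be at least 3")
    if residual_sq_norm == 0:
        return 0.0
    return max(0.0, 1.0 - (n_size - 2) * sigma**2 / residual_sq_norm)


def _patch_sq_dist(img: np.ndarray, x, i, cfg: PatchConfig) -> float:
    px = extract_patch(img, x, cfg)
    pi = extract_patch(img, i, cfg)
    return float(np.sum((px - pi) ** 2))


def nl_weight(
    current_estimate: np.ndarray,
    x: tuple[int, int],
    i: tuple[int, int],
    sigma: float,
    noisy_image: np.ndarray,
    cfg: PatchConfig,
    js_norm: str = "patch",
) -> float:
    """Modified James-Stein non-local weight for one (center, neighbor) pair.

    ``js_norm`` selects what the shrinkage count ``m`` refers to: the patch
    pixel count (default, dimensionally consistent with the residual patch
    norm) or the search-neighborhood pixel count.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a = alpha(x, i)
    if a == 0:
        return 0.0
    residual = np.asarray(noisy_image) - np.asarray(current_estimate)
    rsq = float(np.sum(extract_patch(residual, x, cfg) ** 2))
    m = cfg.n_patch_px if js_norm == "patch" else cfg.n_neigh_px
    shrink = js_shrinkage_factor(rsq, sigma, m)
    d2 = _patch_sq_dist(current_estimate, x, i, cfg)
    return a * shrink * float(np.exp(-d2 / (2.0 * sigma**2)))


def conventional_nl_weight(
    current_estimate: np.ndarray,
    x: tuple[int, int],
    i: tuple[int, int],
    sigma: float,
    cfg: PatchConfig,
) -> float:
    """Conventional non-local weight: the same Gaussian patch-similarity kernel
    without the James-Stein shrinkage factor."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    a = alpha(x, i)
    if a == 0:
        return 0.0
    d2 = _patch_sq_dist(current_estimate, x, i, cfg)
    return a * float(np.exp(-d2 / (2.0 * sigma**2)))


def _boxsum(arr: np.ndarray, size: int) -> np.ndarray:
    """Sum over a size x size window centered at each pixel (zero padding)."""
    return uniform_filter(arr, size=size, mode="constant", cval=0.0) * (size * size)


def compute_weights(
    current_estimate: np.ndarray,
    sigma: float,
    cfg: PatchConfig,
    noisy_image: np.ndarray | None = None,
    mode: str = "js",
    js_norm: str = "patch",
) -> WeightField:
    """Vectorized weight field over all center pixels and neighborhood offsets."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if mode not in ("js", "conventional"):
        raise ValueError(f"unknown weight mode {mode!r}")
    cur = np.asarray(current_estimate, dtype=float)
    H, W = cur.shape
    r, Rn = cfg.patch_radius, cfg.neighborhood_radius
    ns, ps = cfg.neighborhood_size, cfg.patch_size
    weights = np.zeros((ns, ns, H, W))

    if mode == "js":
        if noisy_image is None:
            raise ValueError("js mode needs the noisy image for the residual norm")
        res = np.asarray(noisy_image, dtype=float) - cur
        rp = np.pad(res, r, mode=_PAD_MODE)
        res2 = _boxsum(rp * rp, ps)[r : r + H, r : r + W]
        m = cfg.n_patch_px if js_norm == "patch" else cfg.n_neigh_px
        with np.errstate(divide="ignore"):
            ratio = np.divide(
                (m - 2) * sigma**2, res2, out=np.full((H, W), np.inf), where=res2 > 0
            )
        shrink = np.maximum(0.0, 1.0 - ratio)
        if not shrink.any():
            return WeightField(weights, float(sigma), cfg, mode, is_zero=True)
    else:
        shrink = 1.0

    pad = r + Rn
    g = np.pad(cur, pad, mode=_PAD_MODE)
    g0 = g[pad - r : pad + H + r, pad - r : pad + W + r]
    inv2s2 = 1.0 / (2.0 * sigma**2)
    for dy in range(-Rn, Rn + 1):
        for dx in range(-Rn, Rn + 1):
            if dy == 0 and dx == 0:
                continue
            gt = g[pad - r + dy : pad + H + r + dy, pad - r + dx : pad + W + r + dx]
            A = g0 - gt
            d2 = _boxsum(A * A, ps)[r : r + H, r : r + W]
            weights[dy + Rn, dx + Rn] = shrink * np.exp(-d2 * inv2s2)
    return WeightField(weights, float(sigma), cfg, mode)


def _check_field(field: WeightField, sigma: float) -> None:
    if not np.isclose(field.sigma, sigma, rtol=1e-12, atol=0):
        raise ValueError("weight field was computed at a different sigma")


def rho(image: np.ndarray, sigma: float, field: WeightField, cfg: PatchConfig) -> float:
    """Value of the non-local functional at ``image`` under frozen weights."""
    _check_field(field, sigma)
    if field.is_zero:
        return 0.0
    img = np.asarray(image, dtype=float)
    H, W = img.shape
    r, Rn = cfg.patch_radius, cfg.neighborhood_radius
    ps = cfg.patch_size
    pad = r + Rn
    g = np.pad(img, pad, mode=_PAD_MODE)
    g0 = g[pad - r : pad + H + r, pad - r : pad + W + r]
    total = 0.0
    for dy in range(-Rn, Rn + 1):
        for dx in range(-Rn, Rn + 1):
            if dy == 0 and dx == 0:
                continue
            Wt = field.weights[dy + Rn, dx + Rn]
            if not Wt.any():
                continue
            gt = g[pad - r + dy : pad + H + r + dy, pad - r + dx : pad + W + r + dx]
            A = g0 - gt
            D = _boxsum(A * A, ps)[r : r + H, r : r + W]
            total += float(np.sum(Wt * D))
    return total


@lru_cache(maxsize=8)
def _reflect_fold_index(shape: tuple[int, int], pad: int) -> np.ndarray:
    """Flat interior index of every pixel of the symmetric-padded grid."""
    H, W = shape
    idx = np.arange(H * W).reshape(H, W)
    return np.pad(idx, pad, mode=_PAD_MODE).ravel()


def rho_gradient(
    image: np.ndarray, sigma: float, field: WeightField, cfg: PatchConfig
) -> np.ndarray:
    """Gradient of ``rho`` with respect to the image, weights frozen.

    The functional is an exact quadratic form in the image once the weights
    are frozen; contributions that land on reflection-padded pixels are folded
    back onto their interior sources so central finite differences of ``rho``
    match the returned gradient.
    """
    _check_field(field, sigma)
    img = np.asarray(image, dtype=float)
    H, W = img.shape
    if field.is_zero:
        return np.zeros((H, W))
    r, Rn = cfg.patch_radius, cfg.neighborhood_radius
    ps = cfg.patch_size
    pad = r + Rn
    g = np.pad(img, pad, mode=_PAD_MODE)
    g0 = g[pad - r : pad + H + r, pad - r : pad + W + r]
    gradpad = np.zeros_like(g)
    emb = np.zeros((H + 2 * r, W + 2 * r))
    for dy in range(-Rn, Rn + 1):
        for dx in range(-Rn, Rn + 1):
            if dy == 0 and dx == 0:
                continue
            Wt = field.weights[dy + Rn, dx + Rn]
            if not Wt.any():
                continue
            gt = g[pad - r + dy : pad + H + r + dy, pad - r + dx : pad + W + r + dx]
            A = g0 - gt
            emb[r : r + H, r : r + W] = Wt
            C = _boxsum(emb, ps)
            B = 2.0 * A * C
            gradpad[pad - r : pad + H + r, pad - r : pad + W + r] += B
            gradpad[
                pad - r + dy : pad + H + r + dy, pad - r + dx : pad + W + r + dx
            ] -= B
    flat = _reflect_fold_index((H, W), pad)
    return np.bincount(flat, weights=gradpad.ravel(), minlength=H * W).reshape(H, W)
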