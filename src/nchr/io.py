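"""File I/O: grayscale images, 0/255 masks, HDF5 k-space/scene containers, YAML config.

All writes are atomic (write to a temporary file in the same directory, then
rename), so an interrupted run never leaves a truncated output behind.
Images are 8- or 16-bit grayscale TIFF/PNG and are mapped to [0, 1] floats on
read; k-space measurements and phantom scenes live in one HDF5 container with
``kspace_real`` / ``kspace_imag`` datasets and scalar attributes.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import tifffile
import yaml

from .errors import MalformedContainerError, UnsupportedFormatError
from .kspace import KSpaceMeasurement
from .phantom import PhantomScene

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "read_kspace",
    "write_kspace",
    "read_scene",
    "write_scene",
    "load_yaml_config",
    "atomic_write",
]

_DEPTH_DTYPES = {8: np.uint8, 16: np.uint16}


def atomic_write(path, writer) -> None:
    """Call ``writer(tmp_path)`` then atomically rename onto ``path``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix + ".tmp")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _load_raw(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    if path.suffix.lower() == ".png":
        return iio.imread(path)
    raise UnsupportedFormatError(f"unsupported image extension {path.suffix!r}")


def read_image(path) -> np.ndarray:
    """Load an 8/16-bit grayscale TIFF/PNG, scaled to [0, 1] floats."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = _load_raw(path)
    if arr.ndim != 2:
        raise UnsupportedFormatError(
            f"{path.name}: expected a single grayscale channel, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise UnsupportedFormatError(
            f"{path.name}: unsupported dtype {arr.dtype}, need 8- or 16-bit grayscale"
        )
    return arr.astype(float) / (2**depth - 1)


def write_image(path, image: np.ndarray, depth: int = 16, stretch: bool = False) -> None:
    """Write an image as grayscale TIFF/PNG at the given bit depth.

    With ``stretch`` the image is min-max scaled to the full range and the
    scaling constants are stored in the TIFF description (JSON); otherwise
    values are assumed to lie in [0, 1] and are clipped before quantization,
    so write/read round-trips are exact to one quantization step.
    """
    if depth not in _DEPTH_DTYPES:
        raise UnsupportedFormatError(f"unsupported bit depth {depth}")
    path = Path(path)
    img = np.asarray(image, dtype=float)
    meta = None
    if stretch:
        lo, hi = float(img.min()), float(img.max())
        scale = hi - lo if hi > lo else 1.0
        img = (img - lo) / scale
        meta = json.dumps({"min": lo, "max": hi})
    maxval = 2**depth - 1
    quant = np.clip(np.round(img * maxval), 0, maxval).astype(_DEPTH_DTYPES[depth])

    def _write(tmp: Path) -> None:
        if path.suffix.lower() in (".tif", ".tiff"):
            tifffile.imwrite(tmp, quant, description=meta)
        elif path.suffix.lower() == ".png":
            iio.imwrite(tmp, quant, extension=".png")
        else:
            raise UnsupportedFormatError(f"unsupported image extension {path.suffix!r}")

    atomic_write(path, _write)


def read_mask(path) -> np.ndarray:
    """Load a 0/255 8-bit PNG/TIFF mask as booleans."""
    arr = _load_raw(Path(path))
    if arr.ndim != 2:
        raise UnsupportedFormatError("masks must be single-channel")
    return arr > 0


def write_mask(path, mask: np.ndarray) -> None:
    write_image(path, np.asarray(mask, dtype=float), depth=8)


def write_kspace(path, measurement: KSpaceMeasurement) -> None:
    """Store a measurement in an HDF5 container (datasets kspace_real/imag)."""

    def _write(tmp: Path) -> None:
        with h5py.File(tmp, "w") as h5:
            c = measurement.coefficients
            h5.create_dataset("kspace_real", data=c.real, track_times=False)
            h5.create_dataset("kspace_imag", data=c.imag, track_times=False)
            _write_attrs(h5, measurement)

    atomic_write(path, _write)


def _write_attrs(h5, measurement: KSpaceMeasurement) -> None:
    if measurement.delta is not None:
        h5.attrs["delta"] = float(measurement.delta)
    h5.attrs["speed_factor"] = float(measurement.speed_factor)
    if measurement.base_noise_std is not None:
        h5.attrs["base_noise_std"] = float(measurement.base_noise_std)
    if measurement.seed is not None:
        h5.attrs["seed"] = int(measurement.seed)
    h5.attrs["transform_mode"] = measurement.transform_mode


def read_kspace(path) -> KSpaceMeasurement:
    """Load a measurement; delta stays unset if the container carries none."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as h5:
        for name in ("kspace_real", "kspace_imag"):
            if name not in h5:
                raise MalformedContainerError(f"{path.name}: missing dataset {name!r}")
        re, im = h5["kspace_real"][()], h5["kspace_imag"][()]
        if re.shape != im.shape:
            raise MalformedContainerError(
                f"{path.name}: kspace_real {re.shape} vs kspace_imag {im.shape}"
            )
        attrs = dict(h5.attrs)
    return KSpaceMeasurement(
        re + 1j * im,
        delta=float(attrs["delta"]) if "delta" in attrs else None,
        speed_factor=float(attrs.get("speed_factor", 1.0)),
        base_noise_std=(
            float(attrs["base_noise_std"]) if "base_noise_std" in attrs else None
        ),
        seed=int(attrs["seed"]) if "seed" in attrs else None,
        transform_mode=str(attrs.get("transform_mode", "2d")),
    )


def write_scene(path, scene: PhantomScene, measurement: KSpaceMeasurement | None = None) -> None:
    """Store a phantom scene (and optionally its measurement) in one container."""

    def _write(tmp: Path) -> None:
        with h5py.File(tmp, "w") as h5:
            h5.create_dataset("clean", data=scene.clean_image, track_times=False)
            h5.create_dataset(
                "mask_background",
                data=scene.background_mask.astype(np.uint8),
                track_times=False,
            )
            for r, mask in enumerate(scene.region_masks):
                h5.create_dataset(
                    f"mask_roi_{r}", data=mask.astype(np.uint8), track_times=False
                )
            h5.create_dataset("truth_labels", data=scene.truth_labels, track_times=False)
            if measurement is not None:
                c = measurement.coefficients
                h5.create_dataset("kspace_real", data=c.real, track_times=False)
                h5.create_dataset("kspace_imag", data=c.imag, track_times=False)
                _write_attrs(h5, measurement)

    atomic_write(path, _write)


def read_scene(path):
    """Load a scene container; returns (PhantomScene, KSpaceMeasurement | None)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as h5:
        for name in ("clean", "mask_background"):
            if name not in h5:
                raise MalformedContainerError(f"{path.name}: missing dataset {name!r}")
        clean = h5["clean"][()]
        background = h5["mask_background"][()].astype(bool)
        regions = []
        r = 0
        while f"mask_roi_{r}" in h5:
            regions.append(h5[f"mask_roi_{r}"][()].astype(bool))
            r += 1
        labels = h5["truth_labels"][()] if "truth_labels" in h5 else np.zeros_like(clean, dtype=int)
        scene = PhantomScene(clean, background, regions, labels)
        measurement = None
        if "kspace_real" in h5 and "kspace_imag" in h5:
            attrs = dict(h5.attrs)
            measurement = KSpaceMeasurement(
                h5["kspace_real"][()] + 1j * h5["kspace_imag"][()],
                delta=float(attrs["delta"]) if "delta" in attrs else None,
                speed_factor=float(attrs.get("speed_factor", 1.0)),
                base_noise_std=(
                    float(attrs["base_noise_std"]) if "base_noise_std" in attrs else None
                ),
                seed=int(attrs["seed"]) if "seed" in attrs else None,
                transform_mode=str(attrs.get("transform_mode", "2d")),
            )
    return scene, measurement


def load_yaml_config(path) -> dict:
    """Load a flat YAML mapping of CLI option names to values."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise UnsupportedFormatError("config file must contain a mapping")
    return data
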