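"""Grayscale image reading/writing and run configuration.

Images are normalised to [0, 1] on read (dividing by the bit-depth
maximum) and quantised back on write with round-half-away-from-zero, so a
read/write round trip at the native bit depth is lossless.  Color inputs
are collapsed to luminance with a logged warning; the fusion pipeline is
grayscale by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml

logger = logging.getLogger("medfuse")

__all__ = ["RunConfig", "read_image", "write_image", "load_config"]

_SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff"}
_VOLUME_SUFFIXES = (".nii", ".nii.gz")

# ITU-R BT.601 luminance weights for color -> grayscale collapse
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class RunConfig:
    """Flat key-value run settings; file values are overridden by CLI flags."""

    backend: str = "atrous"
    depth: int = 3
    window: int = 3          # window side in pixels, odd
    tie: str = "prefer_first"
    literal_lowpass: bool = False
    metrics: bool = False
    log_level: str = "WARNING"
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        cfg = load_config(path)
        for key, value in overrides.items():
            if value is not None:
                setattr(cfg, key, value)
        return cfg


def load_config(path: str | Path) -> RunConfig:
    """Load a plain-text key-value (YAML mapping) configuration file.

    Unknown keys are rejected by name rather than silently ignored.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"configuration file {path} must be a flat key-value mapping")
    known = {f.name for f in fields(RunConfig)}
    for key in data:
        if key not in known:
            raise ValueError(
                f"unknown configuration key {key!r} in {path}; "
                f"known keys: {', '.join(sorted(known))}"
            )
    return RunConfig(**data)


def _is_volume(path: Path) -> bool:
    name = path.name.lower()
    return any(name.endswith(s) for s in _VOLUME_SUFFIXES)


def read_image(path: str | Path, slice_index: int | None = None) -> tuple[np.ndarray, int]:
    """Read an 8- or 16-bit grayscale PNG/TIFF as a [0, 1] float grid.

    Returns the normalised array and the source bit depth (8 or 16).
    NIfTI volumes are accepted when nibabel is installed and an explicit
    ``slice_index`` (axial slice) is given; they are min-max normalised
    and reported as 16-bit.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")

    if _is_volume(path):
        return _read_volume_slice(path, slice_index)

    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(
            f"unsupported image format {path.suffix!r}; expected PNG or TIFF"
        )
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        logger.warning("color image %s collapsed to luminance", path)
        arr = (arr.astype(float) @ _LUMA)
        bit_depth = 8
        return np.clip(arr / 255.0, 0.0, 1.0), bit_depth
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0, 8
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0, 16
    raise ValueError(
        f"unsupported pixel type {arr.dtype} in {path}; "
        "expected 8- or 16-bit grayscale"
    )


def _read_volume_slice(path: Path, slice_index: int | None) -> tuple[np.ndarray, int]:
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover - depends on optional extra
        raise ValueError(
            f"{path} is a volume but the optional volume reader (nibabel) "
            "is not installed"
        ) from exc
    if slice_index is None:
        raise ValueError(f"reading the volume {path} requires an explicit slice index")
    data = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume in {path}, got shape {data.shape}")
    if not 0 <= slice_index < data.shape[2]:
        raise ValueError(
            f"slice index {slice_index} out of range for volume with "
            f"{data.shape[2]} slices"
        )
    sl = data[:, :, slice_index]
    lo, hi = sl.min(), sl.max()
    if hi > lo:
        sl = (sl - lo) / (hi - lo)
    else:
        sl = np.zeros_like(sl)
    return sl, 16


def write_image(grid: np.ndarray, path: str | Path, bit_depth: int = 8) -> None:
    """Quantise a [0, 1] grid to the target bit depth and write PNG/TIFF.

    Quantisation rounds half away from zero; out-of-range values are
    clipped with a logged warning.
    """
    path = Path(path)
    if path.suffix.lower() not in _SUPPORTED_SUFFIXES:
        raise ValueError(
            f"unsupported output format {path.suffix!r}; expected PNG or TIFF"
        )
    if bit_depth not in (8, 16):
        raise ValueError(f"bit_depth must be 8 or 16, got {bit_depth}")
    arr = np.asarray(grid, dtype=float)
    if arr.min() < 0.0 or arr.max() > 1.0:
        logger.warning(
            "values outside [0, 1] (range [%g, %g]) clipped when writing %s",
            arr.min(), arr.max(), path,
        )
        arr = np.clip(arr, 0.0, 1.0)
    maxval = 2**bit_depth - 1
    quantised = np.floor(arr * maxval + 0.5)  # half away from zero for x >= 0
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    iio.imwrite(path, quantised.astype(dtype))
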