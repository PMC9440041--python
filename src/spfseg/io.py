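"""Image and mask I/O: PNG/TIFF in, masks and float bias fields out.

Images are loaded as 2-D float fields rescaled to [0, 1] by the dtype's
full range; RGB inputs are converted to luminance first.  Masks are
written as 8-bit PNG with foreground 255 and round-trip losslessly; bias
fields are written as 32-bit float TIFF.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["ImageReadError", "LoadedImage", "read_image", "read_mask", "write_mask", "write_bias"]

_LUMA = np.array([0.2989, 0.5870, 0.1140])


class ImageReadError(IOError):
    """Unreadable or unsupported image file."""


@dataclass(frozen=True)
class LoadedImage:
    values: np.ndarray  # float64 in [0, 1]
    bit_depth: int
    path: str


def read_image(path: str | Path) -> LoadedImage:
    """Load a PNG/TIFF as a [0, 1] float field (RGB -> luminance)."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend specific
        raise ImageReadError(f"cannot read image {path}: {exc}") from exc
    dtype = np.asarray(arr).dtype
    if arr.ndim == 3:
        if arr.shape[-1] in (3, 4):
            arr = arr[..., :3] @ _LUMA
        else:
            raise ImageReadError(
                f"{path}: expected single-channel or RGB, got shape {arr.shape}"
            )
    elif arr.ndim != 2:
        raise ImageReadError(f"{path}: expected a 2-D image, got shape {arr.shape}")

    if dtype == np.uint8:
        depth, full = 8, 255.0
    elif dtype == np.uint16:
        depth, full = 16, 65535.0
    elif np.issubdtype(dtype, np.floating):
        depth, full = 32, 1.0
    else:
        raise ImageReadError(f"{path}: unsupported dtype {dtype}")
    values = np.asarray(arr, dtype=float) / full
    return LoadedImage(values=values, bit_depth=depth, path=str(path))


def read_mask(path: str | Path) -> np.ndarray:
    """Load a binary mask (any nonzero pixel is foreground)."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return np.asarray(arr) > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as 8-bit PNG (foreground 255)."""
    path = Path(path)
    out = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    iio.imwrite(path, out)


def write_bias(bias: np.ndarray, path: str | Path) -> None:
    """Write a bias field as 32-bit float TIFF."""
    tifffile.imwrite(Path(path), np.asarray(bias, dtype=np.float32))


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float field as 8-bit PNG."""
    out = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), np.round(out * 255).astype(np.uint8))
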