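"""Image and table I/O helpers.

Images: 16-bit grayscale TIFF for intensities, 8- or 16-bit PNG for masks
(0 background; single-nucleus masks use 255, cohort masks store the label).
Tables are TSV with header. Writes are atomic (temp file + rename) so a
crashed run never leaves a partial output behind.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile


def atomic_write(path: str | Path, write_fn) -> None:
    """Call ``write_fn(tmp_path)`` then rename tmp over ``path``."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    os.close(fd)
    try:
        write_fn(tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_intensity_tiff(path: str | Path, image: np.ndarray) -> None:
    """Write a float intensity image as 16-bit grayscale TIFF (rounded, clipped)."""
    arr = np.clip(np.rint(image), 0, 65535).astype(np.uint16)
    atomic_write(path, lambda tmp: tifffile.imwrite(tmp, arr))


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale TIFF/PNG as float64."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:  # collapse RGB(A) masks/images
        arr = arr[..., 0]
    return arr.astype(float)


def write_mask_png(path: str | Path, mask: np.ndarray) -> None:
    """Binary mask → 0/255 uint8 PNG; labeled mask → uint8/uint16 PNG of labels."""
    mask = np.asarray(mask)
    if mask.dtype == bool:
        arr = (mask.astype(np.uint8)) * 255
    else:
        vmax = int(mask.max()) if mask.size else 0
        arr = mask.astype(np.uint16 if vmax > 255 else np.uint8)
    atomic_write(path, lambda tmp: iio.imwrite(tmp, arr, extension=".png"))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask image as integer labels (nonzero = nucleus)."""
    arr = read_image(path)
    return arr.astype(np.int64)


def write_tsv(path: str | Path, df: pd.DataFrame, **kwargs) -> None:
    atomic_write(path, lambda tmp: df.to_csv(tmp, sep="\t", index=False, **kwargs))


def read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
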