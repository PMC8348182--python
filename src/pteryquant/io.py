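"""Image, manifest, and configuration I/O.

Images are 8-bit RGB TIFF or PNG.  A manifest is a CSV with one row per
image: ``path, animal, group, day, eye`` (path relative to the manifest's
directory unless absolute).  Run configuration is a flat TOML file.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

MANIFEST_COLUMNS = ["path", "animal", "group", "day", "eye"]


def read_image(path: str | Path) -> np.ndarray:
    """Read an image as an (H, W, 3) uint8 RGB array, dropping any alpha."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    if arr.dtype != np.uint8:
        arr = np.clip(arr, 0, 255).astype(np.uint8)
    return arr


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write an (H, W, 3) uint8 RGB array as TIFF or PNG by extension."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, pixels)
    else:
        iio.imwrite(path, pixels)


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit black/white PNG."""
    write_image(path, (np.asarray(mask, dtype=np.uint8) * 255))


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a manifest CSV, resolving image paths relative to its directory."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"animal": str, "group": str, "eye": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest is missing columns: {missing}")
    df["day"] = df["day"].astype(int)
    base = path.parent
    df["path"] = [str(p) if Path(p).is_absolute() else str(base / p) for p in df["path"]]
    return df


def write_manifest(path: str | Path, rows: pd.DataFrame) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    rows[MANIFEST_COLUMNS].to_csv(path, index=False)


def write_table(path: str | Path, table: pd.DataFrame) -> None:
    """Write a result table deterministically (fixed float format)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, float_format="%.8g")
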