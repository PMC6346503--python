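"""PNG and manifest I/O.

Images are single-channel 8-bit PNGs scaled to [0, 1] on read; masks are
single-channel PNGs with 0 = background and 255 = lesion.  A dataset
manifest is a CSV with columns image, mask, label (paths relative to the
manifest's directory; labels are the grade strings "3".."5").
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

MANIFEST_COLUMNS = ("image", "mask", "label")

__all__ = ["read_image", "write_image", "read_mask", "write_mask",
           "load_manifest", "MANIFEST_COLUMNS"]


def read_image(path) -> np.ndarray:
    """Read a grayscale PNG as float in [0, 1]."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=np.float64)
    return arr / 255.0


def write_image(path, img: np.ndarray) -> None:
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    Image.fromarray((arr * 255.0).round().astype(np.uint8), mode="L").save(path)


def read_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"))
    return arr >= 128


def write_mask(path, mask: np.ndarray) -> None:
    arr = np.where(np.asarray(mask, dtype=bool), 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_manifest(path) -> pd.DataFrame:
    """Load a manifest CSV, resolving image/mask paths against its directory."""
    path = Path(path)
    frame = pd.read_csv(path, dtype=str)
    missing = set(MANIFEST_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns: {sorted(missing)}")
    root = path.parent
    frame["image"] = [str(root / p) for p in frame["image"]]
    frame["mask"] = [str(root / p) for p in frame["mask"]]
    return frame
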