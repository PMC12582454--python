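"""Dataset reading and input normalization.

Datasets are directory trees with one sub-directory per class (PNG/JPEG/
TIFF); class names are the directory names in lexicographic order.  Images
are resized bilinearly to the model's input side (300 by default), scaled to
[0, 1] and standardized per channel with fixed statistics recorded in
:mod:`rntnet.config`.
"""
from __future__ import annotations

from pathlib import Path
from typing import List, Tuple

import numpy as np
from PIL import Image

from .config import IMAGE_SIZE, NORM_MEAN, NORM_STD

__all__ = ["load_image_folder", "resize_batch", "standardize"]

_EXTS = {".png", ".jpg", ".jpeg", ".tif", ".tiff"}


def load_image_folder(root, image_size: int = IMAGE_SIZE
                      ) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """Read a class-per-folder tree -> (X uint8 NHWC, y labels, class names)."""
    root = Path(root)
    classes = sorted(d.name for d in root.iterdir() if d.is_dir())
    if not classes:
        raise FileNotFoundError(f"no class sub-directories under {root}")
    xs, ys = [], []
    for label, cls in enumerate(classes):
        files = sorted(p for p in (root / cls).iterdir()
                       if p.suffix.lower() in _EXTS)
        if not files:
            raise ValueError(f"class directory {cls!r} contains no images")
        for p in files:
            with Image.open(p) as im:
                im = im.convert("RGB").resize((image_size, image_size),
                                              Image.BILINEAR)
                xs.append(np.asarray(im, np.uint8))
            ys.append(label)
    return np.stack(xs), np.asarray(ys, np.int64), classes


def resize_batch(x: np.ndarray, image_size: int) -> np.ndarray:
    """Bilinearly resize a (n, h, w, 3) uint8 batch to the model side."""
    if x.shape[1] == image_size and x.shape[2] == image_size:
        return x
    out = np.empty((len(x), image_size, image_size, 3), np.uint8)
    for i, img in enumerate(x):
        out[i] = np.asarray(Image.fromarray(img).resize(
            (image_size, image_size), Image.BILINEAR))
    return out


def standardize(x: np.ndarray) -> np.ndarray:
    """(n, h, w, 3) uint8/float [0, 255] -> standardized float32 NCHW."""
    x = np.asarray(x, np.float32) / 255.0
    x = (x - np.asarray(NORM_MEAN, np.float32)) / np.asarray(NORM_STD, np.float32)
    return np.ascontiguousarray(x.transpose(0, 3, 1, 2))
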