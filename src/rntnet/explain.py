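"""Grad-CAM: gradient-weighted class activation maps.

The class score's gradient is taken at the backbone's final stage
activation (the last convolutional feature map); channel weights are the
spatially averaged gradients, and the heatmap is the ReLU of the weighted
channel sum, bilinearly upsampled to the input size and max-normalized.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .data import standardize
from .model import RNTNet

__all__ = ["Heatmap", "grad_cam", "save_heatmap_pngs"]


@dataclass
class Heatmap:
    """Non-negative map in [0, 1] over the input pixels."""
    values: np.ndarray
    target_class: int
    source_layer: str = "backbone.stage4"
    degenerate: bool = False  # all-zero weighted sum: normalization skipped


def grad_cam(model: RNTNet, image: np.ndarray, target_class: int) -> Heatmap:
    """Heatmap of the spatial evidence for ``target_class``.

    ``image`` is one (h, w, 3) uint8 (or [0, 255] float) image at the
    model's input size.  The map is invariant to positive rescaling of the
    class score by construction (max-normalization).
    """
    if model.backbone is None:
        raise ValueError(
            "Grad-CAM needs a convolutional source layer with spatial extent; "
            f"the {model.arm!r} arm has no backbone")
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected one (h, w, 3) image, got {image.shape}")
    n_classes = model.cfg.head.n_classes
    if not 0 <= int(target_class) < n_classes:
        raise ValueError(f"target class {target_class} outside [0, {n_classes})")
    model.eval()
    x = standardize(image[None])
    logits = model.forward(x, retain_feature_grad=True)
    seed = np.zeros_like(logits.numpy())
    seed[0, int(target_class)] = 1.0
    logits.backward(seed)
    act = model.backbone.last_feature_map
    grads = act.grad  # (1, C, h, w)
    weights = grads.mean(axis=(2, 3), keepdims=True)
    cam = np.maximum((weights * act.numpy()).sum(axis=1)[0], 0.0)
    size = image.shape[0], image.shape[1]
    cam_img = Image.fromarray(cam.astype(np.float32), mode="F")
    cam_up = np.asarray(cam_img.resize((size[1], size[0]), Image.BILINEAR))
    peak = cam_up.max()
    if peak <= 0:
        return Heatmap(values=np.zeros(size, np.float32),
                       target_class=int(target_class), degenerate=True)
    return Heatmap(values=(cam_up / peak).astype(np.float32),
                   target_class=int(target_class))


def save_heatmap_pngs(heatmap: Heatmap, image: np.ndarray, out_dir,
                      stem: str = "gradcam", alpha: float = 0.4) -> dict:
    """Write the pure heatmap and a jet-colormap overlay as PNGs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.cm as cm

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    jet = cm.get_cmap("jet")(heatmap.values)[..., :3]
    heat_u8 = (255 * jet).astype(np.uint8)
    heat_path = out / f"{stem}_heatmap.png"
    Image.fromarray(heat_u8).save(heat_path)
    base = np.asarray(image, np.float32)
    overlay = np.clip((1 - alpha) * base + alpha * 255 * jet, 0, 255).astype(np.uint8)
    overlay_path = out / f"{stem}_overlay.png"
    Image.fromarray(overlay).save(overlay_path)
    return {"heatmap": heat_path, "overlay": overlay_path}
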