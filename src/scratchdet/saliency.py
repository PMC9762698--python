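"""Input-gradient saliency maps for the scratch classifier.

The saliency of a pixel is the gradient of the target class score with
respect to that pixel, with negative gradients zeroed and the remainder
rescaled to [0, 1] (by default over the whole window; optionally per
frame).  Overlays band the values: below 0.1 fully transparent, [0.1,
0.6) a light-to-dark blue ramp, 0.6 and above the darkest blue at
maximal opacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import CRNNModel
from .windows import WindowSample

__all__ = ["SaliencyMap", "compute_saliency", "render_heatmap"]

_LIGHT_BLUE = np.array([173, 216, 230], dtype=np.float64)
_DARK_BLUE = np.array([0, 0, 139], dtype=np.float64)


@dataclass(frozen=True)
class SaliencyMap:
    """Per-frame non-negative saliency values in [0, 1]."""

    values: np.ndarray = field(repr=False)  # (N, H, W)
    target_class: int = 1

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("saliency values must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    def middle_frame(self) -> np.ndarray:
        return self.values[(self.values.shape[0] - 1) // 2]


def _rescale(v: np.ndarray) -> np.ndarray:
    vmax, vmin = float(v.max()), float(v.min())
    if vmax == vmin:
        return np.zeros_like(v)
    return (v - vmin) / (vmax - vmin)


def compute_saliency(
    model: CRNNModel,
    window: WindowSample,
    target_class: int = 1,
    per_frame_rescale: bool = False,
) -> SaliencyMap:
    """Gradient of the target-class score w.r.t. every input pixel.

    Negative gradients are clipped to zero; the positive part is rescaled
    to [0, 1] over the whole window (or per frame).  The model is run in
    evaluation mode; an all-zero gradient stays all-zero.
    """
    model.eval()
    x = window.frames[None].astype(np.float32)
    logits = model.forward(x)
    dlogits = np.zeros_like(logits)
    dlogits[0, target_class] = 1.0
    grad = model.backward(dlogits)[0]  # (N, H, W)
    pos = np.maximum(grad, 0.0).astype(np.float64)
    if per_frame_rescale:
        values = np.stack([_rescale(f) for f in pos])
    else:
        values = _rescale(pos)
    return SaliencyMap(values, target_class)


def render_heatmap(values: np.ndarray, frame: np.ndarray) -> np.ndarray:
    """Composite a banded blue heatmap over a grayscale frame.

    ``values``: 2-D saliency in [0, 1]; ``frame``: 2-D intensities in
    [0, 1].  Banding (half-open): v < 0.1 transparent; 0.1 <= v < 0.6 a
    light-to-dark blue ramp with proportional opacity; v >= 0.6 dark blue
    at maximal opacity.  Returns an (H, W, 3) uint8 image.
    """
    values = np.asarray(values, dtype=np.float64)
    frame = np.asarray(frame, dtype=np.float64)
    if values.shape != frame.shape:
        raise ValueError(
            f"geometry mismatch: saliency {values.shape} vs frame {frame.shape}"
        )
    base = np.repeat(np.clip(frame, 0, 1)[:, :, None] * 255.0, 3, axis=2)
    ramp = np.clip((values - 0.1) / 0.5, 0.0, 1.0)  # 0 at v=0.1, 1 at v=0.6
    color = _LIGHT_BLUE[None, None, :] + ramp[:, :, None] * (
        _DARK_BLUE - _LIGHT_BLUE
    )[None, None, :]
    alpha = np.where(values < 0.1, 0.0, 0.25 + 0.75 * ramp)[:, :, None]
    out = base * (1.0 - alpha) + color * alpha
    return np.round(out).astype(np.uint8)
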