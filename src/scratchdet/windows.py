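"""N-frame window construction, majority labeling, and augmentation.

The classifier never sees single frames: its input unit is a window of N
consecutive frames.  For training, windows are sampled along the video
with a random stride of 4-10 frames and labeled scratching (1) when a
strict majority of their frames are scratching frames; for inference the
stride is 1 so each frame can receive a prediction via the middle-frame
rule.  Augmentation draws one square crop and one flip decision per axis
per window and applies them identically to all N frames, preserving the
temporal geometry the recurrent part relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import FrameLabelTrack
from .nn.functional import resize_bilinear_batch

__all__ = [
    "WindowSample",
    "AugmentationSpec",
    "label_window",
    "make_training_windows",
    "make_inference_windows",
    "augment_window",
]


@dataclass
class WindowSample:
    """N consecutive frames plus (for training) a binary class label."""

    video_id: str
    start_frame: int
    frames: np.ndarray = field(repr=False)  # (N, H, W)
    label: int | None = None

    @property
    def n(self) -> int:
        return int(self.frames.shape[0])


@dataclass(frozen=True)
class AugmentationSpec:
    """One-draw-per-window random crop / flip / resize pipeline.

    Full-scale defaults follow the recording pipeline (300x300 frames,
    crop 288-300, final 256); :meth:`desk_scale` scales the crop range
    proportionally for 64x64 synthetic frames while keeping the final
    size at 64 so the compact backbone sees the generator's native size.
    """

    resize_initial: tuple[int, int] = (300, 300)
    crop_min: int = 288
    crop_max: int = 300
    flip_prob: float = 0.5
    resize_final: tuple[int, int] = (256, 256)

    def __post_init__(self):
        if not (1 <= self.crop_min <= self.crop_max <= min(self.resize_initial)):
            raise ValueError(
                f"need 1 <= crop_min <= crop_max <= {min(self.resize_initial)}, "
                f"got [{self.crop_min}, {self.crop_max}]"
            )

    @classmethod
    def desk_scale(cls) -> "AugmentationSpec":
        return cls(
            resize_initial=(64, 64), crop_min=61, crop_max=64,
            flip_prob=0.5, resize_final=(64, 64),
        )


def label_window(track: FrameLabelTrack, start: int, n: int) -> int:
    """Majority label: 1 iff strictly more than N/2 frames are scratching.

    The tie at exactly N/2 (possible only for even N) labels 0; the
    comparison ``2 * count > N`` is exact in integers.
    """
    if n < 1:
        raise ValueError("window length must be >= 1")
    if start < 0 or start + n > track.n_frames:
        raise ValueError(
            f"window [{start}, {start + n}) outside track of "
            f"{track.n_frames} frames"
        )
    count = int(track.labels[start : start + n].sum())
    return 1 if 2 * count > n else 0


def make_training_windows(
    track: FrameLabelTrack,
    frames: np.ndarray,
    n: int,
    stride_min: int = 4,
    stride_max: int = 10,
    seed: int = 0,
) -> list[WindowSample]:
    """Sample labeled training windows along the video.

    Starts at frame 0 and advances by a stride drawn uniformly from
    [stride_min, stride_max] (set them equal for a fixed stride);
    generation stops when a window would overrun the video.  The frame
    arrays are views into ``frames``, not copies.
    """
    if track.n_frames < n:
        raise ValueError(f"video has {track.n_frames} frames < window length {n}")
    if not 1 <= stride_min <= stride_max:
        raise ValueError("need 1 <= stride_min <= stride_max")
    if frames.shape[0] != track.n_frames:
        raise ValueError("frames and label track disagree on n_frames")
    rng = np.random.default_rng(seed)
    samples = []
    start = 0
    while start + n <= track.n_frames:
        samples.append(
            WindowSample(
                track.video_id,
                start,
                frames[start : start + n],
                label_window(track, start, n),
            )
        )
        start += int(rng.integers(stride_min, stride_max + 1))
    return samples


def make_inference_windows(n_frames: int, n: int) -> np.ndarray:
    """Stride-1 window starts 0 .. n_frames - N (exactly n_frames - N + 1)."""
    if n < 1:
        raise ValueError("window length must be >= 1")
    if n_frames < n:
        raise ValueError(f"video has {n_frames} frames < window length {n}")
    return np.arange(n_frames - n + 1)


def augment_window(
    sample: WindowSample,
    spec: AugmentationSpec,
    rng: np.random.Generator,
) -> WindowSample:
    """Apply one random crop + flips + final resize to all frames of a window.

    The crop side is uniform over [crop_min, crop_max], the top-left corner
    uniform over valid positions, and each flip axis is an independent
    Bernoulli(flip_prob) draw — all drawn once per window so every frame
    undergoes the same geometric transform.
    """
    frames = sample.frames
    h, w = frames.shape[1:]
    if (h, w) != tuple(spec.resize_initial):
        frames = resize_bilinear_batch(frames, *spec.resize_initial)
        h, w = spec.resize_initial
    side = int(rng.integers(spec.crop_min, spec.crop_max + 1))
    top = int(rng.integers(0, h - side + 1))
    left = int(rng.integers(0, w - side + 1))
    out = frames[:, top : top + side, left : left + side]
    if rng.random() < spec.flip_prob:
        out = out[:, :, ::-1]
    if rng.random() < spec.flip_prob:
        out = out[:, ::-1, :]
    out = resize_bilinear_batch(np.ascontiguousarray(out), *spec.resize_final)
    return WindowSample(sample.video_id, sample.start_frame, out, sample.label)
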