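"""Decoding videos / frame directories into grayscale frame stacks.

Bottom-view recordings arrive either as a movie container, as a directory
of numbered frame images, or as a multi-page TIFF stack.  All of them are
decoded into a :class:`FrameSequence`: float frames in [0, 1], single
common size, nominal 30 fps.  Grayscale conversion uses Rec. 601 luma
weights (0.299, 0.587, 0.114); resizing is bilinear via scikit-image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = ["FrameSequence", "read_video", "write_frames"]

_LUMA = np.array([0.299, 0.587, 0.114])
_IMAGE_EXTS = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


@dataclass(frozen=True)
class FrameSequence:
    """Ordered grayscale frames of one video."""

    video_id: str
    frames: np.ndarray = field(repr=False)  # (T, H, W) float in [0, 1]
    fps: float = 30.0

    def __post_init__(self):
        arr = np.asarray(self.frames)
        if arr.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        object.__setattr__(self, "frames", arr)

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def native_size(self) -> tuple[int, int]:
        return (int(self.frames.shape[1]), int(self.frames.shape[2]))


def _to_gray_unit(img: np.ndarray) -> np.ndarray:
    """RGB(A)/gray of any integer or float dtype -> 2-D float64 in [0, 1]."""
    arr = np.asarray(img)
    if arr.ndim == 3:
        arr = arr[..., :3] @ _LUMA
    if np.issubdtype(np.asarray(img).dtype, np.integer):
        arr = arr / float(np.iinfo(np.asarray(img).dtype).max)
    return np.clip(arr.astype(np.float64), 0.0, 1.0)


def _resize(frame: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    if frame.shape == tuple(target):
        return frame
    return _sk_resize(frame, target, order=1, anti_aliasing=False, mode="edge")


def read_video(
    path,
    target_size: tuple[int, int] | None = None,
    fps: float = 30.0,
    video_id: str | None = None,
) -> FrameSequence:
    """Decode a movie file, frame directory, or TIFF stack.

    Frames are converted to grayscale, scaled to [0, 1], and (optionally)
    resized to ``target_size``.  Decoding is deterministic: two reads of
    the same file produce bit-identical arrays.
    """
    p = Path(path)
    if not p.exists():
        raise IOError(f"no such video source: {p}")
    if p.is_dir():
        files = sorted(f for f in p.iterdir() if f.suffix.lower() in _IMAGE_EXTS)
        if not files:
            raise IOError(f"frame directory {p} contains no image files")
        raw = [iio.imread(f) for f in files]
    elif p.suffix.lower() in {".tif", ".tiff"}:
        stack = iio.imread(p)
        raw = [stack] if stack.ndim == 2 else list(stack)
    else:
        try:
            raw = [np.asarray(f) for f in iio.imiter(p)]
        except Exception as exc:  # codec missing / unreadable container
            raise IOError(f"cannot decode video {p}: {exc}") from exc
    if not raw:
        raise IOError(f"video {p} contains no frames")
    gray = [_to_gray_unit(f) for f in raw]
    sizes = {g.shape for g in gray}
    if len(sizes) > 1:
        raise IOError(f"video {p} has inconsistent frame sizes: {sizes}")
    if target_size is not None:
        gray = [_resize(g, tuple(target_size)) for g in gray]
    return FrameSequence(video_id or p.stem, np.stack(gray), fps=fps)


def write_frames(seq: FrameSequence, directory, fmt: str = "png") -> int:
    """Write one 16-bit image per frame with zero-padded numeric names.

    Returns the number of files written.  16-bit PNG quantisation means a
    written-then-read sequence reproduces values to within 1/65535, and a
    second write/read round trip is exact.
    """
    if seq.n_frames == 0:
        raise IOError("refusing to write an empty frame sequence")
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    width = max(6, len(str(seq.n_frames)))
    for i, frame in enumerate(seq.frames):
        data = np.round(np.clip(frame, 0.0, 1.0) * 65535).astype(np.uint16)
        iio.imwrite(d / f"{i + 1:0{width}d}.{fmt}", data)
    return seq.n_frames
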