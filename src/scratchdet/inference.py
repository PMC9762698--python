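"""Per-frame prediction on full videos via the middle-frame rule.

At inference time every stride-1 window of N frames is classified, and
the window's prediction is assigned to its middle frame
(start + (N - 1) // 2; for even N this is the earlier of the two central
frames).  Leading frames that are never a middle frame copy the first
window's prediction, trailing ones copy the last window's — so every one
of the video's frames receives exactly one label.  The per-frame score is
the softmax scratching-class probability propagated by the same rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotations import FrameLabelTrack, TrainAnnotation, labels_to_trains
from .model import CRNNModel
from .nn import softmax
from .video_io import FrameSequence
from .windows import make_inference_windows

__all__ = ["FramePredictionTrack", "predict_video", "track_to_trains"]


@dataclass(frozen=True)
class FramePredictionTrack:
    """Binary per-frame predictions plus scratch-class probabilities."""

    video_id: str
    labels: np.ndarray = field(repr=False)
    scores: np.ndarray = field(repr=False)

    def __post_init__(self):
        if self.labels.shape != self.scores.shape:
            raise ValueError("labels and scores must have equal length")

    @property
    def n_frames(self) -> int:
        return int(self.labels.shape[0])

    def as_label_track(self) -> FrameLabelTrack:
        return FrameLabelTrack(self.video_id, self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"frame_index": np.arange(self.n_frames),
             "label": self.labels, "score": self.scores}
        )


def predict_video(
    model: CRNNModel,
    seq: FrameSequence,
    n: int | None = None,
    batch_size: int = 512,
) -> FramePredictionTrack:
    """Classify every frame of a video.

    Frames are embedded once by the CNN (overlapping stride-1 windows
    share frames), then the recurrent head scores each window; results are
    independent of ``batch_size``.
    """
    n = model.config.n if n is None else n
    t = seq.n_frames
    starts = make_inference_windows(t, n)  # raises if t < n
    model.eval()
    frames = seq.frames.astype(np.float32)
    if frames.shape[1:] != tuple(model.config.input_size):
        raise ValueError(
            f"frame size {frames.shape[1:]} does not match model input "
            f"{model.config.input_size}; resize during video loading"
        )
    emb = model.encode_frames(frames)
    # windows of embeddings: (n_windows, N, E) gathered view
    win_emb = np.stack([emb[s : s + n] for s in starts])
    logits = np.concatenate(
        [model.classify_embeddings(win_emb[i : i + batch_size])
         for i in range(0, len(starts), batch_size)]
    )
    probs = softmax(logits, axis=1)[:, 1]
    preds = logits.argmax(axis=1).astype(np.int8)

    mid = (n - 1) // 2
    labels = np.empty(t, dtype=np.int8)
    scores = np.empty(t, dtype=np.float64)
    labels[starts + mid] = preds
    scores[starts + mid] = probs
    labels[:mid] = preds[0]
    scores[:mid] = probs[0]
    tail = starts[-1] + mid + 1
    labels[tail:] = preds[-1]
    scores[tail:] = probs[-1]
    return FramePredictionTrack(seq.video_id, labels, scores)


def track_to_trains(
    track: FramePredictionTrack, merge_gap: int = 0
) -> TrainAnnotation:
    """Segment the predicted frame labels into predicted scratching trains."""
    return labels_to_trains(track.as_label_track(), merge_gap=merge_gap,
                            source="predicted")
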