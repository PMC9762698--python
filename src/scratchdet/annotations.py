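"""Scratch-train annotations and their per-frame dual representation.

A *scratching train* is one episode of scratching, from hind-paw lift to
hind-paw return (or to mouth).  An annotation for a video is an ordered,
non-overlapping list of closed frame intervals ``[start, end]`` (0-based,
both inclusive, so duration = end - start + 1).  The equivalent per-frame
view assigns label 1 to every frame inside some train and 0 elsewhere; the
two representations round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ScratchTrain",
    "TrainAnnotation",
    "FrameLabelTrack",
    "AnnotationError",
    "load_annotation",
    "save_annotation",
    "trains_to_labels",
    "labels_to_trains",
    "load_label_track",
    "save_label_track",
    "annotation_stats",
]

SOURCES = ("reference", "manual", "predicted")


class AnnotationError(ValueError):
    """Raised when an annotation violates the interval invariants."""


@dataclass(frozen=True)
class ScratchTrain:
    """Closed frame interval [start, end] of one scratching train."""

    start: int
    end: int

    def __post_init__(self):
        if self.start < 0 or self.end < self.start:
            raise AnnotationError(
                f"invalid train interval ({self.start}, {self.end}): "
                "need 0 <= start <= end"
            )

    @property
    def duration(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class TrainAnnotation:
    """All scratching trains of one video, sorted and non-overlapping."""

    video_id: str
    n_frames: int
    trains: tuple[ScratchTrain, ...] = ()
    source: str = "reference"

    def __post_init__(self):
        if self.source not in SOURCES:
            raise AnnotationError(
                f"source must be one of {SOURCES}, got {self.source!r}"
            )
        object.__setattr__(self, "trains", tuple(self.trains))

    @property
    def total_scratch_frames(self) -> int:
        return sum(t.duration for t in self.trains)

    def validate(self) -> "TrainAnnotation":
        for i, t in enumerate(self.trains):
            if t.end >= self.n_frames:
                raise AnnotationError(
                    f"{self.video_id}: train {i} ({t.start}, {t.end}) exceeds "
                    f"n_frames={self.n_frames}"
                )
            if i and t.start <= self.trains[i - 1].end:
                raise AnnotationError(
                    f"{self.video_id}: trains {i - 1} and {i} overlap or abut: "
                    f"({self.trains[i - 1].start}, {self.trains[i - 1].end}) vs "
                    f"({t.start}, {t.end})"
                )
        return self


def normalize_trains(
    trains: list[tuple[int, int]], n_frames: int, context: str = ""
) -> tuple[ScratchTrain, ...]:
    """Sort intervals, merge abutting/overlap-free neighbours separated by a
    gap of 0 frames (indistinguishable in the label track), and validate
    that no true overlaps remain."""
    ordered = sorted(trains)
    merged: list[list[int]] = []
    for start, end in ordered:
        if start < 0 or end < start or end >= n_frames:
            raise AnnotationError(
                f"{context}: interval ({start}, {end}) out of range for "
                f"n_frames={n_frames}"
            )
        if merged and start <= merged[-1][1]:
            raise AnnotationError(
                f"{context}: interval ({start}, {end}) overlaps "
                f"({merged[-1][0]}, {merged[-1][1]})"
            )
        if merged and start == merged[-1][1] + 1:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return tuple(ScratchTrain(s, e) for s, e in merged)


@dataclass(frozen=True)
class FrameLabelTrack:
    """Per-frame binary scratch (1) / non-scratch (0) labels."""

    video_id: str
    labels: np.ndarray = field(repr=False)

    def __post_init__(self):
        arr = np.asarray(self.labels, dtype=np.int8)
        if arr.ndim != 1:
            raise AnnotationError("labels must be a 1-D sequence")
        if not np.isin(arr, (0, 1)).all():
            raise AnnotationError("labels must contain only 0 and 1")
        object.__setattr__(self, "labels", arr)

    @property
    def n_frames(self) -> int:
        return int(self.labels.shape[0])


def load_annotation(
    path, n_frames: int, source: str = "reference"
) -> TrainAnnotation:
    """Read a train-annotation CSV (video_id, train_id, start_frame,
    end_frame) describing a single video."""
    df = pd.read_csv(path)
    required = {"video_id", "train_id", "start_frame", "end_frame"}
    if missing := required - set(df.columns):
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        return TrainAnnotation("", n_frames, (), source)
    ids = df["video_id"].unique()
    if len(ids) > 1:
        raise AnnotationError(
            f"{path}: expected a single video, found {list(ids)}"
        )
    intervals = list(zip(df["start_frame"].astype(int), df["end_frame"].astype(int)))
    trains = normalize_trains(intervals, n_frames, context=str(path))
    return TrainAnnotation(str(ids[0]), n_frames, trains, source).validate()


def save_annotation(ann: TrainAnnotation, path) -> None:
    pd.DataFrame(
        {
            "video_id": [ann.video_id] * len(ann.trains),
            "train_id": np.arange(1, len(ann.trains) + 1),
            "start_frame": [t.start for t in ann.trains],
            "end_frame": [t.end for t in ann.trains],
        }
    ).to_csv(path, index=False)


def trains_to_labels(ann: TrainAnnotation) -> FrameLabelTrack:
    """Per-frame view: label 1 iff the frame lies inside some train."""
    labels = np.zeros(ann.n_frames, dtype=np.int8)
    for t in ann.trains:
        labels[t.start : t.end + 1] = 1
    return FrameLabelTrack(ann.video_id, labels)


def labels_to_trains(
    track: FrameLabelTrack, merge_gap: int = 0, source: str = "reference"
) -> TrainAnnotation:
    """Maximal runs of 1-labels become trains; runs separated by gaps of at
    most ``merge_gap`` zero-frames are absorbed into one train.

    ``merge_gap=60`` expresses the field's 2-second convention for splitting
    adjacent trains at 30 fps; the default 0 performs no merging.
    """
    labels = track.labels
    if labels.size == 0:
        return TrainAnnotation(track.video_id, 0, (), source)
    diff = np.diff(np.concatenate(([0], labels, [0])))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1) - 1
    runs: list[list[int]] = []
    for s, e in zip(starts, ends):
        if runs and s - runs[-1][1] - 1 <= merge_gap:
            runs[-1][1] = int(e)
        else:
            runs.append([int(s), int(e)])
    trains = tuple(ScratchTrain(s, e) for s, e in runs)
    return TrainAnnotation(track.video_id, track.n_frames, trains, source).validate()


def load_label_track(path) -> FrameLabelTrack:
    df = pd.read_csv(path)
    if not {"frame_index", "label"} <= set(df.columns):
        raise AnnotationError(f"{path}: need columns frame_index, label")
    df = df.sort_values("frame_index")
    video_id = str(df["video_id"].iloc[0]) if "video_id" in df.columns else ""
    return FrameLabelTrack(video_id, df["label"].to_numpy())


def save_label_track(track: FrameLabelTrack, path) -> None:
    pd.DataFrame(
        {
            "frame_index": np.arange(track.n_frames),
            "label": track.labels,
        }
    ).to_csv(path, index=False)


def annotation_stats(anns: list[TrainAnnotation], bins=None) -> dict:
    """Descriptive statistics over a batch of annotations.

    Returns per-video train counts, the pooled duration list, a duration
    histogram and the mean duration — the quantities typically reported for
    a recorded cohort (trains per video, train-duration distribution).
    """
    if not anns:
        raise ValueError("need at least one annotation")
    counts = {a.video_id: len(a.trains) for a in anns}
    durations = np.array(
        [t.duration for a in anns for t in a.trains], dtype=np.int64
    )
    if bins is None:
        upper = int(durations.max()) + 30 if durations.size else 30
        bins = np.arange(0, upper + 1, 30)
    hist, edges = np.histogram(durations, bins=bins)
    return {
        "train_counts": counts,
        "durations": durations,
        "histogram": (hist, edges),
        "mean_duration": float(durations.mean()) if durations.size else float("nan"),
        "n_trains": int(durations.size),
    }
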