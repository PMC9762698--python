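"""Interval annotations, per-frame label tracks, and their round trip."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scratchdet.annotations import (
    AnnotationError,
    FrameLabelTrack,
    ScratchTrain,
    TrainAnnotation,
    annotation_stats,
    labels_to_trains,
    load_annotation,
    load_label_track,
    save_annotation,
    save_label_track,
    trains_to_labels,
)


def _ann(trains, n_frames=100, video_id="v1"):
    return TrainAnnotation(
        video_id, n_frames, tuple(ScratchTrain(s, e) for s, e in trains)
    ).validate()


class TestScratchTrain:
    def test_duration_is_inclusive(self):
        assert ScratchTrain(10, 40).duration == 31
        assert ScratchTrain(5, 5).duration == 1

    @pytest.mark.parametrize("start,end", [(-1, 5), (10, 9)])
    def test_invalid_intervals_rejected(self, start, end):
        with pytest.raises(AnnotationError):
            ScratchTrain(start, end)


class TestCsvIo:
    def test_load_two_trains(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text(
            "video_id,train_id,start_frame,end_frame\nv1,1,10,40\nv1,2,60,65\n"
        )
        ann = load_annotation(p, 100)
        assert ann.video_id == "v1"
        assert [(t.start, t.end) for t in ann.trains] == [(10, 40), (60, 65)]

    def test_overlap_is_a_validation_error(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text(
            "video_id,train_id,start_frame,end_frame\nv1,1,10,40\nv1,2,35,50\n"
        )
        with pytest.raises(AnnotationError, match="overlap"):
            load_annotation(p, 100)

    def test_out_of_range_is_a_validation_error(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("video_id,train_id,start_frame,end_frame\nv1,1,90,120\n")
        with pytest.raises(AnnotationError, match=r"\(90, 120\)"):
            load_annotation(p, 100)

    def test_empty_body_gives_zero_trains(self, tmp_path):
        p = tmp_path / "a.csv"
        p.write_text("video_id,train_id,start_frame,end_frame\n")
        assert load_annotation(p, 100).trains == ()

    def test_round_trip_through_file(self, tmp_path):
        ann = _ann([(10, 40), (60, 65)])
        save_annotation(ann, tmp_path / "out.csv")
        again = load_annotation(tmp_path / "out.csv", 100)
        assert again.trains == ann.trains

    def test_label_track_round_trip_through_file(self, tmp_path):
        track = trains_to_labels(_ann([(3, 7)], n_frames=12))
        save_label_track(track, tmp_path / "t.csv")
        again = load_label_track(tmp_path / "t.csv")
        assert np.array_equal(again.labels, track.labels)


class TestTrainsLabelsConversion:
    def test_inclusive_interval_count(self):
        labels = trains_to_labels(_ann([(10, 20)], n_frames=30)).labels
        assert labels.sum() == 11
        assert labels[10] == 1 and labels[20] == 1 and labels[21] == 0

    def test_empty_and_boundary_cases(self):
        assert trains_to_labels(_ann([], n_frames=30)).labels.sum() == 0
        labels = trains_to_labels(_ann([(0, 0), (29, 29)], n_frames=30)).labels
        assert labels[0] == 1 and labels[29] == 1 and labels.sum() == 2

    @pytest.mark.parametrize(
        "merge_gap,expected",
        [
            (0, [(10, 20), (25, 30)]),
            (3, [(10, 20), (25, 30)]),  # gap of 4 zero-frames > 3
            (4, [(10, 30)]),
        ],
    )
    def test_run_merge_rule(self, merge_gap, expected):
        track = trains_to_labels(_ann([(10, 20), (25, 30)], n_frames=40))
        out = labels_to_trains(track, merge_gap=merge_gap)
        assert [(t.start, t.end) for t in out.trains] == expected

    def test_labels_reject_non_binary(self):
        with pytest.raises(AnnotationError):
            FrameLabelTrack("v", np.array([0, 1, 2]))


@st.composite
def annotations(draw):
    n_frames = draw(st.integers(2, 200))
    n_pts = draw(st.integers(0, min(10, n_frames // 2))) * 2
    pts = sorted(
        draw(
            st.lists(
                st.integers(0, n_frames - 1),
                min_size=n_pts, max_size=n_pts, unique=True,
            )
        )
    )
    trains = list(zip(pts[::2], pts[1::2]))
    from scratchdet.annotations import normalize_trains

    return TrainAnnotation(
        "v", n_frames, normalize_trains(trains, n_frames)
    ).validate()


class TestRoundTripProperty:
    @settings(max_examples=200, derandomize=True)
    @given(annotations())
    def test_labels_round_trip_is_identity(self, ann):
        assert labels_to_trains(trains_to_labels(ann)).trains == ann.trains

    @settings(max_examples=200, derandomize=True)
    @given(annotations())
    def test_duration_sum_equals_label_count(self, ann):
        track = trains_to_labels(ann)
        assert sum(t.duration for t in ann.trains) == int(track.labels.sum())


class TestAnnotationStats:
    def test_counts_durations_mean(self):
        stats = annotation_stats([_ann([(10, 40), (60, 65)])])
        assert stats["train_counts"] == {"v1": 2}
        assert stats["durations"].tolist() == [31, 6]
        assert stats["mean_duration"] == pytest.approx(18.5)

    def test_empty_annotation(self):
        stats = annotation_stats([_ann([])])
        assert stats["train_counts"] == {"v1": 0}
        assert stats["durations"].size == 0
        assert np.isnan(stats["mean_duration"])

    def test_synthetic_cohort_mean_duration_matches_generator(self):
        from scratchdet import SyntheticConfig, generate_cohort

        cfg = SyntheticConfig(n_frames=3000, frame_size=(16, 16), noise_sd=0.0)
        anns = [ann for _, ann, _ in generate_cohort(cfg, 6, seed=7)]
        stats = annotation_stats(anns)
        assert stats["mean_duration"] == pytest.approx(
            cfg.duration_mean, rel=0.10
        )
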