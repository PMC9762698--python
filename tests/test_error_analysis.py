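"""Train matching and the five-type error taxonomy."""

import numpy as np
import pytest

from scratchdet.annotations import (
    FrameLabelTrack,
    ScratchTrain,
    TrainAnnotation,
    labels_to_trains,
    trains_to_labels,
)
from scratchdet.error_analysis import (
    classify_errors,
    error_histograms,
    match_trains,
)


def _ann(intervals, n=200, source="reference"):
    return TrainAnnotation(
        "v", n, tuple(ScratchTrain(s, e) for s, e in intervals), source
    )


def _report(pred_iv, ref_iv, n=200):
    pred, ref = _ann(pred_iv, n, "predicted"), _ann(ref_iv, n)
    return classify_errors(match_trains(pred, ref), pred, ref)


class TestMatchTrains:
    def test_one_to_one(self):
        m = match_trains(_ann([(12, 38)]), _ann([(10, 40)]))
        assert [x.relation for x in m] == ["one_to_one"]

    def test_merge_one_pred_two_refs(self):
        m = match_trains(_ann([(10, 80)]), _ann([(10, 40), (50, 80)]))
        assert [x.relation for x in m] == ["merge"]
        assert m[0].ref_ids == (0, 1) and m[0].pred_ids == (0,)

    def test_split_two_preds_one_ref(self):
        m = match_trains(_ann([(10, 40), (50, 80)]), _ann([(10, 80)]))
        assert [x.relation for x in m] == ["split"]

    def test_disjoint_trains_are_unmatched(self):
        m = match_trains(_ann([(60, 65)]), _ann([(10, 40)]))
        assert sorted(x.relation for x in m) == ["unmatched_pred",
                                                 "unmatched_ref"]

    def test_every_train_appears_exactly_once(self, rng):
        for _ in range(100):
            pred = labels_to_trains(
                FrameLabelTrack("v", rng.integers(0, 2, 150).astype(np.int8)),
                source="predicted")
            ref = labels_to_trains(
                FrameLabelTrack("v", rng.integers(0, 2, 150).astype(np.int8)))
            matches = match_trains(pred, ref)
            pred_ids = [i for m in matches for i in m.pred_ids]
            ref_ids = [j for m in matches for j in m.ref_ids]
            assert sorted(pred_ids) == list(range(len(pred.trains)))
            assert sorted(ref_ids) == list(range(len(ref.trains)))


class TestClassifyErrors:
    def test_false_positive_duration_and_distance(self):
        rep = _report([(60, 65), (100, 140)], [(100, 140)])
        assert rep.type1 == [(0, 6, 34)]  # frames 66..99 separate the trains
        assert rep.type2 == []

    def test_false_negative_duration(self):
        rep = _report([(100, 140)], [(10, 30), (100, 140)])
        assert rep.type2 == [(0, 21)]

    def test_boundary_shift_magnitudes(self):
        rep = _report([(12, 38)], [(10, 40)])
        assert rep.type3 == [(2, 2)]
        assert rep.type3_signed == [(2, -2)]
        assert not rep.type4 and not rep.type5

    def test_merge_missed_interval(self):
        rep = _report([(10, 80)], [(10, 40), (50, 80)])
        assert rep.type4 == [9]  # frames 41..49
        assert rep.type3 == [(0, 0)]

    def test_split_mispredicted_interval(self):
        rep = _report([(10, 40), (50, 80)], [(10, 80)])
        assert rep.type5 == [9]
        assert rep.type3 == [(0, 0)]

    def test_identical_prediction_yields_empty_report(self):
        rep = _report([(10, 40), (60, 90)], [(10, 40), (60, 90)])
        assert rep.is_empty()
        assert all(v == 0 for v in rep.frame_counts().values())

    def test_fraction_normalisation(self):
        rep = _report([(10, 80)], [(10, 40), (50, 80)])
        assert rep.total_ref_scratch_frames == 62
        assert rep.frame_fractions()["type4"] == pytest.approx(9 / 62)

    def test_frame_count_conservation_on_random_pairs(self, rng):
        """Mismatched frames partition exactly into the five types."""
        for _ in range(300):
            pred_labels = (rng.random(200) < 0.35).astype(np.int8)
            ref_labels = (rng.random(200) < 0.35).astype(np.int8)
            pred = labels_to_trains(FrameLabelTrack("v", pred_labels),
                                    source="predicted")
            ref = labels_to_trains(FrameLabelTrack("v", ref_labels))
            rep = classify_errors(match_trains(pred, ref), pred, ref)
            counts = rep.frame_counts()
            mismatched = int((pred_labels != ref_labels).sum())
            assert sum(counts.values()) == mismatched


class TestErrorHistograms:
    def test_binning_example(self):
        rep = _report([], [(0, 11), (50, 84), (100, 169)], n=300)
        hists = error_histograms(rep, bin_edges=(30, 60))
        assert rep.type2 == [(0, 12), (1, 35), (2, 70)]
        assert hists["type2_duration"].tolist() == [1, 1, 1]

    def test_edge_values_fall_in_upper_bin(self):
        rep = _report([], [(0, 29)], n=100)  # duration exactly 30
        hists = error_histograms(rep, bin_edges=(30, 60))
        assert hists["type2_duration"].tolist() == [0, 1, 0]

    def test_empty_report_gives_zero_tables(self):
        rep = _report([(5, 10)], [(5, 10)], n=50)
        hists = error_histograms(rep)
        for key, val in hists.items():
            if key.startswith("type") and "shift" not in key:
                assert val.sum() == 0

    def test_undertrained_model_misses_short_trains_preferentially(self):
        """Emulate a detector that only finds long trains: the missed-train
        fraction must fall with duration, mirroring the duration
        stratification reported for real predictions."""
        rng = np.random.default_rng(0)
        durations = rng.integers(5, 100, size=60)
        pos, refs, preds = 5, [], []
        for d in durations:
            iv = (pos, pos + int(d) - 1)
            refs.append(iv)
            # a weak detector: detection probability grows with duration
            if rng.random() < min(1.0, d / 50):
                preds.append(iv)
            pos += int(d) + 20
        rep = _report(preds, refs, n=pos + 10)
        missed = np.array([d for _, d in rep.type2])
        short_frac = (missed < 30).sum() / max((durations < 30).sum(), 1)
        long_frac = (missed > 60).sum() / max((durations > 60).sum(), 1)
        assert short_frac > long_frac
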