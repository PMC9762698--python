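"""Shared fixtures and stub models for the test suite.

The expensive desk-scale end-to-end runs (tiny CRNN trained on a seeded
synthetic cohort for seeds 0-2) are computed once per session and shared
between the training-performance, held-out-metric, and saliency tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from scratchdet import (
    AugmentationSpec,
    CRNNConfig,
    SyntheticConfig,
    TrainingConfig,
    build_model,
    generate_cohort,
    make_training_windows,
    pooled_metrics,
    predict_video,
    train,
    train_test_split,
    trains_to_labels,
)


class MajorityStub:
    """Oracle stand-in for a trained model (synthetic, not a checkpoint):
    embeds each frame as its reference label and classifies a window as
    scratching iff a strict majority of its frames are scratching.

    Duck-types the model surface that stride-1 inference consumes.
    """

    def __init__(self, ref_labels: np.ndarray, n: int, size=(8, 8)):
        self.config = CRNNConfig.tiny(n=n, input_size=tuple(size))
        self._labels = np.asarray(ref_labels, dtype=np.float64)

    def eval(self):
        return self

    def encode_frames(self, frames, batch_size=256):
        return self._labels[: frames.shape[0], None]

    def classify_embeddings(self, emb):
        frac = emb[:, :, 0].mean(axis=1)
        pos = (2 * frac * self.config.n > self.config.n).astype(np.float64)
        return np.stack([1.0 - pos, pos], axis=1) * 10.0 - 5.0


class ConstantStub(MajorityStub):
    """Predicts one fixed class for every window."""

    def __init__(self, label: int, n_frames: int, n: int, size=(8, 8)):
        super().__init__(np.full(n_frames, label), n, size)

    def classify_embeddings(self, emb):
        pos = emb[:, 0, 0] * 0 + self._labels[0]
        return np.stack([1.0 - pos, pos], axis=1) * 10.0 - 5.0


@pytest.fixture(scope="session")
def desk_scale_runs():
    """Train the tiny CRNN end-to-end on the default synthetic conditions
    (10 videos of 1200 frames, 8 train / 2 test, N=7, 10 epochs) for seeds
    0-2; return per-seed models, logs, metrics, and held-out cohorts."""
    runs = {}
    for seed in (0, 1, 2):
        cohort = generate_cohort(SyntheticConfig(), 10, seed=seed)
        train_videos, test_videos = train_test_split(cohort)
        samples = []
        for i, (seq, ann, _) in enumerate(train_videos):
            track = trains_to_labels(ann)
            samples.extend(
                make_training_windows(
                    track, seq.frames.astype(np.float32), 7,
                    seed=seed * 1000 + i,
                )
            )
        model = build_model(CRNNConfig.tiny(), seed=seed)
        model, log = train(
            model,
            samples,
            TrainingConfig.desk_scale(
                seed=seed, augmentation=AugmentationSpec.desk_scale()
            ),
        )
        preds, refs = [], []
        for seq, ann, _ in test_videos:
            track = predict_video(model, seq)
            preds.append(track.as_label_track())
            refs.append(trains_to_labels(ann))
        runs[seed] = {
            "model": model,
            "log": log,
            "metrics": pooled_metrics(preds, refs),
            "test_videos": test_videos,
            "n_windows": len(samples),
        }
    return runs


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
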