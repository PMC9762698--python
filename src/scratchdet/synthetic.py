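"""Synthetic bottom-view behavior videos with ground-truth annotations.

The generator emulates what the classifier consumes from a real
recording box: a dark arena, a bright body-shaped blob, and a small
hind-paw disc that rests at the body flank, and during annotated
scratching trains lifts toward the nape and oscillates rapidly there.
Distractor behaviors fill the non-scratching stretches: whole-body
translation (locomotion), a slower oscillating anterior disc near the
head (grooming — the same kind of rhythmic motion as scratching, at a
different body location and frequency), and quiet rest with slow drift.
Per-frame illumination jitter and Gaussian pixel noise are added last.

Default geometry is desk scale (64x64, 1200 frames = 40 s at 30 fps) with
roughly six scratching trains of mean duration ~56 frames per video, so
about 30% of frames are scratching frames — proportions comparable to an
acute-model recording, compressed to a video length that trains in
minutes on one CPU.  The same code runs at 300x300 to exercise the
full-scale preprocessing path.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .annotations import TrainAnnotation, normalize_trains
from .video_io import FrameSequence

__all__ = ["SyntheticConfig", "generate_video", "generate_cohort",
           "train_test_split"]


@dataclass(frozen=True)
class SyntheticConfig:
    n_frames: int = 1200
    fps: float = 30.0
    frame_size: tuple[int, int] = (64, 64)
    background: float = 0.08
    body_axes: tuple[float, float] = (18.0, 11.0)  # semi-axes (along, across)
    body_intensity: float = 0.55
    paw_radius: float = 3.0
    paw_intensity: float = 0.9
    scratch_trains: tuple[tuple[int, int], ...] | None = None
    duration_mean: float = 56.0
    duration_sd: float = 25.0
    duration_min: int = 12
    gap_min: int = 40
    gap_mean: float = 120.0
    oscillation_period: float = 4.0
    oscillation_amplitude: float = 3.0
    grooming_period: float = 10.0  # anterior strokes are slower than scratching
    distractors: tuple[str, ...] = ("locomotion", "grooming", "rest")
    noise_sd: float = 0.02
    illumination_jitter: float = 0.03
    seed: int = 0

    def __post_init__(self):
        if self.oscillation_period < 2:
            raise ValueError("oscillation period must be >= 2 frames")
        if self.oscillation_amplitude < 0:
            raise ValueError("oscillation amplitude must be >= 0")
        unknown = set(self.distractors) - {"locomotion", "grooming", "rest"}
        if unknown:
            raise ValueError(f"unknown distractors: {sorted(unknown)}")


def _sample_trains(cfg: SyntheticConfig, rng: np.random.Generator):
    """Durations ~ lognormal(mean, sd), inter-train gaps ~ gap_min +
    exponential; at least one train is always placed."""
    m, s = cfg.duration_mean, cfg.duration_sd
    sigma2 = math.log(1.0 + (s / m) ** 2)
    mu = math.log(m) - sigma2 / 2.0
    trains = []
    pos = cfg.gap_min + int(rng.exponential(max(cfg.gap_mean - cfg.gap_min, 1)))
    while True:
        dur = max(cfg.duration_min, int(round(rng.lognormal(mu, math.sqrt(sigma2)))))
        end = pos + dur - 1
        if end >= cfg.n_frames - 5:
            break
        trains.append((pos, end))
        pos = end + 1 + cfg.gap_min + int(
            rng.exponential(max(cfg.gap_mean - cfg.gap_min, 1))
        )
    if not trains:
        dur = min(max(cfg.duration_min, int(m)), max(cfg.n_frames - 2, 1))
        start = (cfg.n_frames - dur) // 2
        trains.append((start, start + dur - 1))
    return trains


def _paint_ellipse(canvas, yy, xx, cy, cx, a, b, theta, intensity):
    u = (yy - cy) * math.cos(theta) + (xx - cx) * math.sin(theta)
    v = -(yy - cy) * math.sin(theta) + (xx - cx) * math.cos(theta)
    d = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    edge = 1.5 / min(a, b)
    mask = np.clip((1.0 - d) / edge, 0.0, 1.0)
    np.maximum(canvas, intensity * mask, out=canvas)


def _paint_disc(canvas, yy, xx, cy, cx, r, intensity):
    d = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2)
    mask = np.clip(r + 0.5 - d, 0.0, 1.0)
    np.maximum(canvas, intensity * mask, out=canvas)


def _behavior_timeline(cfg, trains, rng):
    """Assign one distractor behavior to every non-scratching episode."""
    timeline = np.full(cfg.n_frames, "rest", dtype=object)
    for s, e in trains:
        timeline[s : e + 1] = "scratch"
    if not cfg.distractors:
        timeline[timeline == "rest"] = "none"
        return timeline
    bounds = [0] + [x for s, e in trains for x in (s, e + 1)] + [cfg.n_frames]
    for lo, hi in zip(bounds[::2], bounds[1::2]):
        if hi > lo:
            timeline[lo:hi] = rng.choice(list(cfg.distractors))
    return timeline


def generate_video(
    cfg: SyntheticConfig,
) -> tuple[FrameSequence, TrainAnnotation, np.ndarray]:
    """Render one video; returns (frames, ground-truth annotation,
    per-frame paw centre coordinates as an (n_frames, 2) [y, x] array).

    Fully deterministic for a fixed config (the seed lives in the config).
    """
    rng = np.random.default_rng(cfg.seed)
    h, w = cfg.frame_size
    scale = min(h, w) / 64.0  # geometry defaults are expressed at 64x64
    a, b = cfg.body_axes[0] * scale, cfg.body_axes[1] * scale
    paw_r = cfg.paw_radius * scale
    amp = cfg.oscillation_amplitude * scale

    if cfg.scratch_trains is not None:
        trains = [(int(s), int(e)) for s, e in cfg.scratch_trains]
    else:
        trains = _sample_trains(cfg, rng)
    norm = normalize_trains(trains, cfg.n_frames, context="synthetic config")
    video_id = f"synth{cfg.seed:05d}"
    ann = TrainAnnotation(video_id, cfg.n_frames, norm, source="reference")

    timeline = _behavior_timeline(cfg, [(t.start, t.end) for t in norm], rng)
    # the animal turns freely: orientation follows a slow random walk with a
    # larger reorientation at each behavior transition
    theta = float(rng.uniform(0, 2 * math.pi))
    side = 1.0 if rng.random() < 0.5 else -1.0
    margin = a + 2 * paw_r + 2.0
    center = np.array(
        [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
        if h > 2 * margin
        else [h / 2.0, w / 2.0]
    )
    velocity = np.zeros(2)
    loco_speed = 1.2 * scale

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    frames = np.empty((cfg.n_frames, h, w), dtype=np.float32)
    paw_track = np.empty((cfg.n_frames, 2), dtype=np.float64)
    in_train_t0 = {t.start: t.start for t in norm}
    t0 = 0
    prev_behavior = None
    for t in range(cfg.n_frames):
        behavior = timeline[t]
        if behavior != prev_behavior:
            if prev_behavior is not None and "none" not in (behavior, prev_behavior):
                theta += float(rng.uniform(-0.8, 0.8))
            if behavior == "locomotion":
                ang = rng.uniform(0, 2 * math.pi)
                velocity = loco_speed * np.array([math.cos(ang), math.sin(ang)])
            if behavior == "scratch":
                t0 = in_train_t0.get(t, t)
            prev_behavior = behavior
        if behavior in ("locomotion", "rest", "grooming"):
            theta += float(rng.normal(0.0, 0.02))
        u_vec = np.array([math.cos(theta), math.sin(theta)])
        p_vec = np.array([-math.sin(theta), math.cos(theta)])
        if behavior == "locomotion":
            center = center + velocity
            for k in range(2):
                lim = (h, w)[k]
                if center[k] < margin or center[k] > lim - margin:
                    velocity[k] = -velocity[k]
                    center[k] = np.clip(center[k], margin, lim - margin)
        elif behavior == "rest":
            center = np.clip(
                center + rng.normal(0.0, 0.1 * scale, size=2),
                margin, [h - margin, w - margin],
            )

        flank = center - 0.55 * a * u_vec + side * 0.8 * b * p_vec
        paw = flank.copy()
        if behavior == "scratch" and amp > 0:
            # the hind paw lifts toward the nape (a postural cue present in
            # every scratching frame) and oscillates rapidly across the body
            lift = center + 0.35 * a * u_vec + side * 0.9 * b * p_vec
            phase = 2 * math.pi * (t - t0) / cfg.oscillation_period
            paw = lift + amp * math.sin(phase) * p_vec * side
        canvas = np.full((h, w), cfg.background, dtype=np.float64)
        _paint_ellipse(canvas, yy, xx, center[0], center[1], a, b, theta,
                       cfg.body_intensity)
        head = center + 0.8 * a * u_vec
        _paint_ellipse(canvas, yy, xx, head[0], head[1], 0.45 * a, 0.55 * b,
                       theta, cfg.body_intensity * 1.15)
        _paint_disc(canvas, yy, xx, paw[0], paw[1], paw_r, cfg.paw_intensity)
        if behavior == "grooming":
            phase = 2 * math.pi * t / cfg.grooming_period
            fore = (center + 0.6 * a * u_vec + side * 0.5 * b * p_vec
                    + amp * math.sin(phase) * p_vec * side)
            _paint_disc(canvas, yy, xx, fore[0], fore[1], paw_r,
                        cfg.paw_intensity)
        gain = 1.0 + (rng.normal(0.0, cfg.illumination_jitter)
                      if cfg.illumination_jitter > 0 else 0.0)
        canvas = canvas * gain
        if cfg.noise_sd > 0:
            canvas = canvas + rng.normal(0.0, cfg.noise_sd, size=(h, w))
        frames[t] = np.clip(canvas, 0.0, 1.0)
        paw_track[t] = paw
    seq = FrameSequence(video_id, frames, fps=cfg.fps)
    return seq, ann, paw_track


def generate_cohort(
    cfg_base: SyntheticConfig, n_videos: int, seed: int = 0
) -> list[tuple[FrameSequence, TrainAnnotation, np.ndarray]]:
    """Generate ``n_videos`` videos with per-video seeds derived from the
    master seed (video i uses seed*1000 + i)."""
    if n_videos < 1:
        raise ValueError("n_videos must be >= 1")
    out = []
    for i in range(n_videos):
        cfg = replace(cfg_base, seed=seed * 1000 + i)
        out.append(generate_video(cfg))
    return out


def train_test_split(items: list, test_fraction: float = 0.2):
    """Deterministic leading/trailing split (default 80/20, mirroring an
    8-training / 2-test cohort at n=10)."""
    n_test = int(round(len(items) * test_fraction))
    if n_test == 0:
        warnings.warn("test split is empty at this cohort size", stacklevel=2)
    n_train = len(items) - n_test
    return items[:n_train], items[n_train:]
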