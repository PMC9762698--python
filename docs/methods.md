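# Methods

## The detection problem

Mouse scratching is quantified by marking, for every frame of a
bottom-view video recorded at 30 frames/s, whether the animal is inside a
*scratching train* — one episode from hind-paw lift to hind-paw return
(or to mouth), comprising one or more rhythmic scratching bouts,
optionally interleaved with paw-licking.  The package represents a
video's annotation in two lossless, interconvertible forms: an ordered
list of closed frame intervals `[start, end]` (0-based, both inclusive,
duration = end − start + 1), and a per-frame 0/1 label track.  Total
scratching time — the sum of train durations — is the downstream proxy
for itch intensity.

## Classifier

The classifier is a convolutional-recurrent network over windows of N
consecutive grayscale frames:

* a per-frame residual CNN encoder producing an embedding vector per
  frame — either a standard ResNet-18 (grayscale stem, [2,2,2,2] blocks,
  64→512 channels, global average pool) with its classification layer
  replaced by a 256-d embedding layer, for 256×256 inputs; or a `tiny`
  3-block residual network (8→16→32→64 channels, global average pool,
  64-d embedding) for 64×64 inputs;
* a 2-layer bidirectional GRU (hidden size 512 full scale / 64 tiny, per
  direction) over the N embeddings, capturing the rhythmic paw dynamics;
* a fully connected head (256 / 64 hidden units, ReLU, dropout 0.2, two
  output scores); the predicted class is the argmax.

Window labels follow a strict majority rule: class 1 iff more than N/2
frames are scratching frames (the exact tie possible for even N labels
0; published window lengths N ∈ {3, 5, 7, 13, 23, 45} are all odd).
Training windows are sampled with a random stride of 4–10 frames (drawn
uniformly per step under a seed; a fixed-stride mode exists for
reproducibility studies).  Inference uses stride 1 and the middle-frame
rule: each window's prediction is assigned to its central frame
(`start + (N−1)//2`; for even N the earlier central frame), and the
leading/trailing frames that are never a middle frame copy the
first/last window's prediction, so every frame is assigned exactly once.
The per-frame probability trace is the softmax scratch-class probability
propagated by the same rule.

Two classifier-head wirings are provided because the exact CNN/RNN
feature fusion is an open design point: `concat_cnn_mean` (default)
concatenates the final hidden states of both GRU directions with the
mean CNN embedding of the window, so the head combines dynamic and
static features directly; `gru_only` feeds the recurrent states alone.
The concat wiring is the default both because the classifier is
described as combining CNN and RNN features and because, at desk scale,
the recurrent-only head proved brittle for poses under-represented in a
small training cohort — the direct static path (the raised-paw posture)
is what generalizes.  The choice is recorded in the model config.

## Numerics: the numpy engine

All network computation (convolution via im2col/GEMM, batch
normalization, max/average pooling, GRU with backpropagation through
time, dropout, Adam, softmax cross-entropy, and input-gradient saliency)
is implemented in numpy inside `scratchdet.nn`, with hand-derived
backward passes.  Every backward pass is verified against central finite
differences in float64 (`tests/test_nn.py`); training runs in float32.
Evaluation-mode forward passes are deterministic; the split inference
path (each frame embedded once, recurrent head per window) is
numerically identical to the windowed forward pass up to float32 GEMM
accumulation order, and predictions are independent of batching.
Dropout masks come from a generator seeded at model build time, so
training is bit-reproducible for a fixed seed under single-threaded
BLAS.  "Binary cross entropy" over the two-score output is implemented
as 2-class softmax cross-entropy, mathematically equivalent to BCE on
the scratch-class probability.

## Training recipe

Adam (standard betas/epsilon) with the learning rate
`lr(e) = lr_init · 0.3^⌊(e−1)/5⌋`, maximum 20 epochs, batch size 16 for
N ≥ 23 and 32 otherwise, dropout 0.2, no early stopping or
validation-based checkpointing.  Full-scale `lr_init` is 1e-4.  The
desk-scale preset (`TrainingConfig.desk_scale`) raises `lr_init` to 1e-3
and uses batch 16 — the smaller of the recipe's two batch sizes — over
10 epochs: a desk cohort provides only ~1350 windows, so a desk-scale
run performs ~8×10² optimizer steps versus ~10⁵ at full scale, and
without both adjustments the plateau the schedule is built around
(accuracy flat after ~10 epochs) is unreachable; the decay shape is
unchanged.  Training augmentation draws one square crop
(uniform side in [crop_min, crop_max], uniform position), one horizontal
and one vertical flip decision (probability 0.5 each) per *window* and
applies them identically to all N frames — per-frame draws would destroy
the temporal coherence the GRU reads.  Full-scale parameters: 300×300
input frames, crop 288–300, final resize 256×256.  Desk scale: 64×64
frames, crop 61–64, final size 64 (kept at the generator's native size
so the tiny backbone needs no second geometry).

## Evaluation

Frame-level, with scratching as the positive class: recall = correctly
predicted scratching frames / reference scratching frames; precision =
correct / all predicted scratching frames; F1 = 2rp/(r+p); accuracy over
both classes.  Undefined ratios (empty denominators) are NaN with an
explicit flag, never silently zero.  Whether multi-video summaries
should pool frames or average per-video metrics is ambiguous, so both
are available (`pooled_metrics` vs per-video `frame_metrics`).  Cohort
comparison reports per-video total scratching frames, the prediction
normalized to reference = 100%, the Pearson correlation across videos
(both r and r², since published figures label r² values "Pearson
correlation coefficient"), and mean absolute percent discrepancy.

## Error taxonomy

Predicted and reference trains are matched by closed-interval overlap
(≥ 1 shared frame); connected components of the bipartite overlap graph
are classified: Type 1 false-positive train (duration and gap to the
nearest reference train recorded), Type 2 missed train (duration),
Type 3 boundary shift (unsigned |Δstart|, |Δend| between a component's
outermost boundaries; signed versions also kept), Type 4 missed interval
(reference gap absorbed into a merged prediction), Type 5 split train
(predicted gap inside a reference train).  Within any component,
mismatched frames partition exactly: outer-boundary mismatches are
Type 3, interior reference-gaps covered by prediction are Type 4,
interior prediction-gaps are Type 5.  This holds for many-to-many
("complex") components too — interior prediction-gaps and reference-gaps
cannot overlap inside one connected component — so per-type frame counts
always sum to the number of mismatched frames (property-tested on random
pairs).  Histogram bin edges default to 10/30/40/60 frames, the
thresholds used to stratify short/medium/long trains and intervals at
30 fps.

## Saliency

Vanilla input gradients: the gradient of the target-class score w.r.t.
each input pixel, negative values zeroed, rescaled to [0,1] over the
whole window (per-frame rescaling optional).  Overlays band the values
half-open: v < 0.1 transparent, 0.1 ≤ v < 0.6 a light-to-dark blue ramp
with proportional opacity, v ≥ 0.6 darkest blue at maximal opacity.  The
middle frame — the frame the window's prediction is assigned to — is the
default visualization target.

## Synthetic videos

The generator renders what the classifier actually consumes from a
recording box: a dark arena (background 0.08), a bright elliptical body
(semi-axes 18×11 px at 64×64, intensity 0.55) with a smaller anterior
"head" ellipse, and a radius-3 hind-paw disc (intensity 0.9) attached at
the body flank.  The animal turns and translates: orientation follows a
slow random walk plus a larger reorientation at each behavior
transition; locomotion episodes translate the body at ~1.2 px/frame with
wall bounces; rest episodes drift slowly.  During a scratching train the
hind paw lifts toward the nape — the postural cue that distinguishes
scratching frames statically — and oscillates sinusoidally across the
body axis (period 4 frames ≈ 7.5 Hz at 30 fps, amplitude 3 px).
Grooming episodes oscillate a second disc near the head at a slower
period (10 frames ≈ 3 Hz), so the distractor shares the *kind* of motion
but not its location or frequency.  Per-frame illumination jitter
(σ = 3%) and Gaussian pixel noise (σ = 0.02) are applied last.

Ground-truth trains are sampled with lognormal durations (mean 56, SD 25
frames, minimum 12) separated by gaps of at least 40 frames (mean 120),
giving ~6 trains and ~30% scratching frames in a default 1200-frame
(40 s) video — proportions comparable to an acute-model recording
compressed to a length that trains in minutes on one CPU.  Defaults were
fixed once: 1200 frames is the point where a cohort of 8 training videos
(~1350 windows at stride 4–10) supports cross-video generalization
rather than per-video memorization.  The generator is seed-deterministic
to the bit and also runs at 300×300 to exercise the full-scale
preprocessing path.

What the generator does *not* emulate: fur texture, limb articulation
and motion blur, paw-licking appearance, occlusion by the tail, wiping
and rearing, or camera vignetting.  Passing desk-scale tests therefore
demonstrates that the pipeline's machinery — window labeling, training,
middle-frame inference, segmentation, metrics, error taxonomy,
saliency — is correct and that the CRNN can learn rhythmic-plus-postural
structure from small data; it does not certify performance on real
recordings.

## Desk-scale study conditions

The end-to-end study mirrors the full-scale design at 1/5 geometry and
~1/60 video length: 10 videos (8 training / 2 held-out, the 80/20 split
of the full cohort), N = 7, tiny backbone, 10 epochs, batch 16,
augmentation on.  Expected behavior, verified per seed for seeds 0–2:
training accuracy ≥ 0.98 within 10 epochs; held-out frame-pooled F1
≥ 0.90; saliency mass concentrated on the oscillating paw region.
`scripts/acceptance.py` re-runs one such study from scratch for the
given seed and also reports the closed-form worked examples (printed
recall/precision pairs → F1) and the learning-rate schedule endpoint.

## Known limitations

* Real videos: no trained full-scale weights ship with the package; the
  ResNet-18/256×256 path is exercised structurally (forward shape and
  checkpoint round-trip) but not trained here.
* Phase-level structure inside trains (scratching bouts vs paw licking)
  is not modeled or annotated; Type 5 attribution to licking phases is
  out of scope.
* Video decoding covers frame directories, TIFF stacks, and any
  container imageio can open in the host environment; MP4/AVI support
  depends on an available codec backend and fails with a clear error
  otherwise.
* Bit determinism holds per machine/BLAS build; across BLAS builds,
  float32 accumulation order may differ in the last ulps.
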