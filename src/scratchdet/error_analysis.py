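"""Train-level error taxonomy for predicted vs reference annotations.

Predicted and reference trains are matched by interval overlap (two
trains are linked iff their closed intervals share at least one frame);
connected components of the overlap graph become matches.  Discrepancies
are then classified into five types:

* **Type 1** — false positive: a predicted train overlapping no reference
  train (recorded with its duration and gap to the nearest reference
  train).
* **Type 2** — false negative: a reference train overlapping no predicted
  train (recorded with its duration).
* **Type 3** — blurred boundary: start/end shifts between the outermost
  matched boundaries of a component (unsigned magnitudes by default,
  signed versions also kept; positive sign = prediction late/long).
* **Type 4** — missed interval: frames predicted as scratching inside the
  gap between two adjacent reference trains that were fused into one
  prediction.
* **Type 5** — split train: non-scratching gaps predicted inside a single
  reference train, splitting it into several predicted trains.

Within a component, every mismatched frame lands in exactly one bucket:
frames outside the overlap of the outermost boundaries are Type 3; interior
reference-only frames (a prediction gap) are Type 5; interior
predicted-only frames (a reference gap) are Type 4.  This keeps per-type
frame counts an exact partition of all mismatched frames, also for
many-to-many ("complex") components, which are flagged as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import ScratchTrain, TrainAnnotation

__all__ = [
    "TrainMatch",
    "ErrorReport",
    "match_trains",
    "classify_errors",
    "error_histograms",
    "DEFAULT_BIN_EDGES",
]

DEFAULT_BIN_EDGES = (10, 30, 40, 60)


@dataclass(frozen=True)
class TrainMatch:
    """One connected component of the prediction/reference overlap graph."""

    ref_ids: tuple[int, ...]
    pred_ids: tuple[int, ...]
    relation: str  # one_to_one | unmatched_pred | unmatched_ref | merge | split | complex


@dataclass
class ErrorReport:
    # (pred_id, duration, distance to nearest reference train; -1 if no refs)
    type1: list[tuple[int, int, int]] = field(default_factory=list)
    # (ref_id, duration)
    type2: list[tuple[int, int]] = field(default_factory=list)
    # unsigned (start_shift, end_shift) per matched component
    type3: list[tuple[int, int]] = field(default_factory=list)
    # signed counterparts: positive start = predicted start late,
    # positive end = predicted end late
    type3_signed: list[tuple[int, int]] = field(default_factory=list)
    type4: list[int] = field(default_factory=list)  # missed-interval lengths
    type5: list[int] = field(default_factory=list)  # mispredicted-interval lengths
    complex_components: int = 0
    total_ref_scratch_frames: int = 0

    def frame_counts(self) -> dict[str, int]:
        return {
            "type1": sum(d for _, d, _ in self.type1),
            "type2": sum(d for _, d in self.type2),
            "type3": sum(s + e for s, e in self.type3),
            "type4": sum(self.type4),
            "type5": sum(self.type5),
        }

    def frame_fractions(self) -> dict[str, float]:
        denom = self.total_ref_scratch_frames
        counts = self.frame_counts()
        if denom == 0:
            return {k: float("nan") for k in counts}
        return {k: v / denom for k, v in counts.items()}

    def is_empty(self) -> bool:
        return not (self.type1 or self.type2 or self.type4 or self.type5
                    or any(s or e for s, e in self.type3))


def _gap(a: ScratchTrain, b: ScratchTrain) -> int:
    """Frames strictly between two disjoint closed intervals (0 if they
    touch or overlap)."""
    if b.start > a.end:
        return b.start - a.end - 1
    if a.start > b.end:
        return a.start - b.end - 1
    return 0


def match_trains(pred: TrainAnnotation, ref: TrainAnnotation) -> list[TrainMatch]:
    """Connected components of the bipartite interval-overlap graph,
    ordered by first frame."""
    edges: dict[int, set[int]] = {i: set() for i in range(len(pred.trains))}
    redges: dict[int, set[int]] = {j: set() for j in range(len(ref.trains))}
    j0 = 0
    for i, p in enumerate(pred.trains):
        for j in range(j0, len(ref.trains)):
            r = ref.trains[j]
            if r.end < p.start:
                j0 = j + 1
                continue
            if r.start > p.end:
                break
            edges[i].add(j)
            redges[j].add(i)
    matches: list[TrainMatch] = []
    seen_p: set[int] = set()
    seen_r: set[int] = set()
    for i in range(len(pred.trains)):
        if i in seen_p:
            continue
        if not edges[i]:
            seen_p.add(i)
            matches.append(TrainMatch((), (i,), "unmatched_pred"))
            continue
        comp_p, comp_r = {i}, set()
        frontier_p = [i]
        while frontier_p:
            refs_new = set()
            for pi in frontier_p:
                refs_new |= edges[pi] - comp_r
            comp_r |= refs_new
            frontier_p = []
            for rj in refs_new:
                for pi in redges[rj]:
                    if pi not in comp_p:
                        comp_p.add(pi)
                        frontier_p.append(pi)
        seen_p |= comp_p
        seen_r |= comp_r
        k, m = len(comp_p), len(comp_r)
        if k == 1 and m == 1:
            relation = "one_to_one"
        elif k == 1:
            relation = "merge"
        elif m == 1:
            relation = "split"
        else:
            relation = "complex"
        matches.append(
            TrainMatch(tuple(sorted(comp_r)), tuple(sorted(comp_p)), relation)
        )
    for j in range(len(ref.trains)):
        if j not in seen_r:
            matches.append(TrainMatch((j,), (), "unmatched_ref"))
    matches.sort(
        key=lambda mt: min(
            [pred.trains[i].start for i in mt.pred_ids]
            + [ref.trains[j].start for j in mt.ref_ids]
        )
    )
    return matches


def _interior_gaps(trains: list[ScratchTrain], lo: int, hi: int) -> list[int]:
    """Lengths of gaps between consecutive trains, clipped to [lo, hi]."""
    out = []
    for a, b in zip(trains, trains[1:]):
        g_lo = max(a.end + 1, lo)
        g_hi = min(b.start - 1, hi)
        if g_hi >= g_lo:
            out.append(g_hi - g_lo + 1)
    return out


def classify_errors(
    matches: list[TrainMatch], pred: TrainAnnotation, ref: TrainAnnotation
) -> ErrorReport:
    """Build the five-type error inventory from matched train components."""
    report = ErrorReport(total_ref_scratch_frames=ref.total_scratch_frames)
    for mt in matches:
        if mt.relation == "unmatched_pred":
            p = pred.trains[mt.pred_ids[0]]
            dist = min((_gap(p, r) for r in ref.trains), default=-1)
            report.type1.append((mt.pred_ids[0], p.duration, dist))
            continue
        if mt.relation == "unmatched_ref":
            r = ref.trains[mt.ref_ids[0]]
            report.type2.append((mt.ref_ids[0], r.duration))
            continue
        ps = [pred.trains[i] for i in mt.pred_ids]
        rs = [ref.trains[j] for j in mt.ref_ids]
        start_signed = ps[0].start - rs[0].start
        end_signed = ps[-1].end - rs[-1].end
        report.type3_signed.append((start_signed, end_signed))
        report.type3.append((abs(start_signed), abs(end_signed)))
        # interior of the component: between the later start and earlier end
        lo = max(ps[0].start, rs[0].start)
        hi = min(ps[-1].end, rs[-1].end)
        report.type4.extend(_interior_gaps(rs, lo, hi))
        report.type5.extend(_interior_gaps(ps, lo, hi))
        if mt.relation == "complex":
            report.complex_components += 1
    return report


def error_histograms(
    report: ErrorReport, bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES
) -> dict[str, np.ndarray]:
    """Bin per-type durations/shifts/interval lengths.

    ``bin_edges`` (e1, ..., ek) define the bins (-inf, e1), [e1, e2), ...,
    [ek, inf); the defaults 10/30/40/60 frames are the thresholds commonly
    used to stratify short/medium/long trains and intervals at 30 fps.
    """
    edges = np.asarray(bin_edges)

    def binned(values) -> np.ndarray:
        counts = np.zeros(len(edges) + 1, dtype=np.int64)
        for v in values:
            counts[int(np.searchsorted(edges, v, side="right"))] += 1
        return counts

    return {
        "bin_edges": edges,
        "type1_duration": binned([d for _, d, _ in report.type1]),
        "type2_duration": binned([d for _, d in report.type2]),
        "type3_start_shift": binned([s for s, _ in report.type3]),
        "type3_end_shift": binned([e for _, e in report.type3]),
        "type4_interval": binned(report.type4),
        "type5_interval": binned(report.type5),
    }
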