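"""Reference-annotation fusion: gold-truth merging and silver-truth creation.

Gold truth merges three expert annotations by per-marker majority voting.
Silver truth fuses the instance masks of several high-performing automatic
methods, driven by the detection markers: for every marker the candidate
segments covering a strict majority of the marker are collected and fused
pixel-wise.  The original algorithm keeps pixels voted by more than
two-thirds of the collected segments and resolves collisions between
inserted segments by the percentage-of-intersection-pixels (PoIP) rule;
the modified algorithm optimises the voting threshold per video against
the gold segmentation reference, falls back to the best-performing
method's segment when too few are collected, and resolves collisions with
a marker-based watershed that produces touching segments.

Because every output segment is generated from exactly one detection
marker, a fused silver truth can miss cells but can never invent one — its
detection score degrades only through false negatives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .errors import GeometryError, UndefinedMeasureError
from .io_ctc import LabeledFrame, TrackedAnnotation, compile_annotation, table_from_frames
from .matching import overlap_matrix
from .measures_technical import (
    AOGMWeights,
    aogm_detection,
    det_measure,
    seg_measure,
)


@dataclass(frozen=True)
class FusionConfig:
    vote_mode: str = "fixed-two-thirds"  # or "optimized-per-video"
    poip_clear_threshold: float = 0.10  # original variant: clear vs remove
    poip_marker_threshold: float = 0.20  # modified variant: seed choice
    fallback_best_performer: bool = True
    min_inputs: int = 1

    def __post_init__(self) -> None:
        for th in (self.poip_clear_threshold, self.poip_marker_threshold):
            if not 0.0 < th < 1.0:
                raise ValueError(f"PoIP threshold {th} outside (0, 1)")
        if self.min_inputs < 1:
            raise ValueError("min_inputs must be >= 1")


@dataclass
class FusedSegment:
    """Provenance of one output segment (or one skipped marker)."""

    marker: int
    size: int
    n_collected: int
    vote_count: int  # strongest pixel-vote inside the emitted component
    poip: float = 0.0  # percent of the segment's original size lost to collisions
    resolution: str = "none"  # none|pixels-cleared|removed|watershed-split|fallback


@dataclass
class FusionResult:
    frames: list[LabeledFrame]
    segments: list[FusedSegment] = field(default_factory=list)
    skipped_markers: list[tuple[int, int]] = field(default_factory=list)
    threshold: Fraction = Fraction(2, 3)

    @property
    def annotation(self) -> TrackedAnnotation:
        """Segmentation-only view compiled leniently (labels = marker ids)."""
        return compile_annotation(
            self.frames, table_from_frames(self.frames), strict=False
        )


def _collect(
    marker_px: np.ndarray, marker: int, candidate_frames: Sequence[LabeledFrame]
) -> list[tuple[int, np.ndarray]]:
    """Per candidate, the segment covering a strict majority of the marker."""
    mask = marker_px == marker
    size = int(mask.sum())
    out = []
    for k, cf in enumerate(candidate_frames):
        labs, counts = np.unique(cf.pixels[mask], return_counts=True)
        keep = labs > 0
        labs, counts = labs[keep], counts[keep]
        if len(labs):
            j = int(np.argmax(counts))
            if counts[j] * 2 > size:
                out.append((k, cf.pixels == labs[j]))
    return out


def _vote(
    collected: list[tuple[int, np.ndarray]], threshold: Fraction
) -> np.ndarray:
    """Pixels voted by strictly more than ``threshold`` of the collected
    segments, reduced to the largest connected component."""
    votes = np.zeros(collected[0][1].shape, dtype=np.int32)
    for _, seg in collected:
        votes += seg
    n = len(collected)
    kept = votes * threshold.denominator > threshold.numerator * n
    if not kept.any():
        return kept
    comp = cc_label(kept, connectivity=1)
    sizes = np.bincount(comp.ravel())
    sizes[0] = 0
    return comp == int(np.argmax(sizes))


def fuse_frame_original(
    marker_frame: LabeledFrame,
    candidate_frames: Sequence[LabeledFrame],
    config: FusionConfig = FusionConfig(),
) -> tuple[LabeledFrame, list[FusedSegment]]:
    """One frame of the original fusion algorithm (two-thirds vote + PoIP).

    Markers are processed in ascending id order.  A marker with fewer than
    ⌈(2/3)·K⌉ collected segments emits nothing.  After each insertion,
    every segment involved in a pixel collision is either cleared of its
    intersection pixels (PoIP ≤ 10 %) or removed entirely (PoIP > 10 %).
    """
    K = len(candidate_frames)
    if K < config.min_inputs:
        raise ValueError(f"need at least {config.min_inputs} candidate results")
    for cf in candidate_frames:
        if cf.pixels.shape != marker_frame.pixels.shape:
            raise GeometryError("candidate/marker geometry mismatch")
    out = np.zeros_like(marker_frame.pixels, dtype=np.uint16)
    orig_size: dict[int, int] = {}
    records: dict[int, FusedSegment] = {}
    skipped: list[tuple[int, int]] = []
    need = math.ceil(2 * K / 3)
    for marker in map(int, marker_frame.labels):
        collected = _collect(marker_frame.pixels, marker, candidate_frames)
        if len(collected) < need:
            skipped.append((marker_frame.frame_index, marker))
            continue
        kept = _vote(collected, Fraction(2, 3))
        if not kept.any():
            skipped.append((marker_frame.frame_index, marker))
            continue
        rec = FusedSegment(
            marker=marker,
            size=int(kept.sum()),
            n_collected=len(collected),
            vote_count=int(
                max(sum(seg for _, seg in collected)[kept].max(), 0)
            ),
        )
        orig_size[marker] = rec.size
        records[marker] = rec
        poip_insert(out, kept, marker, orig_size, records, config.poip_clear_threshold)
    frame = LabeledFrame(out, frame_index=marker_frame.frame_index)
    return frame, [records[m] for m in sorted(records)]


def poip_insert(
    out: np.ndarray,
    new_mask: np.ndarray,
    new_label: int,
    orig_size: dict[int, int],
    records: dict[int, FusedSegment],
    clear_threshold: float = 0.10,
) -> None:
    """Insert a segment, applying the PoIP collision rule in place.

    Every segment involved in a pixel collision — previously inserted ones
    and the new one alike — is judged by the percentage of its original
    size that the intersection represents: above the threshold the whole
    segment is removed, otherwise only its intersection pixels are
    cleared.  Contested pixels therefore never survive."""
    inter = new_mask & (out > 0)
    if not inter.any():
        out[new_mask] = new_label
        return
    for s in (int(v) for v in np.unique(out[inter])):
        inter_s = inter & (out == s)
        poip = 100.0 * inter_s.sum() / orig_size[s]
        records[s].poip = max(records[s].poip, poip)
        if poip > 100.0 * clear_threshold:
            out[out == s] = 0
            records[s].resolution = "removed"
        else:
            out[inter_s] = 0
            records[s].resolution = "pixels-cleared"
    poip_new = 100.0 * inter.sum() / orig_size[new_label]
    records[new_label].poip = poip_new
    if poip_new > 100.0 * clear_threshold:
        records[new_label].resolution = "removed"
    else:
        records[new_label].resolution = "pixels-cleared"
        out[new_mask & ~inter] = new_label


def fuse_video_original(
    markers: Sequence[LabeledFrame],
    candidates: Sequence[Sequence[LabeledFrame]],
    config: FusionConfig = FusionConfig(),
) -> FusionResult:
    """Original fusion applied frame by frame.

    ``candidates[k]`` is the k-th method's full frame sequence.
    """
    result = FusionResult(frames=[], threshold=Fraction(2, 3))
    for t, mf in enumerate(markers):
        frame, recs = fuse_frame_original(mf, [c[t] for c in candidates], config)
        result.frames.append(frame)
        result.segments.extend(recs)
    return result


# ---------------------------------------------------------------------------
# modified variant


def _watershed_resolve(
    out: np.ndarray,
    new_mask: np.ndarray,
    new_label: int,
    marker_px: np.ndarray,
    orig_masks: dict[int, np.ndarray],
    poip_marker_threshold: float,
    records: dict[int, FusedSegment],
) -> None:
    """Split colliding segments into touching ones by marker-based watershed.

    Each involved segment seeds the watershed with its own pixels minus the
    contested ones (PoIP ≤ 20 %) or with its detection marker (PoIP > 20 %);
    the watershed then partitions the union of the involved segments.
    """
    inter = new_mask & (out > 0)
    involved = [int(v) for v in np.unique(out[inter])] + [new_label]
    union = new_mask.copy()
    for s in involved[:-1]:
        union |= out == s
    seeds = np.zeros_like(out, dtype=np.int32)
    for s in involved:
        body = new_mask if s == new_label else (out == s)
        inter_s = body & inter if s == new_label else (body & new_mask)
        poip = 100.0 * inter_s.sum() / max(orig_masks[s].sum(), 1)
        if s in records:
            records[s].poip = max(records[s].poip, poip)
            records[s].resolution = "watershed-split"
        if poip <= 100.0 * poip_marker_threshold and (body & ~inter_s).any():
            seeds[body & ~inter_s] = s
        else:
            seeds[marker_px == s] = s
    dist = ndimage.distance_transform_edt(union)
    labels = watershed(-dist, markers=seeds, mask=union)
    for s in involved:
        out[out == s] = 0
    for s in involved:
        out[labels == s] = s


def fuse_video_with_threshold(
    markers: Sequence[LabeledFrame],
    candidates: Sequence[Sequence[LabeledFrame]],
    threshold: Fraction,
    config: FusionConfig = FusionConfig(),
    ranking: Sequence[int] | None = None,
) -> FusionResult:
    """Modified fusion at a fixed voting threshold.

    ``ranking`` orders candidate indices from best- to worst-performing and
    drives the single-best fallback when fewer segments are collected than
    the per-object threshold ⌈threshold·K⌉.
    """
    K = len(candidates)
    if ranking is None:
        ranking = list(range(K))
    rank_of = {k: i for i, k in enumerate(ranking)}
    need = math.ceil(threshold * K)
    result = FusionResult(frames=[], threshold=threshold)
    for t, mf in enumerate(markers):
        cand_frames = [c[t] for c in candidates]
        out = np.zeros_like(mf.pixels, dtype=np.uint16)
        orig_masks: dict[int, np.ndarray] = {}
        records: dict[int, FusedSegment] = {}
        for marker in map(int, mf.labels):
            collected = _collect(mf.pixels, marker, cand_frames)
            if not collected:
                result.skipped_markers.append((t, marker))
                continue
            if len(collected) < need:
                if not config.fallback_best_performer:
                    result.skipped_markers.append((t, marker))
                    continue
                best = min(collected, key=lambda kc: rank_of[kc[0]])
                kept = best[1]
                resolution = "fallback"
            else:
                kept = _vote(collected, threshold)
                if not kept.any():
                    result.skipped_markers.append((t, marker))
                    continue
                resolution = "none"
            rec = FusedSegment(
                marker=marker,
                size=int(kept.sum()),
                n_collected=len(collected),
                vote_count=int(sum(seg for _, seg in collected)[kept].max()),
                resolution=resolution,
            )
            orig_masks[marker] = kept.copy()
            if (kept & (out > 0)).any():
                records[marker] = rec
                _watershed_resolve(
                    out,
                    kept,
                    marker,
                    mf.pixels,
                    orig_masks,
                    config.poip_marker_threshold,
                    records,
                )
                rec.size = int((out == marker).sum())
            else:
                out[kept] = marker
                records[marker] = rec
        result.frames.append(LabeledFrame(out, frame_index=mf.frame_index))
        result.segments.extend(records[m] for m in sorted(records))
    return result


def candidate_thresholds(k: int) -> list[Fraction]:
    """All fractions m/n, n ≤ k, at which the strict-majority vote can flip."""
    fr = {Fraction(m, n) for n in range(1, k + 1) for m in range(n)}
    fr.add(Fraction(2, 3))
    return sorted(fr)


def fuse_video_modified(
    markers: Sequence[LabeledFrame],
    candidates: Sequence[Sequence[LabeledFrame]],
    gold_seg: Sequence[LabeledFrame],
    config: FusionConfig = FusionConfig(vote_mode="optimized-per-video"),
    ranking: Sequence[int] | None = None,
) -> FusionResult:
    """Modified fusion with the voting threshold optimised per video.

    Scans every achievable voting fraction in ascending order, scores each
    fused video against the gold segmentation reference with SEG, and keeps
    the first maximiser (deterministic).
    """
    if not any(len(f.labels) for f in gold_seg):
        raise UndefinedMeasureError("empty gold segmentation reference")
    best: tuple[float, FusionResult] | None = None
    for th in candidate_thresholds(len(candidates)):
        fused = fuse_video_with_threshold(markers, candidates, th, config, ranking)
        try:
            seg, _ = seg_measure(gold_seg, fused.frames)
        except UndefinedMeasureError:
            seg = -1.0
        if best is None or seg > best[0]:
            best = (seg, fused)
    assert best is not None
    return best[1]


# ---------------------------------------------------------------------------
# gold-truth merging


def merge_gold_annotations(
    annotations: Sequence[Sequence[LabeledFrame]],
    markers: Sequence[LabeledFrame],
) -> list[LabeledFrame]:
    """Majority vote over a triplet of manual annotations.

    Per marker, each annotator's majority-overlapping instance is collected;
    pixels present in at least two collected instances form the merged mask
    (largest connected component).  A marker annotated by fewer than two
    annotators yields no gold mask.
    """
    if len(annotations) != 3:
        raise ValueError(f"expected exactly 3 manual annotations, got {len(annotations)}")
    out_frames: list[LabeledFrame] = []
    for t, mf in enumerate(markers):
        cand = [ann[t] for ann in annotations]
        out = np.zeros_like(mf.pixels, dtype=np.uint16)
        for marker in map(int, mf.labels):
            collected = _collect(mf.pixels, marker, cand)
            if len(collected) < 2:
                continue
            votes = sum(seg.astype(np.int32) for _, seg in collected)
            kept = votes >= 2
            if not kept.any():
                continue
            comp = cc_label(kept, connectivity=1)
            sizes = np.bincount(comp.ravel())
            sizes[0] = 0
            kept = comp == int(np.argmax(sizes))
            out[kept & (out == 0)] = marker  # earlier marker keeps contested px
        out_frames.append(LabeledFrame(out, frame_index=mf.frame_index))
    return out_frames


# ---------------------------------------------------------------------------
# input selection and silver-truth scoring


@dataclass(frozen=True)
class CandidateReport:
    """One method's scores on the training and test splits."""

    name: str
    seg_train: float
    det_train: float
    seg_test: float
    det_test: float

    @property
    def mean_score(self) -> float:
        return (self.seg_train + self.det_train + self.seg_test + self.det_test) / 4


def select_fusion_inputs(
    candidates: Sequence[CandidateReport],
    human_seg_mean: float,
    human_det_mean: float,
    max_inputs: int = 16,
) -> tuple[list[CandidateReport], list[str]]:
    """Keep methods whose SEG and DET exceed half the human mean on both
    splits; at most ``max_inputs`` best by mean score.  Returns the
    selection (best first) and any warnings."""
    qualified = [
        c
        for c in candidates
        if c.seg_train > 0.5 * human_seg_mean
        and c.seg_test > 0.5 * human_seg_mean
        and c.det_train > 0.5 * human_det_mean
        and c.det_test > 0.5 * human_det_mean
    ]
    qualified.sort(key=lambda c: (-c.mean_score, c.name))
    warnings = []
    if len(qualified) < 5:
        warnings.append(
            f"only {len(qualified)} submissions met the quality threshold; "
            "silver truth is historically skipped below 5"
        )
    return qualified[:max_inputs], warnings


def score_silver(
    silver: Sequence[LabeledFrame],
    gold_seg: Sequence[LabeledFrame],
    gold_det: TrackedAnnotation,
    weights: AOGMWeights = AOGMWeights(),
) -> dict:
    """SEG_ST and DET_ST: the silver truth scored as if it were a submission."""
    seg_st, _ = seg_measure(gold_seg, silver)
    silver_ann = compile_annotation(silver, table_from_frames(silver), strict=False)
    det_res = aogm_detection(gold_det, silver_ann, weights)
    return {
        "SEG_ST": seg_st,
        "DET_ST": det_measure(det_res),
        "n_fp": det_res.n_fp,
        "n_fn": det_res.n_fn,
        "aogm_detection": det_res,
    }
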