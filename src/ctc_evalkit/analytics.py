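"""Annotation-quality reports, human-performance banding, correlation
banding, leaderboards and submission screening.

The three manual annotations behind a gold truth are themselves scored
against the merged gold truth; their mean ± 1 s.d. defines the band of
human-level performance against which algorithm scores are classified.
Associations between measures are summarised by Spearman's rank
correlation with a conventional effect-size banding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import UndefinedMeasureError
from .io_ctc import LabeledFrame, TrackedAnnotation, compile_annotation, table_from_frames
from .measures_technical import (
    AOGMWeights,
    aogm_detection,
    det_measure,
    seg_measure,
)


@dataclass
class MeasurementSet:
    """Per-annotator scores of one measure with their mean and s.d."""

    values: tuple[float, float, float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=0))


@dataclass
class AnnotationQualityReport:
    mseg_gt: MeasurementSet
    mdet_gt: MeasurementSet | None = None
    seg_st: float | None = None
    det_st: float | None = None


def human_band(score: float, human_mean: float, human_sd: float) -> str:
    """Classify a score against the human mean ± 1 s.d. band."""
    if human_sd < 0:
        raise ValueError("standard deviation must be non-negative")
    if abs(score - human_mean) <= human_sd:
        return "at"
    return "above" if score > human_mean else "below"


def annotation_quality(
    panel: Sequence[Sequence[LabeledFrame]],
    gold_seg: Sequence[LabeledFrame],
    gold_det: TrackedAnnotation | None = None,
    weights: AOGMWeights = AOGMWeights(),
) -> AnnotationQualityReport:
    """Score each of three manual annotations against the merged gold truth.

    Each annotation is submitted to the standard measures as if it were a
    participant's result: SEG against the gold segmentation masks and,
    when tracking markers are given, DET against the gold detection truth.
    """
    if len(panel) != 3:
        raise ValueError(f"annotation panel must have 3 members, got {len(panel)}")
    seg_scores = []
    det_scores = []
    for frames in panel:
        seg, _ = seg_measure(gold_seg, frames)
        seg_scores.append(seg)
        if gold_det is not None:
            ann = compile_annotation(frames, table_from_frames(frames), strict=False)
            det_scores.append(det_measure(aogm_detection(gold_det, ann, weights)))
    return AnnotationQualityReport(
        mseg_gt=MeasurementSet(tuple(seg_scores)),
        mdet_gt=MeasurementSet(tuple(det_scores)) if det_scores else None,
    )


# ---------------------------------------------------------------------------
# correlation banding

#: Left-closed |rho| intervals and their association labels.
_BANDS = (
    (0.0, "very weak"),
    (0.2, "weak"),
    (0.4, "moderate"),
    (0.6, "strong"),
    (0.8, "very strong"),
)


@dataclass
class CorrelationResult:
    rho: float
    band: str
    sign: int

    @property
    def description(self) -> str:
        prefix = "negative " if self.sign < 0 else ""
        return f"{prefix}{self.band}"


def band_of(rho: float) -> str:
    mag = abs(rho)
    label = _BANDS[0][1]
    for lo, name in _BANDS:
        if mag >= lo:
            label = name
    return label


def spearman_band(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (average ranks on ties) with its band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("series must have equal length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedMeasureError("constant series: correlation undefined")
    rho = float(stats.spearmanr(x, y).statistic)
    return CorrelationResult(rho=rho, band=band_of(rho), sign=1 if rho >= 0 else -1)


# ---------------------------------------------------------------------------
# leaderboards and screening


@dataclass(frozen=True)
class LeaderboardRow:
    method: str
    score: float
    rank: int


def assemble_leaderboard(
    scores: dict[str, float],
) -> list[LeaderboardRow]:
    """Rank methods by score, descending; ties break alphabetically."""
    if not scores:
        raise ValueError("at least one method required")
    ordered = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        LeaderboardRow(method=m, score=s, rank=i + 1)
        for i, (m, s) in enumerate(ordered)
    ]


def top3_points(
    per_dataset_scores: dict[str, dict[str, float]],
) -> dict[str, int]:
    """Aggregate 3/2/1 points for each top-1/2/3 occurrence across datasets."""
    points: dict[str, int] = {}
    for scores in per_dataset_scores.values():
        for row in assemble_leaderboard(scores)[:3]:
            points[row.method] = points.get(row.method, 0) + (4 - row.rank)
    return dict(sorted(points.items(), key=lambda kv: (-kv[1], kv[0])))


def screen_submissions(
    reports: dict[str, dict[str, float]],
    human_means: dict[str, float],
    measures: tuple[str, str] = ("SEG", "DET"),
) -> tuple[dict[str, dict[str, float]], list[str]]:
    """Keep submissions scoring above 50 % of human performance on both of
    the task's primary measures (SEG & DET for segmentation benchmarks,
    SEG & TRA for tracking benchmarks)."""
    kept = {
        name: rep
        for name, rep in reports.items()
        if all(rep[m] > 0.5 * human_means[m] for m in measures)
    }
    warnings = []
    if not kept:
        warnings.append("no submission passed the human-performance screen")
    return kept, warnings
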