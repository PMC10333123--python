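"""Biologically inspired tracking measures: CT, TF, BC(i), CCA.

These express what a biologist would ask of a tracking result: how many
cell tracks are reconstructed whole (complete tracks, CT), how much of a
detected track is reconstructed once the cell is found (track fractions,
TF), how reliably division events are recovered within a tolerance of i
frames (branching correctness, BC(i)), and how faithfully the distribution
of cell-cycle lengths — the time between consecutive divisions — is
reproduced (cell cycle accuracy, CCA).  All four live in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import UndefinedMeasureError
from .io_ctc import TrackedAnnotation
from .matching import NodeMatching, match_video


def complete_tracks(
    reference: TrackedAnnotation,
    computed: TrackedAnnotation,
    matching: NodeMatching | None = None,
) -> float:
    """Fraction of reference tracks reconstructed over exactly their span.

    A reference track is complete iff a single computed label matches it in
    every frame from its first to its last appearance and that computed
    track spans exactly the same frames (a computed track running longer
    than the cell's real life is not a faithful reconstruction).
    """
    m = matching if matching is not None else match_video(reference, computed)
    view = m.track_view(reference)
    ref_tracks = _track_spans(reference)
    if not ref_tracks:
        raise UndefinedMeasureError("no reference tracks: CT undefined")
    comp_tracks = _track_spans(computed)
    n_complete = 0
    for lab, (begin, end) in ref_tracks.items():
        per_frame = view.get(lab, {})
        matched = {per_frame.get(t) for t in range(begin, end + 1)}
        if len(matched) == 1:
            (clab,) = matched
            if clab is not None and comp_tracks.get(clab) == (begin, end):
                n_complete += 1
    return n_complete / len(ref_tracks)


def track_fractions(
    reference: TrackedAnnotation,
    computed: TrackedAnnotation,
    matching: NodeMatching | None = None,
) -> float:
    """Mean, over detected reference tracks, of the longest continuously
    matching single-label tracklet divided by the reference track length.

    A track is detected when at least one of its nodes is matched;
    undetected tracks are excluded from the average.
    """
    m = matching if matching is not None else match_video(reference, computed)
    view = m.track_view(reference)
    fractions = []
    for lab, (begin, end) in _track_spans(reference).items():
        per_frame = view.get(lab, {})
        seq = [per_frame.get(t) for t in range(begin, end + 1)]
        if all(c is None for c in seq):
            continue
        best = run = 0
        prev: int | None = None
        for c in seq:
            run = run + 1 if (c is not None and c == prev) else (1 if c is not None else 0)
            prev = c
            best = max(best, run)
        fractions.append(best / len(seq))
    if not fractions:
        raise UndefinedMeasureError("no detected reference tracks: TF undefined")
    return float(np.mean(fractions))


@dataclass(frozen=True)
class DivisionEvent:
    """A mother cell's final node before it splits into daughters."""

    frame: int
    mother: int


def division_events(annotation: TrackedAnnotation) -> list[DivisionEvent]:
    return [DivisionEvent(t, lab) for t, lab in annotation.division_nodes()]


def branching_correctness(
    reference: TrackedAnnotation,
    computed: TrackedAnnotation,
    tolerance: int = 0,
    matching: NodeMatching | None = None,
) -> float:
    """BC(i): F1-style ratio of division events paired within i frames.

    Reference and computed divisions are paired one-to-one, greedily by
    temporal proximity (ties broken toward the earlier computed event),
    subject to the mothers' tracks corresponding under the node matching
    and |t_ref − t_comp| ≤ tolerance.  BC = 2·paired / (n_ref + n_comp),
    and 1 when neither side has any division.
    """
    m = matching if matching is not None else match_video(reference, computed)
    view = m.track_view(reference)
    ref_div = division_events(reference)
    comp_div = division_events(computed)
    if not ref_div and not comp_div:
        return 1.0

    # computed labels ever matched to each reference track
    partners: dict[int, set[int]] = {
        lab: {c for c in per_frame.values() if c is not None}
        for lab, per_frame in view.items()
    }
    candidates = []  # (|dt|, t_comp, ref_idx, comp_idx)
    for i, rd in enumerate(ref_div):
        for j, cd in enumerate(comp_div):
            dt = abs(rd.frame - cd.frame)
            if dt <= tolerance and cd.mother in partners.get(rd.mother, ()):
                candidates.append((dt, cd.frame, rd.frame, i, j))
    used_ref: set[int] = set()
    used_comp: set[int] = set()
    paired = 0
    for _, _, _, i, j in sorted(candidates):
        if i not in used_ref and j not in used_comp:
            used_ref.add(i)
            used_comp.add(j)
            paired += 1
    return 2.0 * paired / (len(ref_div) + len(comp_div))


def cell_cycle_lengths(annotation: TrackedAnnotation) -> list[int]:
    """Lengths (in frames) of complete cell cycles.

    A track contributes a complete cycle when it is born in a division (has
    a parent) and itself ends in a division; the length is its frame count.
    """
    dividing = {lab for _, lab in annotation.division_nodes()}
    spans = _track_spans(annotation)
    lengths = []
    for r in annotation.table:
        if r.parent and r.label in dividing and r.label in spans:
            begin, end = spans[r.label]
            lengths.append(end - begin + 1)
    return lengths


def cdf_sup_gap(a: list[int] | np.ndarray, b: list[int] | np.ndarray) -> float:
    """Kolmogorov–Smirnov sup-distance between two empirical CDFs."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    grid = np.union1d(a, b)
    fa = np.searchsorted(a, grid, side="right") / len(a)
    fb = np.searchsorted(b, grid, side="right") / len(b)
    return float(np.max(np.abs(fa - fb)))


def cell_cycle_accuracy(
    reference: TrackedAnnotation, computed: TrackedAnnotation
) -> float:
    """CCA = 1 − sup|F_ref − F_comp| over complete-cycle length CDFs.

    Undefined (raises) when either annotation contains no complete cycle —
    the published tables leave CCA blank for such videos.
    """
    ref_lengths = cell_cycle_lengths(reference)
    comp_lengths = cell_cycle_lengths(computed)
    if not ref_lengths or not comp_lengths:
        raise UndefinedMeasureError(
            "no complete cell cycle on one side: CCA not applicable"
        )
    return 1.0 - cdf_sup_gap(ref_lengths, comp_lengths)


@dataclass
class BioMeasureReport:
    ct: float
    tf: float
    bc: dict[int, float] = field(default_factory=dict)
    cca: float | None = None
    n_reference_tracks: int = 0
    n_reference_divisions: int = 0


def evaluate_biological(
    reference: TrackedAnnotation,
    computed: TrackedAnnotation,
    bc_tolerances: tuple[int, ...] = (0, 1, 2, 3),
) -> BioMeasureReport:
    """CT, TF, BC(i) for the requested tolerances, and CCA when defined."""
    m = match_video(reference, computed)
    try:
        cca: float | None = cell_cycle_accuracy(reference, computed)
    except UndefinedMeasureError:
        cca = None
    return BioMeasureReport(
        ct=complete_tracks(reference, computed, matching=m),
        tf=track_fractions(reference, computed, matching=m),
        bc={i: branching_correctness(reference, computed, i, matching=m) for i in bc_tolerances},
        cca=cca,
        n_reference_tracks=len(_track_spans(reference)),
        n_reference_divisions=len(division_events(reference)),
    )


def _track_spans(annotation: TrackedAnnotation) -> dict[int, tuple[int, int]]:
    """Observed (first, last) frame of each track from the pixel data."""
    spans: dict[int, tuple[int, int]] = {}
    for t, lab in annotation.graph.nodes:
        b, e = spans.get(lab, (t, t))
        spans[lab] = (min(b, t), max(e, t))
    return spans
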