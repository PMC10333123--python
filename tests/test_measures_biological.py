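"""CT, TF, BC(i), CCA: verbal definitions pinned by constructed lineages."""

import numpy as np
import pytest
from scipy import stats

from ctc_evalkit.errors import UndefinedMeasureError
from ctc_evalkit.io_ctc import TrackRecord, compile_annotation
from ctc_evalkit.measures_biological import (
    branching_correctness,
    cdf_sup_gap,
    cell_cycle_accuracy,
    complete_tracks,
    evaluate_biological,
    track_fractions,
)
from ctc_evalkit.synthetic import ErrorRequest, corrupt_submission

from conftest import annotation_with_boxes, video_with_boxes

BOX = (4, 8, 4, 8)
BOX2 = (10, 14, 10, 14)


def relabelled_track(n, switch_at=None, new_label=2, drop=()):
    """One cell over n frames, optionally switching computed label mid-way
    or dropping frames; returns a compiled annotation."""
    per_frame = []
    for t in range(n):
        if t in drop:
            per_frame.append({})
        elif switch_at is not None and t >= switch_at:
            per_frame.append({new_label: BOX})
        else:
            per_frame.append({1: BOX})
    from ctc_evalkit.io_ctc import table_from_frames

    frames = video_with_boxes(per_frame)
    return compile_annotation(frames, table_from_frames(frames), strict=False)


class TestCompleteTracks:
    def test_identity_is_fully_complete(self):
        ref = annotation_with_boxes([{1: BOX}] * 4)
        assert complete_tracks(ref, ref) == 1.0

    def test_missing_middle_frame_halves_the_score(self):
        ref = annotation_with_boxes([{1: BOX, 2: BOX2}] * 5)
        comp = relabelled_track(5, drop=(2,))
        # add the intact second track to the computed result
        per_frame = [
            {**({1: BOX} if t != 2 else {}), 2: BOX2} for t in range(5)
        ]
        from ctc_evalkit.io_ctc import table_from_frames

        frames = video_with_boxes(per_frame)
        comp = compile_annotation(frames, table_from_frames(frames), strict=False)
        assert complete_tracks(ref, comp) == 0.5

    def test_computed_track_outliving_the_cell_is_not_complete(self):
        ref_frames = [{1: BOX}] * 3 + [{}] * 2
        ref = compile_annotation(
            video_with_boxes(ref_frames), [TrackRecord(1, 0, 2, 0)]
        )
        comp = annotation_with_boxes([{1: BOX}] * 5)  # 2 extra frames
        assert complete_tracks(ref, comp) == 0.0


class TestTrackFractions:
    def test_identity_is_one(self):
        ref = annotation_with_boxes([{1: BOX}] * 4)
        assert track_fractions(ref, ref) == 1.0

    def test_continuous_seven_of_ten_frames(self):
        ref = annotation_with_boxes([{1: BOX}] * 10)
        comp = relabelled_track(10, drop=(7, 8, 9))
        assert track_fractions(ref, comp) == pytest.approx(0.7)

    def test_label_switch_keeps_longest_single_label_run(self):
        ref = annotation_with_boxes([{1: BOX}] * 10)
        comp = relabelled_track(10, switch_at=4)  # A on 0-3, B on 4-9
        assert track_fractions(ref, comp) == pytest.approx(0.6)

    def test_undetected_tracks_are_excluded(self):
        ref = annotation_with_boxes([{1: BOX, 2: BOX2}] * 4)
        comp = annotation_with_boxes([{1: BOX}] * 4)  # track 2 never detected
        assert track_fractions(ref, comp) == 1.0

    def test_complete_tracks_never_exceed_track_fractions(self, small_scene):
        gold = small_scene.annotation
        for seed in range(4):
            degraded, _ = corrupt_submission(
                gold, ErrorRequest(fn=1, link_del=1), seed=seed
            )
            ct = complete_tracks(gold, degraded)
            tf = track_fractions(gold, degraded)
            assert ct <= tf + 1e-12


def division_annotation(div_frame, n=10, labels=(1, 2, 3)):
    mother, d1, d2 = labels
    per_frame = []
    for t in range(n):
        if t <= div_frame:
            per_frame.append({mother: BOX})
        else:
            per_frame.append({d1: (2, 5, 2, 5), d2: (8, 11, 8, 11)})
    table = [
        TrackRecord(mother, 0, div_frame, 0),
        TrackRecord(d1, div_frame + 1, n - 1, mother),
        TrackRecord(d2, div_frame + 1, n - 1, mother),
    ]
    return compile_annotation(video_with_boxes(per_frame), table)


class TestBranchingCorrectness:
    def test_identical_divisions_score_one_at_any_tolerance(self):
        ann = division_annotation(4)
        for i in range(4):
            assert branching_correctness(ann, ann, i) == 1.0

    def test_one_frame_offset_needs_tolerance_one(self):
        ref = division_annotation(5)
        comp = division_annotation(6)
        assert branching_correctness(ref, comp, 0) == 0.0
        assert branching_correctness(ref, comp, 1) == 1.0

    def test_f1_style_ratio_with_unpaired_reference_division(self):
        # two reference divisions, computed reports only one (paired)
        per_frame = []
        for t in range(10):
            d = {}
            d.update({1: (1, 4, 1, 4)} if t <= 4 else {2: (0, 2, 0, 2), 3: (3, 5, 3, 5)})
            d.update({4: (8, 11, 8, 11)} if t <= 6 else {5: (7, 9, 7, 9), 6: (10, 12, 10, 12)})
            per_frame.append(d)
        table = [
            TrackRecord(1, 0, 4, 0),
            TrackRecord(2, 5, 9, 1),
            TrackRecord(3, 5, 9, 1),
            TrackRecord(4, 0, 6, 0),
            TrackRecord(5, 7, 9, 4),
            TrackRecord(6, 7, 9, 4),
        ]
        ref = compile_annotation(video_with_boxes(per_frame), table)
        # computed merges the second family into one undivided track
        comp_frames = []
        for t in range(10):
            d = {1: (1, 4, 1, 4)} if t <= 4 else {2: (0, 2, 0, 2), 3: (3, 5, 3, 5)}
            d[4] = (8, 11, 8, 11) if t <= 6 else (7, 12, 7, 12)
            comp_frames.append(dict(d))
        comp_table = [
            TrackRecord(1, 0, 4, 0),
            TrackRecord(2, 5, 9, 1),
            TrackRecord(3, 5, 9, 1),
            TrackRecord(4, 0, 9, 0),
        ]
        comp = compile_annotation(video_with_boxes(comp_frames, shape=(16, 16)), comp_table)
        assert branching_correctness(ref, comp, 1) == pytest.approx(2 / 3)

    def test_non_decreasing_in_tolerance(self):
        ref = division_annotation(3)
        comp = division_annotation(6)
        values = [branching_correctness(ref, comp, i) for i in range(5)]
        assert values == sorted(values)


class TestCellCycleAccuracy:
    def two_generation_annotation(self, first_cycle_len, n=None):
        """grandmother divides at 0; mother lives first_cycle_len frames then
        divides; granddaughters run to the end."""
        div2 = first_cycle_len  # mother spans frames 1..first_cycle_len
        n = n or div2 + 4
        per_frame = []
        for t in range(n):
            if t < 1:
                per_frame.append({1: BOX})
            elif t <= div2:
                per_frame.append({2: (2, 5, 2, 5), 3: (8, 11, 8, 11)})
            else:
                per_frame.append(
                    {3: (8, 11, 8, 11), 4: (1, 3, 1, 3), 5: (4, 6, 4, 6)}
                )
        table = [
            TrackRecord(1, 0, 0, 0),
            TrackRecord(2, 1, div2, 1),
            TrackRecord(3, 1, n - 1, 1),
            TrackRecord(4, div2 + 1, n - 1, 2),
            TrackRecord(5, div2 + 1, n - 1, 2),
        ]
        return compile_annotation(video_with_boxes(per_frame), table)

    def test_identical_cycles_score_one(self):
        ann = self.two_generation_annotation(5)
        assert cell_cycle_accuracy(ann, ann) == 1.0

    def test_disjoint_cycle_lengths_score_zero(self):
        ref = self.two_generation_annotation(10)
        comp = self.two_generation_annotation(20)
        assert cell_cycle_accuracy(ref, comp) == 0.0

    def test_no_complete_cycle_is_not_applicable(self):
        ref = self.two_generation_annotation(5)
        comp = annotation_with_boxes([{1: BOX}] * 9)  # no divisions at all
        with pytest.raises(UndefinedMeasureError):
            cell_cycle_accuracy(ref, comp)

    def test_sup_gap_quarter_example(self):
        assert cdf_sup_gap([10, 10, 20, 20], [10, 20, 20, 20]) == pytest.approx(0.25)

    def test_sup_gap_matches_two_sample_ks_statistic(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.integers(5, 30, size=rng.integers(1, 12))
            b = rng.integers(5, 30, size=rng.integers(1, 12))
            expected = stats.ks_2samp(a, b, method="exact").statistic
            assert cdf_sup_gap(a, b) == pytest.approx(expected, abs=1e-12)


class TestDegradationMonotonicity:
    def test_injected_errors_never_raise_any_measure(self, small_scene):
        gold = small_scene.annotation
        base = evaluate_biological(gold, gold)
        for seed in range(3):
            degraded, _ = corrupt_submission(
                gold, ErrorRequest(fn=1, merge=1, link_del=1), seed=seed
            )
            rep = evaluate_biological(gold, degraded)
            assert rep.ct <= base.ct and rep.tf <= base.tf
            for i in rep.bc:
                assert rep.bc[i] <= base.bc[i]
            assert all(0 <= v <= 1 for v in (rep.ct, rep.tf, *rep.bc.values()))
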