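"""Label fusion: consensus recovery, PoIP rules, watershed, silver scoring."""

from fractions import Fraction

import numpy as np
import pytest

from ctc_evalkit.fusion import (
    CandidateReport,
    FusedSegment,
    FusionConfig,
    fuse_frame_original,
    fuse_video_modified,
    fuse_video_original,
    fuse_video_with_threshold,
    merge_gold_annotations,
    poip_insert,
    score_silver,
    select_fusion_inputs,
)
from ctc_evalkit.measures_technical import seg_measure
from ctc_evalkit.synthetic import SceneConfig, generate_scene, make_annotator_panel

from conftest import frame_with_boxes, video_with_boxes


def marker_frame(boxes, shape=(16, 16)):
    return frame_with_boxes(boxes, shape=shape)


class TestOriginalFrameFusion:
    def test_unanimous_candidates_reproduce_the_square(self):
        marker = marker_frame({1: (5, 7, 5, 7)})
        square = {1: (4, 8, 4, 8)}
        fused, recs = fuse_frame_original(marker, [frame_with_boxes(square)] * 4)
        np.testing.assert_array_equal(fused.pixels, frame_with_boxes(square).pixels)
        assert recs[0].n_collected == 4 and recs[0].resolution == "none"

    def test_single_collected_segment_of_three_emits_nothing(self):
        marker = marker_frame({1: (5, 7, 5, 7)})
        candidates = [
            frame_with_boxes({1: (4, 8, 4, 8)}),
            frame_with_boxes({}),
            frame_with_boxes({}),
        ]
        fused, recs = fuse_frame_original(marker, candidates)
        assert not fused.pixels.any() and recs == []

    def test_strict_two_thirds_pixel_vote(self):
        # 3 collected segments: pixels voted by exactly 2 are dropped (2 !> 2)
        marker = marker_frame({1: (5, 7, 5, 7)})
        candidates = [
            frame_with_boxes({1: (4, 8, 4, 8)}),
            frame_with_boxes({1: (4, 8, 4, 8)}),
            frame_with_boxes({1: (4, 8, 4, 7)}),  # misses column 7
        ]
        fused, _ = fuse_frame_original(marker, candidates)
        np.testing.assert_array_equal(
            fused.pixels, frame_with_boxes({1: (4, 8, 4, 7)}).pixels
        )

    def test_consensus_recovery_with_silent_minority(self):
        # ceil(2/3 * 6) = 4 identical inputs, 2 producing nothing -> exact mask
        marker = marker_frame({1: (5, 7, 5, 7)})
        square = {1: (4, 8, 4, 8)}
        candidates = [frame_with_boxes(square)] * 4 + [frame_with_boxes({})] * 2
        fused, _ = fuse_frame_original(marker, candidates)
        np.testing.assert_array_equal(fused.pixels, frame_with_boxes(square).pixels)


class TestPoipRule:
    def build(self, size_a, size_b, shared):
        """Two 1-px-high horizontal strips overlapping in `shared` pixels."""
        out = np.zeros((4, 200), np.uint16)
        a = np.zeros_like(out, bool)
        b = np.zeros_like(out, bool)
        a[0, :size_a] = True
        b[0, size_a - shared : size_a - shared + size_b] = True
        records = {
            1: FusedSegment(1, size_a, 3, 3),
            2: FusedSegment(2, size_b, 3, 3),
        }
        sizes = {1: size_a, 2: size_b}
        poip_insert(out, a, 1, sizes, records)
        poip_insert(out, b, 2, sizes, records)
        return out, records

    def test_five_percent_clears_pixels_only(self):
        out, recs = self.build(100, 100, 5)
        assert recs[1].resolution == "pixels-cleared" and recs[1].poip == 5.0
        assert (out == 1).sum() == 95  # lost exactly the contested pixels

    def test_above_ten_percent_removes_the_segment(self):
        out, recs = self.build(100, 40, 5)
        assert recs[1].poip == 5.0 and recs[1].resolution == "pixels-cleared"
        assert recs[2].poip == 12.5 and recs[2].resolution == "removed"
        assert (out == 2).sum() == 0 and (out == 1).sum() == 95

    def test_exactly_ten_percent_is_kept(self):
        out, recs = self.build(100, 40, 4)  # 4/40 = 10 % -> not > 10 %
        assert recs[2].resolution == "pixels-cleared"
        assert (out == 2).sum() == 36

    def test_contested_pixels_never_survive(self):
        out, _ = self.build(100, 100, 8)
        assert (out > 0).sum() == 2 * (100 - 8)


class TestModifiedFusion:
    def fixture(self, seed=0):
        scene = generate_scene(
            SceneConfig(
                seed=seed,
                shape=(72, 72),
                n_initial_cells=4,
                radius_range=(5.0, 7.0),
                n_frames=3,
                division_prob=0.0,
            )
        )
        candidates = make_annotator_panel(scene.annotation, jitter_px=1, seed=seed + 100)
        candidates.append([f for f in scene.annotation.frames])
        return scene, candidates

    def test_optimized_threshold_never_scores_below_fixed_two_thirds(self):
        for seed in range(3):
            scene, candidates = self.fixture(seed)
            fixed = fuse_video_original(scene.markers.frames, candidates)
            seg_fixed, _ = seg_measure(scene.annotation.frames, fixed.frames)
            optimized = fuse_video_modified(
                scene.markers.frames, candidates, scene.annotation.frames
            )
            seg_opt, _ = seg_measure(scene.annotation.frames, optimized.frames)
            assert seg_opt >= seg_fixed - 1e-12

    def test_unanimous_candidates_pick_lowest_threshold(self):
        scene, _ = self.fixture()
        candidates = [[f for f in scene.annotation.frames] for _ in range(3)]
        fused = fuse_video_modified(
            scene.markers.frames, candidates, scene.annotation.frames
        )
        assert fused.threshold == Fraction(0, 1)

    def test_fallback_uses_best_ranked_method(self):
        marker = marker_frame({1: (5, 7, 5, 7)})
        best = frame_with_boxes({1: (4, 8, 4, 8)})
        candidates = [[best], [frame_with_boxes({})], [frame_with_boxes({})]]
        fused = fuse_video_with_threshold(
            [marker], candidates, Fraction(2, 3), ranking=[0, 1, 2]
        )
        np.testing.assert_array_equal(fused.frames[0].pixels, best.pixels)
        assert fused.segments[0].resolution == "fallback"

    def test_watershed_splits_collisions_into_touching_segments(self):
        # two markers whose candidate proposals overlap heavily
        marker = marker_frame({1: (6, 8, 4, 6), 2: (6, 8, 10, 12)})
        merged = frame_with_boxes({1: (4, 10, 2, 14)})  # one blob spans both
        candidates = [[merged], [merged], [merged]]
        fused = fuse_video_with_threshold(
            [marker], candidates, Fraction(0, 1)
        )
        px = fused.frames[0].pixels
        union = frame_with_boxes({1: (4, 10, 2, 14)}).pixels > 0
        assert set(np.unique(px[union])) == {1, 2}  # both survive, disjoint
        assert not (px[~union]).any()
        assert np.array_equal(px > 0, union)  # watershed covers the union

    def test_output_frames_are_disjoint_label_images(self):
        for seed in range(3):
            scene, candidates = self.fixture(seed)
            fused = fuse_video_modified(
                scene.markers.frames, candidates, scene.annotation.frames
            )
            for f in fused.frames:
                assert f.pixels.dtype.kind == "u"  # one label per pixel by type


class TestGoldMerging:
    def test_identical_triplet_returns_identical_masks(self):
        square = video_with_boxes([{1: (4, 8, 4, 8)}])
        markers = video_with_boxes([{1: (5, 7, 5, 7)}])
        merged = merge_gold_annotations([square, square, square], markers)
        np.testing.assert_array_equal(merged[0].pixels, square[0].pixels)

    def test_majority_pixels_win_over_an_offset_annotator(self):
        a = video_with_boxes([{1: (4, 8, 4, 8)}])
        b = video_with_boxes([{1: (4, 8, 4, 8)}])
        c = video_with_boxes([{1: (4, 8, 6, 10)}])  # shifted by half
        markers = video_with_boxes([{1: (5, 7, 5, 7)}])
        merged = merge_gold_annotations([a, b, c], markers)
        np.testing.assert_array_equal(merged[0].pixels, a[0].pixels)

    def test_marker_annotated_by_one_annotator_yields_no_mask(self):
        a = video_with_boxes([{1: (4, 8, 4, 8)}])
        empty = video_with_boxes([{}])
        markers = video_with_boxes([{1: (5, 7, 5, 7)}])
        merged = merge_gold_annotations([a, empty, empty], markers)
        assert not merged[0].pixels.any()

    def test_cell_missed_by_one_annotator_is_still_recovered(self, small_scene):
        gold = small_scene.annotation
        lab = int(gold.frames[0].labels[0])
        panel = make_annotator_panel(
            gold, jitter_px=0, misses=({(0, lab)}, set(), set()), seed=1
        )
        merged = merge_gold_annotations(panel, small_scene.markers.frames)
        assert (merged[0].pixels == lab).any()


class TestSilverScoring:
    def test_silver_truth_has_no_false_positives(self):
        rng_seeds = range(8)
        for seed in rng_seeds:
            scene = generate_scene(
                SceneConfig(
                    seed=seed, shape=(64, 64), n_initial_cells=4,
                    radius_range=(4.0, 6.0), n_frames=3, division_prob=0.0,
                )
            )
            candidates = make_annotator_panel(scene.annotation, jitter_px=1, seed=seed)
            fused = fuse_video_original(scene.markers.frames, candidates)
            report = score_silver(
                fused.frames, scene.annotation.frames, scene.markers
            )
            assert report["n_fp"] == 0
            assert 0.0 <= report["SEG_ST"] <= 1.0
            assert 0.0 <= report["DET_ST"] <= 1.0

    def test_perfect_silver_scores_one(self, small_scene):
        gold = small_scene.annotation
        report = score_silver(gold.frames, gold.frames, small_scene.markers)
        assert report["SEG_ST"] == 1.0 and report["DET_ST"] == 1.0


class TestInputSelection:
    def reports(self, n, base=0.9):
        return [
            CandidateReport(f"m{i:02d}", base - 0.01 * i, base, base, base)
            for i in range(n)
        ]

    def test_half_human_threshold_excludes_borderline_method(self):
        # human SEG mean 0.9: candidate at 0.44 misses the 0.45 bar
        low = CandidateReport("low", 0.44, 0.9, 0.9, 0.9)
        selected, _ = select_fusion_inputs([low], 0.9, 0.9)
        assert selected == []

    def test_at_most_sixteen_best_kept(self):
        selected, _ = select_fusion_inputs(self.reports(20), 0.9, 0.9)
        assert len(selected) == 16
        assert selected[0].name == "m00"  # best mean score first

    def test_fewer_than_five_triggers_warning(self):
        selected, warnings = select_fusion_inputs(self.reports(3), 0.9, 0.9)
        assert len(selected) == 3
        assert any("less than 5" in w or "5" in w for w in warnings)
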