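"""Shared fixtures: tiny hand-built annotations and seeded synthetic scenes."""

from __future__ import annotations

import numpy as np
import pytest

from ctc_evalkit.io_ctc import (
    LabeledFrame,
    TrackRecord,
    TrackedAnnotation,
    compile_annotation,
)
from ctc_evalkit.synthetic import Scene, SceneConfig, generate_scene


def frame_with_boxes(
    boxes: dict[int, tuple[int, int, int, int]],
    t: int = 0,
    shape: tuple[int, int] = (16, 16),
) -> LabeledFrame:
    """A frame whose instances are axis-aligned boxes (r0, r1, c0, c1), exclusive ends."""
    px = np.zeros(shape, dtype=np.uint16)
    for label, (r0, r1, c0, c1) in boxes.items():
        px[r0:r1, c0:c1] = label
    return LabeledFrame(px, frame_index=t)


def video_with_boxes(
    per_frame: list[dict[int, tuple[int, int, int, int]]],
    shape: tuple[int, int] = (16, 16),
) -> list[LabeledFrame]:
    return [frame_with_boxes(b, t, shape) for t, b in enumerate(per_frame)]


def annotation_with_boxes(
    per_frame: list[dict[int, tuple[int, int, int, int]]],
    table: list[TrackRecord] | None = None,
    shape: tuple[int, int] = (16, 16),
) -> TrackedAnnotation:
    frames = video_with_boxes(per_frame, shape)
    if table is None:
        from ctc_evalkit.io_ctc import table_from_frames

        table = table_from_frames(frames)
    return compile_annotation(frames, table)


def one_cell_annotation(
    n_frames: int, box: tuple[int, int, int, int] = (4, 8, 4, 8)
) -> TrackedAnnotation:
    return annotation_with_boxes([{1: box} for _ in range(n_frames)])


@pytest.fixture(scope="session")
def scene() -> Scene:
    """A mid-sized dividing scene reused across modules (read-only)."""
    return generate_scene(
        SceneConfig(seed=11, division_prob=0.05, n_frames=14, n_initial_cells=6)
    )


@pytest.fixture(scope="session")
def small_scene() -> Scene:
    """A compact scene for repeated corruption runs (read-only)."""
    return generate_scene(
        SceneConfig(
            seed=5,
            shape=(96, 96),
            n_initial_cells=6,
            radius_range=(5.0, 7.0),
            n_frames=8,
            displacement=1.5,
            division_prob=0.06,
        )
    )
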