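"""Reading, writing and validation of tracking-benchmark annotation packages.

An annotation package is a directory of per-frame integer-labelled TIFF
masks (``mask%03d.tif`` for results, ``man_track%03d.tif`` for detection /
tracking markers, ``man_seg%03d.tif`` for segmentation references) plus a
plain-text track table (``res_track.txt`` / ``man_track.txt``) with one
record ``label begin end parent`` per line.  :func:`compile_annotation`
turns the pair into a lineage graph whose nodes are ``(frame, label)``
occurrences, with track-link edges between consecutive frames of one label
and parent edges from a mother's last node to each daughter's first node.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import tifffile

from .errors import (
    AnnotationError,
    FormatError,
    GapError,
    GeometryError,
    TrackTableError,
)

#: Edge attribute values on the lineage graph.
EDGE_TRACK = "track"
EDGE_PARENT = "parent"


@dataclass
class LabeledFrame:
    """One frame of instance labels (0 = background), 2D or 3D."""

    pixels: np.ndarray
    frame_index: int
    spacing: tuple[float, ...] | None = None  # physical size per axis, µm

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise FormatError(
                f"frame {self.frame_index}: labels must be integers, "
                f"got {self.pixels.dtype}"
            )
        if self.pixels.ndim not in (2, 3):
            raise GeometryError(
                f"frame {self.frame_index}: expected 2D or 3D, got "
                f"{self.pixels.ndim}D"
            )
        if self.pixels.size and self.pixels.min() < 0:
            raise FormatError(f"frame {self.frame_index}: negative label values")

    @property
    def labels(self) -> np.ndarray:
        """Sorted positive labels present in this frame."""
        u = np.unique(self.pixels)
        return u[u > 0]

    def mask(self, label: int) -> np.ndarray:
        return self.pixels == label


@dataclass(frozen=True)
class TrackRecord:
    """One row of a track table: a label's frame span and its parent."""

    label: int
    begin: int
    end: int
    parent: int = 0

    def __post_init__(self) -> None:
        if self.label <= 0:
            raise TrackTableError(f"label must be positive, got {self.label}")
        if self.begin > self.end:
            raise TrackTableError(
                f"track {self.label}: begin {self.begin} > end {self.end}"
            )
        if self.parent == self.label:
            raise TrackTableError(f"track {self.label} is its own parent")
        if self.parent < 0:
            raise TrackTableError(f"track {self.label}: negative parent")


@dataclass
class TrackedAnnotation:
    """Label frames + track table compiled into a lineage graph.

    Graph nodes are ``(frame_index, label)`` pairs for every occurrence of a
    tracked label in the pixel data.  Edges carry a ``kind`` attribute:
    ``"track"`` links consecutive frames of one label, ``"parent"`` links a
    mother's last node to a daughter's first node (and may skip frames).
    """

    frames: list[LabeledFrame]
    table: list[TrackRecord]
    graph: nx.DiGraph
    coverage_gaps: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def record(self, label: int) -> TrackRecord:
        return self._by_label[label]

    @property
    def _by_label(self) -> dict[int, TrackRecord]:
        return {r.label: r for r in self.table}

    def nodes_of_track(self, label: int) -> list[tuple[int, int]]:
        """Graph nodes of one track in frame order."""
        return sorted(n for n in self.graph.nodes if n[1] == label)

    def division_nodes(self) -> list[tuple[int, int]]:
        """Mother nodes: nodes with >= 2 outgoing parent edges."""
        out = []
        for n in self.graph.nodes:
            k = sum(
                1
                for _, _, d in self.graph.out_edges(n, data=True)
                if d["kind"] == EDGE_PARENT
            )
            if k >= 2:
                out.append(n)
        return sorted(out)


# ---------------------------------------------------------------------------
# readers / writers


def _frame_number(name: str, stem: str) -> int | None:
    m = re.fullmatch(re.escape(stem) + r"(\d{3,4})\.tif{1,2}", name)
    return int(m.group(1)) if m else None


def read_label_sequence(
    directory: str | Path, name_pattern: str = "mask%03d.tif"
) -> list[LabeledFrame]:
    """Read a directory of per-frame label TIFFs into ascending frame order.

    ``name_pattern`` is a printf-style pattern such as ``"mask%03d.tif"``;
    4-digit padding is auto-detected when no 3-digit file matches.  The
    numbered range must be contiguous.
    """
    directory = Path(directory)
    stem = name_pattern.split("%")[0]
    found: dict[int, Path] = {}
    for p in sorted(directory.iterdir()):
        n = _frame_number(p.name, stem)
        if n is not None:
            if n in found:
                raise FormatError(f"duplicate frame number {n} in {directory}")
            found[n] = p
    if not found:
        raise FileNotFoundError(f"no files matching {stem}NNN.tif in {directory}")
    indices = sorted(found)
    lo, hi = indices[0], indices[-1]
    missing = sorted(set(range(lo, hi + 1)) - set(indices))
    if missing:
        raise GapError(
            f"missing frame(s) {missing} in {directory} (range {lo}..{hi})"
        )
    frames: list[LabeledFrame] = []
    shape = None
    for i in indices:
        px = tifffile.imread(found[i])
        if not np.issubdtype(np.asarray(px).dtype, np.integer):
            raise FormatError(f"{found[i].name}: non-integer pixel type {px.dtype}")
        if shape is None:
            shape = px.shape
        elif px.shape != shape:
            raise GeometryError(
                f"{found[i].name}: shape {px.shape} inconsistent with {shape}"
            )
        frames.append(LabeledFrame(px, frame_index=i))
    return frames


def write_label_sequence(
    frames: Sequence[LabeledFrame],
    directory: str | Path,
    name_pattern: str = "mask%03d.tif",
    dtype=np.uint16,
) -> None:
    """Write frames as per-frame TIFFs; inverse of :func:`read_label_sequence`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    limit = np.iinfo(dtype).max
    for f in frames:
        if f.pixels.size and f.pixels.max() > limit:
            raise FormatError(
                f"frame {f.frame_index}: label {f.pixels.max()} exceeds "
                f"{np.dtype(dtype).name} range"
            )
        tifffile.imwrite(
            directory / (name_pattern % f.frame_index),
            f.pixels.astype(dtype),
        )


def read_track_file(path: str | Path) -> list[TrackRecord]:
    """Parse a ``label begin end parent`` track table."""
    path = Path(path)
    records: list[TrackRecord] = []
    seen: set[int] = set()
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise TrackTableError(
                f"{path.name}:{lineno}: expected 4 integers, got {line!r}"
            )
        try:
            label, begin, end, parent = (int(x) for x in parts)
        except ValueError as exc:
            raise TrackTableError(f"{path.name}:{lineno}: {exc}") from exc
        if label in seen:
            raise TrackTableError(f"{path.name}:{lineno}: duplicate label {label}")
        seen.add(label)
        records.append(TrackRecord(label, begin, end, parent))
    _validate_parents(records)
    return records


def _validate_parents(records: Iterable[TrackRecord]) -> None:
    by_label = {r.label: r for r in records}
    for r in by_label.values():
        if r.parent:
            if r.parent not in by_label:
                raise TrackTableError(
                    f"track {r.label}: unknown parent {r.parent}"
                )
            if by_label[r.parent].end >= r.begin:
                raise TrackTableError(
                    f"track {r.label}: parent {r.parent} ends at "
                    f"{by_label[r.parent].end}, not before begin {r.begin}"
                )


def write_track_file(records: Sequence[TrackRecord], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{r.label} {r.begin} {r.end} {r.parent}\n" for r in records)
    )


# ---------------------------------------------------------------------------
# compilation


def compile_annotation(
    frames: Sequence[LabeledFrame],
    table: Sequence[TrackRecord],
    strict: bool = True,
) -> TrackedAnnotation:
    """Build the lineage graph from frames and a track table.

    In strict mode every table span must be fully covered by mask pixels and
    every positive pixel label must appear in the table.  In lenient mode
    (sparse references such as segmentation gold truth) uncovered frames are
    recorded as ``coverage_gaps`` and pixel labels outside the table are
    tolerated.
    """
    frames = list(frames)
    table = list(table)
    _validate_parents(table)
    by_label = {r.label: r for r in table}
    present: dict[int, set[int]] = {}  # label -> frames where it has pixels
    for f in frames:
        for lab in f.labels:
            present.setdefault(int(lab), set()).add(f.frame_index)

    gaps: list[tuple[int, int]] = []
    for lab, where in present.items():
        if lab not in by_label:
            if strict:
                raise AnnotationError(f"orphan label {lab}: in pixels, not in table")
            continue
        r = by_label[lab]
        outside = {t for t in where if t < r.begin or t > r.end}
        if outside:
            raise AnnotationError(
                f"label {lab} appears outside its span [{r.begin},{r.end}]: "
                f"frames {sorted(outside)}"
            )
    for r in table:
        covered = present.get(r.label, set())
        missing = [t for t in range(r.begin, r.end + 1) if t not in covered]
        if missing:
            if strict:
                raise AnnotationError(
                    f"track {r.label}: no pixels in frame(s) {missing} "
                    f"of span [{r.begin},{r.end}]"
                )
            gaps.extend((t, r.label) for t in missing)

    g = nx.DiGraph()
    for lab, where in present.items():
        if lab not in by_label:
            continue  # lenient orphan
        ts = sorted(where)
        for t in ts:
            g.add_node((t, lab))
        for a, b in zip(ts, ts[1:]):
            if b == a + 1:  # track links never skip frames
                g.add_edge((a, lab), (b, lab), kind=EDGE_TRACK)
    for r in table:
        if r.parent and r.parent in present and present.get(r.label):
            p_end = max(t for t in present[r.parent])
            c_begin = min(t for t in present[r.label])
            if p_end >= c_begin:
                raise AnnotationError(
                    f"track {r.label}: parent {r.parent} last seen at frame "
                    f"{p_end}, not before child begin {c_begin}"
                )
            g.add_edge((p_end, r.parent), (c_begin, r.label), kind=EDGE_PARENT)
    return TrackedAnnotation(frames, table, g, coverage_gaps=gaps)


def read_annotation(
    directory: str | Path,
    name_pattern: str = "mask%03d.tif",
    track_file: str = "res_track.txt",
    strict: bool = True,
) -> TrackedAnnotation:
    """Read and compile a full annotation package from one directory."""
    directory = Path(directory)
    frames = read_label_sequence(directory, name_pattern)
    table = read_track_file(directory / track_file)
    return compile_annotation(frames, table, strict=strict)


def write_annotation(
    annotation: TrackedAnnotation,
    directory: str | Path,
    name_pattern: str = "mask%03d.tif",
    track_file: str = "res_track.txt",
) -> None:
    directory = Path(directory)
    write_label_sequence(annotation.frames, directory, name_pattern)
    write_track_file(annotation.table, directory / track_file)


def table_from_frames(frames: Sequence[LabeledFrame]) -> list[TrackRecord]:
    """Derive a parentless track table from label occurrences (spans only)."""
    span: dict[int, tuple[int, int]] = {}
    for f in frames:
        for lab in map(int, f.labels):
            b, e = span.get(lab, (f.frame_index, f.frame_index))
            span[lab] = (min(b, f.frame_index), max(e, f.frame_index))
    return [TrackRecord(lab, b, e, 0) for lab, (b, e) in sorted(span.items())]
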