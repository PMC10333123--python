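"""Seeded generation of synthetic tracking benchmarks and ledgered corruption.

The generator produces a complete annotation package — intensity video,
instance masks, detection markers (eroded masks) and a track table — for a
population of moving, dividing elliptical cells.  Every random draw comes
from a single seeded stream consumed in a fixed order, so a seed pins the
package bit-exactly.

:func:`corrupt_submission` degrades a perfect submission by a requested
number of detection and linking errors at mutually non-interacting sites
(no two injections touch the same track), and returns the realised
:class:`ErrorLedger` including the edge operations each injection implies.
The weighted ledger sum is then an exact oracle for the graph edit costs
computed by :mod:`~ctc_evalkit.measures_technical`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import InfeasibleInjectionError
from .io_ctc import (
    LabeledFrame,
    TrackRecord,
    TrackedAnnotation,
    compile_annotation,
)
from .measures_technical import AOGMWeights


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one synthetic video.

    Intensities follow a two-level model: background ``bg_mean`` and cell
    interior ``fg_mean``, both with additive Gaussian noise of standard
    deviation ``noise_sd`` — so the scene's analytic signal-to-noise ratio
    is ``(fg_mean − bg_mean)/noise_sd`` and its contrast ratio
    ``fg_mean/bg_mean``.  Cells are ellipses (2D) or ellipsoids (3D) that
    take a fixed-length step in a random direction each frame and divide
    with probability ``division_prob`` per cell per frame.
    """

    shape: tuple[int, ...] = (128, 128)
    n_initial_cells: int = 6
    radius_range: tuple[float, float] = (6.0, 10.0)
    fg_mean: float = 100.0
    bg_mean: float = 10.0
    noise_sd: float = 5.0
    displacement: float = 2.0
    division_prob: float = 0.02
    n_frames: int = 20
    marker_erosion: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius_range[0] < 2:
            raise ValueError("cell radii must be >= 2 px")
        if not 0.0 <= self.division_prob <= 1.0:
            raise ValueError("division_prob must be in [0, 1]")


@dataclass
class SceneTruth:
    """Analytic property values implied by the generating parameters."""

    snr: float
    cr: float
    res: float  # analytic mean cell area/volume from the sampled semi-axes
    ove: float  # expected consecutive-frame IoU for the configured step
    n_divisions: int


@dataclass
class Scene:
    intensity: list[np.ndarray]
    annotation: TrackedAnnotation
    markers: TrackedAnnotation
    truth: SceneTruth
    config: SceneConfig


def expected_disk_overlap(radius: float, step: float) -> float:
    """IoU of two equal disks whose centres are ``step`` apart (closed form)."""
    r, d = float(radius), float(step)
    if d >= 2 * r:
        return 0.0
    if d == 0:
        return 1.0
    inter = 2 * r * r * math.acos(d / (2 * r)) - 0.5 * d * math.sqrt(4 * r * r - d * d)
    return inter / (2 * math.pi * r * r - inter)


@dataclass
class _Cell:
    label: int
    center: np.ndarray  # float, per axis
    radii: np.ndarray  # semi-axes, per axis
    angle: float  # 2D orientation; ignored in 3D
    active: bool = True


def _paint_cells(cells: list[_Cell], shape: tuple[int, ...]) -> np.ndarray:
    """Rasterise cells into a disjoint label image.

    Contested pixels (claimed by several ellipses) go to the cell whose
    normalised ellipse coordinate is smallest — i.e. the cell whose body
    most deeply contains the pixel — which keeps masks disjoint without a
    processing-order bias.
    """
    out = np.zeros(shape, dtype=np.uint16)
    best = np.full(shape, np.inf)
    grids = np.indices(shape).astype(float)
    for cell in cells:
        if not cell.active:
            continue
        rel = [g - c for g, c in zip(grids, cell.center)]
        if len(shape) == 2:
            ca, sa = math.cos(cell.angle), math.sin(cell.angle)
            u = ca * rel[0] + sa * rel[1]
            v = -sa * rel[0] + ca * rel[1]
            q = (u / cell.radii[0]) ** 2 + (v / cell.radii[1]) ** 2
        else:
            q = sum((r / rad) ** 2 for r, rad in zip(rel, cell.radii))
        inside = q <= 1.0
        claim = inside & (q < best)
        out[claim] = cell.label
        best[claim] = q[claim]
    return out


def generate_scene(config: SceneConfig) -> Scene:
    """Generate one synthetic package; the same seed gives identical bits."""
    rng = np.random.default_rng(config.seed)
    ndim = len(config.shape)
    shape = tuple(config.shape)
    r_lo, r_hi = config.radius_range

    cells: list[_Cell] = []
    next_label = 1
    margin = r_hi + 1
    for _ in range(config.n_initial_cells):
        placed = False
        for _attempt in range(200):
            center = rng.uniform(margin, np.array(shape) - margin)
            radii = rng.uniform(r_lo, r_hi, size=ndim)
            if all(
                np.linalg.norm(center - c.center) > radii.max() + c.radii.max() + 2
                for c in cells
            ):
                cells.append(
                    _Cell(next_label, center, radii, rng.uniform(0, math.pi))
                )
                next_label += 1
                placed = True
                break
        if not placed:
            raise InfeasibleInjectionError(
                "overcrowding: cannot place initial cells without overlap"
            )

    parents: dict[int, int] = {}  # daughter label -> mother label
    mask_frames: list[LabeledFrame] = []
    intensity: list[np.ndarray] = []
    pending_daughters: list[_Cell] = []

    for t in range(config.n_frames):
        if t > 0:
            for cell in cells:
                if not cell.active:
                    continue
                direction = rng.normal(size=ndim)
                norm = np.linalg.norm(direction)
                if norm > 0:
                    cell.center = cell.center + config.displacement * direction / norm
            cells.extend(pending_daughters)
            pending_daughters = []

        px = _paint_cells(cells, shape)
        for cell in cells:
            if cell.active and not np.any(px == cell.label):
                cell.active = False  # left the field of view (or fully occluded)
        mask_frames.append(LabeledFrame(px, frame_index=t))
        noise = rng.normal(0.0, config.noise_sd, size=shape)
        img = np.where(px > 0, config.fg_mean, config.bg_mean) + noise
        intensity.append(img)

        # decide divisions after rendering: the mother's last frame is t
        if t < config.n_frames - 1:
            for cell in list(cells):
                if not cell.active:
                    continue
                if rng.random() < config.division_prob:
                    offset = rng.normal(size=ndim)
                    offset = offset / max(np.linalg.norm(offset), 1e-9)
                    gap = 0.8 * cell.radii.max()
                    d_radii = np.maximum(cell.radii * 0.75, 2.0)
                    for sign in (+1.0, -1.0):
                        d = _Cell(
                            next_label,
                            cell.center + sign * gap * offset,
                            d_radii.copy(),
                            rng.uniform(0, math.pi),
                        )
                        parents[next_label] = cell.label
                        next_label += 1
                        pending_daughters.append(d)
                    cell.active = False

    table = _table_with_parents(mask_frames, parents)
    annotation = compile_annotation(mask_frames, table, strict=True)
    marker_frames = [
        _erode_labels(f, config.marker_erosion) for f in mask_frames
    ]
    markers = compile_annotation(marker_frames, table, strict=True)

    areas = [_analytic_size(c.radii) for c in cells + pending_daughters]
    mean_radius = (r_lo + r_hi) / 2
    truth = SceneTruth(
        snr=(
            (config.fg_mean - config.bg_mean) / config.noise_sd
            if config.noise_sd > 0
            else float("inf")
        ),
        cr=config.fg_mean / config.bg_mean,
        res=float(np.mean(areas)) if areas else 0.0,
        ove=expected_disk_overlap(mean_radius, config.displacement),
        n_divisions=len(annotation.division_nodes()),
    )
    return Scene(intensity, annotation, markers, truth, config)


def _analytic_size(radii: np.ndarray) -> float:
    """Continuum area of an ellipse / volume of an ellipsoid."""
    if len(radii) == 2:
        return math.pi * float(np.prod(radii))
    return 4.0 / 3.0 * math.pi * float(np.prod(radii))


def _table_with_parents(
    frames: list[LabeledFrame], parents: dict[int, int]
) -> list[TrackRecord]:
    span: dict[int, tuple[int, int]] = {}
    for f in frames:
        for lab in map(int, f.labels):
            b, e = span.get(lab, (f.frame_index, f.frame_index))
            span[lab] = (min(b, f.frame_index), max(e, f.frame_index))
    records = []
    for lab, (b, e) in sorted(span.items()):
        p = parents.get(lab, 0)
        if p and (p not in span or span[p][1] >= b):
            p = 0  # mother vanished before dividing cleanly
        records.append(TrackRecord(lab, b, e, p))
    return records


def _erode_labels(frame: LabeledFrame, erosion: int) -> LabeledFrame:
    """Per-instance binary erosion; instances that would vanish keep their mask."""
    out = np.zeros_like(frame.pixels)
    for lab in frame.labels:
        mask = frame.pixels == lab
        er = ndimage.binary_erosion(mask, iterations=erosion) if erosion else mask
        if not er.any():
            er = mask
        out[er] = lab
    return LabeledFrame(out, frame_index=frame.frame_index)


# ---------------------------------------------------------------------------
# ledgered corruption


@dataclass(frozen=True)
class ErrorRequest:
    """How many errors of each kind to inject."""

    fn: int = 0
    fp: int = 0
    merge: int = 0
    link_del: int = 0
    link_change: int = 0
    link_add: int = 0
    jitter: int = 0
    non_interacting: bool = True


@dataclass
class ErrorLedger:
    """Realised injections in terms of the graph edit operations they imply.

    ``missing_links`` counts reference edges the curator must add (lost by
    node deletions, merges and cut links); ``spurious_links`` counts
    computed edges to delete; ``changed_links`` counts edges whose kind
    (track-link vs parent) was flipped.
    """

    fn: int = 0
    fp: int = 0
    merge: int = 0
    missing_links: int = 0
    spurious_links: int = 0
    changed_links: int = 0
    jitter: int = 0
    non_interacting: bool = True
    sites: list[str] = field(default_factory=list)

    def expected_detection_cost(self, w: AOGMWeights = AOGMWeights()) -> float:
        return w.w_fn * self.fn + w.w_fp * self.fp + w.w_split * self.merge

    def expected_full_cost(self, w: AOGMWeights = AOGMWeights()) -> float:
        return (
            self.expected_detection_cost(w)
            + w.w_edge_add * self.missing_links
            + w.w_edge_delete * self.spurious_links
            + w.w_edge_change * self.changed_links
        )


def corrupt_submission(
    gold: TrackedAnnotation, request: ErrorRequest, seed: int = 0
) -> tuple[TrackedAnnotation, ErrorLedger]:
    """Degrade a perfect submission by the requested error counts.

    Each injection consumes one or two whole tracks that no other injection
    touches, so the induced edit operations are independent and the ledger
    sum is an exact cost oracle.  Raises
    :class:`~ctc_evalkit.errors.InfeasibleInjectionError` when the scene
    has too few eligible tracks.
    """
    rng = np.random.default_rng(seed)
    frames = [
        LabeledFrame(f.pixels.copy(), f.frame_index) for f in gold.frames
    ]
    table = {r.label: r for r in gold.table}
    ledger = ErrorLedger(non_interacting=request.non_interacting)

    spans = {r.label: (r.begin, r.end) for r in gold.table}
    mothers = {r.parent for r in gold.table if r.parent}
    used: set[int] = set()

    def eligible(min_len: int = 1, childless: bool = True):
        labs = [
            lab
            for lab, (b, e) in spans.items()
            if lab not in used
            and e - b + 1 >= min_len
            and (not childless or lab not in mothers)
        ]
        return list(rng.permutation(labs)) if labs else []

    def take(labs: list[int], what: str) -> int:
        if not labs:
            raise InfeasibleInjectionError(
                f"no eligible track left for {what} injection"
            )
        lab = int(labs.pop(0))
        used.add(lab)
        return lab

    def delete_pixels(t: int, lab: int) -> None:
        frames[t].pixels[frames[t].pixels == lab] = 0

    def relabel(t: int, lab: int, new: int) -> None:
        frames[t].pixels[frames[t].pixels == lab] = new

    next_label = max(table) + 1

    # -- false negatives: drop the last node of a childless track
    for _ in range(request.fn):
        pool = eligible(min_len=2)
        lab = take(pool, "false-negative")
        b, e = spans[lab]
        delete_pixels(e, lab)
        table[lab] = replace(table[lab], end=e - 1)
        ledger.fn += 1
        ledger.missing_links += 1  # the link into the dropped node
        ledger.sites.append(f"fn track={lab} frame={e}")

    # -- merges: absorb track B into neighbour A in their common final frame
    for _ in range(request.merge):
        pool = [
            lab for lab in eligible(min_len=2) if spans[lab][1] == gold.n_frames - 1
        ]
        a = take(pool, "merge")
        pool = [lab for lab in pool if spans[lab][1] == spans[a][1]]
        b_lab = take(pool, "merge")
        e = spans[a][1]
        relabel(e, b_lab, a)
        table[b_lab] = replace(table[b_lab], end=e - 1)
        ledger.merge += 1
        ledger.missing_links += 2  # both tracks' links into the merged node
        ledger.spurious_links += 1  # A's own link now enters a to-be-split node
        ledger.sites.append(f"merge tracks={a},{b_lab} frame={e}")

    # -- cut links: detach the last node of a track into a fresh label
    for _ in range(request.link_del):
        pool = eligible(min_len=2)
        lab = take(pool, "link-deletion")
        b, e = spans[lab]
        relabel(e, lab, next_label)
        table[lab] = replace(table[lab], end=e - 1)
        table[next_label] = TrackRecord(next_label, e, e, 0)
        ledger.missing_links += 1
        ledger.sites.append(f"link_del track={lab} frame={e}")
        next_label += 1

    # -- semantics change: report the final link of a track as a division
    for _ in range(request.link_change):
        pool = eligible(min_len=2)
        lab = take(pool, "link-change")
        b, e = spans[lab]
        relabel(e, lab, next_label)
        table[lab] = replace(table[lab], end=e - 1)
        table[next_label] = TrackRecord(next_label, e, e, parent=lab)
        ledger.changed_links += 1
        ledger.sites.append(f"link_change track={lab} frame={e}")
        next_label += 1

    # -- spurious blobs (and spurious 2-frame tracks carrying a bogus link)
    fg_union = np.zeros(frames[0].pixels.shape, dtype=bool)
    for f in frames:
        fg_union |= f.pixels > 0
    clearance = ndimage.binary_dilation(fg_union, iterations=4)

    def place_blob(t: int, lab: int) -> None:
        nonlocal clearance
        shape = frames[t].pixels.shape
        for _attempt in range(500):
            center = rng.uniform(4, np.array(shape) - 4)
            idx = np.indices(shape)
            dist2 = sum((g - c) ** 2 for g, c in zip(idx, center))
            blob = dist2 <= 3.0**2
            if not (blob & clearance).any():
                frames[t].pixels[blob] = lab
                clearance = clearance | ndimage.binary_dilation(blob, iterations=3)
                return
        raise InfeasibleInjectionError("no background room for a spurious blob")

    frame_pool = list(rng.permutation(gold.n_frames))
    for _ in range(request.fp):
        if not frame_pool:
            raise InfeasibleInjectionError("no frame left for a spurious blob")
        t = int(frame_pool.pop(0))
        place_blob(t, next_label)
        table[next_label] = TrackRecord(next_label, t, t, 0)
        ledger.fp += 1
        ledger.sites.append(f"fp frame={t} label={next_label}")
        next_label += 1

    for _ in range(request.link_add):
        frame_pool = [t for t in frame_pool if t + 1 < gold.n_frames]
        if not frame_pool:
            raise InfeasibleInjectionError("no frame pair left for a spurious link")
        t = int(frame_pool.pop(0))
        if t + 1 in frame_pool:
            frame_pool.remove(t + 1)
        place_blob(t, next_label)
        place_blob(t + 1, next_label)
        table[next_label] = TrackRecord(next_label, t, t + 1, 0)
        ledger.fp += 2
        ledger.spurious_links += 1
        ledger.sites.append(f"link_add frames={t},{t + 1} label={next_label}")
        next_label += 1

    # -- boundary jitter: dilate one node's mask into the background
    for _ in range(request.jitter):
        pool = eligible(min_len=1)
        lab = take(pool, "jitter")
        b, e = spans[lab]
        t = int(rng.integers(b, e + 1))
        mask = frames[t].pixels == lab
        grown = ndimage.binary_dilation(mask) & (frames[t].pixels == 0)
        frames[t].pixels[grown] = lab
        ledger.jitter += 1
        ledger.sites.append(f"jitter track={lab} frame={t}")

    degraded = compile_annotation(
        frames, sorted(table.values(), key=lambda r: r.label), strict=True
    )
    return degraded, ledger


# ---------------------------------------------------------------------------
# simulated manual annotations


def make_annotator_panel(
    gold: TrackedAnnotation,
    jitter_px: int = 1,
    misses: tuple[set[tuple[int, int]], ...] | None = None,
    seed: int = 0,
) -> list[list[LabeledFrame]]:
    """Three simulated manual annotations: gold with independent boundary
    jitter of at most ``jitter_px`` per instance, and optional per-annotator
    missed instances given as sets of ``(frame, label)``."""
    if misses is None:
        misses = (set(), set(), set())
    if len(misses) != 3:
        raise ValueError("misses must be given for exactly 3 annotators")
    max_r = min(
        int(np.sqrt(np.count_nonzero(f.pixels == lab) / math.pi))
        for f in gold.frames
        for lab in f.labels
    ) if any(len(f.labels) for f in gold.frames) else 0
    if jitter_px >= max(max_r, 1) and jitter_px > 0:
        raise ValueError(
            f"jitter radius {jitter_px} not below the smallest cell radius"
        )
    rng = np.random.default_rng(seed)
    panel: list[list[LabeledFrame]] = []
    for k in range(3):
        frames_k: list[LabeledFrame] = []
        for f in gold.frames:
            px = np.zeros_like(f.pixels)
            for lab in map(int, f.labels):
                if (f.frame_index, lab) in misses[k]:
                    continue
                mask = f.pixels == lab
                r = int(rng.integers(0, jitter_px + 1))
                grow = bool(rng.integers(0, 2))
                if r:
                    if grow:
                        mask = ndimage.binary_dilation(mask, iterations=r) & (
                            (f.pixels == 0) | (f.pixels == lab)
                        )
                    else:
                        er = ndimage.binary_erosion(mask, iterations=r)
                        if er.any():
                            mask = er
                px[mask & (px == 0)] = lab
            frames_k.append(LabeledFrame(px, frame_index=f.frame_index))
        panel.append(frames_k)
    return panel
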