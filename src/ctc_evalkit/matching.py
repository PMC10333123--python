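"""Per-frame correspondence between reference and computed instances.

A reference instance r is assigned to a computed instance c iff c covers a
strict majority of r's pixels (|r ∩ c| > 0.5·|r|).  Because the threshold
exceeds one half, at most one computed instance can qualify, so every
reference instance has at most one match — the uniqueness this module's
classification counts rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse

from .errors import GeometryError
from .io_ctc import LabeledFrame, TrackedAnnotation

Node = tuple[int, int]  # (frame_index, label)


@dataclass
class NodeMatching:
    """Assignment of reference nodes to computed nodes with TP/FN/FP/split counts."""

    ref_to_comp: dict[Node, Node | None] = field(default_factory=dict)
    comp_assigned: dict[Node, set[Node]] = field(default_factory=dict)

    @property
    def n_ref(self) -> int:
        return len(self.ref_to_comp)

    @property
    def n_comp(self) -> int:
        return len(self.comp_assigned)

    @property
    def n_tp(self) -> int:
        return sum(1 for c in self.ref_to_comp.values() if c is not None)

    @property
    def n_fn(self) -> int:
        return sum(1 for c in self.ref_to_comp.values() if c is None)

    @property
    def n_fp(self) -> int:
        return sum(1 for refs in self.comp_assigned.values() if not refs)

    @property
    def n_split(self) -> int:
        """Split operations needed: a computed node holding k references needs k−1."""
        return sum(max(0, len(refs) - 1) for refs in self.comp_assigned.values())

    def unique_pairs(self) -> dict[Node, Node]:
        """Reference→computed map restricted to 1:1 matched pairs."""
        out: dict[Node, Node] = {}
        for r, c in self.ref_to_comp.items():
            if c is not None and len(self.comp_assigned[c]) == 1:
                out[r] = c
        return out

    def update(self, other: "NodeMatching") -> None:
        self.ref_to_comp.update(other.ref_to_comp)
        self.comp_assigned.update(other.comp_assigned)

    def track_view(self, reference: TrackedAnnotation) -> dict[int, dict[int, int | None]]:
        """Per reference track label: {frame -> matched computed label or None}."""
        view: dict[int, dict[int, int | None]] = {}
        for (t, lab), c in self.ref_to_comp.items():
            view.setdefault(lab, {})[t] = c[1] if c is not None else None
        return view


def overlap_matrix(
    reference: np.ndarray, computed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pixel-overlap counts between every reference/computed label pair.

    Returns (ref_labels, comp_labels, counts) with counts[i, j] the number
    of pixels carrying ref_labels[i] in the reference and comp_labels[j] in
    the computed frame.
    """
    fg = (reference > 0) | (computed > 0)
    r = reference[fg].ravel()
    c = computed[fg].ravel()
    ref_labels = np.unique(reference[reference > 0])
    comp_labels = np.unique(computed[computed > 0])
    ri = np.searchsorted(ref_labels, r)
    ci = np.searchsorted(comp_labels, c)
    keep = (r > 0) & (c > 0)
    counts = sparse.coo_matrix(
        (np.ones(keep.sum(), dtype=np.int64), (ri[keep], ci[keep])),
        shape=(len(ref_labels), len(comp_labels)),
    ).toarray()
    return ref_labels, comp_labels, counts


def match_frame(reference: LabeledFrame, computed: LabeledFrame) -> NodeMatching:
    """Match one frame by the strict-majority overlap test.

    Exact 50% coverage is a non-match; an empty computed frame is legal
    (every reference instance becomes a false negative).
    """
    if reference.pixels.shape != computed.pixels.shape:
        raise GeometryError(
            f"frame {reference.frame_index}: reference shape "
            f"{reference.pixels.shape} != computed shape {computed.pixels.shape}"
        )
    t = reference.frame_index
    ref_labels, comp_labels, counts = overlap_matrix(reference.pixels, computed.pixels)
    ref_sizes = np.array(
        [np.count_nonzero(reference.pixels == lab) for lab in ref_labels]
    )
    m = NodeMatching()
    for c in comp_labels:
        m.comp_assigned[(t, int(c))] = set()
    for i, lab in enumerate(ref_labels):
        node = (t, int(lab))
        m.ref_to_comp[node] = None
        if counts.shape[1]:
            j = int(np.argmax(counts[i]))
            if counts[i, j] * 2 > ref_sizes[i]:
                cnode = (t, int(comp_labels[j]))
                m.ref_to_comp[node] = cnode
                m.comp_assigned[cnode].add(node)
    return m


def match_video(
    reference: TrackedAnnotation, computed: TrackedAnnotation
) -> NodeMatching:
    """Frame-wise matching over a whole video."""
    if reference.n_frames != computed.n_frames:
        raise GeometryError(
            f"frame count mismatch: reference {reference.n_frames}, "
            f"computed {computed.n_frames}"
        )
    m = NodeMatching()
    for rf, cf in zip(reference.frames, computed.frames):
        m.update(match_frame(rf, cf))
    return m
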