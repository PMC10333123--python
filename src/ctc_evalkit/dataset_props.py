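"""Quantitative dataset-quality properties of a time-lapse video.

Ten scalars characterise how hard a dataset is to segment and track:

==========  ===============================================================
SNR         (μ_fg − μ_bg) / σ_bg — signal-to-noise ratio
CR          μ_fg / μ_bg — contrast ratio
Het_i       mean over instances of σ_instance / (μ_fg − μ_bg) — internal
            signal heterogeneity of the cells
Het_b       std / mean of per-instance mean intensities — heterogeneity of
            the signal between cells
Res         mean instance size in pixels (voxels) — resolution
Sha         mean 2D circularity 4πA/P² or 3D sphericity
            π^{1/3}(6V)^{2/3}/S — regularity of the cell shape
Spa         mean centroid distance to the nearest other instance, divided
            by the mean equivalent diameter — cell spacing
Cha         mean |μ_cell(t+1) − μ_cell(t)| / (μ_fg − μ_bg) over
            consecutive same-track frames — intensity change over time
Ove         mean IoU of one track's masks in consecutive frames — overlap
Mit         number of division events (also reported per track per frame)
==========  ===============================================================

Foreground statistics pool all instance pixels; the background is the
complement of a 2-pixel dilation of the foreground, which keeps boundary
halos out of μ_bg and σ_bg.  Frame-level values are averaged over frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.measure import regionprops

from .errors import GeometryError, UndefinedMeasureError
from .io_ctc import LabeledFrame, TrackedAnnotation


@dataclass
class DatasetProperties:
    snr: float
    cr: float
    het_i: float
    het_b: float
    res: float
    sha: float
    spa: float
    cha: float
    ove: float
    mit: int
    mit_rate: float  # divisions per track per frame

    def as_dict(self) -> dict:
        return {
            "SNR": self.snr,
            "CR": self.cr,
            "Het_i": self.het_i,
            "Het_b": self.het_b,
            "Res": self.res,
            "Sha": self.sha,
            "Spa": self.spa,
            "Cha": self.cha,
            "Ove": self.ove,
            "Mit": self.mit,
            "Mit_rate": self.mit_rate,
        }


def _frame_stats(img: np.ndarray, seg: np.ndarray) -> dict | None:
    fg = seg > 0
    if not fg.any():
        return None
    bg = ~ndimage.binary_dilation(fg, iterations=2)
    if not bg.any():
        raise UndefinedMeasureError("no background pixels: σ_bg undefined")
    mu_fg = float(img[fg].mean())
    mu_bg = float(img[bg].mean())
    sd_bg = float(img[bg].std())
    labels = np.unique(seg[fg])
    inst_means, inst_sds, sizes, centroids = [], [], [], []
    for lab in labels:
        m = seg == lab
        vals = img[m]
        inst_means.append(float(vals.mean()))
        inst_sds.append(float(vals.std()))
        sizes.append(int(m.sum()))
        centroids.append(np.array(ndimage.center_of_mass(m)))
    return {
        "mu_fg": mu_fg,
        "mu_bg": mu_bg,
        "sd_bg": sd_bg,
        "labels": labels,
        "inst_means": np.array(inst_means),
        "inst_sds": np.array(inst_sds),
        "sizes": np.array(sizes),
        "centroids": centroids,
    }


def _shape_regularity(seg: np.ndarray) -> float | None:
    """Mean circularity (2D) or sphericity (3D), clipped to 1 to absorb the
    slight overestimate rasterisation gives the Crofton perimeter."""
    vals = []
    for rp in regionprops(seg.astype(np.int32)):
        if seg.ndim == 2:
            p = rp.perimeter_crofton
            if p > 0:
                vals.append(min(4 * np.pi * rp.area / p**2, 1.0))
        else:
            mask = rp.image
            surface = _surface_area(mask)
            if surface > 0:
                v = rp.area
                vals.append(min(np.pi ** (1 / 3) * (6 * v) ** (2 / 3) / surface, 1.0))
    return float(np.mean(vals)) if vals else None


def _surface_area(mask: np.ndarray) -> float:
    """Exposed voxel-face count — a simple digital surface-area estimate."""
    padded = np.pad(mask, 1)
    faces = 0
    for axis in range(mask.ndim):
        diff = np.diff(padded.astype(np.int8), axis=axis)
        faces += int(np.abs(diff).sum())
    return float(faces)


def compute_properties(
    intensity: Sequence[np.ndarray],
    segmentation: Sequence[LabeledFrame],
    tracking: TrackedAnnotation | None = None,
) -> DatasetProperties:
    """All dataset properties for one video.

    ``segmentation`` supplies the (typically silver-truth) instance masks;
    ``tracking`` supplies the lineage used for Cha, Ove and Mit and
    defaults to track identities taken from the segmentation labels.
    """
    if len(intensity) != len(segmentation):
        raise GeometryError("intensity and segmentation frame counts differ")
    per_frame = []
    for img, sf in zip(intensity, segmentation):
        if img.shape != sf.pixels.shape:
            raise GeometryError("intensity/segmentation geometry mismatch")
        st = _frame_stats(np.asarray(img, dtype=float), sf.pixels)
        if st is not None:
            per_frame.append((sf.frame_index, st, sf.pixels))
    if not per_frame:
        raise UndefinedMeasureError("no segmented instances in any frame")

    snr, cr, het_i, het_b, res, sha, spa = [], [], [], [], [], [], []
    for _, st, seg in per_frame:
        contrast = st["mu_fg"] - st["mu_bg"]
        if st["sd_bg"] > 0:
            snr.append(contrast / st["sd_bg"])
        if st["mu_bg"] != 0:
            cr.append(st["mu_fg"] / st["mu_bg"])
        if contrast != 0:
            het_i.append(float(np.mean(st["inst_sds"])) / contrast)
        mean_of_means = float(np.mean(st["inst_means"]))
        if mean_of_means != 0:
            het_b.append(float(np.std(st["inst_means"])) / mean_of_means)
        res.append(float(np.mean(st["sizes"])))
        s = _shape_regularity(seg)
        if s is not None:
            sha.append(s)
        if len(st["centroids"]) >= 2:
            cents = np.stack(st["centroids"])
            d = np.linalg.norm(cents[:, None] - cents[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            nearest = d.min(axis=1).mean()
            eq_diam = _mean_equivalent_diameter(st["sizes"], seg.ndim)
            spa.append(float(nearest / eq_diam))

    # track-linked temporal measures
    track_frames = tracking.frames if tracking is not None else list(segmentation)
    cha_vals, ove_vals = [], []
    stats_by_index = {t: st for t, st, _ in per_frame}
    for a, b in zip(track_frames, track_frames[1:]):
        common = np.intersect1d(a.labels, b.labels)
        for lab in common:
            ma, mb = a.pixels == lab, b.pixels == lab
            inter = int((ma & mb).sum())
            union = int((ma | mb).sum())
            ove_vals.append(inter / union)
            sa = stats_by_index.get(a.frame_index)
            sb = stats_by_index.get(b.frame_index)
            if sa is None or sb is None:
                continue
            contrast = sa["mu_fg"] - sa["mu_bg"]
            if contrast == 0:
                continue
            ia = np.flatnonzero(sa["labels"] == lab)
            ib = np.flatnonzero(sb["labels"] == lab)
            if len(ia) and len(ib):
                cha_vals.append(
                    abs(sb["inst_means"][ib[0]] - sa["inst_means"][ia[0]]) / contrast
                )

    if tracking is not None:
        mit = len(tracking.division_nodes())
        n_track_frames = sum(r.end - r.begin + 1 for r in tracking.table)
    else:
        mit = 0
        n_track_frames = sum(len(f.labels) for f in segmentation)

    def avg(vals, default=float("nan")):
        return float(np.mean(vals)) if vals else default

    return DatasetProperties(
        snr=avg(snr),
        cr=avg(cr),
        het_i=avg(het_i),
        het_b=avg(het_b),
        res=avg(res),
        sha=avg(sha),
        spa=avg(spa),
        cha=avg(cha_vals, default=float("nan")),
        ove=avg(ove_vals, default=float("nan")),
        mit=mit,
        mit_rate=mit / n_track_frames if n_track_frames else 0.0,
    )


def _mean_equivalent_diameter(sizes: np.ndarray, ndim: int) -> float:
    if ndim == 2:
        return float(np.mean(2 * np.sqrt(sizes / np.pi)))
    return float(np.mean((6 * sizes / np.pi) ** (1 / 3)))


def iqr_color_scale(values: Sequence[float]) -> np.ndarray:
    """Map values to [0, 1] for rendering, after clamping outliers beyond
    1.5× the interquartile range from the quartiles (outliers saturate at
    the scale ends)."""
    v = np.asarray(values, dtype=float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = v[(v >= lo) & (v <= hi)]
    vmin, vmax = inliers.min(), inliers.max()
    if vmax == vmin:
        return np.full_like(v, 0.5)
    return np.clip((v - vmin) / (vmax - vmin), 0.0, 1.0)
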