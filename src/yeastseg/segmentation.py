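"""Score-map to instance-mask post-processing.

Turns a per-pixel cell-likeness score map (1 = cell-like, 0 = border or
background) into an instance labeling in four steps:

1. threshold the scores (default 0.5, strict) to get putative cell pixels;
2. seed each cell at the local maxima of the Euclidean distance transform,
   where a local maximum has no strictly greater value within a circular
   neighborhood of ``seed_radius_px`` (default 5 px);
3. grow a watershed region from each seed on the negated distance transform;
4. apply the cell-cell boundary test: for each pair of adjacent regions,
   average the scores of the top 3/4 of their boundary pixels (the bottom
   quarter is ignored because an erroneous boundary touches real boundaries
   at its two ends) and merge the pair when that trimmed mean exceeds 0.99 —
   such a boundary runs through cell-like pixels and is an artefact of
   multiple distance-transform peaks inside one cell (e.g. dumbbell shapes).

Step 4 is what makes the pipeline work without a fluorescent marker picking
a unique interior point per cell.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.segmentation import watershed as _sk_watershed

__all__ = [
    "SegmentationParams",
    "threshold_scores",
    "find_seeds",
    "watershed_assign",
    "boundary_pixels",
    "boundary_score",
    "merge_oversegmented",
    "segment",
]

_STRUCT8 = np.ones((3, 3), bool)


@dataclass(frozen=True)
class SegmentationParams:
    """Pipeline thresholds; defaults are the method's published operating point."""

    score_threshold: float = 0.5
    seed_radius_px: int = 5
    boundary_quantile: float = 0.75
    merge_threshold: float = 0.99
    min_area_px: int = 0

    def __post_init__(self):
        if not 0.0 < self.score_threshold < 1.0:
            raise ValueError("score_threshold must lie in (0, 1)")
        if self.seed_radius_px < 1:
            raise ValueError("seed_radius_px must be >= 1")
        if not 0.0 < self.boundary_quantile <= 1.0:
            raise ValueError("boundary_quantile must lie in (0, 1]")
        if not 0.0 < self.merge_threshold < 1.0:
            raise ValueError("merge_threshold must lie in (0, 1)")
        if self.min_area_px < 0:
            raise ValueError("min_area_px must be >= 0")


def _check_scores(score: np.ndarray) -> np.ndarray:
    score = np.asarray(score, dtype=float)
    if score.ndim != 2:
        raise ValueError("score map must be 2D")
    if not np.isfinite(score).all():
        raise ValueError("score map contains non-finite values")
    if score.min() < 0 or score.max() > 1:
        raise ValueError("scores must lie in [0, 1]")
    return score


def threshold_scores(score: np.ndarray, score_threshold: float = 0.5) -> np.ndarray:
    """Step 1: strict threshold — a pixel is foreground iff score > threshold."""
    if not 0.0 < score_threshold < 1.0:
        raise ValueError("score_threshold must lie in (0, 1)")
    return _check_scores(score) > score_threshold


def _disk_footprint(radius: int) -> np.ndarray:
    r = int(radius)
    rr, cc = np.mgrid[-r:r + 1, -r:r + 1]
    return rr**2 + cc**2 <= r**2


def find_seeds(foreground: np.ndarray, seed_radius_px: int = 5) -> np.ndarray:
    """Step 2: one seed per local-maximum cluster of the distance transform.

    A pixel is a local maximum when no strictly greater distance value lies
    within the Euclidean disc of radius ``seed_radius_px`` around it.
    8-connected plateaus of equal maximal value collapse to a single seed
    (plateau centroid snapped to the nearest plateau pixel), and every
    8-connected foreground component is guaranteed at least one seed.

    Returns an (n, 2) integer array of (row, col) seed coordinates, sorted
    lexicographically.
    """
    foreground = np.asarray(foreground, dtype=bool)
    if not foreground.any():
        return np.empty((0, 2), dtype=int)
    edt = ndi.distance_transform_edt(foreground)
    footprint = _disk_footprint(seed_radius_px)
    local_max = (edt >= ndi.grey_dilation(edt, footprint=footprint)) & foreground
    seeds = _collapse_plateaus(local_max)
    # a component whose own maximum is shadowed by a taller neighbor within
    # the radius could end up seedless; seed it at its distance-transform peak
    comp, n_comp = ndi.label(foreground, structure=_STRUCT8)
    if n_comp:
        seeded = np.zeros(n_comp + 1, dtype=bool)
        for r, c in seeds:
            seeded[comp[r, c]] = True
        missing = [i for i in range(1, n_comp + 1) if not seeded[i]]
        for i in missing:
            sel = comp == i
            masked = np.where(sel, edt, -1.0)
            peak = masked == masked.max()
            extra = _collapse_plateaus(peak & sel)
            seeds = np.vstack([seeds, extra[:1]]) if len(seeds) else extra[:1]
    order = np.lexsort((seeds[:, 1], seeds[:, 0]))
    return seeds[order]


def _collapse_plateaus(candidates: np.ndarray) -> np.ndarray:
    """One seed per 8-connected candidate cluster: centroid snapped to the
    nearest cluster pixel."""
    lab, n = ndi.label(candidates, structure=_STRUCT8)
    if n == 0:
        return np.empty((0, 2), dtype=int)
    out = np.empty((n, 2), dtype=int)
    centroids = ndi.center_of_mass(candidates, lab, range(1, n + 1))
    for i, cen in enumerate(centroids):
        pts = np.argwhere(lab == i + 1)
        d2 = ((pts - np.asarray(cen)) ** 2).sum(axis=1)
        out[i] = pts[np.argmin(d2)]
    return out


def watershed_assign(foreground: np.ndarray, seeds: np.ndarray) -> np.ndarray:
    """Step 3: seeded watershed on the negated distance transform.

    Regions meet with no unlabeled separating line, so boundary pixels exist
    as region pixels and carry scores the boundary test can read.
    """
    foreground = np.asarray(foreground, dtype=bool)
    seeds = np.asarray(seeds, dtype=int).reshape(-1, 2)
    labels = np.zeros(foreground.shape, dtype=np.int32)
    if len(seeds) == 0:
        return labels
    for r, c in seeds:
        if not foreground[r, c]:
            raise ValueError(f"seed ({r}, {c}) is not on a foreground pixel")
    edt = ndi.distance_transform_edt(foreground)
    markers = np.zeros(foreground.shape, dtype=np.int32)
    for i, (r, c) in enumerate(seeds, start=1):
        markers[r, c] = i
    return _sk_watershed(-edt, markers=markers, mask=foreground,
                         connectivity=2, watershed_line=False).astype(np.int32)


def boundary_pixels(labels: np.ndarray, id_a: int, id_b: int) -> set[tuple[int, int]]:
    """Step 4 support: the two-sided interface between regions a and b.

    All pixels of region a with an 8-neighbor in region b, plus the converse;
    empty iff the regions are not adjacent.
    """
    labels = np.asarray(labels)
    region_a = labels == id_a
    region_b = labels == id_b
    if not region_a.any():
        raise ValueError(f"label {id_a} not present")
    if not region_b.any():
        raise ValueError(f"label {id_b} not present")
    near_b = ndi.binary_dilation(region_b, _STRUCT8)
    near_a = ndi.binary_dilation(region_a, _STRUCT8)
    sel = (region_a & near_b) | (region_b & near_a)
    return {(int(r), int(c)) for r, c in np.argwhere(sel)}


def boundary_score(
    score: np.ndarray,
    boundary: set[tuple[int, int]] | np.ndarray,
    boundary_quantile: float = 0.75,
) -> float:
    """Trimmed mean score of an interface: mean of the top
    ``ceil(boundary_quantile * n)`` (at least 1) boundary-pixel scores."""
    pts = np.asarray(sorted(boundary) if isinstance(boundary, set) else boundary,
                     dtype=int).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("boundary is empty — regions are not adjacent")
    vals = np.sort(np.asarray(score, float)[pts[:, 0], pts[:, 1]])[::-1]
    keep = max(int(np.ceil(boundary_quantile * len(vals))), 1)
    return float(vals[:keep].mean())


def _adjacent_pairs(labels: np.ndarray) -> set[tuple[int, int]]:
    """All 8-adjacent positive label pairs (a < b), found by comparing the
    label image with its one-pixel shifts."""
    pairs: set[tuple[int, int]] = set()
    shifts = [(0, 1), (1, 0), (1, 1), (1, -1)]
    for dr, dc in shifts:
        a = labels[max(dr, 0):labels.shape[0] + min(dr, 0),
                   max(dc, 0):labels.shape[1] + min(dc, 0)]
        b = labels[max(-dr, 0):labels.shape[0] + min(-dr, 0),
                   max(-dc, 0):labels.shape[1] + min(-dc, 0)]
        sel = (a > 0) & (b > 0) & (a != b)
        if sel.any():
            lo = np.minimum(a[sel], b[sel])
            hi = np.maximum(a[sel], b[sel])
            pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


def relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Map surviving labels to consecutive 1..n in increasing label order."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(int(labels.max()) + 1 if labels.size else 1, dtype=np.int32)
    for new, old in enumerate(present, start=1):
        lut[old] = new
    return lut[labels]


def merge_oversegmented(
    score: np.ndarray,
    labels: np.ndarray,
    params: SegmentationParams | None = None,
) -> np.ndarray:
    """Step 4: iterate the cell-cell boundary test to a fixed point.

    While any adjacent pair's trimmed-mean boundary score strictly exceeds
    ``merge_threshold``, merge the highest-scoring pair (ties broken by the
    lexicographically smallest (min ID, max ID) pair), recompute the affected
    interfaces, and repeat.  Surviving labels are relabeled consecutively.
    """
    params = params or SegmentationParams()
    score = _check_scores(score)
    labels = np.asarray(labels).astype(np.int32).copy()
    pairs = _adjacent_pairs(labels)
    cache: dict[tuple[int, int], float] = {}
    while True:
        for p in pairs:
            if p not in cache:
                cache[p] = boundary_score(
                    score, boundary_pixels(labels, *p), params.boundary_quantile
                )
        best: tuple[int, int] | None = None
        for p in sorted(pairs):
            s = cache[p]
            if s > params.merge_threshold and (best is None or s > cache[best]):
                best = p
        if best is None:
            break
        a, b = best  # a < b: b is absorbed into a
        labels[labels == b] = a
        pairs = {
            (min(x if x != b else a, y if y != b else a),
             max(x if x != b else a, y if y != b else a))
            for x, y in pairs if {x, y} != {a, b}
        }
        cache = {p: s for p, s in cache.items() if a not in p and b not in p}
    return relabel_consecutive(labels)


def segment(
    score: np.ndarray, params: SegmentationParams | None = None
) -> np.ndarray:
    """Full pipeline: threshold, seed, watershed, boundary-test merge, and
    removal of components smaller than ``min_area_px``."""
    params = params or SegmentationParams()
    score = _check_scores(score)
    foreground = threshold_scores(score, params.score_threshold)
    seeds = find_seeds(foreground, params.seed_radius_px)
    labels = watershed_assign(foreground, seeds)
    labels = merge_oversegmented(score, labels, params)
    if params.min_area_px > 0:
        areas = np.bincount(labels.ravel())
        small = np.flatnonzero(areas < params.min_area_px)
        labels[np.isin(labels, small[small > 0])] = 0
        labels = relabel_consecutive(labels)
    return labels
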