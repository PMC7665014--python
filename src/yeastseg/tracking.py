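"""Frame-to-frame cell tracking by bipartite matching.

Each cell is summarized by the triplet (x, y, A): center of mass and area in
pixels.  Per frame, triplets are mean-centered and rescaled so the population
variances become (3, 3, 1) — deliberately weighting position over area —
and consecutive frames are matched by minimizing the summed Euclidean
distances between normalized triplets (Hungarian algorithm).  Unmatched
cells in the later frame are births and receive fresh IDs; unmatched cells
in the earlier frame are deaths.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment

__all__ = [
    "CellFeatures",
    "NormalizedTriplet",
    "FrameAssignment",
    "extract_features",
    "normalize_features",
    "match_frames",
    "track_timelapse",
]

#: Target population variances for (x, y, area) after rescaling.
FEATURE_VARIANCES = (3.0, 3.0, 1.0)


class CellFeatures(NamedTuple):
    """Per-cell (x, y, area): center of mass (x = column, y = row) and pixel count."""

    cell_id: int
    x: float
    y: float
    area: int


class NormalizedTriplet(NamedTuple):
    cell_id: int
    u: float
    v: float
    w: float


@dataclass
class FrameAssignment:
    """Result of matching one frame pair: matched (prev_id, next_id) pairs,
    next-frame births and prev-frame deaths."""

    pairs: list[tuple[int, int]]
    births: list[int]
    deaths: list[int]


def extract_features(mask: np.ndarray) -> list[CellFeatures]:
    """One record per positive label: unweighted center of mass and area."""
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if len(labels) == 0:
        return []
    coms = ndi.center_of_mass(mask > 0, mask, labels)
    areas = ndi.sum_labels(np.ones_like(mask, dtype=np.int64), mask, labels)
    return [
        CellFeatures(int(lab), x=float(c[1]), y=float(c[0]), area=int(a))
        for lab, c, a in zip(labels, coms, areas)
    ]


def normalize_features(frame: Sequence[CellFeatures]) -> list[NormalizedTriplet]:
    """Center each feature over the frame and rescale to variances (3, 3, 1).

    Variances are population variances (divide by n), so the invariant is
    exact for any frame of >= 2 cells with non-degenerate spread.  A feature
    with zero variance is left centered (all zeros) without scaling; a
    single-cell frame maps to (0, 0, 0).
    """
    if len(frame) == 0:
        raise ValueError("cannot normalize an empty frame")
    raw = np.array([(f.x, f.y, f.area) for f in frame], dtype=float)
    centered = raw - raw.mean(axis=0)
    std = centered.std(axis=0)  # population std
    scale = np.sqrt(FEATURE_VARIANCES)
    out = np.zeros_like(centered)
    for j in range(3):
        if std[j] > 0:
            out[:, j] = centered[:, j] / std[j] * scale[j]
    return [
        NormalizedTriplet(f.cell_id, *row) for f, row in zip(frame, out)
    ]


def match_frames(
    prev: Sequence[CellFeatures],
    next_: Sequence[CellFeatures],
    max_cost: float | None = None,
) -> FrameAssignment:
    """Minimum-cost bipartite matching between two frames.

    Costs are Euclidean distances between the frames' normalized triplets;
    the rectangular assignment matches min(|prev|, |next|) pairs and the
    total cost equals the exhaustive-search optimum.  With ``max_cost`` set,
    pairs costlier than the gate are converted into a death plus a birth.
    """
    if len(prev) == 0 or len(next_) == 0:
        return FrameAssignment(
            pairs=[], births=[f.cell_id for f in next_],
            deaths=[f.cell_id for f in prev],
        )
    p = np.array([t[1:] for t in normalize_features(prev)])
    q = np.array([t[1:] for t in normalize_features(next_)])
    cost = np.linalg.norm(p[:, None, :] - q[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(cost)
    pairs: list[tuple[int, int]] = []
    for i, j in zip(rows, cols):
        if max_cost is not None and cost[i, j] > max_cost:
            continue
        pairs.append((prev[i].cell_id, next_[j].cell_id))
    matched_prev = {a for a, _ in pairs}
    matched_next = {b for _, b in pairs}
    return FrameAssignment(
        pairs=sorted(pairs),
        births=sorted(f.cell_id for f in next_ if f.cell_id not in matched_next),
        deaths=sorted(f.cell_id for f in prev if f.cell_id not in matched_prev),
    )


def track_timelapse(
    masks: Sequence[np.ndarray], max_cost: float | None = None
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """Propagate consistent IDs through a mask sequence.

    The first frame keeps its labels; every later frame is relabeled by
    composing frame-pair assignments.  Births receive fresh, never-reused
    IDs.  Returns the relabeled masks and a track table with columns
    (frame, cell_id, x, y, area_px).
    """
    if len(masks) == 0:
        raise ValueError("need at least one frame")
    tracked: list[np.ndarray] = [np.asarray(masks[0]).astype(np.int32).copy()]
    rows: list[tuple[int, int, float, float, int]] = []
    prev_feats = extract_features(tracked[0])
    next_fresh = max((f.cell_id for f in prev_feats), default=0) + 1
    for f in prev_feats:
        rows.append((0, f.cell_id, f.x, f.y, f.area))
    for t in range(1, len(masks)):
        cur = np.asarray(masks[t])
        cur_feats = extract_features(cur)
        assign = match_frames(prev_feats, cur_feats, max_cost=max_cost)
        mapping: dict[int, int] = {b: a for a, b in assign.pairs}
        for b in assign.births:
            mapping[b] = next_fresh
            next_fresh += 1
        lut = np.zeros(int(cur.max()) + 1, dtype=np.int32)
        for old, new in mapping.items():
            lut[old] = new
        relab = lut[cur]
        tracked.append(relab)
        prev_feats = extract_features(relab)
        for f in prev_feats:
            rows.append((t, f.cell_id, f.x, f.y, f.area))
    table = pd.DataFrame(rows, columns=["frame", "cell_id", "x", "y", "area_px"])
    return tracked, table
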