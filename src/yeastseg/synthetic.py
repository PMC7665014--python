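"""Synthetic yeast microscopy fields with exact ground truth.

Generates instance label masks of budding-yeast-like cells (round to
filamentous, with attached buds), renders stylized phase-contrast-style
images (dark cell interiors, bright halos, optional bright vacuole-like
inclusions, Gaussian noise), manufactures the ideal per-pixel score map a
perfect pixel classifier would emit (1 on cell bodies, 0 on background and
cell-cell borders), and produces growing, budding, drifting timelapses with
lineage ground truth.

Everything is a pure function of its parameters and the contained seed, so
downstream modules can be tested without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "SynthCellSpec",
    "SynthFieldParams",
    "SynthTimelapse",
    "PlacementError",
    "rasterize_cell",
    "generate_field",
    "render_image",
    "ideal_score_map",
    "intercell_borders",
    "degrade_score_map",
    "generate_timelapse",
]

_SHAPE_KINDS = ("ellipse", "capsule", "dumbbell", "filament", "budded")


class PlacementError(RuntimeError):
    """Raised when rejection sampling cannot place all requested cells."""

    def __init__(self, placed: int, requested: int):
        self.placed = placed
        self.requested = requested
        super().__init__(
            f"could only place {placed} of {requested} cells; "
            "enlarge the image, shrink the cells, or reduce crowding"
        )


@dataclass(frozen=True)
class SynthCellSpec:
    """Analytic description of a single cell, rasterized on demand.

    ``axes`` are semi-axis lengths in pixels; for a ``dumbbell`` they are the
    two lobe radii, for a ``budded`` cell the mother's semi-axes. The bud's
    radius is ``bud_fraction`` times the mother's minor semi-axis.
    """

    shape_kind: str
    center: tuple[float, float]  # (row, col)
    axes: tuple[float, float]
    orientation: float = 0.0  # radians, measured from the row axis
    bud_fraction: float = 0.0
    neck_width: float = 4.0
    lobe_separation: float = 0.0  # dumbbell: distance between lobe centers

    def __post_init__(self):
        if self.shape_kind not in _SHAPE_KINDS:
            raise ValueError(f"unknown shape_kind {self.shape_kind!r}")
        if min(self.axes) <= 0:
            raise ValueError("axes must be positive")
        if not 0.0 <= self.bud_fraction <= 1.0:
            raise ValueError("bud_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SynthFieldParams:
    """Parameters of a synthetic field of cells.

    ``crowding`` is the minimal background gap between distinct cells in
    pixels; 0 allows cells to share an interface.  The default of 1 pixel
    mirrors the annotation convention in which the border between adjacent
    cells is background-valued in the pixel target, so the ideal score map is
    lossless with respect to the mask (see docs).  ``noise_sd`` is additive
    Gaussian noise in raw 16-bit intensity units.
    """

    image_shape: tuple[int, int] = (192, 192)
    n_cells: int = 10
    cell_size_range: tuple[float, float] = (80.0, 400.0)
    crowding: int = 1
    noise_sd: float = 60.0
    halo_strength: float = 1.0
    vacuole_prob: float = 0.3
    rng_seed: int = 0
    shape_kinds: tuple[str, ...] = ("ellipse",)
    aspect_range: tuple[float, float] = (1.0, 1.6)
    max_tries: int = 100

    def __post_init__(self):
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if self.cell_size_range[0] <= 0 or (
            self.cell_size_range[1] < self.cell_size_range[0]
        ):
            raise ValueError("invalid cell_size_range")
        if self.cell_size_range[1] > self.image_shape[0] * self.image_shape[1]:
            raise ValueError("cell_size_range exceeds the image area")
        for k in self.shape_kinds:
            if k not in _SHAPE_KINDS:
                raise ValueError(f"unknown shape kind {k!r}")


@dataclass
class SynthTimelapse:
    """A timelapse with persistent ground-truth IDs and lineage.

    ``lineage`` maps child ID -> (mother ID, birth frame index).
    """

    masks: list[np.ndarray]
    lineage: dict[int, tuple[int, int]]
    drift_px: int


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _coord_grids(shape):
    return np.meshgrid(
        np.arange(shape[0], dtype=float),
        np.arange(shape[1], dtype=float),
        indexing="ij",
    )


def _ellipse_support(rr, cc, center, axes, orientation):
    dr, dc = rr - center[0], cc - center[1]
    co, si = np.cos(orientation), np.sin(orientation)
    u = dr * co + dc * si
    v = -dr * si + dc * co
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _capsule_support(rr, cc, center, half_length, radius, orientation):
    # Distance of pixel centers to the spine segment of the capsule.
    co, si = np.cos(orientation), np.sin(orientation)
    dr, dc = rr - center[0], cc - center[1]
    u = dr * co + dc * si
    v = -dr * si + dc * co
    del v
    u = np.clip(u, -half_length, half_length)
    return (dr - u * co) ** 2 + (dc - u * si) ** 2 <= radius**2


def rasterize_cell(spec: SynthCellSpec, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a cell spec on the pixel grid (center-of-pixel test)."""
    rr, cc = _coord_grids(shape)
    k = spec.shape_kind
    if k == "ellipse":
        return _ellipse_support(rr, cc, spec.center, spec.axes, spec.orientation)
    if k in ("capsule", "filament"):
        radius = min(spec.axes)
        half_length = max(spec.axes) - radius
        return _capsule_support(rr, cc, spec.center, half_length, radius,
                                spec.orientation)
    if k == "dumbbell":
        r_a, r_b = spec.axes
        sep = spec.lobe_separation or (r_a + r_b + 4.0)
        co, si = np.cos(spec.orientation), np.sin(spec.orientation)
        ca = (spec.center[0] - co * sep / 2, spec.center[1] - si * sep / 2)
        cb = (spec.center[0] + co * sep / 2, spec.center[1] + si * sep / 2)
        lobes = _ellipse_support(rr, cc, ca, (r_a, r_a), 0.0) | _ellipse_support(
            rr, cc, cb, (r_b, r_b), 0.0
        )
        # rectangular neck joining the lobe centers
        dr, dc = rr - spec.center[0], cc - spec.center[1]
        u = dr * co + dc * si
        v = -dr * si + dc * co
        neck = (np.abs(u) <= sep / 2) & (np.abs(v) <= spec.neck_width / 2)
        return lobes | neck
    if k == "budded":
        mother = _ellipse_support(rr, cc, spec.center, spec.axes,
                                  spec.orientation)
        r_bud = max(spec.bud_fraction * min(spec.axes), 1.0)
        co, si = np.cos(spec.orientation), np.sin(spec.orientation)
        offset = spec.axes[0] + r_bud * 0.6  # bud overlaps the mother rim
        bud_c = (spec.center[0] + co * offset, spec.center[1] + si * offset)
        bud = _ellipse_support(rr, cc, bud_c, (r_bud, r_bud), 0.0)
        return mother | bud
    raise ValueError(k)


# ---------------------------------------------------------------------------
# field generation
# ---------------------------------------------------------------------------

def _sample_spec(rng: np.random.Generator, params: SynthFieldParams) -> SynthCellSpec:
    kind = params.shape_kinds[rng.integers(len(params.shape_kinds))]
    area = rng.uniform(*params.cell_size_range)
    aspect = rng.uniform(*params.aspect_range)
    if kind in ("filament",):
        aspect = rng.uniform(2.5, 4.0)
    b = np.sqrt(area / (np.pi * aspect))
    a = aspect * b
    nrows, ncols = params.image_shape
    margin = a + 2
    if 2 * margin >= min(nrows, ncols):
        margin = min(nrows, ncols) / 2 - 1
    center = (
        rng.uniform(margin, nrows - margin),
        rng.uniform(margin, ncols - margin),
    )
    orientation = rng.uniform(0, np.pi)
    if kind == "dumbbell":
        r = np.sqrt(area / (2 * np.pi))
        return SynthCellSpec(kind, center, (r, r), orientation,
                             neck_width=4.0, lobe_separation=2.2 * r)
    if kind == "budded":
        return SynthCellSpec(kind, center, (a, b), orientation,
                             bud_fraction=rng.uniform(0.2, 0.5))
    return SynthCellSpec(kind, center, (a, b), orientation)


def generate_field(
    params: SynthFieldParams,
) -> tuple[np.ndarray, list[SynthCellSpec]]:
    """Place ``n_cells`` pairwise disjoint cells by rejection sampling.

    Returns an integer label mask (labels 1..n, 0 background) and the specs.
    Raises :class:`PlacementError` after ``max_tries`` failed attempts for a
    cell, reporting how many were placed.
    """
    rng = np.random.default_rng(params.rng_seed)
    mask = np.zeros(params.image_shape, dtype=np.int32)
    occupied = np.zeros(params.image_shape, dtype=bool)
    specs: list[SynthCellSpec] = []
    for label in range(1, params.n_cells + 1):
        for _ in range(params.max_tries):
            spec = _sample_spec(rng, params)
            support = rasterize_cell(spec, params.image_shape)
            if not support.any():
                continue
            if params.crowding > 0:
                probe = ndi.binary_dilation(
                    support, structure=np.ones((3, 3), bool),
                    iterations=params.crowding,
                )
            else:
                probe = support
            if (probe & occupied).any():
                continue
            mask[support] = label
            occupied |= support
            specs.append(spec)
            break
        else:
            raise PlacementError(placed=label - 1, requested=params.n_cells)
    return mask, specs


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

_BG_LEVEL = 1000.0
_INTERIOR_LEVEL = 400.0
_HALO_LEVEL = 3000.0
_VACUOLE_LEVEL = 2000.0


def render_image(mask: np.ndarray, params: SynthFieldParams) -> np.ndarray:
    """Render a stylized phase-contrast-like 16-bit image from a label mask.

    Cell interiors are dark, each cell carries a bright 1-2 px halo just
    outside its border, and with probability ``vacuole_prob`` a cell contains
    a bright round inclusion whose edge must *not* become an instance
    boundary downstream. Deterministic given ``params.rng_seed``.
    """
    rng = np.random.default_rng([int(params.rng_seed) % (2**31), 17])
    fg = mask > 0
    img = np.full(mask.shape, _BG_LEVEL, dtype=float)
    img[fg] = _INTERIOR_LEVEL
    halo = ndi.binary_dilation(fg, structure=np.ones((3, 3), bool), iterations=2) & ~fg
    img[halo] = _BG_LEVEL + params.halo_strength * (_HALO_LEVEL - _BG_LEVEL)
    # vacuole-like bright inclusions inside some cells
    labels = np.unique(mask)
    labels = labels[labels > 0]
    for lab in labels:
        if rng.random() >= params.vacuole_prob:
            continue
        core = ndi.binary_erosion(mask == lab, np.ones((3, 3), bool), iterations=2)
        pts = np.argwhere(core)
        if len(pts) < 5:
            continue
        r0, c0 = pts[rng.integers(len(pts))]
        rad = max(1.5, 0.25 * np.sqrt(len(pts) / np.pi))
        rr, cc = _coord_grids(mask.shape)
        vac = ((rr - r0) ** 2 + (cc - c0) ** 2 <= rad**2) & core
        img[vac] = _VACUOLE_LEVEL
    img = ndi.gaussian_filter(img, sigma=0.6)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


# ---------------------------------------------------------------------------
# score maps
# ---------------------------------------------------------------------------

def intercell_borders(mask: np.ndarray, width: int) -> np.ndarray:
    """Pixels covered by the dilations (8-connected, ``width`` iterations)
    of at least two distinct labels — the cell-cell border band."""
    if width <= 0:
        return np.zeros(mask.shape, dtype=bool)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    coverage = np.zeros(mask.shape, dtype=np.int16)
    struct = np.ones((3, 3), bool)
    for lab in labels:
        coverage += ndi.binary_dilation(mask == lab, struct, iterations=width)
    return coverage >= 2


def ideal_score_map(
    mask: np.ndarray, border_width: int = 1, smooth_sigma: float = 0.0
) -> np.ndarray:
    """The score map a perfect pixel classifier would produce.

    1 on cell-body pixels, 0 on background; wherever two distinct labels come
    within ``border_width`` dilation steps of each other a 0-valued
    separating band is written, so thresholding keeps touching cells apart.
    Optional Gaussian smoothing keeps values in [0, 1].
    """
    if border_width < 0:
        raise ValueError("border_width must be >= 0")
    score = (mask > 0).astype(float)
    score[intercell_borders(mask, border_width)] = 0.0
    if smooth_sigma > 0:
        score = np.clip(ndi.gaussian_filter(score, smooth_sigma), 0.0, 1.0)
    return score


def degrade_score_map(
    score: np.ndarray,
    mode: str,
    rng: np.random.Generator | None = None,
    width: float = 2.0,
    amplitude: float = 0.2,
) -> np.ndarray:
    """Inject the failure modes the post-processing has to repair.

    ``erase_boundary`` fills the 0-valued band between cells with score 1
    (a missed interface -> dumbbell-shaped support); ``blur`` applies a
    Gaussian of sigma ``width``; ``noise`` adds uniform noise of the given
    amplitude. Output is clipped to [0, 1].
    """
    score = np.asarray(score, dtype=float)
    if mode == "erase_boundary":
        out = score.copy()
        closed = ndi.binary_closing(
            score > 0.5, structure=np.ones((3, 3), bool),
            iterations=max(int(round(width)), 1),
        )
        out[closed] = 1.0
        return out
    if mode == "blur":
        if width == 0:
            return score.copy()
        return np.clip(ndi.gaussian_filter(score, sigma=width), 0.0, 1.0)
    if mode == "noise":
        if amplitude == 0:
            return score.copy()
        if rng is None:
            raise ValueError("noise mode needs an rng")
        return np.clip(score + rng.uniform(-amplitude, amplitude, score.shape),
                       0.0, 1.0)
    raise ValueError(f"unknown degradation mode {mode!r}")


# ---------------------------------------------------------------------------
# timelapse
# ---------------------------------------------------------------------------

@dataclass
class _Cell:
    cid: int
    center: np.ndarray  # integer (row, col)
    radius: float


def _discs_to_mask(cells: Sequence[_Cell], shape) -> np.ndarray:
    mask = np.zeros(shape, dtype=np.int32)
    rr, cc = _coord_grids(shape)
    for c in cells:
        sup = (rr - c.center[0]) ** 2 + (cc - c.center[1]) ** 2 <= c.radius**2
        mask[sup] = c.cid
    return mask


def _collides(cells, center, radius, skip=None, gap=0.3):
    for other in cells:
        if other is skip:
            continue
        d = np.hypot(*(np.asarray(center, float) - other.center))
        if d < radius + other.radius + gap:
            return True
    return False


def generate_timelapse(
    params: SynthFieldParams,
    n_frames: int,
    drift_px: int = 1,
    growth_rate: float = 0.12,
    bud_prob: float = 0.05,
    bud_radius: float = 2.0,
    mature_radius: float = 6.0,
) -> SynthTimelapse:
    """Simulate a colony timelapse: growth, budding, small integer drift.

    Cells are discs with integer centers, so with ``drift_px = 0`` and no
    budding every centroid is constant and, because translation on the pixel
    grid is exact, areas depend only on the (non-decreasing) radius.  Buds
    appear as new IDs of radius ``bud_radius`` tangent to their mother, with
    the (mother, birth frame) pair recorded in the lineage.  As in real
    budding yeast, a mother carries at most one attached bud over the
    simulated window, and a new bud keeps a few pixels of clearance from
    every cell other than its mother so that cells stay distinguishable by
    their (position, area) features.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng([int(params.rng_seed) % (2**31), 523])
    nrows, ncols = params.image_shape
    cells: list[_Cell] = []
    # initial placement
    for cid in range(1, params.n_cells + 1):
        for _ in range(params.max_tries):
            radius = float(np.sqrt(rng.uniform(*params.cell_size_range) / np.pi))
            center = np.array([
                rng.integers(int(radius) + 3, nrows - int(radius) - 3),
                rng.integers(int(radius) + 3, ncols - int(radius) - 3),
            ], dtype=float)
            if not _collides(cells, center, radius, gap=2.0):
                cells.append(_Cell(cid, center, radius))
                break
        else:
            raise PlacementError(placed=cid - 1, requested=params.n_cells)
    lineage: dict[int, tuple[int, int]] = {}
    mothers_with_bud: set[int] = set()
    next_id = params.n_cells + 1
    masks = [_discs_to_mask(cells, params.image_shape)]
    for frame in range(1, n_frames):
        # growth (skip if it would collide; radius stays non-decreasing)
        for c in cells:
            r_new = c.radius + growth_rate
            if not _collides(cells, c.center, r_new, skip=c):
                edge = max(int(np.ceil(r_new)) + 1, 1)
                if (edge <= c.center[0] < nrows - edge
                        and edge <= c.center[1] < ncols - edge):
                    c.radius = r_new
        # integer drift, rejected on collision or leaving the frame
        if drift_px > 0:
            for c in cells:
                step = rng.integers(-drift_px, drift_px + 1, size=2).astype(float)
                cand = c.center + step
                edge = int(np.ceil(c.radius)) + 1
                if not (edge <= cand[0] < nrows - edge
                        and edge <= cand[1] < ncols - edge):
                    continue
                if not _collides(cells, cand, c.radius, skip=c):
                    c.center = cand
        # budding: one attached bud per mother, clear of all other cells
        for c in list(cells):
            if (c.radius < mature_radius or c.cid in mothers_with_bud
                    or rng.random() >= bud_prob):
                continue
            theta = rng.uniform(0, 2 * np.pi)
            offset = c.radius + bud_radius + 0.8
            cand = np.round(c.center + offset * np.array(
                [np.cos(theta), np.sin(theta)]))
            edge = int(np.ceil(bud_radius)) + 1
            if not (edge <= cand[0] < nrows - edge
                    and edge <= cand[1] < ncols - edge):
                continue
            others = [o for o in cells if o is not c]
            if _collides(others, cand, bud_radius, gap=3.0):
                continue
            if _collides([c], cand, bud_radius, gap=0.3):
                continue
            cells.append(_Cell(next_id, cand, bud_radius))
            mothers_with_bud.add(c.cid)
            lineage[next_id] = (c.cid, frame)
            next_id += 1
        masks.append(_discs_to_mask(cells, params.image_shape))
    return SynthTimelapse(masks=masks, lineage=lineage, drift_px=drift_px)
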