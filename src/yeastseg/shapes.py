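"""Cell-shape analysis: moment-ellipse elongation and binned profiles.

Each cell's elongation (major axis / minor axis) is obtained by equating the
central second moments of its pixel set with those of an ellipse; the axis
ratio is the square root of the moment-matrix eigenvalue ratio, so the
common scale factor cancels.  The population analysis scales areas by a
reference group's mean area, discards the largest 2.5% of the pooled
population, splits the remaining scaled-area range into 8 equal bins, and
reports per-genotype, per-bin mean elongation with SEM and STD — elongation
versus area read as a proxy for time since budding, since cells grow
continuously.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats

__all__ = [
    "elongation",
    "shape_table",
    "bin_elongation_vs_area",
    "compare_groups_one_tailed",
]


def elongation(pixels: np.ndarray) -> float:
    """Major/minor axis ratio of the moment-equivalent ellipse.

    ``pixels`` is an (n, 2) array of (row, col) coordinates or a 2D boolean
    mask.  Collinear pixel sets are degenerate and return ``inf``; a single
    pixel raises, as no ellipse is defined.
    """
    pts = np.asarray(pixels)
    if pts.ndim == 2 and pts.dtype == bool:
        pts = np.argwhere(pts)
    pts = pts.astype(float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("expected an (n, 2) coordinate array or boolean mask")
    if len(pts) < 2:
        raise ValueError("elongation undefined for fewer than 2 pixels")
    cov = np.cov(pts, rowvar=False, bias=True)  # central second moments
    evals = np.linalg.eigvalsh(cov)
    lam_min, lam_max = float(evals[0]), float(evals[1])
    if lam_min <= 0:
        return math.inf
    return math.sqrt(lam_max / lam_min)


def shape_table(mask: np.ndarray, px_area_um2: float = 1.0) -> pd.DataFrame:
    """Per-cell shape records: columns cell_id, area_px, area_um2, elongation."""
    if px_area_um2 <= 0:
        raise ValueError("px_area_um2 must be positive")
    mask = np.asarray(mask)
    labels = np.unique(mask)
    labels = labels[labels > 0]
    rows = []
    for lab in labels:
        pts = np.argwhere(mask == lab)
        elong = elongation(pts) if len(pts) >= 2 else math.nan
        rows.append((int(lab), len(pts), len(pts) * px_area_um2, elong))
    return pd.DataFrame(
        rows, columns=["cell_id", "area_px", "area_um2", "elongation"]
    )


def bin_elongation_vs_area(
    tables: dict[str, pd.DataFrame],
    reference: str,
    n_bins: int = 8,
    discard_top_frac: float = 0.025,
) -> pd.DataFrame:
    """Binned elongation-versus-area profiles for several genotypes.

    Areas are divided by the reference genotype's mean area, so 1 on the
    abscissa is the mean reference-cell size.  The largest
    ``floor(discard_top_frac * n)`` records of the *pooled* population are
    discarded, the remaining scaled-area range is split into ``n_bins``
    equal-width bins (half-open, last bin closed), and per genotype and bin
    the count, mean elongation, SEM (sample STD / sqrt(n)) and STD are
    reported; empty bins carry NaN statistics.

    Returns a tidy frame with columns genotype, bin, bin_low, bin_high, n,
    mean_elongation, sem, std.
    """
    if reference not in tables:
        raise ValueError(f"reference genotype {reference!r} missing")
    ref = tables[reference]
    if len(ref) == 0:
        raise ValueError("reference genotype has no records")
    ref_mean_area = float(ref["area_px"].mean())
    pooled = pd.concat(
        [t.assign(genotype=g) for g, t in tables.items()], ignore_index=True
    )
    if len(pooled) == 0:
        raise ValueError("no records to bin")
    pooled = pooled.assign(area_scaled=pooled["area_px"] / ref_mean_area)
    n_discard = int(math.floor(discard_top_frac * len(pooled)))
    if n_discard > 0:
        order = np.argsort(pooled["area_scaled"].to_numpy(), kind="stable")
        pooled = pooled.iloc[order[: len(pooled) - n_discard]]
    lo = float(pooled["area_scaled"].min())
    hi = float(pooled["area_scaled"].max())
    edges = np.linspace(lo, hi, n_bins + 1)
    # half-open bins, last bin closed: every retained record lands in one bin
    idx = np.clip(np.searchsorted(edges, pooled["area_scaled"], side="right") - 1,
                  0, n_bins - 1)
    pooled = pooled.assign(_bin=idx)
    rows = []
    for g in tables:
        sub = pooled[pooled["genotype"] == g]
        for b in range(n_bins):
            vals = sub.loc[sub["_bin"] == b, "elongation"].to_numpy(float)
            n = len(vals)
            if n:
                mean = float(vals.mean())
                std = float(vals.std(ddof=1)) if n > 1 else 0.0
                sem = std / math.sqrt(n)
            else:
                mean = sem = std = math.nan
            rows.append((g, b, edges[b], edges[b + 1], n, mean, sem, std))
    return pd.DataFrame(
        rows,
        columns=["genotype", "bin", "bin_low", "bin_high", "n",
                 "mean_elongation", "sem", "std"],
    )


def compare_groups_one_tailed(
    a: np.ndarray, b: np.ndarray, alternative: str = "greater"
) -> tuple[float, float]:
    """Generic single-tail two-sample t test (e.g. elongation of two
    genotypes in one bin).  Returns (t statistic, p value)."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float),
                          alternative=alternative)
    return float(res.statistic), float(res.pvalue)
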