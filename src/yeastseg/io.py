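"""TIFF stack / mask / score-map I/O and run configuration.

Masks are unsigned 16-bit integer TIFFs (0 = background, positive IDs =
cells); score maps are 32-bit float TIFFs in [0, 1]; raw stacks round-trip
losslessly at their stored bit depth.  Run configuration is a flat
``section.key = value`` text file whose keys default to the method's
published parameter values; unknown keys are rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "RunConfig",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "read_scores",
    "write_scores",
]

log = logging.getLogger("yeastseg")


@dataclass
class ImageStack:
    """An ordered sequence of equally shaped 2D frames."""

    frames: list[np.ndarray]

    def __post_init__(self):
        if len(self.frames) == 0:
            raise ValueError("stack has no frames")
        shape = self.frames[0].shape
        for f in self.frames:
            if f.shape != shape:
                raise ValueError("stack frames have mixed shapes")

    def __len__(self):
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    def __getitem__(self, i):
        return self.frames[i]

    @property
    def dtype(self):
        return self.frames[0].dtype


def read_stack(path: str | Path) -> ImageStack:
    """Read a single- or multi-page TIFF into a stack, dtype preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    try:
        arr = tifffile.imread(path)
    except Exception as exc:
        raise OSError(f"could not read TIFF {path}: {exc}") from exc
    if arr.ndim == 2:
        frames = [arr]
    elif arr.ndim == 3:
        frames = list(arr)
    else:
        raise ValueError(f"{path}: unsupported TIFF dimensionality {arr.ndim}")
    return ImageStack(frames=frames)


def write_stack(frames, path: str | Path) -> None:
    frames = list(frames)
    tifffile.imwrite(Path(path), np.stack(frames) if len(frames) > 1
                     else frames[0], photometric="minisblack")


def write_mask(mask, path: str | Path) -> None:
    """Write one label mask or a mask stack as uint16 TIFF (IDs < 2^16)."""
    frames = [np.asarray(m) for m in (mask if isinstance(mask, (list, tuple))
                                      else ([mask] if np.ndim(mask) == 2
                                            else list(mask)))]
    for f in frames:
        if f.min() < 0:
            raise ValueError("mask labels must be non-negative")
        if f.max() > 65535:
            raise ValueError(
                f"label {int(f.max())} exceeds the uint16 limit (65535)")
    write_stack([f.astype(np.uint16) for f in frames], path)


def read_mask(path: str | Path) -> ImageStack:
    stack = read_stack(path)
    return ImageStack([f.astype(np.int32) for f in stack])


def write_scores(scores, path: str | Path) -> None:
    """Write score map(s) as 32-bit float TIFF."""
    frames = [np.asarray(s, dtype=np.float32)
              for s in ([scores] if np.ndim(scores) == 2 else list(scores))]
    write_stack(frames, path)


def read_scores(path: str | Path) -> ImageStack:
    stack = read_stack(path)
    return ImageStack([f.astype(np.float64) for f in stack])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_CONFIG_DEFAULTS: dict[str, float | int | str] = {
    "segment.score_threshold": 0.5,
    "segment.seed_radius_px": 5,
    "segment.boundary_quantile": 0.75,
    "segment.merge_threshold": 0.99,
    "segment.min_area_px": 0,
    "train.batch_size": 25,
    "train.epochs": 100,
    "train.tile_size": 256,
    "eval.iou_threshold": 0.5,
    "shape.n_bins": 8,
    "shape.discard_top_frac": 0.025,
    "global.rng_seed": 0,
    "global.log_level": "INFO",
}


@dataclass
class RunConfig:
    """Flat, namespaced key-value configuration with strict key checking."""

    values: dict[str, float | int | str] = field(
        default_factory=lambda: dict(_CONFIG_DEFAULTS))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        cfg = cls()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, raw = (s.strip() for s in line.split("=", 1))
            if key not in _CONFIG_DEFAULTS:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            default = _CONFIG_DEFAULTS[key]
            if isinstance(default, int):
                cfg.values[key] = int(raw)
            elif isinstance(default, float):
                cfg.values[key] = float(raw)
            else:
                cfg.values[key] = raw
        return cfg

    def __getitem__(self, key: str):
        if key not in self.values:
            raise KeyError(f"unknown config key {key!r}")
        return self.values[key]
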