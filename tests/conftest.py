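import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from yeastseg.synthetic import SynthCellSpec, rasterize_cell

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def labels_equal_up_to_relabel(gt: np.ndarray, pred: np.ndarray) -> bool:
    """Exact pixel-set equality of two labelings modulo a label bijection."""
    if gt.shape != pred.shape:
        return False
    if ((gt > 0) != (pred > 0)).any():
        return False
    fg = gt > 0
    mapping: dict[int, int] = {}
    for g, p in zip(gt[fg].tolist(), pred[fg].tolist()):
        if mapping.setdefault(g, p) != p:
            return False
    return len(set(mapping.values())) == len(mapping)


def disc_mask(shape=(60, 60), center=(30, 30), radius=20):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def dumbbell_support(shape=(80, 80), lobe_radius=10, separation=30,
                     neck_width=4):
    spec = SynthCellSpec(
        "dumbbell", (shape[0] / 2, shape[1] / 2),
        (lobe_radius, lobe_radius), 0.0,
        neck_width=neck_width, lobe_separation=separation,
    )
    return rasterize_cell(spec, shape)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
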