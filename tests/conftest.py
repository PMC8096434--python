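"""Shared fixtures: small synthetic scenes and constructed shapes."""

import numpy as np
import pytest
from scipy import ndimage

from btx.posture import (
    Posture,
    PostureConfig,
    compute_midline,
    find_endpoints,
    smooth_outline_eft,
    trace_outline,
)
from btx.segmentation import Blob


def make_blob(mask: np.ndarray, values=None) -> Blob:
    ys, xs = np.nonzero(np.asarray(mask, dtype=bool))
    if values is None:
        vals = np.full(ys.size, 100, dtype=np.uint8)
    else:
        vals = np.asarray(values)[ys, xs]
    return Blob(ys=ys, xs=xs, values=vals)


def ellipse_mask(shape=(60, 100), center=(50, 30), radii=(40, 15)) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return ((xx - center[0]) / radii[0]) ** 2 + ((yy - center[1]) / radii[1]) ** 2 <= 1


def teardrop_mask(shape=(240, 240), center=(120, 120), length=30.0, half_width=6.0,
                  direction=0.0) -> np.ndarray:
    """Blunt head toward +direction, sharp tail behind."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    dx, dy = np.cos(direction), np.sin(direction)
    u = ((xx - center[0]) * dx + (yy - center[1]) * dy) / length + 0.5
    v = -(xx - center[0]) * dy + (yy - center[1]) * dx
    taper = np.clip(np.sqrt(np.clip(u, 0.0, 1.0)), 0.12, 1.0)
    return (u >= 0) & (u <= 1) & (np.abs(v) <= half_width * taper)


def random_solid_mask(rng: np.random.Generator, size: int = 20) -> np.ndarray:
    """Random hole-free 8-connected mask (largest component, holes filled)."""
    while True:
        m = rng.random((size, size)) < 0.4
        lab, n = ndimage.label(m, structure=np.ones((3, 3), bool))
        if n == 0:
            continue
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
        big = lab == (1 + int(np.argmax(sizes)))
        return ndimage.binary_fill_holes(big)


def posture_from_mask(mask: np.ndarray, config: PostureConfig | None = None,
                      n_efd: int = 10) -> Posture:
    cfg = config or PostureConfig()
    raw = trace_outline(np.asarray(mask, dtype=bool))
    sm = smooth_outline_eft(raw, n_efd)
    ep = find_endpoints(sm, cfg)
    ml = compute_midline(sm, ep.head_index, cfg)
    return Posture(outline=sm, raw_outline=raw, endpoints=ep, midline=ml)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def posture_config():
    return PostureConfig()
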