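"""2D posture estimation: outline, head/tail, midline, normalized crops.

The outline is traced *around* pixels (along pixel corners, clockwise in
image coordinates), so a single pixel is still a valid 4-corner outline and
the shoelace area of the polygon equals the pixel count exactly for
hole-free masks (holes are filled before tracing).  The outline can be
smoothed either by truncating its elliptic Fourier series or by a circular
triangular-weighted moving average.  The pointiest end (a curvature/area
score) is taken as head or tail; a two-cursor walk from the head along both
sides of the outline yields the midline with a per-point body thickness.
Finally each blob can be resampled into a fixed-size crop with the head
locked to a fixed anchor and the body axis along +x, which removes most
pose variation before identity classification.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .segmentation import Blob, _STRUCT8

__all__ = [
    "Outline",
    "Midline",
    "Endpoints",
    "PostureConfig",
    "MidlineError",
    "trace_outline",
    "shoelace_area",
    "smooth_outline_eft",
    "smooth_outline_weighted",
    "find_endpoints",
    "compute_midline",
    "normalize_image",
    "moments_orientation",
    "Posture",
    "compute_posture",
]


@dataclass
class Outline:
    """Closed polygon at pixel-corner resolution, clockwise in image
    coordinates (first vertex not repeated at the end)."""

    points: np.ndarray  # (K, 2) float, columns (x, y)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length at each vertex, starting at 0."""
        d = np.diff(self.points, axis=0)
        return np.concatenate([[0.0], np.cumsum(np.hypot(d[:, 0], d[:, 1]))])

    def point_at_arc(self, s) -> np.ndarray:
        """Interpolated point(s) at arc position(s) ``s`` (wraps around)."""
        pts = np.vstack([self.points, self.points[:1]])
        seg = np.diff(pts, axis=0)
        lens = np.hypot(seg[:, 0], seg[:, 1])
        cum = np.concatenate([[0.0], np.cumsum(lens)])
        total = cum[-1]
        s = np.mod(np.asarray(s, dtype=float), total)
        idx = np.clip(np.searchsorted(cum, s, side="right") - 1, 0, len(lens) - 1)
        frac = (s - cum[idx]) / np.where(lens[idx] > 0, lens[idx], 1.0)
        return pts[idx] + frac[..., None] * seg[idx]


@dataclass
class Midline:
    points: np.ndarray  # (M, 2) head to tail, sub-pixel
    thickness: np.ndarray  # (M,) left-right chord width
    head_index: int  # outline vertex index of the head
    tail_index: int

    @property
    def length(self) -> float:
        d = np.diff(self.points, axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())


@dataclass
class Endpoints:
    head_index: int
    tail_index: int
    ambiguous: bool = False


@dataclass
class PostureConfig:
    smoothing: str = "eft"  # eft | weighted | none
    n_efd: int = 8
    smooth_window: int = 5
    pointiest_is: str = "tail"  # head | tail
    midline_resolution: int = 25
    normalized_image_size: tuple[int, int] = (80, 80)

    def validate(self) -> None:
        if self.n_efd < 2:
            raise ValueError("n_efd must be >= 2")
        if self.smooth_window % 2 != 1:
            raise ValueError("smooth_window must be odd")
        if self.pointiest_is not in ("head", "tail"):
            raise ValueError("pointiest_is must be 'head' or 'tail'")
        if self.smoothing not in ("eft", "weighted", "none"):
            raise ValueError("smoothing must be eft, weighted or none")


class MidlineError(RuntimeError):
    """The two-cursor walk failed to produce a midline."""


# ---------------------------------------------------------------------------
# Outline tracing

# direction codes: 0=+x, 1=+y, 2=-x, 3=-y (clockwise on screen, y down)
_DIRS = np.array([(1, 0), (0, 1), (-1, 0), (0, -1)])


def trace_outline(blob: Blob | np.ndarray) -> Outline:
    """Corner-following boundary walk, clockwise in image coordinates.

    Disconnected masks trace the largest 8-connected component (with a
    warning); interior holes are filled first so that the traced polygon's
    shoelace area equals the component's (filled) pixel count exactly.
    """
    if isinstance(blob, Blob):
        mask = blob.mask()
        ox, oy = blob.bbox[0], blob.bbox[1]
    else:
        mask = np.asarray(blob, dtype=bool)
        ox = oy = 0
    if not mask.any():
        raise ValueError("cannot trace the outline of an empty mask")
    labels, n_lab = ndimage.label(mask, structure=_STRUCT8)
    if n_lab > 1:
        warnings.warn("disconnected mask: tracing the largest component")
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n_lab + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    mask = ndimage.binary_fill_holes(mask)

    h, w = mask.shape
    pad = np.zeros((h + 2, w + 2), dtype=bool)
    pad[1:-1, 1:-1] = mask
    # outgoing boundary edges per corner, keyed by direction
    # top edge of pixel (x, y): corner (x, y) -> (x+1, y), dir 0
    edges: dict[tuple[int, int], list[int]] = {}

    def add_edges(ys, xs, cx_off, cy_off, d):
        for y, x in zip(ys, xs):
            edges.setdefault((x + cx_off, y + cy_off), []).append(d)

    top = mask & ~pad[:-2, 1:-1]
    right = mask & ~pad[1:-1, 2:]
    bottom = mask & ~pad[2:, 1:-1]
    left = mask & ~pad[1:-1, :-2]
    ys, xs = np.nonzero(top)
    add_edges(ys, xs, 0, 0, 0)
    ys, xs = np.nonzero(right)
    add_edges(ys, xs, 1, 0, 1)
    ys, xs = np.nonzero(bottom)
    add_edges(ys, xs, 1, 1, 2)
    ys, xs = np.nonzero(left)
    add_edges(ys, xs, 0, 1, 3)

    # The topmost-leftmost boundary corner can never be a pinch corner (that
    # would need a pixel above-left of it), so it has exactly one outgoing
    # edge (+x) and the walk terminates exactly when it returns there.
    start = min(edges, key=lambda c: (c[1], c[0]))
    d = 0
    corner = start
    points = []
    while True:
        points.append(corner)
        out = edges[corner]
        # prefer counterclockwise turn, then straight, then clockwise; this
        # carries the walk through pinch corners around the whole component
        for turn in (3, 0, 1, 2):
            nd = (d + turn) % 4
            if nd in out:
                break
        else:  # pragma: no cover - cannot happen on valid boundaries
            raise RuntimeError("outline tracing dead end")
        out.remove(nd)
        d = nd
        dx, dy = _DIRS[d]
        corner = (corner[0] + int(dx), corner[1] + int(dy))
        if corner == start:
            break
    pts = np.asarray(points, dtype=float)
    pts[:, 0] += ox
    pts[:, 1] += oy
    return Outline(points=pts)


def shoelace_area(outline: Outline) -> float:
    """Unsigned polygon area by the shoelace formula."""
    p = outline.points
    q = np.roll(p, -1, axis=0)
    return abs(float(np.sum(p[:, 0] * q[:, 1] - q[:, 0] * p[:, 1])) / 2.0)


# ---------------------------------------------------------------------------
# Smoothing


def smooth_outline_eft(outline: Outline, n_efd: int) -> Outline:
    """Truncate the outline's elliptic Fourier series to ``n_efd``
    descriptors (the constant locus term counts as the first), reconstructed
    at the original point count.

    Two descriptors (locus + fundamental) reconstruct an exact ellipse.
    Corner-traced outlines have unit-length edges, so the uniform vertex
    parameterisation used here coincides with arc length.
    """
    if n_efd < 2:
        raise ValueError("n_efd must be >= 2")
    p = outline.points
    z = p[:, 0] + 1j * p[:, 1]
    if np.allclose(z, z[0]):
        raise ValueError("degenerate outline: all points coincide")
    k = len(z)
    spec = np.fft.fft(z)
    n_harm = n_efd - 1
    if 2 * n_harm + 1 < k:
        keep = np.zeros(k, dtype=bool)
        keep[: n_harm + 1] = True
        keep[k - n_harm:] = True
        spec = np.where(keep, spec, 0.0)
    rec = np.fft.ifft(spec)
    return Outline(points=np.column_stack([rec.real, rec.imag]))


def smooth_outline_weighted(outline: Outline, window: int) -> Outline:
    """Circular moving average of vertex positions with triangular weights."""
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if window >= len(outline):
        raise ValueError("window must be smaller than the point count")
    if window == 1:
        return Outline(points=outline.points.copy())
    half = window // 2
    wts = np.array([half + 1 - abs(i) for i in range(-half, half + 1)], dtype=float)
    wts /= wts.sum()
    p = outline.points
    out = np.zeros_like(p)
    for i, wt in zip(range(-half, half + 1), wts):
        out += wt * np.roll(p, -i, axis=0)
    return Outline(points=out)


# ---------------------------------------------------------------------------
# Endpoints and midline


_AMBIGUITY_SPREAD = 0.05  # minimal pointiness spread for a confident head/tail


def _pointiness_scores(outline: Outline) -> np.ndarray:
    """Pointiness per vertex from turning angle and enclosed triangle area.

    Both are measured over a +-5%-of-perimeter window: the turning angle
    (pi minus the angle between the two arms) is near 1 at a sharp tip and
    0 on a straight stretch, but saturates when the window folds around a
    strongly curved end; the normalized area of the triangle spanned by the
    arms stays large exactly there, so the two terms together rank blunt
    round ends and sharp tips above flat flanks."""
    per = outline.perimeter
    w = 0.05 * per
    s = outline.arc_lengths()
    a = outline.point_at_arc(s - w)
    b = outline.point_at_arc(s + w)
    p = outline.points
    va = a - p
    vb = b - p
    na = np.hypot(va[:, 0], va[:, 1])
    nb = np.hypot(vb[:, 0], vb[:, 1])
    cosang = np.clip((va * vb).sum(axis=1) / np.maximum(na * nb, 1e-12), -1.0, 1.0)
    theta = np.arccos(cosang)  # angle between the arms: small at a sharp tip
    chord = np.hypot(*(a - b).T)
    # chord shortness measures the total turning inside the window without
    # saturating when the window folds around a strongly curved end; the
    # angle term breaks ties between equally short chords
    return (1.0 - chord / (2.0 * w)) + 0.25 * (np.pi - theta) / np.pi


def find_endpoints(outline: Outline, config: PostureConfig) -> Endpoints:
    """Locate head and tail on a smoothed outline.

    The global pointiness maximum is the pointiest end (head or tail per
    ``config.pointiest_is``); the opposite endpoint is the vertex at maximal
    arc distance.  Near-circular shapes, whose pointiness spread is tiny,
    are flagged ambiguous (posture is still usable, visual fields are not).
    """
    config.validate()
    scores = _pointiness_scores(outline)
    tip = int(np.argmax(scores))
    ambiguous = float(scores.max() - scores.min()) < _AMBIGUITY_SPREAD
    s = outline.arc_lengths()
    per = outline.perimeter
    target = (s[tip] + per / 2.0) % per
    opposite = int(np.argmin(np.abs((s - target + per / 2.0) % per - per / 2.0)))
    if config.pointiest_is == "tail":
        return Endpoints(head_index=opposite, tail_index=tip, ambiguous=ambiguous)
    return Endpoints(head_index=tip, tail_index=opposite, ambiguous=ambiguous)


def compute_midline(outline: Outline, head_index: int, config: PostureConfig) -> Midline:
    """Two-cursor walk from the head along opposite outline directions.

    Both cursors advance in steps of roughly equal arc length (+-25%
    wiggle-room), each step pair chosen to minimise the left-right chord;
    midline points are chord midpoints and the chord length is the local
    body thickness.  The result is resampled to ``midline_resolution``
    points by arc length.
    """
    config.validate()
    per = outline.perimeter
    s = outline.arc_lengths()
    s_head = s[head_index]
    n_steps = max(config.midline_resolution * 2, 16)
    step = per / (2.0 * n_steps)
    wiggle = np.linspace(0.75 * step, 1.25 * step, 5)

    head_pt = outline.points[head_index]
    mid_pts = [head_pt.copy()]
    thick = [0.0]
    u = v = 0.0  # arc advanced on each side
    guard = 0
    while u + v < per - 2.0 * step:
        guard += 1
        if guard > 8 * n_steps:
            raise MidlineError("cursors failed to meet while walking the outline")
        la = outline.point_at_arc(s_head + u + wiggle)  # candidates left
        rb = outline.point_at_arc(s_head - v - wiggle)  # candidates right
        d = la[:, None, :] - rb[None, :, :]
        chord = np.hypot(d[..., 0], d[..., 1])
        i, j = np.unravel_index(int(np.argmin(chord)), chord.shape)
        u += float(wiggle[i])
        v += float(wiggle[j])
        pl = outline.point_at_arc(s_head + u)
        pr = outline.point_at_arc(s_head - v)
        mid_pts.append((pl + pr) / 2.0)
        thick.append(float(np.hypot(*(pl - pr))))
    tail_arc = (s_head + (u + (per - v)) / 2.0) % per
    mid_pts.append(outline.point_at_arc(tail_arc))
    thick.append(0.0)
    tail_index = int(np.argmin(np.abs((s - tail_arc + per / 2.0) % per - per / 2.0)))

    pts = np.asarray(mid_pts)
    th = np.asarray(thick)
    # arc-length resampling to midline_resolution points
    d = np.diff(pts, axis=0)
    seg = np.hypot(d[:, 0], d[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] <= 0:
        raise MidlineError("degenerate midline of zero length")
    want = np.linspace(0.0, cum[-1], config.midline_resolution)
    rx = np.interp(want, cum, pts[:, 0])
    ry = np.interp(want, cum, pts[:, 1])
    rt = np.interp(want, cum, th)
    return Midline(points=np.column_stack([rx, ry]), thickness=rt,
                   head_index=head_index, tail_index=tail_index)


# ---------------------------------------------------------------------------
# Normalized crops and moment orientation


def moments_orientation(blob: Blob | np.ndarray) -> tuple[float, bool]:
    """Main-axis angle in [0, 180) degrees from central second moments.

    Returns (angle, ambiguous); ambiguous is set for isotropic blobs.  Note
    the inherent 180-degree head/flip ambiguity of image moments.
    """
    mask = blob.mask() if isinstance(blob, Blob) else np.asarray(blob, dtype=bool)
    ys, xs = np.nonzero(mask)
    if ys.size < 2:
        raise ValueError("moments_orientation needs at least two pixels")
    x = xs - xs.mean()
    y = ys - ys.mean()
    mu20 = float((x * x).mean())
    mu02 = float((y * y).mean())
    mu11 = float((x * y).mean())
    if abs(mu20 - mu02) < 1e-12 and abs(mu11) < 1e-12:
        return 0.0, True
    ang = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)
    deg = math.degrees(ang) % 180.0
    return deg, False


def _midline_direction(midline: Midline) -> float:
    """Body-axis angle from the head-to-tail chord.

    The chord equals the initial midline direction for a straight body and
    is markedly more stable against midline-walk jitter than any local
    tangent, which keeps normalized crops consistent frame to frame."""
    d = midline.points[-1] - midline.points[0]
    return math.atan2(d[1], d[0])


def normalize_image(blob: Blob, midline: Midline | None, config: PostureConfig) -> np.ndarray:
    """Fixed-size grayscale crop with the head at a fixed anchor.

    A rigid transform maps the head point to (25% from the left edge,
    vertical centre) and the initial midline direction to +x; bilinear
    sampling, zero outside the blob mask.  Without a midline the crop falls
    back to moment-based alignment ([0, 180) axis, centred), which leaves
    the 180-degree flip unresolved.
    """
    config.validate()
    out_w, out_h = config.normalized_image_size
    x0, y0, _, _ = blob.bbox
    img = blob.image()
    mask = blob.mask().astype(float)

    if midline is not None:
        phi = _midline_direction(midline)
        head = midline.points[0]
        anchor = np.array([0.25 * out_w, out_h / 2.0])
    else:
        deg, _ = moments_orientation(blob)
        phi = math.radians(deg)
        ys, xs = np.nonzero(blob.mask())
        head = np.array([xs.mean() + x0 + 0.5, ys.mean() + y0 + 0.5])
        anchor = np.array([out_w / 2.0, out_h / 2.0])

    c, s = math.cos(phi), math.sin(phi)
    uu, vv = np.meshgrid(np.arange(out_w) + 0.5, np.arange(out_h) + 0.5)
    du = uu - anchor[0]
    dv = vv - anchor[1]
    sx = head[0] + c * du - s * dv
    sy = head[1] + s * du + c * dv
    # to local crop coordinates (pixel centres at integer + 0.5)
    coords = np.stack([sy - y0 - 0.5, sx - x0 - 0.5])
    vals = ndimage.map_coordinates(img, coords, order=1, mode="constant", cval=0.0)
    m = ndimage.map_coordinates(mask, coords, order=1, mode="constant", cval=0.0)
    return np.where(m >= 0.5, vals, 0.0)


# ---------------------------------------------------------------------------
# Pipeline convenience


@dataclass
class Posture:
    outline: Outline  # smoothed outline used downstream
    raw_outline: Outline
    endpoints: Endpoints
    midline: Midline | None
    flags: tuple[str, ...] = ()


def compute_posture(blob: Blob, config: PostureConfig) -> Posture:
    """Full per-blob posture: trace, smooth, endpoints, midline."""
    config.validate()
    raw = trace_outline(blob)
    if config.smoothing == "eft":
        sm = smooth_outline_eft(raw, config.n_efd)
    elif config.smoothing == "weighted":
        sm = smooth_outline_weighted(raw, config.smooth_window)
    else:
        sm = raw
    ep = find_endpoints(sm, config)
    flags = []
    if ep.ambiguous:
        flags.append("endpoint_ambiguous")
    midline = None
    try:
        midline = compute_midline(sm, ep.head_index, config)
    except MidlineError:
        flags.append("midline_failed")
    return Posture(outline=sm, raw_outline=raw, endpoints=ep, midline=midline,
                   flags=tuple(flags))
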