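"""2D visual field reconstruction by ray casting against posture outlines.

Each individual gets two eyes placed just inside its outline near the
snout, spaced by the local body thickness.  From each eye, rays are cast at
a fixed angular resolution (body-relative angles) and intersected with the
outline polygons of every individual, including the focal one
(self-occlusion).  Per angular bin, the nearest hit fills the first
occlusion order and subsequent hits from other occluders fill higher
orders; each order stores three channels: occluder identity, distance, and
the body part that was hit (outline arc position from the occluder's head,
in percent of its perimeter).

Each eye covers a field of ``fov`` degrees wrapped asymmetrically around
its gaze: it sees its whole lateral hemifield from straight back around to
``fov - 180`` degrees past the front on the opposite side.  With the
default 260-degree fov this tiles the full circle with a frontal binocular
overlap of 2*fov - 360 = 160 degrees, as in laterally-eyed fish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .posture import Midline, Outline, Posture

__all__ = ["EyeConfig", "Eye", "VisualField", "place_eyes", "compute_visual_field",
           "export_visual_fields"]


@dataclass
class EyeConfig:
    fov: float = 260.0  # degrees per eye
    rays: int = 512  # angular bins over the full 360 degrees
    eye_offset_ratio: float = 0.1  # along the midline, back from the snout
    eye_separation_ratio: float = 0.9  # fraction of local half-thickness
    eye_rotation: float = 0.0  # degrees, rotates gaze away from the body axis
    max_orders: int = 2

    def validate(self) -> None:
        if not 0 < self.fov <= 360:
            raise ValueError("fov must be in (0, 360]")
        if self.rays < 8:
            raise ValueError("rays must be >= 8")
        if self.max_orders < 1:
            raise ValueError("max_orders must be >= 1")


@dataclass
class Eye:
    position: np.ndarray  # (2,) px
    gaze: float  # rad, world frame
    side: int  # -1 left, +1 right (relative to travel direction, y down)


@dataclass
class VisualField:
    """Channels indexed [eye, order, channel, bin].

    channel 0: occluder identity (-1 where nothing is seen / outside fov)
    channel 1: distance to the hit (px; NaN where empty)
    channel 2: body part hit (percent of outline perimeter from the head)

    Bin ``k`` covers equal angle; bin centres map the body-relative range
    (-180, 180].  ``bin_angles`` gives the centres in degrees.
    """

    data: np.ndarray  # (2, max_orders, 3, rays) float
    bin_angles: np.ndarray  # (rays,) degrees in (-180, 180]
    fov_mask: np.ndarray  # (2, rays) bool: bin within that eye's fov

    @property
    def identity(self) -> np.ndarray:
        return self.data[:, :, 0, :]

    @property
    def distance(self) -> np.ndarray:
        return self.data[:, :, 1, :]

    @property
    def body_part(self) -> np.ndarray:
        return self.data[:, :, 2, :]


def place_eyes(midline: Midline, outline: Outline, config: EyeConfig) -> tuple[Eye, Eye]:
    """Two eyes near the snout, mirrored about the midline.

    The anchor sits ``eye_offset_ratio`` along the midline from the head;
    eyes are offset perpendicular to the local midline direction by
    ``eye_separation_ratio * local thickness / 2`` and gaze along the local
    direction rotated by +-``eye_rotation``.
    """
    config.validate()
    if midline is None:
        raise ValueError("visual field needs a valid midline")
    pts = midline.points
    d = np.diff(pts, axis=0)
    seg = np.hypot(d[:, 0], d[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    s0 = config.eye_offset_ratio * total
    x = np.interp(s0, cum, pts[:, 0])
    y = np.interp(s0, cum, pts[:, 1])
    th = np.interp(s0, cum, midline.thickness)
    idx = min(np.searchsorted(cum, s0, side="right"), len(seg)) - 1
    idx = max(idx, 0)
    tangent = math.atan2(d[idx, 1], d[idx, 0])
    # midline runs head -> tail; gaze is forward (away from the tail)
    gaze_fwd = tangent + math.pi
    half = config.eye_separation_ratio * th / 2.0
    rot = math.radians(config.eye_rotation)
    eyes = []
    for side in (-1, +1):
        nx = math.cos(gaze_fwd + side * math.pi / 2.0)
        ny = math.sin(gaze_fwd + side * math.pi / 2.0)
        eyes.append(Eye(position=np.array([x + half * nx, y + half * ny]),
                        gaze=_wrap(gaze_fwd + side * rot), side=side))
    return eyes[0], eyes[1]


def _wrap(a):
    return (np.asarray(a) + np.pi) % (2.0 * np.pi) - np.pi


def _ray_segment_hits(origin, angles, seg_a, seg_b):
    """Intersect rays (origin, angle) with segments a->b.

    Returns (t, u, valid): t ray distances (R, S), u segment parameters.
    """
    dx = np.cos(angles)[:, None]
    dy = np.sin(angles)[:, None]
    ax = seg_a[None, :, 0] - origin[0]
    ay = seg_a[None, :, 1] - origin[1]
    ex = (seg_b[:, 0] - seg_a[:, 0])[None, :]
    ey = (seg_b[:, 1] - seg_a[:, 1])[None, :]
    denom = dx * ey - dy * ex
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ax * ey - ay * ex) / denom
        u = (ax * dy - ay * dx) / denom
    valid = (np.abs(denom) > 1e-12) & (t > 1e-9) & (u >= 0.0) & (u < 1.0)
    return t, u, valid


def compute_visual_field(focal_id: int, postures: dict[int, Posture],
                         config: EyeConfig) -> VisualField:
    """Cast rays from the focal individual's eyes against every outline.

    ``postures`` maps identity -> :class:`Posture` (possibly the last
    available posture for currently undetected individuals).  The focal
    posture must have a valid midline.  For the focal outline, hits closer
    than a small guard distance are discarded: the eyes sit just inside the
    body, so every ray trivially crosses the local boundary, and only
    genuine self-occlusion (the body blocking rays) should register.
    """
    config.validate()
    focal = postures[focal_id]
    if focal.midline is None:
        raise ValueError("visual field unavailable: focal posture has no midline")
    left, right = place_eyes(focal.midline, focal.outline, config)
    body_axis = left.gaze - math.radians(config.eye_rotation) * left.side

    rays = config.rays
    # bin centres over (-180, 180], body-relative
    bin_angles = -180.0 + (np.arange(rays) + 0.5) * (360.0 / rays)
    world_angles = np.radians(bin_angles) + body_axis

    # collect all outline segments with per-segment metadata
    seg_a, seg_b, seg_id = [], [], []
    seg_base, seg_len, seg_per = [], [], []  # arc-from-head bookkeeping
    for ident, post in sorted(postures.items()):
        pts = post.outline.points
        nxt = np.roll(pts, -1, axis=0)
        arcs = post.outline.arc_lengths()
        per = post.outline.perimeter
        head = post.endpoints.head_index
        d = nxt - pts
        lens = np.hypot(d[:, 0], d[:, 1])
        seg_a.append(pts)
        seg_b.append(nxt)
        seg_id.append(np.full(len(pts), ident))
        seg_base.append((arcs - arcs[head]) % per)
        seg_len.append(lens)
        seg_per.append(np.full(len(pts), per))
    seg_a = np.concatenate(seg_a)
    seg_b = np.concatenate(seg_b)
    seg_id = np.concatenate(seg_id)
    seg_base = np.concatenate(seg_base)
    seg_len = np.concatenate(seg_len)
    seg_per = np.concatenate(seg_per)

    # the eyes sit just inside the body: ignore the trivial crossing of the
    # local boundary, keep genuine self-occlusion (rays blocked by the body)
    guard = max(2.0, 0.75 * float(np.max(focal.midline.thickness)))

    data = np.full((2, config.max_orders, 3, rays), np.nan)
    data[:, :, 0, :] = -1.0
    fov_mask = np.zeros((2, rays), dtype=bool)

    for ei, eye in enumerate((left, right)):
        # asymmetric fov window around the gaze (see module docstring)
        rel = np.degrees(_wrap(world_angles - eye.gaze))
        if eye.side < 0:  # left eye: from its own side (back) across the front
            lo, hi = -(config.fov - 180.0), 180.0
        else:
            lo, hi = -180.0, config.fov - 180.0
        if config.fov >= 360.0:
            inside = np.ones(rays, dtype=bool)
        else:
            inside = (rel >= lo) & (rel <= hi)
        fov_mask[ei] = inside
        t, u, valid = _ray_segment_hits(eye.position, world_angles, seg_a, seg_b)
        self_hit = seg_id[None, :] == focal_id
        valid &= ~(self_hit & (t < guard))
        for k in np.nonzero(inside)[0]:
            hit_idx = np.nonzero(valid[k])[0]
            if hit_idx.size == 0:
                continue
            order = np.argsort(t[k, hit_idx], kind="stable")
            seen: list[int] = []
            for h in hit_idx[order]:
                ident = int(seg_id[h])
                if ident in seen:
                    continue
                o = len(seen)
                if o >= config.max_orders:
                    break
                dist = float(t[k, h])
                arc = (seg_base[h] + u[k, h] * seg_len[h]) % seg_per[h]
                data[ei, o, 0, k] = ident
                data[ei, o, 1, k] = dist
                data[ei, o, 2, k] = float(arc / seg_per[h] * 100.0)
                seen.append(ident)
    return VisualField(data=data, bin_angles=bin_angles, fov_mask=fov_mask)


def export_visual_fields(fields: dict, path, legend_path=None) -> None:
    """Write visual fields to a columnar NPZ archive.

    ``fields`` maps (frame, individual) or individual -> :class:`VisualField`.
    Each field is stored under ``vf_<frame>_<individual>`` (or
    ``vf_<individual>``) as its [eye, order, channel, bin] array; bin centre
    angles go under ``bin_angles``.  A channel legend is written as a
    sidecar CSV when ``legend_path`` is given.
    """
    arrays = {}
    bin_angles = None
    for key, field in fields.items():
        name = "vf_" + ("_".join(str(k) for k in key) if isinstance(key, tuple)
                        else str(key))
        arrays[name] = field.data
        bin_angles = field.bin_angles
    if bin_angles is not None:
        arrays["bin_angles"] = bin_angles
    np.savez(path, **arrays)
    if legend_path is not None:
        with open(legend_path, "w") as fh:
            fh.write("axis,index,meaning\n")
            fh.write("eye,0,left\neye,1,right\n")
            fh.write("channel,0,occluder identity (-1 = none)\n")
            fh.write("channel,1,distance to occluder (px)\n")
            fh.write("channel,2,body part hit (% of outline from head)\n")
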