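"""Ground-truthed synthetic scenes for exercising the tracking pipeline.

Agents are elongated, individually textured bodies moving by smooth correlated
random walks over a static background.  Crossings between pairs of agents are
scheduled as a Poisson process and realised by steering both members of a pair
toward a common meeting point, which produces the touching/overlapping blobs
the splitting and re-identification code paths need.  Every frame comes with
exact ground truth (centroid, heading, visibility), so any tracking or
identification output can be scored against it.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "simulate_trajectories",
    "render_scene",
    "generate_dataset",
    "score_identity_accuracy",
]


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic scene.

    Distances are in pixels, speeds in px/frame, angles in radians and
    intensities in 8-bit grayscale units.  ``overlap_rate`` is the expected
    number of scripted crossings per agent per minute of video.
    """

    n_agents: int = 4
    frame_size: tuple[int, int] = (256, 256)  # (width, height)
    n_frames: int = 200
    fps: float = 25.0
    agent_length: float = 24.0
    agent_width: float = 8.0
    speed_mean: float = 2.5
    speed_sd: float = 0.8
    turn_sd: float = 0.18
    texture_contrast: float = 40.0
    overlap_rate: float = 0.0
    disappear_prob: float = 0.0
    background_level: int = 200
    noise_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")
        if self.frame_size[0] <= 0 or self.frame_size[1] <= 0:
            raise ValueError("frame_size dimensions must be positive")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.agent_length <= 0 or self.agent_width <= 0:
            raise ValueError("agent dimensions must be positive")
        if not 0.0 <= self.disappear_prob <= 1.0:
            raise ValueError("disappear_prob must be in [0, 1]")
        if self.speed_sd < 0 or self.turn_sd < 0 or self.noise_sd < 0:
            raise ValueError("spread parameters (speed_sd, turn_sd, noise_sd) must be >= 0")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must be an 8-bit grayscale value")


@dataclass
class GroundTruth:
    """Per-frame, per-agent truth: centroids, headings and visibility.

    ``x``/``y``/``heading`` have shape (n_frames, n_agents); ``visible`` is a
    boolean array of the same shape.  ``crossing_events`` lists the scripted
    crossings as (frame, agent_a, agent_b) tuples.
    """

    x: np.ndarray
    y: np.ndarray
    heading: np.ndarray
    visible: np.ndarray
    crossing_events: list[tuple[int, int, int]] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return self.x.shape[0]

    @property
    def n_agents(self) -> int:
        return self.x.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: frame, id, x, y, heading, visible."""
        f, a = np.meshgrid(np.arange(self.n_frames), np.arange(self.n_agents), indexing="ij")
        return pd.DataFrame(
            {
                "frame": f.ravel(),
                "id": a.ravel(),
                "x": self.x.ravel(),
                "y": self.y.ravel(),
                "heading": self.heading.ravel(),
                "visible": self.visible.ravel(),
            }
        )


def _wrap_angle(a):
    """Map angles to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a), 2.0 * np.pi)


def simulate_trajectories(config: SceneConfig) -> GroundTruth:
    """Correlated random walk paths with reflection at arena borders.

    Per-frame speed is a normal draw clipped at zero; heading increments are
    normal with sd ``turn_sd``.  Scripted crossings (Poisson with rate
    ``overlap_rate`` per agent per minute) temporarily steer a pair toward a
    common meeting point.  Deterministic per (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    w, h = config.frame_size
    n, t_total = config.n_agents, config.n_frames
    margin = config.agent_length / 2.0 + 2.0
    if 2 * margin >= min(w, h):
        margin = min(w, h) / 4.0

    x = np.empty((t_total, n))
    y = np.empty((t_total, n))
    heading = np.empty((t_total, n))
    visible = np.ones((t_total, n), dtype=bool)

    x[0] = rng.uniform(margin, w - margin, n)
    y[0] = rng.uniform(margin, h - margin, n)
    heading[0] = rng.uniform(-np.pi, np.pi, n)

    # Poisson-scheduled crossing events; each steers a random pair toward a
    # meeting point over `approach` frames.
    events: list[tuple[int, int, int]] = []
    approach = 30
    if config.overlap_rate > 0 and n >= 2 and t_total > approach:
        minutes = t_total / config.fps / 60.0
        lam = config.overlap_rate * n * minutes
        n_events = int(rng.poisson(lam))
        for _ in range(n_events):
            t_ev = int(rng.integers(approach, t_total))
            a, b = rng.choice(n, size=2, replace=False)
            events.append((t_ev, int(a), int(b)))
        events.sort()
    # steer[t, agent] -> meeting point or NaN
    steer = np.full((t_total, n, 2), np.nan)

    speeds = np.clip(rng.normal(config.speed_mean, config.speed_sd, (t_total, n)), 0.0, None)
    turns = rng.normal(0.0, config.turn_sd, (t_total, n))
    vis_draw = rng.uniform(0.0, 1.0, (t_total, n))
    meet_jitter = rng.uniform(-0.15, 0.15, (len(events), 2))

    for k, (t_ev, a, b) in enumerate(events):
        t0 = max(1, t_ev - approach)
        for t in range(t0, min(t_ev, t_total)):
            # meeting point fixed lazily at steering start from current midpoint
            steer[t, a, 0] = steer[t, b, 0] = k
            steer[t, a, 1] = steer[t, b, 1] = t_ev

    meet_points: dict[int, np.ndarray] = {}

    for t in range(1, t_total):
        heading[t] = _wrap_angle(heading[t - 1] + turns[t])
        for i in range(n):
            if not np.isnan(steer[t, i, 0]):
                k = int(steer[t, i, 0])
                if k not in meet_points:
                    # transversal crossing: both agents steer toward the
                    # midpoint of their positions extrapolated to the event
                    # frame, so their paths cross at speed instead of
                    # converging head-on and dwelling
                    t_ev, a, b = events[k]
                    horizon = max(t_ev - (t - 1), 1)
                    xa = x[t - 1, a] + config.speed_mean * horizon * np.cos(heading[t - 1, a])
                    ya = y[t - 1, a] + config.speed_mean * horizon * np.sin(heading[t - 1, a])
                    xb = x[t - 1, b] + config.speed_mean * horizon * np.cos(heading[t - 1, b])
                    yb = y[t - 1, b] + config.speed_mean * horizon * np.sin(heading[t - 1, b])
                    mp = np.array([(xa + xb) / 2.0, (ya + yb) / 2.0])
                    mp += meet_jitter[k] * config.agent_length
                    mp[0] = np.clip(mp[0], margin, w - margin)
                    mp[1] = np.clip(mp[1], margin, h - margin)
                    meet_points[k] = mp
                mp = meet_points[k]
                target = np.arctan2(mp[1] - y[t - 1, i], mp[0] - x[t - 1, i])
                # blend toward the target direction for a smooth approach
                delta = _wrap_angle(target - heading[t, i])
                heading[t, i] = _wrap_angle(heading[t, i] + 0.35 * delta)
        dx = speeds[t] * np.cos(heading[t])
        dy = speeds[t] * np.sin(heading[t])
        x[t] = x[t - 1] + dx
        y[t] = y[t - 1] + dy
        # reflect at borders
        for arr, lim in ((x, w), (y, h)):
            low = arr[t] < margin
            high = arr[t] > lim - margin
            arr[t][low] = 2 * margin - arr[t][low]
            arr[t][high] = 2 * (lim - margin) - arr[t][high]
        refl = (x[t] != x[t - 1] + dx) | (y[t] != y[t - 1] + dy)
        if refl.any():
            heading[t][refl] = np.arctan2((y[t] - y[t - 1])[refl], (x[t] - x[t - 1])[refl])
        visible[t] = vis_draw[t] >= config.disappear_prob

    return GroundTruth(x=x, y=y, heading=heading, visible=visible, crossing_events=events)


# ---------------------------------------------------------------------------
# Rendering


def _texture_coeffs(rng: np.random.Generator, n_agents: int, n_terms: int = 4) -> np.ndarray:
    """Per-identity fixed low-frequency texture coefficients."""
    amp = rng.uniform(0.4, 1.0, (n_agents, n_terms))
    phase = rng.uniform(0.0, 2 * np.pi, (n_agents, n_terms))
    freq = rng.uniform(1.0, 3.5, (n_agents, n_terms))
    out = np.stack([amp, phase, freq], axis=-1)
    return out


def _render_agent(frame: np.ndarray, cx: float, cy: float, th: float, config: SceneConfig,
                  coeffs: np.ndarray) -> None:
    """Draw one capsule-shaped textured agent into ``frame`` (in place)."""
    h_img, w_img = frame.shape
    half_len = (config.agent_length - config.agent_width) / 2.0
    radius = config.agent_width / 2.0
    # capsule endpoints (head toward +heading)
    ex, ey = np.cos(th), np.sin(th)
    hx, hy = cx + half_len * ex, cy + half_len * ey
    tx, ty = cx - half_len * ex, cy - half_len * ey

    x0 = max(0, int(np.floor(min(hx, tx) - radius - 1)))
    x1 = min(w_img, int(np.ceil(max(hx, tx) + radius + 2)))
    y0 = max(0, int(np.floor(min(hy, ty) - radius - 1)))
    y1 = min(h_img, int(np.ceil(max(hy, ty) + radius + 2)))
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    px = xx + 0.5 - tx
    py = yy + 0.5 - ty
    seg = np.array([hx - tx, hy - ty])
    seg_len2 = seg @ seg
    tpar = np.clip((px * seg[0] + py * seg[1]) / max(seg_len2, 1e-12), 0.0, 1.0)
    dx = px - tpar * seg[0]
    dy = py - tpar * seg[1]
    dist = np.hypot(dx, dy)
    # teardrop: taper the radius toward the tail end
    local_r = radius * (0.55 + 0.45 * np.sqrt(np.clip(tpar, 0.0, 1.0)))
    mask = dist <= local_r

    # body coordinates: u along the axis in [0, 1] (tail->head), v across
    u = tpar[mask]
    base = config.background_level - 110.0  # base darkness of the body
    tex = np.zeros_like(u)
    for amp, phase, freq in coeffs:
        tex += amp * np.cos(2 * np.pi * freq * u + phase)
    # normalize the pattern to unit peak so texture_contrast is the actual
    # peak intensity modulation of the body
    uu = np.linspace(0.0, 1.0, 64)
    peak = max(np.abs(sum(a * np.cos(2 * np.pi * f * uu + p)
                          for a, p, f in coeffs)).max(), 1e-9)
    body = base + config.texture_contrast * tex / peak
    sub = frame[y0:y1, x0:x1]
    sub[mask] = np.clip(body, 0.0, 255.0)


def render_scene(truth: GroundTruth, config: SceneConfig) -> np.ndarray:
    """Render grayscale frames (n_frames, height, width) uint8 from truth.

    Visible agents are drawn as tapered capsules darker than the background,
    each carrying a fixed per-identity low-frequency texture; i.i.d. Gaussian
    noise with sd ``noise_sd`` is added and the result quantised to 8 bits.
    """
    config.validate()
    if truth.n_agents != config.n_agents or truth.n_frames != config.n_frames:
        raise ValueError("ground truth is inconsistent with the scene config")
    w, h = config.frame_size
    rng = np.random.default_rng(config.seed + 1_000_003)
    coeffs = _texture_coeffs(rng, config.n_agents)
    frames = np.empty((config.n_frames, h, w), dtype=np.uint8)
    for t in range(config.n_frames):
        img = np.full((h, w), float(config.background_level))
        for i in range(config.n_agents):
            if truth.visible[t, i]:
                _render_agent(img, truth.x[t, i], truth.y[t, i], truth.heading[t, i],
                              config, coeffs[i])
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, img.shape)
        frames[t] = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return frames


def generate_dataset(config: SceneConfig, out_dir: str | None = None) -> tuple[np.ndarray, GroundTruth]:
    """Simulate and render a full scene; optionally write fixtures to disk.

    When ``out_dir`` is given, frames are written as 8-bit grayscale PNGs and
    the ground truth as CSV and a columnar NPZ archive.
    """
    truth = simulate_trajectories(config)
    frames = render_scene(truth, config)
    if out_dir is not None:
        import imageio.v3 as iio

        try:
            os.makedirs(out_dir, exist_ok=True)
            for t in range(frames.shape[0]):
                iio.imwrite(os.path.join(out_dir, f"frame_{t:06d}.png"), frames[t])
            truth.to_frame().to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False)
            np.savez(
                os.path.join(out_dir, "ground_truth.npz"),
                x=truth.x, y=truth.y, heading=truth.heading, visible=truth.visible,
            )
            with open(os.path.join(out_dir, "scene_config.txt"), "w") as fh:
                for f in dataclasses.fields(config):
                    fh.write(f"{f.name}={getattr(config, f.name)}\n")
        except OSError as exc:
            raise OSError(f"failed to write dataset fixtures to {out_dir}: {exc}") from exc
    return frames, truth


# ---------------------------------------------------------------------------
# Scoring


def _centroid_table(sol) -> pd.DataFrame:
    df = sol.to_frame() if hasattr(sol, "to_frame") else pd.DataFrame(sol)
    required = {"frame", "id", "x", "y"}
    if not required.issubset(df.columns):
        raise ValueError(f"trajectory table must have columns {sorted(required)}")
    if "visible" in df.columns:
        df = df[df["visible"].astype(bool)]
    df = df.dropna(subset=["x", "y"])
    return df

def score_identity_accuracy(solution_a, solution_b, width: float):
    """Similarity of two trajectory tables under a 1%-of-video-width rule.

    Identity labels of the two solutions are matched globally by minimising
    the mean per-frame euclidean distance (bipartite assignment), so a pure
    relabelling scores 1.0.  Per frame, a matched individual counts as wrong
    when its distance exceeds ``0.01 * width``.  Returns ``(similarity,
    coverage)`` where similarity is the fraction of correct (frame,
    individual) pairs among those present in both solutions and ``coverage``
    maps each A-identity to the fraction of its frames matched in B.
    """
    a = _centroid_table(solution_a)
    b = _centroid_table(solution_b)
    common = np.intersect1d(a["frame"].unique(), b["frame"].unique())
    if common.size == 0:
        raise ValueError("solutions share no frames; similarity undefined")
    a = a[a["frame"].isin(common)]
    b = b[b["frame"].isin(common)]
    ids_a = np.sort(a["id"].unique())
    ids_b = np.sort(b["id"].unique())

    pa = a.pivot_table(index="frame", columns="id", values=["x", "y"])
    pb = b.pivot_table(index="frame", columns="id", values=["x", "y"])
    frames = pa.index.intersection(pb.index)
    pa = pa.loc[frames]
    pb = pb.loc[frames]

    ax = pa["x"].reindex(columns=ids_a).to_numpy()  # (F, Na)
    ay = pa["y"].reindex(columns=ids_a).to_numpy()
    bx = pb["x"].reindex(columns=ids_b).to_numpy()
    by = pb["y"].reindex(columns=ids_b).to_numpy()

    # mean distance cost matrix over co-present frames
    dx = ax[:, :, None] - bx[:, None, :]
    dy = ay[:, :, None] - by[:, None, :]
    dist = np.hypot(dx, dy)  # (F, Na, Nb) with NaN where absent
    with np.errstate(invalid="ignore"):
        mean_dist = np.nanmean(dist, axis=0)
    # pairs never co-present get a large finite cost
    big = np.nanmax(mean_dist[np.isfinite(mean_dist)]) if np.isfinite(mean_dist).any() else 1.0
    cost = np.where(np.isfinite(mean_dist), mean_dist, big * 10 + 1e6)
    rows, cols = linear_sum_assignment(cost)

    tol = 0.01 * float(width)
    n_correct = 0
    n_total = 0
    coverage: dict[int, float] = {}
    for r, c in zip(rows, cols):
        d = dist[:, r, c]
        present = np.isfinite(d)
        n_a_present = int(np.isfinite(ax[:, r]).sum())
        n_total += int(present.sum())
        n_correct += int((d[present] <= tol).sum())
        coverage[int(ids_a[r])] = present.sum() / n_a_present if n_a_present else 0.0
    similarity = n_correct / n_total if n_total else 0.0
    return similarity, coverage
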