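"""Frame-to-frame data association and trajectory maintenance.

Each frame, every active trajectory predicts its next position from an
exponentially weighted mean of its recent velocities (rotated by its mean
angular speed — a light-weight stand-in for a full Kalman filter).  Every
trajectory/blob pair inside a hard search radius receives a probability from
a Gaussian kernel on the prediction error; pairs above a threshold form a
sparse graph whose connected components ("cliques") are matched
independently.  The default matcher enumerates conflict-free assignment sets
in a branch-and-bound tree (exact optimum of the probability sum) and falls
back on the Hungarian method when the tree grows past a node cap; a greedy
approximation is available for very large groups.  Touching individuals are
separated by re-thresholding the background-difference image of the merged
blob at increasing thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import linear_sum_assignment

from .segmentation import Blob, _STRUCT8

__all__ = [
    "TrackerConfig",
    "Individual",
    "MatchClique",
    "Assignment",
    "TreeComplexityExceeded",
    "predict_state",
    "match_probability",
    "build_cliques",
    "tree_match",
    "hungarian_match",
    "greedy_match",
    "split_overlapping",
    "Tracker",
]


@dataclass
class TrackerConfig:
    track_max_individuals: int | str = "unknown"  # count, or "unknown"
    track_max_speed: float = 300.0  # px / s
    matching_probability_threshold: float = 0.1
    max_reassign_time: float = 0.5  # s
    clique_node_cap: int = 100_000
    matcher: str = "tree"  # tree | hungarian | approximate
    segmentation_threshold: int = 25  # start point for overlap splitting

    def validate(self) -> None:
        if self.track_max_speed <= 0:
            raise ValueError("track_max_speed must be positive")
        if not 0.0 < self.matching_probability_threshold < 1.0:
            raise ValueError("matching_probability_threshold must be in (0, 1)")
        if self.max_reassign_time <= 0:
            raise ValueError("max_reassign_time must be positive")
        if self.matcher not in ("tree", "hungarian", "approximate"):
            raise ValueError("matcher must be tree, hungarian or approximate")

    @property
    def known_count(self) -> bool:
        return self.track_max_individuals != "unknown"


@dataclass
class Assignment:
    """One blob assigned to one individual in one frame."""

    frame: int
    time: float
    x: float
    y: float
    probability: float
    blob: Blob | None = None
    speed: float = 0.0
    heading: float = 0.0
    midline_length: float | None = None


@dataclass
class Segment:
    start: int
    end: int
    reason: str  # "start" | "lost" | "uncertain" | "timestamp_gap"


class Individual:
    """Per-identity time series of assigned blobs with segment bookkeeping."""

    def __init__(self, identity: int):
        self.identity = identity
        self.assignments: dict[int, Assignment] = {}
        self.segments: list[Segment] = []
        self.velocities: list[tuple[float, float]] = []  # px/s, recent last
        self.angular_speeds: list[float] = []  # rad/s
        self.last_frame: int | None = None
        self.last_time: float | None = None
        self.final_identity: int | None = None

    @property
    def last_position(self) -> tuple[float, float]:
        a = self.assignments[self.last_frame]
        return (a.x, a.y)

    @property
    def last_heading(self) -> float:
        return self.assignments[self.last_frame].heading

    def segment_of_frame(self, frame: int) -> int | None:
        for i, seg in enumerate(self.segments):
            if seg.start <= frame <= seg.end:
                return i
        return None

    def add(self, a: Assignment, new_segment_reason: str | None) -> None:
        if a.frame in self.assignments:
            raise RuntimeError(f"individual {self.identity} already has a blob in frame {a.frame}")
        if self.last_time is not None:
            dt = a.time - self.last_time
            prev = self.assignments[self.last_frame]
            vx, vy = (a.x - prev.x) / dt, (a.y - prev.y) / dt
            a.speed = math.hypot(vx, vy)
            a.heading = math.atan2(vy, vx) if a.speed > 1e-9 else prev.heading
            self.velocities.append((vx, vy))
            dh = _wrap(a.heading - prev.heading)
            self.angular_speeds.append(dh / dt)
            if len(self.velocities) > 5:
                del self.velocities[0]
                del self.angular_speeds[0]
        self.assignments[a.frame] = a
        if not self.segments:
            self.segments.append(Segment(a.frame, a.frame, "start"))
        elif new_segment_reason is not None:
            self.segments.append(Segment(a.frame, a.frame, new_segment_reason))
        else:
            self.segments[-1].end = a.frame
        self.last_frame = a.frame
        self.last_time = a.time


def _wrap(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


# ---------------------------------------------------------------------------
# Prediction and match probability


_HALF_LIFE_FRAMES = 2.0  # velocity EW-mean half-life
_N_VELOCITIES = 5


def predict_state(individual: Individual, t: float) -> tuple[tuple[float, float], float]:
    """Predicted (position, heading) at time ``t``.

    The position is extrapolated with an exponentially weighted mean of the
    last <=5 velocities (half-life two frames) rotated by the mean angular
    speed over the prediction horizon; with a single observation the
    prediction is simply the last position.
    """
    if individual.last_time is None:
        raise ValueError("cannot predict from an individual with no history")
    x0, y0 = individual.last_position
    h0 = individual.last_heading
    dt = t - individual.last_time
    vels = individual.velocities[-_N_VELOCITIES:]
    if not vels or dt <= 0:
        return (x0, y0), h0
    w = np.array([0.5 ** (k / _HALF_LIFE_FRAMES) for k in range(len(vels) - 1, -1, -1)])
    w /= w.sum()
    v = np.asarray(vels)
    vbar = (w[:, None] * v).sum(axis=0)
    om = individual.angular_speeds[-_N_VELOCITIES:]
    ombar = float((w * np.asarray(om)).sum()) if om else 0.0
    rot = ombar * dt
    c, s = math.cos(rot), math.sin(rot)
    vx = c * vbar[0] - s * vbar[1]
    vy = s * vbar[0] + c * vbar[1]
    return (x0 + vx * dt, y0 + vy * dt), _wrap(h0 + rot)


def match_probability(individual: Individual, blob: Blob, t: float,
                      config: TrackerConfig, frame_interval: float) -> float:
    """Probability of extending ``individual`` with ``blob`` at time ``t``.

    Gaussian kernel on the prediction error d with sigma = R/3 where
    R = track_max_speed * dt is a hard search radius (p = 0 beyond it),
    multiplied by a time-gap decay 0.5 ** (gap_s / max_reassign_time) that
    penalises reappearance after lost frames.
    """
    dt = t - individual.last_time
    if dt <= 0:
        return 0.0
    (px, py), _ = predict_state(individual, t)
    bx, by = blob.centroid
    d = math.hypot(bx - px, by - py)
    radius = config.track_max_speed * dt
    if d > radius:
        return 0.0
    sigma = radius / 3.0
    gap = max(0.0, dt - frame_interval)
    g = 0.5 ** (gap / config.max_reassign_time)
    return math.exp(-(d * d) / (2.0 * sigma * sigma)) * g


# ---------------------------------------------------------------------------
# Cliques and matchers


@dataclass
class MatchClique:
    """A connected component of the above-threshold probability graph."""

    trajectories: list[int]  # identities
    blobs: list[int]  # blob indices into the frame's blob list
    edges: dict[tuple[int, int], float] = field(default_factory=dict)  # (identity, blob) -> p


class TreeComplexityExceeded(RuntimeError):
    """Signals that tree matching exceeded its node cap (fall back on Hungarian)."""


def build_cliques(individuals: dict[int, Individual], blobs: list[Blob], t: float,
                  config: TrackerConfig, frame_interval: float):
    """Compute match probabilities, drop edges <= threshold, and return the
    connected components of the resulting bipartite graph, plus the lists of
    unmatched identities and blob indices."""
    edges: dict[tuple[int, int], float] = {}
    for ident, ind in individuals.items():
        for bi, blob in enumerate(blobs):
            p = match_probability(ind, blob, t, config, frame_interval)
            if p > config.matching_probability_threshold:
                edges[(ident, bi)] = p
    # union-find over nodes ("t", ident) and ("b", bi)
    parent: dict = {}

    def find(u):
        while parent[u] != u:
            parent[u] = parent[parent[u]]
            u = parent[u]
        return u

    def union(u, v):
        parent.setdefault(u, u)
        parent.setdefault(v, v)
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[rv] = ru

    for (ident, bi) in edges:
        union(("t", ident), ("b", bi))
    comps: dict = {}
    for (ident, bi), p in edges.items():
        root = find(("t", ident))
        c = comps.setdefault(root, MatchClique(trajectories=[], blobs=[], edges={}))
        if ident not in c.trajectories:
            c.trajectories.append(ident)
        if bi not in c.blobs:
            c.blobs.append(bi)
        c.edges[(ident, bi)] = p
    cliques = []
    for c in comps.values():
        c.trajectories.sort()
        c.blobs.sort()
        cliques.append(c)
    cliques.sort(key=lambda c: c.trajectories[0])
    matched_t = {i for c in cliques for i in c.trajectories}
    matched_b = {b for c in cliques for b in c.blobs}
    unmatched_t = [i for i in sorted(individuals) if i not in matched_t]
    unmatched_b = [b for b in range(len(blobs)) if b not in matched_b]
    return cliques, unmatched_t, unmatched_b


def tree_match(clique: MatchClique, node_cap: int = 100_000) -> dict[int, int]:
    """Exact maximum of the probability sum over conflict-free partial
    assignments, by depth-first branch-and-bound.

    Trajectories are visited sorted by best edge descending; each may take
    any of its blobs (best first) or stay unassigned.  The optimistic bound
    is the sum of the best remaining edges.  Raises
    :class:`TreeComplexityExceeded` after ``node_cap`` explored nodes.
    """
    trajs = sorted(
        clique.trajectories,
        key=lambda i: (-max((clique.edges.get((i, b), 0.0) for b in clique.blobs), default=0.0), i),
    )
    options = {
        i: sorted(
            [(b, p) for (ti, b), p in clique.edges.items() if ti == i],
            key=lambda bp: (-bp[1], bp[0]),
        )
        for i in trajs
    }
    best_edge = [max((p for _, p in options[i]), default=0.0) for i in trajs]
    # suffix sums of best edges = optimistic bound
    suffix = np.concatenate([np.cumsum(best_edge[::-1])[::-1], [0.0]])

    best_total = -1.0
    best_assign: dict[int, int] = {}
    used: set[int] = set()
    current: dict[int, int] = {}
    nodes = 0

    def dfs(k: int, total: float) -> None:
        nonlocal best_total, best_assign, nodes
        nodes += 1
        if nodes > node_cap:
            raise TreeComplexityExceeded(f"explored more than {node_cap} nodes")
        if k == len(trajs):
            if total > best_total + 1e-15:
                best_total = total
                best_assign = dict(current)
            return
        if total + suffix[k] <= best_total + 1e-15:
            return  # cannot beat the incumbent
        i = trajs[k]
        for b, p in options[i]:
            if b in used:
                continue
            used.add(b)
            current[i] = b
            dfs(k + 1, total + p)
            del current[i]
            used.discard(b)
        dfs(k + 1, total)  # leave trajectory i unassigned

    dfs(0, 0.0)
    return best_assign


def hungarian_match(clique: MatchClique) -> dict[int, int]:
    """Optimal assignment by the Kuhn-Munkres algorithm on the rectangular
    probability matrix (missing edges cost 0); equals the tree optimum."""
    trajs, blobs = clique.trajectories, clique.blobs
    if not trajs or not blobs:
        return {}
    p = np.zeros((len(trajs), len(blobs)))
    for (i, b), prob in clique.edges.items():
        p[trajs.index(i), blobs.index(b)] = prob
    rows, cols = linear_sum_assignment(-p)
    return {trajs[r]: blobs[c] for r, c in zip(rows, cols) if p[r, c] > 0.0}


def greedy_match(clique: MatchClique, blob_order=None) -> dict[int, int]:
    """Approximate matcher: blobs processed in (y0, x0) bounding-box order,
    each taking its best still-available trajectory; no backtracking."""
    order = blob_order if blob_order is not None else sorted(clique.blobs)
    taken: set[int] = set()
    out: dict[int, int] = {}
    for b in order:
        cands = sorted(
            [(p, i) for (i, bb), p in clique.edges.items() if bb == b and i not in taken],
            key=lambda pi: (-pi[0], pi[1]),
        )
        if cands:
            p, i = cands[0]
            taken.add(i)
            out[i] = b
    return out


def assignment_total(clique: MatchClique, assign: dict[int, int]) -> float:
    return sum(clique.edges.get((i, b), 0.0) for i, b in assign.items())


# ---------------------------------------------------------------------------
# Overlap splitting


def split_overlapping(blob: Blob, expected_count: int, background: np.ndarray,
                      start_threshold: int = 25) -> tuple[list[Blob], bool]:
    """Split a merged blob by raising the background-difference threshold.

    The threshold increases in steps of 1 until at least ``expected_count``
    similarly sized components emerge (each >= 60% of the median component
    size); interior pixels lost to the higher threshold are re-attached to
    the nearest surviving component.  Returns ``(blobs, True)`` on success or
    ``([original blob], False)`` when no threshold separates the objects.
    """
    if expected_count < 2:
        raise ValueError("expected_count must be >= 2")
    x0, y0, w, h = blob.bbox
    mask = blob.mask()
    img = blob.image()
    bg = background[y0:y0 + h, x0:x0 + w].astype(float)
    diff = np.abs(img - bg)
    diff[~mask] = 0.0

    for thr in range(int(start_threshold), 255):
        fg = diff >= thr
        labels, n_lab = ndimage.label(fg, structure=_STRUCT8)
        if n_lab < expected_count:
            continue
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n_lab + 1))
        med = np.median(sizes)
        big = [lab for lab, s in enumerate(sizes, start=1) if s >= 0.6 * med]
        if len(big) < expected_count:
            continue
        # keep the similar-size components, re-attach all remaining blob
        # pixels (holes + small fragments) to the nearest kept component
        keep = np.isin(labels, big)
        seeds = np.where(keep, labels, 0)
        _, (iy, ix) = ndimage.distance_transform_edt(seeds == 0, return_indices=True)
        full = np.where(mask, seeds[iy, ix], 0)
        pieces = []
        for lab in big:
            ys, xs = np.nonzero(full == lab)
            pieces.append(Blob(ys=ys + y0, xs=xs + x0, values=img[ys, xs].astype(np.uint8)))
        pieces.sort(key=lambda b: (b.bbox[1], b.bbox[0]))
        return pieces, True
    return [blob], False


# ---------------------------------------------------------------------------
# The tracker


class Tracker:
    """Sequential frame-by-frame tracker.

    Feed frames in order with :meth:`advance_frame`; afterwards
    ``individuals`` maps identity to :class:`Individual`.
    """

    def __init__(self, config: TrackerConfig, background: np.ndarray | None = None):
        config.validate()
        self.config = config
        self.background = None if background is None else np.asarray(background)
        self.individuals: dict[int, Individual] = {}
        self.frame = -1
        self.prev_time: float | None = None
        self._intervals: list[float] = []
        self._blob_sizes: list[int] = []  # assigned single-blob sizes
        self.next_identity = 0

    # -- helpers

    @property
    def median_blob_size(self) -> float:
        "Running median pixel count of assigned blobs (one individual)."
        if not self._blob_sizes:
            return 0.0
        return float(np.median(self._blob_sizes[-500:]))

    @property
    def median_interval(self) -> float:
        if not self._intervals:
            return 0.0
        return float(np.median(self._intervals[-101:]))

    def _active(self, t: float) -> dict[int, Individual]:
        """Individuals still eligible for matching (seen recently enough)."""
        out = {}
        for ident, ind in self.individuals.items():
            if ind.last_time is None:
                continue
            gap = t - ind.last_time - self.median_interval
            if gap <= self.config.max_reassign_time + 1e-9:
                out[ident] = ind
        return out

    def _new_individual(self, blob: Blob, t: float, frame: int) -> None:
        ident = self.next_identity
        self.next_identity += 1
        ind = Individual(ident)
        cx, cy = blob.centroid
        ind.add(Assignment(frame=frame, time=t, x=cx, y=cy, probability=1.0, blob=blob), None)
        self.individuals[ident] = ind

    def _match_clique(self, clique: MatchClique) -> dict[int, int]:
        m = self.config.matcher
        if m == "hungarian":
            return hungarian_match(clique)
        if m == "approximate":
            return greedy_match(clique)
        try:
            return tree_match(clique, self.config.clique_node_cap)
        except TreeComplexityExceeded:
            return hungarian_match(clique)

    # -- main entry

    def advance_frame(self, blobs: list[Blob], t: float) -> None:
        """Process one frame's blobs at timestamp ``t`` (seconds)."""
        self.frame += 1
        frame = self.frame
        if self.prev_time is not None:
            if t <= self.prev_time:
                raise ValueError("timestamps must be strictly increasing")
            self._intervals.append(t - self.prev_time)

        if frame == 0 or not self.individuals:
            # initial frame: assign top-left to bottom-right
            ordered = sorted(blobs, key=lambda b: (b.bbox[1], b.bbox[0]))
            if self.config.known_count:
                ordered = ordered[: int(self.config.track_max_individuals)]
            for blob in ordered:
                self._new_individual(blob, t, frame)
            self.prev_time = t
            return

        interval = self.median_interval or (t - self.prev_time)
        active = self._active(t)
        blobs = list(blobs)

        # (1) known-count mode: try to split merged blobs when a clique has
        # fewer blobs than trajectories competing for them; a blob that
        # cannot be split stays unassigned (all involved individuals remain
        # lost until they are found separately again), because matching a
        # merged blob to one of its members would hijack that identity
        unsplittable: list[Blob] = []
        if self.config.known_count and self.background is not None:
            for _ in range(8):  # several rounds in case several blobs merged
                cliques, _, _ = build_cliques(active, blobs, t, self.config, interval)
                deficient = [c for c in cliques if len(c.blobs) < len(c.trajectories)]
                progressed = False
                med = self.median_blob_size
                for c in deficient:
                    missing = len(c.trajectories) - len(c.blobs)
                    largest = max(c.blobs, key=lambda bi: blobs[bi].n_pixels)
                    expected = 1 + missing
                    if med > 0 and blobs[largest].n_pixels < 0.6 * expected * med:
                        # too small to plausibly contain `expected` bodies:
                        # splitting would shred a single individual
                        continue
                    pieces, ok = split_overlapping(
                        blobs[largest], expected, self.background,
                        self.config.segmentation_threshold)
                    if not ok:
                        unsplittable.append(blobs[largest])
                    blobs = blobs[:largest] + blobs[largest + 1:] + (pieces if ok else [])
                    progressed = True
                    break  # blob indices changed; rebuild cliques
                if not progressed:
                    break

        # (2) build cliques and match
        cliques, unmatched_t, unmatched_b = build_cliques(active, blobs, t, self.config, interval)
        assigned_blobs: set[int] = set()
        timestamp_gap = (
            self.prev_time is not None
            and self.median_interval > 0
            and (t - self.prev_time) > 1.5 * self.median_interval
        )

        for clique in cliques:
            assign = self._match_clique(clique)
            for ident, bi in sorted(assign.items()):
                if bi in assigned_blobs:
                    raise RuntimeError("internal invariant violation: blob assigned twice")
                assigned_blobs.add(bi)
                ind = self.individuals[ident]
                p = clique.edges[(ident, bi)]
                reason = None
                if ind.last_frame is not None and frame - ind.last_frame > 1:
                    reason = "lost"
                elif timestamp_gap:
                    reason = "timestamp_gap"
                elif (1.0 - p) > 0.5:
                    reason = "uncertain"
                blob = blobs[bi]
                cx, cy = blob.centroid
                ind.add(Assignment(frame=frame, time=t, x=cx, y=cy, probability=p, blob=blob),
                        reason)
                self._blob_sizes.append(blob.n_pixels)

        # (4) unmatched individuals stay lost (drop-out is handled by _active)

        # (5) unmatched viable blobs -> new identities
        leftover = [bi for bi in range(len(blobs)) if bi not in assigned_blobs]
        for bi in sorted(leftover, key=lambda bi: (blobs[bi].bbox[1], blobs[bi].bbox[0])):
            if self.config.known_count:
                # only while fewer active identities than the known count
                if len(self._active(t)) < int(self.config.track_max_individuals):
                    self._new_individual(blobs[bi], t, frame)
            else:
                self._new_individual(blobs[bi], t, frame)

        self.prev_time = t

    # -- output

    def to_frame(self):
        """Long-format trajectory table (frame, id, x, y, heading, visible)."""
        import pandas as pd

        rows = []
        for ident, ind in sorted(self.individuals.items()):
            final = ind.final_identity if ind.final_identity is not None else ident
            for f, a in sorted(ind.assignments.items()):
                rows.append({"frame": f, "id": final, "x": a.x, "y": a.y,
                             "heading": a.heading, "visible": True})
        return pd.DataFrame(rows)
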