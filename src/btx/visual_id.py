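"""Uniqueness-guided visual identification of unmarked individuals.

Kinematic tracking alone accumulates identity mistakes at crossings.  This
module corrects them with an appearance classifier trained without any
manual labels: trajectories are cut into switch-free *consecutive segments*;
frame ranges where every individual sits inside one such segment (*global
segments*) provide safe training labels.  Training starts from the best
global segment and *accumulates* further ones, guided by a per-frame
*uniqueness* score (images of individuals in one frame should be predicted
as pairwise distinct identities)::

    uniqueness(x) = (|uids| / |f(x)|) * E(mean of claimed probabilities),
    E(v) = (1 + exp(-pi)) / (1 + exp(-pi * v))

where ``uids`` maps each claimed identity to the best probability claiming
it and ``f(x)`` is the list of tracked objects in frame x.  A training step
is kept only while the mean uniqueness stays within 99% of the best value
so far; accumulation stops when uniqueness exceeds 1 - 0.5/N or when per-
individual coverage gaps drop below 25% of the video.  Finally, per-segment
averaged predictions assign identities, with contested identities resolved
by

    S(p, x) = sig(p) + sig(x / (N_me + N_he)),  sig(x) = 1/(1 + e^(2*pi*(0.5-x)))

unless the ratio of the two best probabilities exceeds 0.6, in which case
the kinematic tracker's assignment is kept (deferred).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "VisualIdConfig",
    "ConsecutiveSegment",
    "GlobalSegment",
    "QualityMetrics",
    "AccumulationState",
    "LinearBackend",
    "MLPBackend",
    "split_into_segments",
    "find_global_segments",
    "segment_quality",
    "rank_global_segments",
    "frame_uniqueness",
    "average_uniqueness",
    "train_initial",
    "accumulation_step",
    "check_stopping",
    "train_final",
    "sig",
    "eq2_score",
    "assign_identities",
    "correct_switches",
    "AccumulationExhausted",
]


@dataclass
class VisualIdConfig:
    grid: int = 10  # coverage cells across the arena width
    keep_per_bin: int = 4  # global-segment candidates kept per video quarter
    uniqueness_samples: int = 100  # evenly spaced frames for the uniqueness curve
    max_epochs: int = 150
    memory_budget_bytes: int = 1_000_000_000  # caps the merged training set
    min_images_per_class: int = 5
    median_window: int = 25  # frames, for switch correction
    plateau_eps: float = 1e-3
    patience: int = 10
    deferral_ratio: float = 0.6  # R_max rule
    improvement_keep: float = 0.99  # 99%-of-best rejection
    max_accumulation_steps: int = 30
    seed: int = 0

    def validate(self) -> None:
        if self.grid < 1:
            raise ValueError("grid must be >= 1")
        if self.median_window % 2 != 1:
            raise ValueError("median_window must be odd")
        if not 0 < self.improvement_keep <= 1:
            raise ValueError("improvement_keep must be in (0, 1]")


# ---------------------------------------------------------------------------
# Classifier backends (numpy; deterministic per seed)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _focal_loss_grad(p: np.ndarray, y: np.ndarray, gamma: float = 2.0):
    """Categorical focal loss and its gradient w.r.t. the logits.

    Down-weighs classes that are already predicted reliably, which softens
    class imbalance.  ``y`` holds integer labels.
    """
    n = p.shape[0]
    pt = np.clip(p[np.arange(n), y], 1e-12, 1.0)
    loss = float(np.mean((1.0 - pt) ** gamma * (-np.log(pt))))
    # dL/dp_t, then chain through the softmax jacobian
    dl_dpt = gamma * (1.0 - pt) ** (gamma - 1.0) * np.log(pt) - (1.0 - pt) ** gamma / pt
    grad = p * (dl_dpt * pt)[:, None]
    grad[np.arange(n), y] -= dl_dpt * pt
    return loss, -grad / n


# early-stopping checks only engage after this many epochs, so that a slow
# warm-up is not mistaken for a plateau
_WARMUP_EPOCHS = 40


class _AdamOpt:
    def __init__(self, shapes, lr=0.05):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        out = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mh = self.m[i] / (1 - self.b1 ** self.t)
            vh = self.v[i] / (1 - self.b2 ** self.t)
            out.append(p - self.lr * mh / (np.sqrt(vh) + self.eps))
        return out


class LinearBackend:
    """Gradient-trained linear softmax classifier on down-sampled crops.

    The "fast" reference backend: 8-bit crops are bilinearly resized to
    ``input_size``, scaled to [-1, 1] (value / 127.5 - 1), flattened and
    classified by a single affine layer with softmax.  Training uses Adam on
    the categorical focal loss with a random x-shift augmentation, honouring
    the standard stopping criteria (epoch cap, plateau, overfitting, perfect
    training accuracy).  Deterministic given ``seed``.
    """

    hidden: tuple[int, ...] = ()

    def __init__(self, n_classes: int, input_size: tuple[int, int] = (16, 16),
                 seed: int = 0, lr: float = 0.05, augment_shift: int = 1):
        self.n_classes = n_classes
        self.input_size = input_size
        self.seed = seed
        self.lr = lr
        self.augment_shift = augment_shift
        self._rng = np.random.default_rng(seed)
        d = input_size[0] * input_size[1]
        dims = (d,) + tuple(self.hidden) + (n_classes,)
        self.weights = [self._rng.normal(0.0, 0.05, (dims[i], dims[i + 1]))
                        for i in range(len(dims) - 1)]
        self.biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
        # per-feature centering offset, fitted on the training set; removes
        # the large constant background component and conditions the descent
        self.center = np.zeros(d)

    # -- features

    def _features(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=float)
        if images.ndim == 2:
            images = images[None]
        h, w = self.input_size
        if images.shape[1:] != (h, w):
            zy = h / images.shape[1]
            zx = w / images.shape[2]
            images = np.stack([ndimage.zoom(im, (zy, zx), order=1) for im in images])
        x = images / 127.5 - 1.0
        return x.reshape(len(x), -1) - self.center

    # -- forward / backward

    def _forward(self, x: np.ndarray):
        acts = [x]
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = acts[-1] @ w + b
            if i < len(self.weights) - 1:
                z = np.tanh(z)
            acts.append(z)
        return acts[:-1], _softmax(acts[-1])

    def predict(self, images) -> np.ndarray:
        """Probability matrix (n_images, n_classes); rows sum to 1."""
        if len(images) == 0:
            return np.zeros((0, self.n_classes))
        _, p = self._forward(self._features(images))
        return p

    def _grads(self, acts, p, y):
        loss, dz = _focal_loss_grad(p, y)
        gw, gb = [], []
        for i in range(len(self.weights) - 1, -1, -1):
            gw.insert(0, acts[i].T @ dz)
            gb.insert(0, dz.sum(axis=0))
            if i > 0:
                da = dz @ self.weights[i].T
                dz = da * (1.0 - acts[i] ** 2)  # tanh'
        return loss, gw, gb

    def fit(self, images, labels, val_images=None, val_labels=None,
            max_epochs: int = 150, plateau_eps: float = 1e-3, patience: int = 10,
            batch_size: int = 128) -> dict:
        """Train; returns a history dict with the stop reason."""
        if not self.center.any():
            # fit the centering offset once; later (warm-started) units keep
            # it so that features stay consistent across training units
            self.center = self._features(np.asarray(images, dtype=float)).mean(axis=0)
        x = self._features(images)
        y = np.asarray(labels, dtype=int)
        # x-shift augmentation is applied at the original crop resolution
        # (positional noise in the source image), then re-featurized
        if self.augment_shift > 0:
            images = np.asarray(images)
            if images.ndim == 2:
                images = images[None]
            x_shifted = [self._features(np.roll(images, s, axis=2))
                         for s in (-self.augment_shift, self.augment_shift)]
        else:
            x_shifted = []
        has_val = val_images is not None and len(val_images) > 0
        if has_val:
            xv = self._features(val_images)
            yv = np.asarray(val_labels, dtype=int)
        opt = _AdamOpt([w.shape for w in self.weights] + [b.shape for b in self.biases],
                       lr=self.lr)
        rng = np.random.default_rng(self.seed + 1)
        n = len(x)
        history = {"train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
                   "stop_reason": "max_epochs", "epochs": 0}
        val_acc_hist: list[float] = []
        val_loss_hist: list[float] = []
        train_loss_hist: list[float] = []
        for epoch in range(max_epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                # per-image random shift in x only (no flips/rotations:
                # orientation is already normalized away)
                if x_shifted:
                    variants = (x, x_shifted[0], x_shifted[1])
                    choice = rng.integers(0, 3, len(idx))
                    xb = np.stack([variants[c][i] for c, i in zip(choice, idx)])
                else:
                    xb = x[idx]
                acts, p = self._forward(xb)
                loss, gw, gb = self._grads(acts, p, y[idx])
                ep_loss += loss * len(idx)
                new = opt.step(self.weights + self.biases, gw + gb)
                k = len(self.weights)
                self.weights, self.biases = new[:k], new[k:]
            ep_loss /= n
            _, p_tr = self._forward(x)
            train_acc = float((p_tr.argmax(axis=1) == y).mean())
            history["train_loss"].append(ep_loss)
            history["train_acc"].append(train_acc)
            train_loss_hist.append(ep_loss)
            if has_val:
                _, pv = self._forward(xv)
                ptv = np.clip(pv[np.arange(len(yv)), yv], 1e-12, 1.0)
                vloss = float(np.mean((1 - ptv) ** 2 * (-np.log(ptv))))
                vacc = float((pv.argmax(axis=1) == yv).mean())
                history["val_loss"].append(vloss)
                history["val_acc"].append(vacc)
                val_acc_hist.append(vacc)
                val_loss_hist.append(vloss)
            history["epochs"] = epoch + 1
            if train_acc >= 1.0:
                history["stop_reason"] = "train_accuracy_1"
                break
            if has_val and len(val_acc_hist) > max(patience, _WARMUP_EPOCHS):
                # plateau: the best validation accuracy so far has not
                # improved over the last `patience` epochs
                if max(val_acc_hist) - max(val_acc_hist[:-patience]) < plateau_eps:
                    history["stop_reason"] = "plateau"
                    break
                vr = val_loss_hist[-(patience + 1):]
                tr = train_loss_hist[-(patience + 1):]
                if all(vr[i + 1] > vr[i] for i in range(patience)) and tr[-1] < tr[0]:
                    history["stop_reason"] = "overfitting"
                    break
        return history

    # -- snapshots

    def snapshot(self) -> dict:
        return {"weights": [w.copy() for w in self.weights],
                "biases": [b.copy() for b in self.biases],
                "center": self.center.copy()}

    def restore(self, state: dict) -> None:
        self.weights = [w.copy() for w in state["weights"]]
        self.biases = [b.copy() for b in state["biases"]]
        self.center = state["center"].copy()


class MLPBackend(LinearBackend):
    """One hidden tanh layer of 100 units; otherwise like LinearBackend."""

    hidden = (100,)


# ---------------------------------------------------------------------------
# Segments


@dataclass
class ConsecutiveSegment:
    """A switch-free run of frames for one individual."""

    individual: int
    start: int
    end: int
    reason: str = "start"  # why the segment began
    frames: list[int] = field(default_factory=list)  # frames with images
    images: np.ndarray | None = None  # (n, h, w) normalized crops
    final_identity: int | None = None
    resolution: str | None = None  # unambiguous | Eq2 | deferred

    @property
    def key(self) -> tuple[int, int]:
        return (self.individual, self.start)

    @property
    def n_frames(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "ConsecutiveSegment") -> bool:
        return self.start <= other.end and other.start <= self.end


@dataclass
class QualityMetrics:
    min_cells_visited: int
    avg_samples: float


@dataclass
class GlobalSegment:
    """A frame range in which every individual sits inside one segment."""

    start: int
    end: int
    segments: dict[int, ConsecutiveSegment]  # individual -> covering segment
    metrics: QualityMetrics | None = None
    # classes the segment was trained under once accepted (tracker identities
    # inside a later segment may belong to different real identities)
    class_map: dict[int, int] | None = None

    @property
    def key(self) -> tuple[int, int]:
        return (self.start, self.end)

    @property
    def middle(self) -> float:
        return (self.start + self.end) / 2.0


def split_into_segments(individuals: dict) -> dict[int, list[ConsecutiveSegment]]:
    """Cut each tracked individual at every split event.

    The tracker already records segment boundaries (lost / uncertain /
    timestamp gap); each recorded segment becomes one ConsecutiveSegment.
    """
    out: dict[int, list[ConsecutiveSegment]] = {}
    for ident, ind in sorted(individuals.items()):
        segs = []
        for s in ind.segments:
            frames = [f for f in range(s.start, s.end + 1) if f in ind.assignments]
            segs.append(ConsecutiveSegment(individual=ident, start=s.start, end=s.end,
                                           reason=s.reason, frames=frames))
        out[ident] = segs
    return out


def attach_images(segments: dict[int, list[ConsecutiveSegment]], image_source) -> None:
    """Fill ``segment.images`` using ``image_source(individual, frame)``.

    The source returns a normalized crop or None (e.g. posture failed);
    frames without an image are dropped from ``segment.frames``.
    """
    for segs in segments.values():
        for seg in segs:
            imgs, kept = [], []
            for f in seg.frames:
                im = image_source(seg.individual, f)
                if im is not None:
                    imgs.append(im)
                    kept.append(f)
            seg.frames = kept
            seg.images = np.stack(imgs) if imgs else None


def find_global_segments(segments: dict[int, list[ConsecutiveSegment]],
                         n_individuals: int) -> list[GlobalSegment]:
    """Maximal frame ranges where all N individuals are each inside one
    consecutive segment (a segment boundary of any individual ends the
    range)."""
    if len(segments) < n_individuals:
        return []
    idents = sorted(segments)[:]
    if len(idents) != n_individuals:
        idents = sorted(segments)
    events = sorted({s.start for segs in segments.values() for s in segs}
                    | {s.end + 1 for segs in segments.values() for s in segs})
    out: list[GlobalSegment] = []
    for lo, hi in zip(events, events[1:]):
        cover: dict[int, ConsecutiveSegment] = {}
        for ident in idents:
            seg = next((s for s in segments[ident] if s.start <= lo and hi - 1 <= s.end), None)
            if seg is None:
                break
            cover[ident] = seg
        else:
            if out and out[-1].end == lo - 1 and \
                    all(out[-1].segments[i] is cover[i] for i in cover):
                out[-1].end = hi - 1
            else:
                out.append(GlobalSegment(start=lo, end=hi - 1, segments=cover))
    return out


def segment_quality(gseg: GlobalSegment, individuals: dict,
                    arena_size: tuple[int, int], grid: int = 10) -> QualityMetrics:
    """Spatial coverage and sample count over a global segment.

    The arena is divided into a grid of equally sized rectangular cells
    (``grid`` across the width, scaled to the aspect ratio); per individual
    the centre-point cell transitions are counted.  Using transitions rather
    than distance travelled rewards sweeps over tight circling.
    """
    w, h = arena_size
    cell = w / grid
    ny = max(1, math.ceil(h / cell))
    min_cells = None
    samples = []
    for ident, seg in sorted(gseg.segments.items()):
        ind = individuals[ident]
        cells = []
        for f in range(gseg.start, gseg.end + 1):
            a = ind.assignments.get(f)
            if a is None:
                continue
            cells.append((min(int(a.x // cell), grid - 1), min(int(a.y // cell), ny - 1)))
        trans = sum(1 for c0, c1 in zip(cells, cells[1:]) if c0 != c1)
        min_cells = trans if min_cells is None else min(min_cells, trans)
        samples.append(len(cells))
    return QualityMetrics(min_cells_visited=int(min_cells or 0),
                          avg_samples=float(np.mean(samples)) if samples else 0.0)


def rank_global_segments(gsegs: list[GlobalSegment], video_length: int,
                         keep_per_bin: int = 4) -> list[GlobalSegment]:
    """Bin candidates by middle frame into video quarters, keep the best
    ``keep_per_bin`` per bin by (min_cells_visited, avg_samples), and
    interleave the bins round-robin starting from the best overall."""
    bins: list[list[GlobalSegment]] = [[] for _ in range(4)]
    for g in gsegs:
        q = min(3, int(4 * g.middle / max(video_length, 1)))
        bins[q].append(g)
    for q in range(4):
        bins[q].sort(key=lambda g: (-g.metrics.min_cells_visited, -g.metrics.avg_samples,
                                    g.start))
        bins[q] = bins[q][:keep_per_bin]
    nonempty = [q for q in range(4) if bins[q]]
    if not nonempty:
        return []
    best_bin = max(nonempty, key=lambda q: (bins[q][0].metrics.min_cells_visited,
                                            bins[q][0].metrics.avg_samples))
    order = [(best_bin + k) % 4 for k in range(4)]
    out: list[GlobalSegment] = []
    depth = 0
    while any(depth < len(bins[q]) for q in order):
        for q in order:
            if depth < len(bins[q]):
                out.append(bins[q][depth])
        depth += 1
    return out


# ---------------------------------------------------------------------------
# Uniqueness


def E_scale(v: float) -> float:
    """Non-linear rescaling of mean claimed probability, E(1) = 1."""
    return (1.0 + math.exp(-math.pi)) / (1.0 + math.exp(-math.pi * v))


def frame_uniqueness(probabilities: np.ndarray) -> float:
    """Uniqueness of one frame from the (n_objects, N) probability matrix.

    Each object claims its argmax identity; ``uids`` keeps the best
    probability per claimed identity.  The unique fraction |uids|/|f(x)| is
    scaled by E(mean claimed probability).
    """
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 2 or p.shape[0] == 0:
        raise ValueError("frame_uniqueness needs a non-empty (objects, identities) matrix")
    uids: dict[int, float] = {}
    for row in p:
        maxid = int(np.argmax(row))
        val = float(row[maxid])
        if maxid in uids:
            uids[maxid] = max(uids[maxid], val)
        else:
            uids[maxid] = val
    mean_claimed = sum(uids.values()) / len(uids)
    return (len(uids) / p.shape[0]) * E_scale(mean_claimed)


def uniqueness_threshold(n_individuals: int) -> float:
    """1 - 0.5/N: above this, almost every identity appears exactly once."""
    return 1.0 - 0.5 / n_individuals


def average_uniqueness(backend, sample_frames: dict[int, np.ndarray]):
    """Mean and per-frame uniqueness over cached evenly spaced sample frames.

    ``sample_frames`` maps frame -> (n_objects, h, w) image stack.  Returns
    (mean, per-frame dict, valley frames below 1 - 0.5/N).
    """
    scores: dict[int, float] = {}
    for f, images in sorted(sample_frames.items()):
        if images is None or len(images) == 0:
            continue  # empty frames are skipped, not scored
        scores[f] = frame_uniqueness(backend.predict(images))
    if not scores:
        return 0.0, {}, []
    mean = float(np.mean(list(scores.values())))
    thr = uniqueness_threshold(backend.n_classes)
    valleys = [f for f, s in scores.items() if s < thr]
    return mean, scores, valleys


# ---------------------------------------------------------------------------
# Training units


class AccumulationExhausted(RuntimeError):
    """No viable candidate global segments remain."""


@dataclass
class AccumulationState:
    n_individuals: int
    config: VisualIdConfig
    label_map: dict[int, int]  # tracker identity -> class index
    candidates: list[GlobalSegment] = field(default_factory=list)
    status: dict[tuple[int, int], str] = field(default_factory=dict)  # key -> untried/added/failed/rejected
    added: list[GlobalSegment] = field(default_factory=list)
    best_state: dict | None = None
    best_uniqueness: float = 0.0
    uniqueness_history: list[float] = field(default_factory=list)
    steps: int = 0
    video_length: int = 0
    samples_max: int = 0
    failed_initial: bool = False

    def coverage_gap(self, individual: int) -> int:
        """Frames of the video not covered by trained-on segments."""
        covered = np.zeros(self.video_length, dtype=bool)
        for g in self.added:
            seg = g.segments.get(individual)
            if seg is not None:
                covered[max(0, g.start):min(self.video_length, g.end + 1)] = True
        return int((~covered).sum())


def _balanced_split(seg_images: dict[int, np.ndarray], rng: np.random.Generator,
                    min_per_class: int):
    """Class-balance by down-sampling to the smallest class (+20% headroom),
    then split 4:1 into train and validation."""
    counts = {i: len(v) for i, v in seg_images.items()}
    if min(counts.values()) < min_per_class:
        return None
    cap = int(math.floor(1.2 * min(counts.values())))
    xs, ys, xv, yv = [], [], [], []
    for cls, imgs in sorted(seg_images.items()):
        idx = rng.permutation(len(imgs))[:cap]
        k = max(1, int(round(len(idx) / 5.0)))
        val_idx, tr_idx = idx[:k], idx[k:]
        xs.append(imgs[tr_idx])
        ys.append(np.full(len(tr_idx), cls))
        xv.append(imgs[val_idx])
        yv.append(np.full(len(val_idx), cls))
    return (np.concatenate(xs), np.concatenate(ys),
            np.concatenate(xv), np.concatenate(yv))


def _segment_class_images(gseg: GlobalSegment, label_map: dict[int, int]):
    out: dict[int, np.ndarray] = {}
    for ident, seg in sorted(gseg.segments.items()):
        if seg.images is None or ident not in label_map:
            return None
        out[label_map[ident]] = seg.images
    return out


def samples_max_from_budget(budget_bytes: int, image_size: tuple[int, int]) -> int:
    """Memory budget translated into a sample cap (float32 per pixel)."""
    return max(1, budget_bytes // (4 * image_size[0] * image_size[1]))


def train_initial(candidates: list[GlobalSegment], backend, config: VisualIdConfig,
                  video_length: int, sample_frames: dict[int, np.ndarray],
                  n_individuals: int) -> AccumulationState:
    """Train on the best viable candidate; its identities define the labels.

    Candidates whose smallest class has fewer than ``min_images_per_class``
    images are rejected and the next one is tried.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    state = None
    for cand in candidates:
        idents = sorted(cand.segments)
        label_map = {ident: k for k, ident in enumerate(idents)}
        cls_images = _segment_class_images(cand, label_map)
        if cls_images is None:
            continue
        split = _balanced_split(cls_images, rng, config.min_images_per_class)
        if split is None:
            continue
        xt, yt, xv, yv = split
        hist = backend.fit(xt, yt, xv, yv, max_epochs=config.max_epochs,
                           plateau_eps=config.plateau_eps, patience=config.patience)
        h, w = xt.shape[1:]
        state = AccumulationState(
            n_individuals=n_individuals, config=config, label_map=label_map,
            video_length=video_length,
            samples_max=samples_max_from_budget(config.memory_budget_bytes, (h, w)))
        cand.class_map = dict(label_map)
        state.added.append(cand)
        state.status[cand.key] = "added"
        mean_u, _, _ = average_uniqueness(backend, sample_frames)
        state.best_state = backend.snapshot()
        state.best_uniqueness = mean_u
        state.uniqueness_history.append(mean_u)
        # chance-level validation accuracy means the appearance carries no
        # identity information; the pipeline must report failure rather than
        # silently shuffle identities
        val_best = max(hist.get("val_acc", [0.0]) or [0.0])
        state.failed_initial = val_best < max(0.45, 1.5 / n_individuals)
        return state
    raise AccumulationExhausted("no candidate segment has enough images per identity")


def _segment_uniqueness(gseg: GlobalSegment, backend, stride: int = 5) -> float:
    vals = []
    idents = sorted(gseg.segments)
    by_frame: dict[int, list] = {}
    for ident in idents:
        seg = gseg.segments[ident]
        if seg.images is None:
            continue
        for f, im in zip(seg.frames, seg.images):
            by_frame.setdefault(f, []).append(im)
    for f in sorted(by_frame)[::stride]:
        vals.append(frame_uniqueness(backend.predict(np.stack(by_frame[f]))))
    return float(np.mean(vals)) if vals else 0.0


def _pow2_floor(x: float) -> int:
    return 0 if x < 1 else 2 ** int(math.floor(math.log2(x)))


def _distance_to_trained(gseg: GlobalSegment, added: list[GlobalSegment]) -> int:
    d = None
    for g in added:
        if gseg.start <= g.end and g.start <= gseg.end:
            return 0
        gap = g.start - gseg.end if g.start > gseg.end else gseg.start - g.end
        d = gap if d is None else min(d, gap)
    return int(d or 0)


def _merged_training_set(state: AccumulationState, extra=None):
    """Previously added segments (sub-sampled by their share of the total
    frames, under the memory budget) plus an optional new candidate labelled
    with its predicted classes."""
    xs, ys = [], []
    total_frames = sum(g.end - g.start + 1 for g in state.added) or 1
    for g in state.added:
        share = (g.end - g.start + 1) / total_frames
        cap = max(1, int(state.samples_max * share / state.n_individuals))
        cmap = g.class_map or state.label_map
        for ident, seg in sorted(g.segments.items()):
            if seg.images is None:
                continue
            stride = max(1, math.ceil(len(seg.images) / cap))
            xs.append(seg.images[::stride])
            ys.append(np.full(len(seg.images[::stride]), cmap[ident]))
    if extra is not None:
        cand, predicted = extra
        for ident, seg in sorted(cand.segments.items()):
            xs.append(seg.images)
            ys.append(np.full(len(seg.images), predicted[ident]))
    return np.concatenate(xs), np.concatenate(ys)


def accumulation_step(state: AccumulationState, backend,
                      sample_frames: dict[int, np.ndarray]) -> AccumulationState:
    """One accumulation round: pick the most promising untried global
    segment, sanity-check its predicted identities, retrain on the merged
    set, and keep the model only if mean uniqueness stays within 99% of the
    best so far."""
    config = state.config
    untried = [g for g in state.candidates
               if state.status.get(g.key, "untried") in ("untried", "failed")]
    if not untried:
        raise AccumulationExhausted("no viable candidate segments remain")

    scored = []
    for g in untried:
        u = _segment_uniqueness(g, backend)
        if state.steps >= 5 and u < state.best_uniqueness / 2.0:
            state.status[g.key] = "rejected"  # disqualified: U_prev/2 rule
            continue
        u_pct = round(u * 20.0) / 20.0  # integer percentage in 5% steps
        dist = _pow2_floor(_distance_to_trained(g, state.added))
        m = g.metrics or QualityMetrics(0, 0.0)
        has_images = all(s.images is not None for s in g.segments.values())
        retry = state.status.get(g.key, "untried") == "failed"
        scored.append(((retry, u_pct, -dist, -m.min_cells_visited, -m.avg_samples,
                        not has_images, g.start), g))
    if not scored:
        raise AccumulationExhausted("all remaining candidates were disqualified")
    scored.sort(key=lambda t: t[0])
    state.steps += 1

    # plausibility sweep: per unobstructed sequence (each per-individual piece
    # of a global segment is one), predicted identities must be pairwise
    # unique; implausible segments are saved for later and the search goes on
    cand = None
    predicted: dict[int, int] = {}
    for _, g in scored:
        pred = {}
        for ident, seg in sorted(g.segments.items()):
            p = backend.predict(seg.images).mean(axis=0)
            pred[ident] = int(np.argmax(p))
        if len(set(pred.values())) == len(pred):
            cand, predicted = g, pred
            break
        state.status[g.key] = "failed"  # re-queued later
    if cand is None:
        raise AccumulationExhausted(
            "no remaining candidate yields plausibly unique identities")

    # merge with prior segments, sub-sampled by their share of the total
    x, y = _merged_training_set(state, extra=(cand, predicted))
    rng = np.random.default_rng(config.seed + state.steps)
    idx = rng.permutation(len(x))
    k = max(1, len(x) // 5)
    backend.fit(x[idx[k:]], y[idx[k:]], x[idx[:k]], y[idx[:k]],
                max_epochs=config.max_epochs, plateau_eps=config.plateau_eps,
                patience=config.patience)

    mean_u, _, _ = average_uniqueness(backend, sample_frames)
    state.uniqueness_history.append(mean_u)
    if mean_u >= config.improvement_keep * state.best_uniqueness:
        state.status[cand.key] = "added"
        cand.class_map = dict(predicted)
        state.added.append(cand)
        if mean_u > state.best_uniqueness:
            state.best_uniqueness = mean_u
            state.best_state = backend.snapshot()
    else:
        backend.restore(state.best_state)
        state.status[cand.key] = "rejected"
    return state


def check_stopping(state: AccumulationState) -> str:
    """'done' when coverage gaps are small (< 25% of the video for every
    individual) or mean uniqueness exceeds 1 - 0.5/N; else 'continue'."""
    if state.best_uniqueness > uniqueness_threshold(state.n_individuals):
        return "done"
    if state.video_length > 0 and all(
            state.coverage_gap(i) < 0.25 * state.video_length
            for i in state.label_map):
        return "done"
    return "continue"


def final_epoch_cap(max_epochs: int) -> int:
    """max{3, 0.25 * max_epochs} (floor), e.g. 37 for the default 150."""
    return max(3, int(max_epochs * 0.25))


def train_final(state: AccumulationState, backend,
                sample_frames: dict[int, np.ndarray]):
    """One last unit on the fully merged dataset (no held-out validation),
    capped at max{3, 0.25*max_epochs} epochs; kept only if the mean
    uniqueness improves."""
    config = state.config
    x, y = _merged_training_set(state)
    backend.fit(x, y, None, None, max_epochs=final_epoch_cap(config.max_epochs),
                plateau_eps=config.plateau_eps, patience=config.patience)
    mean_u, _, _ = average_uniqueness(backend, sample_frames)
    state.uniqueness_history.append(mean_u)
    if mean_u > state.best_uniqueness:
        state.best_uniqueness = mean_u
        state.best_state = backend.snapshot()
    else:
        backend.restore(state.best_state)
    return backend


# ---------------------------------------------------------------------------
# Assignment


def sig(x: float) -> float:
    """Logistic ramp with sig(0.5) = 0.5; exaggerates differences between
    low values, dampens differences between high ones."""
    return 1.0 / (1.0 + math.exp(2.0 * math.pi * (0.5 - x)))


def eq2_score(p: float, x: float, n_me: int, n_he: int) -> float:
    """S(p, x) = sig(p) + sig(x / (N_me + N_he)) for contested assignments."""
    return sig(p) + sig(x / (n_me + n_he))


def correct_switches(frame_ids: np.ndarray, window: int = 25) -> int | None:
    """Detect a mid-segment identity switch via a running-window median.

    ``frame_ids`` holds per-frame argmax identities.  Returns the index of
    the first persistent median change (split point) or None.  Single-frame
    glitches are absorbed by the median.
    """
    if window % 2 != 1:
        raise ValueError("window must be odd")
    n = len(frame_ids)
    if n < 2 * window:
        return None
    ids = np.asarray(frame_ids)
    half = window // 2
    med = np.empty(n - 2 * half, dtype=ids.dtype)
    for i in range(half, n - half):
        med[i - half] = int(np.median(ids[i - half:i + half + 1]))
    changes = np.nonzero(med[1:] != med[:-1])[0]
    for c in changes:
        new_id = med[c + 1]
        run_end = c + 1
        while run_end < len(med) and med[run_end] == new_id:
            run_end += 1
        if run_end - (c + 1) >= window:
            return int(c + 1 + half)  # back to frame index within the segment
    return None


def assign_identities(backend, segments: dict[int, list[ConsecutiveSegment]],
                      state: AccumulationState) -> list[ConsecutiveSegment]:
    """Assign a final identity to every consecutive segment.

    Segments are first checked (and possibly split) for mid-segment identity
    switches, then each receives the class with maximal segment-averaged
    probability.  When overlapping segments contest one identity, the ratio
    of the two maximal probabilities defers the decision to the kinematic
    tracker if it exceeds 0.6; otherwise Eq2's sample-size-aware score picks
    the winner and the loser keeps its tracker identity.
    """
    config = state.config
    inv_label = {v: k for k, v in state.label_map.items()}

    # switch correction: split segments whose framewise median identity flips
    all_segs: list[ConsecutiveSegment] = []
    for ident, segs in sorted(segments.items()):
        for seg in segs:
            if seg.images is None or len(seg.images) == 0:
                all_segs.append(seg)
                continue
            preds = backend.predict(seg.images)
            split_at = correct_switches(preds.argmax(axis=1), config.median_window)
            if split_at is None:
                all_segs.append(seg)
            else:
                f_split = seg.frames[split_at]
                left = replace(seg, end=f_split - 1, frames=seg.frames[:split_at],
                               images=seg.images[:split_at])
                right = replace(seg, start=f_split, frames=seg.frames[split_at:],
                                images=seg.images[split_at:], reason="switch")
                all_segs.extend([left, right])

    # per-segment averaged probabilities
    probs: dict[int, np.ndarray] = {}
    for k, seg in enumerate(all_segs):
        if seg.images is not None and len(seg.images) > 0:
            probs[k] = backend.predict(seg.images).mean(axis=0)

    for cls in range(backend.n_classes):
        contenders = [k for k in probs if int(np.argmax(probs[k])) == cls]
        if not contenders:
            continue
        # only simultaneously overlapping segments actually compete
        groups: list[list[int]] = []
        for k in sorted(contenders, key=lambda k: all_segs[k].start):
            placed = False
            for grp in groups:
                if any(all_segs[k].overlaps(all_segs[j]) for j in grp):
                    grp.append(k)
                    placed = True
                    break
            if not placed:
                groups.append([k])
        for grp in groups:
            pmax = {k: float(probs[k][cls]) for k in grp}
            # a rival must overlap substantially (1-3 shared boundary frames
            # are crossing-handover fuzz, not simultaneity) and carry at
            # least as many images as a trainable class requires — a one-
            # image segment's averaged probability is meaningless
            min_ov = config.min_images_per_class

            def _rivalry(a: ConsecutiveSegment, b: ConsecutiveSegment) -> bool:
                ov = min(a.end, b.end) - max(a.start, b.start) + 1
                return ov >= min_ov

            rivals = {k: [j for j in grp if j != k
                          and len(all_segs[j].frames) >= config.min_images_per_class
                          and _rivalry(all_segs[k], all_segs[j])] for k in grp}
            for k in grp:
                seg = all_segs[k]
                if not rivals[k]:
                    seg.final_identity = inv_label.get(cls, cls)
                    seg.resolution = "unambiguous"
                    continue
                # R_max rule against the simultaneously overlapping rivals
                ratios = []
                for j in rivals[k]:
                    r = pmax[k] / pmax[j] if pmax[j] > 0 else math.inf
                    ratios.append(1.0 / r if r > 1.0 else r)
                if any(r > config.deferral_ratio for r in ratios):
                    seg.resolution = "deferred"  # tracker identity kept
                    continue

                def s_key(m):
                    n_me = len(all_segs[m].frames)
                    n_he = max(len(all_segs[j].frames)
                               for j in ([k] + rivals[k]) if j != m)
                    return (eq2_score(pmax[m], n_me, n_me, n_he),
                            n_me, -all_segs[m].start)

                seg.resolution = "Eq2"
                if all(s_key(k) >= s_key(j) for j in rivals[k]):
                    seg.final_identity = inv_label.get(cls, cls)
    return all_segs
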