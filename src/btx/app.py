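"""Configuration registry, pipeline orchestration and the ``btx`` CLI.

Stages (``simulate -> convert -> track -> identify -> export``) communicate
through on-disk artifacts in a working directory: PNG frame sequences and
ground-truth tables from ``simulate``, a ``.pvs`` blob container from
``convert``, trajectory tables from ``track``/``export``, corrected tracks
and a per-segment assignment report from ``identify``.  ``evaluate``
compares any two trajectory tables under the 1%-of-width rule.  Every run
appends a machine-readable JSON line (seed, config hash, timings, status)
to ``run_log.jsonl``.  Batch use needs no display.
"""

from __future__ import annotations

import argparse
import difflib
import glob
import hashlib
import json
import os
import time
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pv_io, segmentation, synthetic_scene, tracking, visual_id
from .posture import PostureConfig, compute_posture, normalize_image

__all__ = ["ParamRegistry", "load_config", "run_pipeline", "run_visual_id", "main"]


# ---------------------------------------------------------------------------
# Parameter registry


@dataclass
class ParamSpec:
    default: object
    type: type
    unit: str
    doc: str


_PARAMS: dict[str, ParamSpec] = {
    # synthetic scene
    "n_agents": ParamSpec(4, int, "count", "number of simulated agents"),
    "frame_width": ParamSpec(256, int, "px", "frame width"),
    "frame_height": ParamSpec(256, int, "px", "frame height"),
    "n_frames": ParamSpec(200, int, "count", "number of frames"),
    "fps": ParamSpec(25.0, float, "Hz", "frame rate"),
    "agent_length": ParamSpec(24.0, float, "px", "agent body length"),
    "agent_width": ParamSpec(8.0, float, "px", "agent body width"),
    "speed_mean": ParamSpec(2.5, float, "px/frame", "mean agent speed"),
    "speed_sd": ParamSpec(0.8, float, "px/frame", "sd of agent speed"),
    "turn_sd": ParamSpec(0.18, float, "rad/frame", "sd of heading increments"),
    "texture_contrast": ParamSpec(40.0, float, "gray", "per-identity texture amplitude"),
    "overlap_rate": ParamSpec(0.0, float, "1/(agent*min)", "expected crossing rate"),
    "disappear_prob": ParamSpec(0.0, float, "probability", "per-frame disappearance"),
    "background_level": ParamSpec(200, int, "gray", "background intensity"),
    "noise_sd": ParamSpec(3.0, float, "gray", "additive sensor noise sd"),
    # segmentation
    "track_threshold": ParamSpec(25, int, "gray", "background-difference threshold"),
    "blob_size_min": ParamSpec(10, int, "px", "minimum blob area"),
    "blob_size_max": ParamSpec(1_000_000, int, "px", "maximum blob area"),
    "background_mode": ParamSpec("mode", str, "", "background estimator: min/max/mode/mean"),
    "use_mask": ParamSpec(False, bool, "", "segment from external binary masks"),
    "equalize_luminance": ParamSpec(False, bool, "", "match frame mean to background mean"),
    # tracking
    "track_max_individuals": ParamSpec("unknown", str, "count", "known individual count, or 'unknown'"),
    "track_max_speed": ParamSpec(300.0, float, "px/s", "maximal allowed travel speed"),
    "matching_probability_threshold": ParamSpec(0.1, float, "probability", "minimal edge probability"),
    "max_reassign_time": ParamSpec(0.5, float, "s", "lost individuals stay matchable this long"),
    "clique_node_cap": ParamSpec(100_000, int, "count", "tree-matching node budget"),
    "matcher": ParamSpec("tree", str, "", "matcher: tree/hungarian/approximate"),
    # posture
    "smoothing": ParamSpec("eft", str, "", "outline smoothing: eft/weighted/none"),
    "n_efd": ParamSpec(8, int, "count", "elliptic Fourier descriptors kept"),
    "smooth_window": ParamSpec(5, int, "count", "weighted-smoothing window (odd)"),
    "pointiest_is": ParamSpec("tail", str, "", "label of the pointiest outline end"),
    "midline_resolution": ParamSpec(25, int, "count", "midline points"),
    "normalized_image_width": ParamSpec(80, int, "px", "normalized crop width"),
    "normalized_image_height": ParamSpec(80, int, "px", "normalized crop height"),
    # visual identification
    "keep_per_bin": ParamSpec(4, int, "count", "candidate segments kept per video quarter"),
    "uniqueness_samples": ParamSpec(100, int, "count", "frames sampled for uniqueness"),
    "max_epochs": ParamSpec(150, int, "count", "training epoch cap"),
    "memory_budget_bytes": ParamSpec(1_000_000_000, int, "bytes", "training-set memory budget"),
    "median_window": ParamSpec(25, int, "frames", "switch-correction median window"),
    "backend": ParamSpec("linear", str, "", "classifier backend: linear/mlp"),
    "grid": ParamSpec(10, int, "count", "coverage grid cells across the width"),
    # run
    "seed": ParamSpec(0, int, "", "seed for every source of randomness"),
}


class ParamRegistry(dict):
    """Resolved configuration: registered name -> value."""

    def config_hash(self) -> str:
        blob = json.dumps({k: repr(v) for k, v in sorted(self.items())})
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _coerce(key: str, raw: str):
    spec = _PARAMS[key]
    if spec.type is bool:
        return str(raw).lower() in ("1", "true", "yes", "on")
    if key == "track_max_individuals" and str(raw) != "unknown":
        return int(raw)
    try:
        return spec.type(raw)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"parameter {key!r} expects {spec.type.__name__}, got {raw!r}") from exc


def load_config(path: str | None = None, overrides: list[str] | None = None) -> ParamRegistry:
    """Resolve the configuration: command line > file > defaults.

    The file is plain text, one ``key=value`` per line, ``#`` comments.
    Unknown keys raise a parameter error listing the nearest registered
    names.
    """
    reg = ParamRegistry({k: (s.default if k != "track_max_individuals" else s.default)
                         for k, s in _PARAMS.items()})

    def apply(key: str, value: str, source: str):
        key = key.strip()
        if key not in _PARAMS:
            near = difflib.get_close_matches(key, _PARAMS, n=3)
            hint = f"; did you mean {', '.join(near)}?" if near else ""
            raise ValueError(f"unknown parameter {key!r} (from {source}){hint}")
        reg[key] = _coerce(key, value.strip())

    if path:
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"malformed config line: {line!r}")
                apply(*line.split("=", 1), source=path)
    for ov in overrides or []:
        if "=" not in ov:
            raise ValueError(f"override must be key=value, got {ov!r}")
        apply(*ov.split("=", 1), source="command line")
    return reg


# ---------------------------------------------------------------------------
# Config -> dataclass adapters


def scene_config(reg: ParamRegistry) -> synthetic_scene.SceneConfig:
    return synthetic_scene.SceneConfig(
        n_agents=reg["n_agents"], frame_size=(reg["frame_width"], reg["frame_height"]),
        n_frames=reg["n_frames"], fps=reg["fps"], agent_length=reg["agent_length"],
        agent_width=reg["agent_width"], speed_mean=reg["speed_mean"],
        speed_sd=reg["speed_sd"], turn_sd=reg["turn_sd"],
        texture_contrast=reg["texture_contrast"], overlap_rate=reg["overlap_rate"],
        disappear_prob=reg["disappear_prob"], background_level=reg["background_level"],
        noise_sd=reg["noise_sd"], seed=reg["seed"])


def segmentation_config(reg: ParamRegistry) -> segmentation.SegmentationConfig:
    return segmentation.SegmentationConfig(
        threshold=reg["track_threshold"],
        blob_size_range=(reg["blob_size_min"], reg["blob_size_max"]),
        use_mask=reg["use_mask"], equalize_luminance=reg["equalize_luminance"])


def tracker_config(reg: ParamRegistry) -> tracking.TrackerConfig:
    tmi = reg["track_max_individuals"]
    return tracking.TrackerConfig(
        track_max_individuals=tmi if tmi == "unknown" else int(tmi),
        track_max_speed=reg["track_max_speed"],
        matching_probability_threshold=reg["matching_probability_threshold"],
        max_reassign_time=reg["max_reassign_time"],
        clique_node_cap=reg["clique_node_cap"], matcher=reg["matcher"],
        segmentation_threshold=reg["track_threshold"])


def posture_config(reg: ParamRegistry) -> PostureConfig:
    return PostureConfig(
        smoothing=reg["smoothing"], n_efd=reg["n_efd"], smooth_window=reg["smooth_window"],
        pointiest_is=reg["pointiest_is"], midline_resolution=reg["midline_resolution"],
        normalized_image_size=(reg["normalized_image_width"], reg["normalized_image_height"]))


def visual_id_config(reg: ParamRegistry) -> visual_id.VisualIdConfig:
    return visual_id.VisualIdConfig(
        grid=reg["grid"], keep_per_bin=reg["keep_per_bin"],
        uniqueness_samples=reg["uniqueness_samples"], max_epochs=reg["max_epochs"],
        memory_budget_bytes=reg["memory_budget_bytes"],
        median_window=reg["median_window"], seed=reg["seed"])


def make_backend(reg_or_name, n_classes: int, seed: int = 0):
    name = reg_or_name["backend"] if isinstance(reg_or_name, dict) else reg_or_name
    if name == "linear":
        return visual_id.LinearBackend(n_classes=n_classes, seed=seed)
    if name == "mlp":
        return visual_id.MLPBackend(n_classes=n_classes, seed=seed)
    raise ValueError(f"unknown backend {name!r}")


# ---------------------------------------------------------------------------
# High-level visual-identification run (shared by CLI, tests, acceptance)


class NormalizedImageSource:
    """Caches per-(individual, frame) normalized posture crops.

    Head/tail labels from pointiness alone flip occasionally at low
    resolution; since the animals swim head-first, a midline whose forward
    direction opposes the motion direction (while actually moving) is
    reversed before normalization.
    """

    # minimal speed (px/s) at which the motion direction is trusted
    min_flip_speed = 25.0
    # crops whose blob area deviates more than this fraction from the
    # individual's median area are rejected (merged blobs, split fragments)
    size_tolerance = 0.3

    def __init__(self, individuals: dict, config: PostureConfig):
        self.individuals = individuals
        self.config = config
        self._cache: dict[tuple[int, int], np.ndarray | None] = {}
        self._median_size: dict[int, float] = {}

    def _plausible_size(self, ident: int, blob) -> bool:
        if ident not in self._median_size:
            sizes = [a.blob.n_pixels for a in self.individuals[ident].assignments.values()
                     if a.blob is not None]
            self._median_size[ident] = float(np.median(sizes)) if sizes else 0.0
        med = self._median_size[ident]
        return med <= 0 or abs(blob.n_pixels - med) <= self.size_tolerance * med

    def __call__(self, ident: int, frame: int):
        key = (ident, frame)
        if key not in self._cache:
            a = self.individuals[ident].assignments.get(frame)
            if (a is None or a.blob is None or a.blob.n_pixels < 3
                    or not self._plausible_size(ident, a.blob)):
                self._cache[key] = None
            else:
                try:
                    post = compute_posture(a.blob, self.config)
                    ml = post.midline
                    if ml is not None and a.speed > self.min_flip_speed:
                        fwd = ml.points[0] - ml.points[-1]  # tail -> head
                        if fwd @ np.array([np.cos(a.heading), np.sin(a.heading)]) < 0:
                            ml = type(ml)(points=ml.points[::-1].copy(),
                                          thickness=ml.thickness[::-1].copy(),
                                          head_index=ml.tail_index,
                                          tail_index=ml.head_index)
                    img = normalize_image(a.blob, ml, self.config)
                    if ml is not None:
                        a.midline_length = ml.length
                    self._cache[key] = np.clip(img, 0, 255).astype(np.uint8)
                except (ValueError, RuntimeError):
                    self._cache[key] = None
        return self._cache[key]


def _sample_frames_for_uniqueness(individuals: dict, source, n_frames: int,
                                  n_samples: int) -> dict[int, np.ndarray]:
    frames = np.unique(np.linspace(0, n_frames - 1, n_samples).astype(int))
    out: dict[int, np.ndarray] = {}
    for f in frames:
        imgs = []
        for ident in sorted(individuals):
            im = source(ident, int(f))
            if im is not None:
                imgs.append(im)
        if imgs:
            out[int(f)] = np.stack(imgs)
    return out


def run_visual_id(tracker: tracking.Tracker, n_frames: int, arena_size: tuple[int, int],
                  pcfg: PostureConfig, vcfg: visual_id.VisualIdConfig,
                  backend_name: str = "linear"):
    """Full visual-identification pass over a finished tracking run.

    Returns ``(corrected_tracks, state, assigned_segments, status)`` where
    status is ``ok`` or ``failed`` (appearance unlearnable / no usable
    global segments — identities are then left untouched rather than
    silently shuffled).
    """
    individuals = tracker.individuals
    n = (int(tracker.config.track_max_individuals) if tracker.config.known_count
         else len(individuals))
    source = NormalizedImageSource(individuals, pcfg)
    segments = split_into_segments_with_images(individuals, source)
    gsegs = visual_id.find_global_segments(segments, n)
    for g in gsegs:
        g.metrics = visual_id.segment_quality(g, individuals, arena_size, vcfg.grid)
    ranked = visual_id.rank_global_segments(gsegs, n_frames, vcfg.keep_per_bin)
    sample_frames = _sample_frames_for_uniqueness(individuals, source, n_frames,
                                                  vcfg.uniqueness_samples)
    backend = make_backend(backend_name, n_classes=n, seed=vcfg.seed)
    try:
        state = visual_id.train_initial(ranked, backend, vcfg, n_frames, sample_frames, n)
    except visual_id.AccumulationExhausted:
        return tracker.to_frame(), None, [], "failed"
    state.candidates = ranked
    if state.failed_initial:
        return tracker.to_frame(), state, [], "failed"
    while (visual_id.check_stopping(state) == "continue"
           and state.steps < vcfg.max_accumulation_steps):
        try:
            visual_id.accumulation_step(state, backend, sample_frames)
        except visual_id.AccumulationExhausted:
            break
    backend.restore(state.best_state)
    visual_id.train_final(state, backend, sample_frames)
    assigned = visual_id.assign_identities(backend, segments, state)
    corrected = corrected_tracks(individuals, assigned)
    return corrected, state, assigned, "ok"


def split_into_segments_with_images(individuals: dict, source):
    segments = visual_id.split_into_segments(individuals)
    visual_id.attach_images(segments, source)
    return segments


def _propagate_identities(assigned_segments) -> None:
    """Fill unassigned segments from agreeing assigned neighbours.

    A deferred or image-less segment keeps its tracker identity; but when
    the previous and next assigned segments of the same tracker individual
    carry the same final identity, the tracker asserts continuity across
    the gap and the segment inherits that identity.  A single assigned
    neighbour suffices when the segments touch without a gap.
    """
    by_ind: dict[int, list] = {}
    for seg in assigned_segments:
        by_ind.setdefault(seg.individual, []).append(seg)
    for segs in by_ind.values():
        segs.sort(key=lambda s: s.start)
        for i, seg in enumerate(segs):
            if seg.final_identity is not None:
                continue
            prev = next((segs[j] for j in range(i - 1, -1, -1)
                         if segs[j].final_identity is not None), None)
            nxt = next((segs[j] for j in range(i + 1, len(segs))
                        if segs[j].final_identity is not None), None)
            # only bridge when both sides agree: identity swaps happen
            # exactly inside unassignable stretches, so a single assigned
            # neighbour is not evidence enough
            if prev is not None and nxt is not None \
                    and prev.final_identity == nxt.final_identity:
                seg.final_identity = prev.final_identity
                seg.resolution = (seg.resolution or "") + "+continuity"


def corrected_tracks(individuals: dict, assigned_segments) -> pd.DataFrame:
    """Per-frame table with final identities applied segment-wise."""
    _propagate_identities(assigned_segments)
    rows = []
    for seg in assigned_segments:
        ind = individuals[seg.individual]
        final = seg.final_identity if seg.final_identity is not None else seg.individual
        corrected = seg.final_identity is not None
        for f in range(seg.start, seg.end + 1):
            a = ind.assignments.get(f)
            if a is None:
                continue
            rows.append({"frame": f, "id": final, "x": a.x, "y": a.y,
                         "heading": a.heading, "visible": True,
                         "_prio": 0 if corrected else 1})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    df = (df.sort_values(["frame", "id", "_prio"])
            .drop_duplicates(["frame", "id"], keep="first")
            .drop(columns="_prio").reset_index(drop=True))
    return df


def run_identity_benchmark(seed: int = 1, n_agents: int = 8, n_frames: int = 1500,
                           backend_name: str = "linear") -> dict:
    """Full tracking + visual-identification benchmark on one synthetic scene.

    The scene emulates a top-down tank recording: 8 textured agents in a
    1024 px arena (body-length-to-arena ratio as in typical laboratory
    videos), one minute at 25 Hz with ~24 scripted path crossings.  Returns
    the identity similarity against ground truth for the kinematic tracker
    alone and after visual identification, plus run diagnostics.
    """
    cfg = synthetic_scene.SceneConfig(
        n_agents=n_agents, n_frames=n_frames, frame_size=(1024, 1024),
        overlap_rate=3.0, texture_contrast=40.0, seed=seed)
    truth = synthetic_scene.simulate_trajectories(cfg)
    frames = synthetic_scene.render_scene(truth, cfg)
    bg = segmentation.estimate_background(frames[::30], "mode")
    scfg = segmentation.SegmentationConfig(threshold=25, blob_size_range=(20, 10_000))
    tracker = tracking.Tracker(
        tracking.TrackerConfig(track_max_individuals=n_agents, track_max_speed=500.0),
        background=bg.image)
    for t in range(cfg.n_frames):
        tracker.advance_frame(segmentation.segment_frame(frames[t], bg, scfg),
                              t / cfg.fps)
    del frames
    sim_tracker, _ = synthetic_scene.score_identity_accuracy(
        truth, tracker.to_frame(), cfg.frame_size[0])
    pcfg = PostureConfig(normalized_image_size=(32, 32))
    vcfg = visual_id.VisualIdConfig(seed=seed)
    corrected, state, assigned, status = run_visual_id(
        tracker, cfg.n_frames, cfg.frame_size, pcfg, vcfg, backend_name)
    sim_corrected, coverage = synthetic_scene.score_identity_accuracy(
        truth, corrected, cfg.frame_size[0])
    return {
        "tracker_similarity": sim_tracker,
        "corrected_similarity": sim_corrected,
        "mean_coverage": float(np.mean(list(coverage.values()))),
        "n_crossings": len(truth.crossing_events),
        "status": status,
        "final_uniqueness": None if state is None else state.best_uniqueness,
        "n_segments": len(assigned),
    }


# ---------------------------------------------------------------------------
# Pipeline stages


def _log_run(workdir: str, entry: dict) -> None:
    with open(os.path.join(workdir, "run_log.jsonl"), "a") as fh:
        fh.write(json.dumps(entry) + "\n")


def _require(path: str, producer: str) -> str:
    if not os.path.exists(path):
        raise FileNotFoundError(
            f"missing artifact {path!r}: run the {producer!r} stage first")
    return path


def _load_frames(workdir: str) -> np.ndarray:
    import imageio.v3 as iio

    files = sorted(glob.glob(os.path.join(workdir, "frames", "frame_*.png")))
    _require(files[0] if files else os.path.join(workdir, "frames"), "simulate")
    return np.stack([iio.imread(f) for f in files])


def _stage_simulate(reg: ParamRegistry, workdir: str) -> dict:
    cfg = scene_config(reg)
    frames, truth = synthetic_scene.generate_dataset(cfg, os.path.join(workdir, "frames"))
    truth.to_frame().to_csv(os.path.join(workdir, "ground_truth.csv"), index=False)
    ts = (np.arange(cfg.n_frames) / cfg.fps * 1e6).astype(np.int64)
    np.savez(os.path.join(workdir, "timestamps.npz"), timestamps_us=ts)
    return {"frames": int(frames.shape[0])}


def _stage_convert(reg: ParamRegistry, workdir: str) -> dict:
    frames = _load_frames(workdir)
    scfg = segmentation_config(reg)
    bg = segmentation.estimate_background(frames[:: max(1, len(frames) // 50)],
                                          reg["background_mode"])
    ts_path = os.path.join(workdir, "timestamps.npz")
    ts = (pv_io.load_timestamps_sidecar(ts_path) if os.path.exists(ts_path)
          else (np.arange(len(frames)) / reg["fps"] * 1e6).astype(np.int64))
    recs = []
    for t, frame in enumerate(frames):
        pre = segmentation.preprocess_frame(frame, bg, scfg)
        blobs = segmentation.segment_frame(pre, bg, scfg)
        recs.append(pv_io.FrameRecord(
            timestamp_us=int(ts[t]),
            blobs=[pv_io.BlobRecord.from_blob(b) for b in blobs]))
    header = pv_io.PVSHeader(width=frames.shape[2], height=frames.shape[1],
                             frame_count=len(frames), background=bg.image)
    pv_io.write_container(os.path.join(workdir, "video.pvs"), header, recs)
    return {"frames": len(frames), "blobs": int(sum(len(r.blobs) for r in recs))}


def _run_tracking(reg: ParamRegistry, workdir: str) -> tuple[tracking.Tracker, pv_io.PVSHeader]:
    path = _require(os.path.join(workdir, "video.pvs"), "convert")
    header = pv_io.read_header(path)
    tracker = tracking.Tracker(tracker_config(reg), background=header.background)
    for rec in pv_io.read_all_frames(path):
        blobs = [b.to_blob() for b in rec.blobs]
        tracker.advance_frame(blobs, rec.timestamp_us / 1e6)
    return tracker, header


def _stage_track(reg: ParamRegistry, workdir: str) -> dict:
    tracker, _ = _run_tracking(reg, workdir)
    tracker.to_frame().to_csv(os.path.join(workdir, "tracks.csv"), index=False)
    log = []
    for ident, ind in sorted(tracker.individuals.items()):
        for f, a in sorted(ind.assignments.items()):
            log.append({"frame": f, "identity": ident, "x": a.x, "y": a.y,
                        "probability": a.probability})
    pd.DataFrame(log).to_csv(os.path.join(workdir, "assignments.csv"), index=False)
    return {"individuals": len(tracker.individuals)}


def _stage_identify(reg: ParamRegistry, workdir: str) -> dict:
    _require(os.path.join(workdir, "tracks.csv"), "track")
    tracker, header = _run_tracking(reg, workdir)
    corrected, state, assigned, status = run_visual_id(
        tracker, tracker.frame + 1, (header.width, header.height),
        posture_config(reg), visual_id_config(reg), reg["backend"])
    corrected.to_csv(os.path.join(workdir, "tracks_corrected.csv"), index=False)
    report = [{"individual": s.individual, "start": s.start, "end": s.end,
               "final_identity": s.final_identity, "resolution": s.resolution,
               "n_images": 0 if s.images is None else len(s.images)}
              for s in assigned]
    pd.DataFrame(report).to_csv(os.path.join(workdir, "segment_report.csv"), index=False)
    out = {"status": status}
    if state is not None:
        out["mean_uniqueness"] = state.best_uniqueness
    return out


def _stage_export(reg: ParamRegistry, workdir: str) -> dict:
    tracker, _ = _run_tracking(reg, workdir)
    files = pv_io.export_trajectories(
        list(tracker.individuals.values()),
        os.path.join(workdir, "trajectory"), format="both")
    return {"files": len(files)}


def _stage_evaluate(reg: ParamRegistry, workdir: str) -> dict:
    sol_path = os.path.join(
        workdir, "tracks_corrected.csv" if os.path.exists(
            os.path.join(workdir, "tracks_corrected.csv")) else "tracks.csv")
    _require(sol_path, "track")
    truth_path = _require(os.path.join(workdir, "ground_truth.csv"), "simulate")
    sol = pd.read_csv(sol_path)
    truth = pd.read_csv(truth_path)
    sim, coverage = synthetic_scene.score_identity_accuracy(
        truth, sol, reg["frame_width"])
    print(f"similarity: {sim:.4f}")
    return {"similarity": sim,
            "coverage": {str(k): round(v, 4) for k, v in coverage.items()}}


_STAGES = {
    "simulate": _stage_simulate,
    "convert": _stage_convert,
    "track": _stage_track,
    "identify": _stage_identify,
    "export": _stage_export,
    "evaluate": _stage_evaluate,
}


def run_pipeline(command: str, registry: ParamRegistry, workdir: str = ".") -> int:
    """Run one stage; returns a process exit status (0 = success)."""
    if command not in _STAGES:
        raise ValueError(f"unknown command {command!r}; choose from {sorted(_STAGES)}")
    os.makedirs(workdir, exist_ok=True)
    t0 = time.time()
    entry = {"command": command, "seed": registry["seed"],
             "config_hash": registry.config_hash(), "status": "ok"}
    try:
        entry["result"] = _STAGES[command](registry, workdir)
        return 0
    except Exception as exc:  # logged, then re-raised for the caller
        entry["status"] = "error"
        entry["error"] = str(exc)
        raise
    finally:
        entry["elapsed_s"] = round(time.time() - t0, 3)
        _log_run(workdir, entry)


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(
        prog="btx",
        description="multi-animal tracking with posture, visual fields and "
                    "uniqueness-guided visual identification")
    parser.add_argument("command", choices=sorted(_STAGES))
    parser.add_argument("-c", "--config", help="plain-text key=value config file")
    parser.add_argument("-s", "--set", action="append", default=[], metavar="KEY=VALUE",
                        help="override a registered parameter")
    parser.add_argument("--seed", type=int, default=None)
    parser.add_argument("-d", "--workdir", default=".")
    args = parser.parse_args(argv)
    overrides = list(args.set)
    if args.seed is not None:
        overrides.append(f"seed={args.seed}")
    registry = load_config(args.config, overrides)
    return run_pipeline(args.command, registry, args.workdir)


if __name__ == "__main__":
    raise SystemExit(main())
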