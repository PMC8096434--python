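"""Background modelling and foreground blob extraction.

The background is estimated pixelwise from a uniform sample of frames
(min/max/mode/mean); each frame is then thresholded on its absolute
difference to the background (or replaced by an external binary mask) and
split into 8-connected components.  Each surviving component becomes a
:class:`Blob` carrying its original grayscale values.

Image coordinates: origin top-left, x right, y down, 0-based; pixel (x, y)
occupies the unit square [x, x+1) x [y, y+1).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "Blob",
    "BackgroundModel",
    "SegmentationConfig",
    "estimate_background",
    "preprocess_frame",
    "segment_frame",
]

# 8-connectivity structuring element, chosen to keep thin diagonal
# extremities (tails) attached to the body.
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class Blob:
    """One segmented foreground object: pixel coordinates + grayscale values."""

    ys: np.ndarray  # row index per pixel
    xs: np.ndarray  # column index per pixel
    values: np.ndarray  # original grayscale value per pixel (uint8)

    def __post_init__(self):
        self.ys = np.asarray(self.ys, dtype=np.int32)
        self.xs = np.asarray(self.xs, dtype=np.int32)
        self.values = np.asarray(self.values)

    @property
    def n_pixels(self) -> int:
        return int(self.ys.size)

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(x0, y0, w, h) of the tight bounding box."""
        x0 = int(self.xs.min())
        y0 = int(self.ys.min())
        return (x0, y0, int(self.xs.max()) - x0 + 1, int(self.ys.max()) - y0 + 1)

    @property
    def centroid(self) -> tuple[float, float]:
        """(x, y) centre of mass of the pixel centres."""
        return (float(self.xs.mean()) + 0.5, float(self.ys.mean()) + 0.5)

    def mask(self) -> np.ndarray:
        """Dense boolean mask of the bounding box."""
        x0, y0, w, h = self.bbox
        m = np.zeros((h, w), dtype=bool)
        m[self.ys - y0, self.xs - x0] = True
        return m

    def image(self, fill: float = 0.0) -> np.ndarray:
        """Dense grayscale crop of the bounding box, ``fill`` outside the mask."""
        x0, y0, w, h = self.bbox
        img = np.full((h, w), fill, dtype=float)
        img[self.ys - y0, self.xs - x0] = self.values
        return img


@dataclass
class BackgroundModel:
    image: np.ndarray
    mode: str
    sample_count: int


@dataclass
class SegmentationConfig:
    threshold: int = 25
    blob_size_range: tuple[int, int] = (10, 1_000_000)
    use_mask: bool = False
    equalize_luminance: bool = False
    dark_only: bool = False  # restrict to objects darker than the background

    def validate(self) -> None:
        if not 0 < self.threshold <= 255:
            raise ValueError("threshold must be in (0, 255]")
        lo, hi = self.blob_size_range
        if lo > hi:
            raise ValueError("blob_size_range min must not exceed max")


def estimate_background(frames, mode: str = "mode") -> BackgroundModel:
    """Pixelwise background from a uniform sample of frames.

    ``mode`` is one of ``min``, ``max``, ``mode`` (8-bit histogram, ties
    broken toward the larger value) or ``mean``.
    """
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise ValueError("estimate_background needs at least one sampled frame")
    n = frames.shape[0]
    if mode == "min":
        img = frames.min(axis=0)
    elif mode == "max":
        img = frames.max(axis=0)
    elif mode == "mean":
        img = np.rint(frames.mean(axis=0)).astype(np.uint8)
    elif mode == "mode":
        f8 = frames.astype(np.uint8)
        counts = np.zeros((256,) + f8.shape[1:], dtype=np.uint16)
        idx = np.indices(f8.shape[1:])
        for k in range(n):
            counts[f8[k], idx[0], idx[1]] += 1
        # ties toward the larger grayscale value
        img = (255 - np.argmax(counts[::-1], axis=0)).astype(np.uint8)
    else:
        raise ValueError(f"unknown background mode {mode!r}")
    return BackgroundModel(image=np.asarray(img, dtype=np.uint8), mode=mode, sample_count=n)


def preprocess_frame(frame: np.ndarray, background: BackgroundModel,
                     config: SegmentationConfig) -> np.ndarray:
    """Optional luminance equalization: scale the frame so its global mean
    matches the background's global mean.  Pass-through otherwise."""
    frame = np.asarray(frame)
    if frame.shape != background.image.shape:
        raise ValueError("frame dimensions do not match the background")
    if not config.equalize_luminance:
        return frame
    fmean = float(frame.mean())
    if fmean == 0.0:
        import warnings

        warnings.warn("all-zero frame: luminance equalization skipped")
        return frame
    scale = float(background.image.mean()) / fmean
    return np.clip(np.rint(frame.astype(float) * scale), 0, 255).astype(frame.dtype)


def segment_frame(frame: np.ndarray, background: BackgroundModel,
                  config: SegmentationConfig, mask: np.ndarray | None = None) -> list[Blob]:
    """Threshold the background difference (or apply the external mask) and
    return size-filtered 8-connected blobs ordered top-left to bottom-right.
    """
    config.validate()
    frame = np.asarray(frame)
    if frame.shape != background.image.shape:
        raise ValueError("frame dimensions do not match the background")
    if config.use_mask:
        if mask is None:
            raise ValueError("use_mask is set but no mask was given")
        mask = np.asarray(mask)
        if mask.shape != frame.shape:
            raise ValueError("mask dimensions do not match the frame")
        fg = mask > 0
    else:
        diff = frame.astype(np.int16) - background.image.astype(np.int16)
        if config.dark_only:
            fg = -diff >= config.threshold
        else:
            fg = np.abs(diff) >= config.threshold
    labels, n_lab = ndimage.label(fg, structure=_STRUCT8)
    if n_lab == 0:
        return []
    lo, hi = config.blob_size_range
    blobs = []
    objects = ndimage.find_objects(labels)
    for lab, sl in enumerate(objects, start=1):
        ys, xs = np.nonzero(labels[sl] == lab)
        if not lo <= ys.size <= hi:
            continue
        ys = ys + sl[0].start
        xs = xs + sl[1].start
        blobs.append(Blob(ys=ys, xs=xs, values=frame[ys, xs]))
    blobs.sort(key=lambda b: (b.bbox[1], b.bbox[0]))
    return blobs
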