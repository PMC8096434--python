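"""Preprocessed-video container (.pvs) and trajectory table export.

The container stores, per frame, only the segmented blobs (bounding box plus
horizontal grayscale runs) together with a microsecond timestamp, and ends
with a byte-offset index so that any frame can be read with a single seek.

Byte layout (little-endian throughout)::

    header:  magic "PVS1" | u16 version=1 | u32 width | u32 height |
             u8 channels | u64 frame_count | width*height raw background |
             u64 index_offset
    frame:   u8 flags | u64 timestamp_us | u16 n_blobs | blobs ...
             (flags bit 0: payload after the flag byte is deflate-compressed)
    blob:    u16 x0 | u16 y0 | u16 w | u16 h | u16 n_lines | lines ...
    line:    u16 y | u16 x_start | u16 length | `length` grayscale bytes
    index:   frame_count * u64 absolute byte offsets, starting at index_offset
"""

from __future__ import annotations

import io
import struct
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import Blob

__all__ = [
    "PVSHeader",
    "FrameRecord",
    "BlobRecord",
    "PVFormatError",
    "write_container",
    "read_header",
    "read_frame",
    "read_all_frames",
    "export_trajectories",
    "load_timestamps_sidecar",
]

MAGIC = b"PVS1"
VERSION = 1
FLAG_DEFLATE = 0x01


class PVFormatError(ValueError):
    """Raised for malformed or inconsistent container data."""


@dataclass
class PVSHeader:
    width: int
    height: int
    frame_count: int
    background: np.ndarray
    channels: int = 1
    version: int = VERSION
    index_offset: int = 0

    def validate(self) -> None:
        bg = np.asarray(self.background)
        if bg.shape != (self.height, self.width):
            raise PVFormatError("background dimensions do not match width/height")
        if self.channels != 1:
            raise PVFormatError("only single-channel containers are supported")


@dataclass
class BlobRecord:
    """Run-length encoded blob: (y, x_start, length) runs with grayscale bytes."""

    bbox: tuple[int, int, int, int]  # x0, y0, w, h
    lines: list[tuple[int, int, bytes]] = field(default_factory=list)

    @classmethod
    def from_blob(cls, blob: Blob) -> "BlobRecord":
        x0, y0, w, h = blob.bbox
        order = np.lexsort((blob.xs, blob.ys))
        ys, xs, vals = blob.ys[order], blob.xs[order], np.asarray(blob.values, dtype=np.uint8)[order]
        lines: list[tuple[int, int, bytes]] = []
        i = 0
        n = ys.size
        while i < n:
            j = i + 1
            while j < n and ys[j] == ys[i] and xs[j] == xs[j - 1] + 1:
                j += 1
            lines.append((int(ys[i]), int(xs[i]), vals[i:j].tobytes()))
            i = j
        return cls(bbox=(x0, y0, w, h), lines=lines)

    def to_blob(self) -> Blob:
        ys, xs, vals = [], [], []
        for y, x_start, data in self.lines:
            k = len(data)
            ys.append(np.full(k, y, dtype=np.int32))
            xs.append(np.arange(x_start, x_start + k, dtype=np.int32))
            vals.append(np.frombuffer(data, dtype=np.uint8))
        return Blob(ys=np.concatenate(ys), xs=np.concatenate(xs), values=np.concatenate(vals))

    def validate(self) -> None:
        x0, y0, w, h = self.bbox
        last: dict[int, int] = {}
        for y, xs, data in self.lines:
            if not (y0 <= y < y0 + h and x0 <= xs and xs + len(data) <= x0 + w):
                raise PVFormatError("blob run lies outside its bounding box")
            if y in last and xs < last[y]:
                raise PVFormatError("blob runs within a line must be sorted and disjoint")
            last[y] = xs + len(data)


@dataclass
class FrameRecord:
    timestamp_us: int
    blobs: list[BlobRecord] = field(default_factory=list)


def _pack_frame_payload(rec: FrameRecord) -> bytes:
    out = bytearray()
    out += struct.pack("<QH", rec.timestamp_us, len(rec.blobs))
    for blob in rec.blobs:
        blob.validate()
        x0, y0, w, h = blob.bbox
        out += struct.pack("<5H", x0, y0, w, h, len(blob.lines))
        for y, xs, data in blob.lines:
            out += struct.pack("<3H", y, xs, len(data))
            out += data
    return bytes(out)


def write_container(path, header: PVSHeader, frames, compress: bool = False) -> None:
    """Write a .pvs container; ``frames`` is an iterable of FrameRecord.

    Timestamps must be strictly increasing.  ``compress`` stores each frame
    payload deflate-compressed (lossless), marked by the frame flag byte.
    """
    header.validate()
    bg = np.asarray(header.background, dtype=np.uint8)
    offsets: list[int] = []
    prev_ts = -1
    count = 0
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<HII B Q", header.version, header.width, header.height,
                             header.channels, header.frame_count))
        fh.write(bg.tobytes())
        index_pos_field = fh.tell()
        fh.write(struct.pack("<Q", 0))  # index_offset placeholder
        for rec in frames:
            if rec.timestamp_us <= prev_ts:
                raise PVFormatError("frame timestamps must be strictly increasing")
            prev_ts = rec.timestamp_us
            for blob in rec.blobs:
                x0, y0, w, h = blob.bbox
                if x0 + w > header.width or y0 + h > header.height:
                    raise PVFormatError("blob bounding box exceeds frame dimensions")
            offsets.append(fh.tell())
            payload = _pack_frame_payload(rec)
            if compress:
                fh.write(struct.pack("<B", FLAG_DEFLATE))
                comp = zlib.compress(payload, 6)
                fh.write(struct.pack("<I", len(comp)))
                fh.write(comp)
            else:
                fh.write(struct.pack("<B", 0))
                fh.write(payload)
            count += 1
        if count != header.frame_count:
            raise PVFormatError(
                f"header announces {header.frame_count} frames but {count} were written")
        index_offset = fh.tell()
        for off in offsets:
            fh.write(struct.pack("<Q", off))
        fh.seek(index_pos_field)
        fh.write(struct.pack("<Q", index_offset))


_HEADER_FIXED = struct.Struct("<HII B Q")


def _open(path_or_file):
    if hasattr(path_or_file, "read"):
        return path_or_file, False
    return open(path_or_file, "rb"), True


def read_header(path_or_file) -> PVSHeader:
    fh, owned = _open(path_or_file)
    try:
        fh.seek(0)
        magic = fh.read(4)
        if magic != MAGIC:
            raise PVFormatError(f"bad magic {magic!r}; not a PVS container")
        raw = fh.read(_HEADER_FIXED.size)
        if len(raw) < _HEADER_FIXED.size:
            raise PVFormatError("truncated header")
        version, width, height, channels, frame_count = _HEADER_FIXED.unpack(raw)
        if version != VERSION:
            raise PVFormatError(f"unsupported container version {version}")
        bg_raw = fh.read(width * height)
        if len(bg_raw) < width * height:
            raise PVFormatError("truncated background image")
        background = np.frombuffer(bg_raw, dtype=np.uint8).reshape(height, width)
        off_raw = fh.read(8)
        if len(off_raw) < 8:
            raise PVFormatError("truncated header (missing index offset)")
        (index_offset,) = struct.unpack("<Q", off_raw)
        return PVSHeader(width=width, height=height, frame_count=frame_count,
                         background=background, channels=channels, version=version,
                         index_offset=index_offset)
    finally:
        if owned:
            fh.close()


def _parse_frame_payload(payload: bytes) -> FrameRecord:
    view = memoryview(payload)
    try:
        ts, n_blobs = struct.unpack_from("<QH", view, 0)
        pos = 10
        blobs = []
        for _ in range(n_blobs):
            x0, y0, w, h, n_lines = struct.unpack_from("<5H", view, pos)
            pos += 10
            lines = []
            for _ in range(n_lines):
                y, xs, ln = struct.unpack_from("<3H", view, pos)
                pos += 6
                data = bytes(view[pos:pos + ln])
                if len(data) < ln:
                    raise PVFormatError("truncated blob line data")
                pos += ln
                lines.append((y, xs, data))
            blobs.append(BlobRecord(bbox=(x0, y0, w, h), lines=lines))
        return FrameRecord(timestamp_us=ts, blobs=blobs)
    except struct.error as exc:
        raise PVFormatError(f"corrupt frame payload: {exc}") from exc


def read_frame(path_or_file, index: int) -> FrameRecord:
    """Random access to frame ``index``: touches only header, index and the
    frame's own bytes."""
    fh, owned = _open(path_or_file)
    try:
        header = read_header(fh)
        if not 0 <= index < header.frame_count:
            raise IndexError(f"frame index {index} out of range [0, {header.frame_count})")
        fh.seek(header.index_offset + 8 * index)
        raw = fh.read(8)
        if len(raw) < 8:
            raise PVFormatError("truncated frame index")
        (offset,) = struct.unpack("<Q", raw)
        fh.seek(offset)
        flag_raw = fh.read(1)
        if len(flag_raw) < 1:
            raise PVFormatError("truncated frame record")
        flags = flag_raw[0]
        if flags & FLAG_DEFLATE:
            size_raw = fh.read(4)
            if len(size_raw) < 4:
                raise PVFormatError("truncated compressed frame record")
            (comp_len,) = struct.unpack("<I", size_raw)
            comp = fh.read(comp_len)
            if len(comp) < comp_len:
                raise PVFormatError("truncated compressed frame record")
            try:
                payload = zlib.decompress(comp)
            except zlib.error as exc:
                raise PVFormatError(f"corrupt deflate stream: {exc}") from exc
        else:
            # uncompressed frames end where the next frame (or the index) begins
            if index + 1 < header.frame_count:
                fh.seek(header.index_offset + 8 * (index + 1))
                (end,) = struct.unpack("<Q", fh.read(8))
            else:
                end = header.index_offset
            fh.seek(offset + 1)
            payload = fh.read(end - offset - 1)
        return _parse_frame_payload(payload)
    finally:
        if owned:
            fh.close()


def read_all_frames(path_or_file) -> list[FrameRecord]:
    fh, owned = _open(path_or_file)
    try:
        header = read_header(fh)
        return [read_frame(fh, i) for i in range(header.frame_count)]
    finally:
        if owned:
            fh.close()


def load_timestamps_sidecar(path) -> np.ndarray:
    """Read per-frame timestamps (microseconds) from a sidecar NPZ keyed by
    frame index (array under 'timestamps_us' or the first array present)."""
    with np.load(path) as npz:
        key = "timestamps_us" if "timestamps_us" in npz.files else npz.files[0]
        return np.asarray(npz[key], dtype=np.int64)


# ---------------------------------------------------------------------------
# Trajectory export

_EXPORT_COLUMNS = [
    "frame", "time", "x", "y", "speed", "heading",
    "midline_length", "segment_id", "identity", "final_identity",
]


def individual_table(ind) -> pd.DataFrame:
    """Per-individual export table with missing-value sentinels (NaN) on
    frames inside the tracked range where the individual was lost."""
    frames = sorted(ind.assignments)
    if not frames:
        return pd.DataFrame(columns=_EXPORT_COLUMNS)
    full = np.arange(frames[0], frames[-1] + 1)
    rows = []
    for f in full:
        a = ind.assignments.get(int(f))
        seg = ind.segment_of_frame(int(f))
        rows.append(
            {
                "frame": int(f),
                "time": a.time if a else np.nan,
                "x": a.x if a else np.nan,
                "y": a.y if a else np.nan,
                "speed": a.speed if a else np.nan,
                "heading": a.heading if a else np.nan,
                "midline_length": (a.midline_length if a and a.midline_length is not None else np.nan),
                "segment_id": seg if seg is not None else np.nan,
                "identity": ind.identity,
                "final_identity": (ind.final_identity if getattr(ind, "final_identity", None) is not None
                                   else ind.identity),
            }
        )
    return pd.DataFrame(rows, columns=_EXPORT_COLUMNS)


def export_trajectories(individuals, path_prefix: str, format: str = "csv") -> list[str]:
    """Write one table per individual as CSV and/or columnar NPZ.

    ``format`` is ``csv``, ``npz`` or ``both``.  Missing values are empty
    fields in CSV and NaN in NPZ.  Returns the list of files written.
    """
    if format not in ("csv", "npz", "both"):
        raise ValueError("format must be csv, npz or both")
    written = []
    for ind in individuals:
        table = individual_table(ind)
        if format in ("csv", "both"):
            fn = f"{path_prefix}_id{ind.identity}.csv"
            table.to_csv(fn, index=False, float_format="%.6f", lineterminator="\n")
            written.append(fn)
        if format in ("npz", "both"):
            fn = f"{path_prefix}_id{ind.identity}.npz"
            np.savez(fn, **{c: table[c].to_numpy(dtype=float) for c in _EXPORT_COLUMNS})
            written.append(fn)
    return written
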