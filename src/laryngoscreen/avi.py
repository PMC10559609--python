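"""Minimal uncompressed AVI (RIFF) container support.

Writes and reads 24-bit BI_RGB video-only AVI files: the lowest common
denominator that every player and toolchain understands without codecs.
Frames are stored as bottom-up BGR rows padded to 4-byte boundaries, one
``00db`` chunk per frame; the frame rate is carried in the stream header
as a rational ``dwRate / dwScale``.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

__all__ = ["write_avi", "read_avi"]

_FPS_SCALE = 1000  # fps stored as rate/scale with millihertz resolution


def _row_stride(width: int) -> int:
    return (width * 3 + 3) & ~3


def _encode_frame(frame: np.ndarray) -> bytes:
    """RGB (H, W, 3) uint8 -> padded bottom-up BGR bytes."""
    h, w, _ = frame.shape
    stride = _row_stride(w)
    bgr = frame[::-1, :, ::-1]  # flip vertically, swap to BGR
    if stride == w * 3:
        return bgr.tobytes()
    out = np.zeros((h, stride), dtype=np.uint8)
    out[:, : w * 3] = bgr.reshape(h, w * 3)
    return out.tobytes()


def _decode_frame(data: bytes, width: int, height: int) -> np.ndarray:
    stride = _row_stride(width)
    arr = np.frombuffer(data, dtype=np.uint8, count=height * stride)
    arr = arr.reshape(height, stride)[:, : width * 3].reshape(height, width, 3)
    return arr[::-1, :, ::-1].copy()


def write_avi(path, frames, fps: float) -> None:
    """Write an uncompressed AVI.

    Parameters
    ----------
    path : path-like
        Destination file.
    frames : sequence of (H, W, 3) uint8 arrays
        All frames must share one shape.
    fps : float
        Frame rate; stored with 1/1000 Hz resolution.
    """
    frames = list(frames)
    if not frames:
        raise ValueError("cannot write an AVI with zero frames")
    if fps <= 0:
        raise ValueError("fps must be positive")
    first = np.asarray(frames[0])
    if first.ndim != 3 or first.shape[2] != 3 or first.dtype != np.uint8:
        raise ValueError("frames must be (H, W, 3) uint8 RGB arrays")
    h, w = first.shape[:2]
    n = len(frames)
    frame_bytes = h * _row_stride(w)
    rate = round(fps * _FPS_SCALE)

    avih = struct.pack(
        "<14I",
        round(1e6 / fps),  # dwMicroSecPerFrame
        frame_bytes * round(fps),  # dwMaxBytesPerSec
        0,  # dwPaddingGranularity
        0x10,  # AVIF_HASINDEX
        n, 0, 1, frame_bytes,
        w, h, 0, 0, 0, 0,
    )
    strh = struct.pack(
        "<4s4sI2H8I4h",
        b"vids", b"DIB ", 0, 0, 0, 0,
        _FPS_SCALE, rate, 0, n, frame_bytes, 0xFFFFFFFF, 0,
        0, 0, w, h,
    )
    strf = struct.pack("<IiiHHIIiiII", 40, w, h, 1, 24, 0, frame_bytes, 0, 0, 0, 0)

    def chunk(fourcc: bytes, payload: bytes) -> bytes:
        pad = b"\0" if len(payload) & 1 else b""
        return fourcc + struct.pack("<I", len(payload)) + payload + pad

    def lst(fourcc: bytes, payload: bytes) -> bytes:
        return chunk(b"LIST", fourcc + payload)

    strl = lst(b"strl", chunk(b"strh", strh) + chunk(b"strf", strf))
    hdrl = lst(b"hdrl", chunk(b"avih", avih) + strl)

    movi_payload = b"".join(chunk(b"00db", _encode_frame(np.asarray(f))) for f in frames)
    movi = lst(b"movi", movi_payload)

    # idx1: one entry per frame, offsets relative to the start of 'movi' fourcc
    idx_entries = []
    offset = 4
    for _ in range(n):
        idx_entries.append(struct.pack("<4sIII", b"00db", 0x10, offset, frame_bytes))
        offset += 8 + frame_bytes + (frame_bytes & 1)
    idx1 = chunk(b"idx1", b"".join(idx_entries))

    body = b"AVI " + hdrl + movi + idx1
    with open(path, "wb") as fh:
        fh.write(b"RIFF" + struct.pack("<I", len(body)) + body)


def read_avi(path):
    """Read an uncompressed AVI written by :func:`write_avi` (or compatible).

    Returns
    -------
    frames : list of (H, W, 3) uint8 RGB arrays
    fps : float

    Raises
    ------
    IOError
        If the file is not a RIFF/AVI container or uses a compressed codec.
    """
    data = Path(path).read_bytes()
    if len(data) < 12 or data[:4] != b"RIFF" or data[8:12] != b"AVI ":
        raise IOError(f"not an AVI (RIFF) file: {path}")

    fps = None
    width = height = None
    compression = None
    frames_raw: list[bytes] = []

    def walk(buf: bytes) -> None:
        nonlocal fps, width, height, compression
        pos = 0
        while pos + 8 <= len(buf):
            fourcc = buf[pos : pos + 4]
            (size,) = struct.unpack_from("<I", buf, pos + 4)
            payload = buf[pos + 8 : pos + 8 + size]
            if fourcc == b"LIST":
                walk(payload[4:])
            elif fourcc == b"strh" and payload[:4] == b"vids":
                scale, rate = struct.unpack_from("<II", payload, 20)
                if scale and rate:
                    fps = rate / scale
            elif fourcc == b"strf" and len(payload) >= 40:
                _, width, height, _, bitcount, compression = struct.unpack_from(
                    "<IiiHHI", payload, 0
                )
                if bitcount != 24:
                    raise IOError(f"unsupported AVI bit depth {bitcount} (need 24)")
            elif fourcc in (b"00db", b"00dc") and size > 0:
                frames_raw.append(payload)
            pos += 8 + size + (size & 1)

    walk(data[12:])

    if compression not in (0, None):
        raise IOError("compressed AVI streams are not supported; re-encode as BI_RGB")
    if width is None or height is None:
        raise IOError(f"no video stream format found in {path}")
    if fps is None:
        raise IOError(
            f"frame-rate metadata missing in {path}; pass an explicit fps override"
        )
    frames = [_decode_frame(raw, width, height) for raw in frames_raw]
    return frames, float(fps)
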