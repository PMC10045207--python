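"""Sensor/frame synchronization and digital derotation.

A two-axis gimbal stabilizes pitch and roll of the camera's view axes but
leaves a residual rotation of the optical plane. That roll angle can be
recovered from the gimbal's left-facing view vector ``h`` and down-facing
view vector ``v`` (geodetic coordinates) as ``atan2(h_z, v_z)``, and removed
digitally by rotating each frame by the negated angle.

Gimbal and flight-sensor logs are sampled asynchronously from the camera, so
each frame is first paired with the sensor sample closest in time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "GimbalSample",
    "FrameRecord",
    "StabilizedFrame",
    "match_sensor_to_frames",
    "compute_roll_angle",
    "derotate_frame",
    "stabilize_sequence",
]


@dataclass(frozen=True)
class GimbalSample:
    """One gimbal log entry: time plus the two view unit vectors."""

    t: float
    h: np.ndarray  # left-facing view vector (3,)
    v: np.ndarray  # down-facing view vector (3,)


@dataclass(frozen=True)
class FrameRecord:
    """A timestamped 8-bit RGB frame."""

    index: int
    t: float
    image: np.ndarray  # (H, W, 3) uint8


@dataclass(frozen=True)
class StabilizedFrame:
    """A derotated frame, centered in a zero-padded square canvas."""

    image: np.ndarray  # (S, S, 3) with S = max(H, W) of the source
    applied_angle: float  # radians actually applied (the negated roll)
    index: int = 0
    t: float = 0.0


def match_sensor_to_frames(
    frame_times: Sequence[float], sensor_times: Sequence[float]
) -> np.ndarray:
    """Pair every frame with the temporally nearest sensor sample.

    For each frame timestamp ``t`` the returned index ``m`` minimizes
    ``|t - sensor_times[m]|``. Exact ties break to the earlier sensor index,
    which keeps the matching deterministic and order-independent.

    Parameters
    ----------
    frame_times, sensor_times
        Strictly/weakly ascending timestamp sequences in seconds.

    Returns
    -------
    ndarray of int with one sensor index per frame.
    """
    ft = np.asarray(frame_times, dtype=float)
    st = np.asarray(sensor_times, dtype=float)
    if ft.size == 0 or st.size == 0:
        raise ValueError("timestamp sequences must be nonempty")
    if np.any(np.diff(ft) < 0) or np.any(np.diff(st) < 0):
        raise ValueError("timestamp sequences must be sorted ascending")
    # candidate on the right, then compare with its left neighbour
    right = np.searchsorted(st, ft, side="left")
    right = np.clip(right, 0, st.size - 1)
    left = np.clip(right - 1, 0, st.size - 1)
    d_left = np.abs(ft - st[left])
    d_right = np.abs(ft - st[right])
    chosen = np.where(d_left <= d_right, left, right)
    # tie-break to the earliest sensor index achieving the minimal distance
    # (covers duplicate timestamps and exactly equidistant neighbours)
    d = np.abs(ft - st[chosen])
    first = np.searchsorted(st, ft - d, side="left")
    first = np.clip(first, 0, st.size - 1)
    use_first = np.abs(ft - st[first]) <= d
    return np.where(use_first, first, chosen)


def compute_roll_angle(h: np.ndarray, v: np.ndarray) -> float:
    """Residual roll of the optical plane from the gimbal view vectors.

    Returns ``atan2(h_z, v_z)`` in (-pi, pi]. The result is invariant to the
    (common) scale of the vectors, so no normalization is applied.
    """
    h = np.asarray(h, dtype=float)
    v = np.asarray(v, dtype=float)
    if not (np.all(np.isfinite(h)) and np.all(np.isfinite(v))):
        raise ValueError("gimbal vectors must be finite")
    hz, vz = float(h[2]), float(v[2])
    if hz == 0.0 and vz == 0.0:
        raise ValueError("degenerate gimbal geometry: h_z and v_z both zero")
    return float(np.arctan2(hz, vz))


def _center_in_square(image: np.ndarray) -> np.ndarray:
    h, w = image.shape[:2]
    s = max(h, w)
    canvas = np.zeros((s, s) + image.shape[2:], dtype=image.dtype)
    oy, ox = (s - h) // 2, (s - w) // 2
    canvas[oy : oy + h, ox : ox + w] = image
    return canvas


def derotate_frame(frame: FrameRecord, angle: float) -> StabilizedFrame:
    """Rotate a frame by ``-angle`` about its center, bilinearly interpolated.

    The source is first centered within a zero-padded square of side
    ``max(H, W)`` so the rotation never crops content; pixels that fall
    outside the source stay zero.
    """
    if not np.isfinite(angle):
        raise ValueError("angle must be finite")
    img = np.asarray(frame.image)
    if img.size == 0:
        raise ValueError("empty image")
    square = _center_in_square(img)
    if angle == 0.0:
        out = square.astype(np.float64)
    else:
        # scipy rotates counterclockwise in array (row, col) coordinates about
        # the center ((S-1)/2, (S-1)/2); order=1 is bilinear.
        out = ndimage.rotate(
            square.astype(np.float64),
            np.degrees(-angle),
            axes=(1, 0),
            reshape=False,
            order=1,
            mode="constant",
            cval=0.0,
        )
    out = np.clip(np.round(out), 0, 255).astype(np.uint8)
    return StabilizedFrame(image=out, applied_angle=-angle, index=frame.index, t=frame.t)


def stabilize_sequence(bundle) -> list[StabilizedFrame]:
    """Derotate every frame of a recording bundle.

    The roll angle for each frame comes from the gimbal sample nearest in
    time. Returns one square stabilized frame per input frame.
    """
    frames = list(bundle.frames)
    gimbal = list(bundle.gimbal)
    if not gimbal:
        raise ValueError("recording bundle has no gimbal log")
    if not frames:
        raise ValueError("recording bundle has no frames")
    frame_times = [f.t for f in frames]
    sensor_times = [g.t for g in gimbal]
    matches = match_sensor_to_frames(frame_times, sensor_times)
    out = []
    for frame, m in zip(frames, matches):
        g = gimbal[int(m)]
        angle = compute_roll_angle(g.h, g.v)
        out.append(derotate_frame(frame, angle))
    return out
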