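"""Face-aware iterative exposure-time control.

rPPG signal strength grows with the light collected from the skin, so the
face region should be exposed as brightly as possible short of clipping.
The controller drives the 98th percentile ``v`` of the face-region pixel
values into the open band (190, 230) on an 8-bit scale by the multiplicative
update ``l <- (190 + 230) / (2 v) * l``, which for a linear camera lands
``v`` at the band center 210 in a single step. At most 10 iterations are
attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .contracts import CameraContract, FaceDetectorContract

__all__ = ["ExposureResult", "face_percentile_value", "adjust_exposure"]

TARGET_LOW = 190
TARGET_HIGH = 230
MAX_ITERATIONS = 10
PERCENTILE = 98


@dataclass(frozen=True)
class ExposureResult:
    exposure_time: float  # milliseconds
    final_face_value: float  # 8-bit intensity (98th percentile in face box)
    iterations_used: int
    converged: bool
    clamped: bool = False  # exposure hit a camera bound at some point
    bbox_reused: bool = False  # detection failed mid-loop; last bbox reused


def face_percentile_value(
    image: np.ndarray, bbox: tuple[int, int, int, int], percentile: float = PERCENTILE
) -> int:
    """Nearest-rank percentile of the pixel values inside a bounding box.

    Uses the ceil(q/100 * n)-th order statistic, which is deterministic and
    always an actual 8-bit pixel value.
    """
    img = np.asarray(image)
    if img.ndim == 3:  # color input: gray = channel mean
        img = img.mean(axis=2)
    x, y, w, h = bbox
    x0, y0 = max(int(x), 0), max(int(y), 0)
    x1 = min(int(x) + int(w), img.shape[1])
    y1 = min(int(y) + int(h), img.shape[0])
    region = img[y0:y1, x0:x1]
    if region.size == 0:
        raise ValueError("face bbox does not intersect the image")
    flat = np.sort(region.reshape(-1))
    rank = max(int(math.ceil(percentile / 100.0 * flat.size)), 1)
    return int(flat[rank - 1])


def adjust_exposure(
    camera: CameraContract,
    detector: FaceDetectorContract,
    initial_exposure: float,
    max_iterations: int = MAX_ITERATIONS,
) -> ExposureResult:
    """Iteratively adjust exposure until the face percentile sits in (190, 230).

    Each round captures at the current exposure, detects the face, measures
    the 98th percentile ``v`` of the face box, and either accepts the
    exposure or rescales it by ``(190 + 230) / (2 v)``. Exposures are clamped
    to the camera's bounds (flagged in the result). If detection fails after
    the first capture, the previous box is reused and flagged; failure on the
    very first capture is an error.
    """
    lo = float(getattr(camera, "min_exposure_ms", 0.0))
    hi = float(getattr(camera, "max_exposure_ms", float("inf")))
    exposure = float(initial_exposure)
    clamped = False
    bbox_reused = False
    bbox = None
    v = 0.0
    for n in range(max_iterations + 1):
        image = camera.capture(exposure)
        found = detector.detect(image)
        if found is None:
            if bbox is None:
                raise RuntimeError("face not detected on the initial capture")
            bbox_reused = True
        else:
            bbox = found
        v = face_percentile_value(image, bbox)
        if TARGET_LOW < v < TARGET_HIGH:
            return ExposureResult(
                exposure_time=exposure,
                final_face_value=v,
                iterations_used=n,
                converged=True,
                clamped=clamped,
                bbox_reused=bbox_reused,
            )
        if n == max_iterations:
            break
        if v <= 0:
            # fully dark frame: the multiplicative rule is undefined; jump to
            # the longest exposure available and keep iterating
            nxt = hi if math.isfinite(hi) else exposure * 10.0
            if nxt == hi:
                clamped = True
        else:
            nxt = (TARGET_LOW + TARGET_HIGH) / (2.0 * v) * exposure
        if nxt < lo or nxt > hi:
            nxt = min(max(nxt, lo), hi)
            clamped = True
        exposure = nxt
    return ExposureResult(
        exposure_time=exposure,
        final_face_value=v,
        iterations_used=max_iterations,
        converged=False,
        clamped=clamped,
        bbox_reused=bbox_reused,
    )
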