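"""Pluggable contracts for the camera, face detector and landmark provider.

The pipeline's contribution is what happens around detection, not the
detectors themselves, so these are structural interfaces. The synthetic
scene simulator ships ground-truth implementations of all three; adapters to
real detectors (Haar cascades, face-mesh networks) can be plugged in without
touching the pipeline.
"""

from __future__ import annotations

from typing import Optional, Protocol, runtime_checkable

import numpy as np


@runtime_checkable
class CameraContract(Protocol):
    """A stills camera controlled only through its exposure time."""

    min_exposure_ms: float
    max_exposure_ms: float

    def capture(self, exposure_time_ms: float) -> np.ndarray:
        """Return an (H, W) uint8 gray image for the given exposure time."""
        ...


@runtime_checkable
class FaceDetectorContract(Protocol):
    """Returns a face bounding box (x, y, w, h) in pixels, or None."""

    def detect(self, image: np.ndarray) -> Optional[tuple[int, int, int, int]]:
        ...


@runtime_checkable
class LandmarkProviderContract(Protocol):
    """Yields the ROI layout (polygons in pixel coordinates) for one frame."""

    def layout(self, frame_index: int, bbox: tuple[int, int, int, int]):
        """Return an ROILayout for the frame, anchored to ``bbox``."""
        ...
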