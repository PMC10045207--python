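"""Facial ROI layout, tracking and raw color-signal extraction.

A face-box time series is built over the stabilized frames; runs of
consecutive detections at least five seconds long become the usable
time-frame segments. Within each segment, 30 measurement polygons (forehead
and cheek patches) and 4 noise polygons (nostril and eye regions, which
carry lighting but no pulse) are anchored to the face box, and the mean
R, G, B value inside each polygon is extracted per frame together with the
tracking side-channels the de-noising stage consumes: vertex coordinates,
center of mass, and pixel count.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from matplotlib.path import Path as MplPath

from .contracts import FaceDetectorContract, LandmarkProviderContract
from .flight_sync import StabilizedFrame

__all__ = [
    "ROIPolygon",
    "ROILayout",
    "FaceDetectionSeries",
    "TimeFrameSegment",
    "RawROISignals",
    "default_layout_template",
    "layout_from_bbox",
    "detect_face_series",
    "segment_timeframes",
    "extract_roi_signals",
    "roi_signals_to_frame",
]

N_MEASUREMENT_ROIS = 30
NOISE_ROI_LABELS = ("nostril-center", "nostril-right", "eye-center", "eye-right")
MIN_SEGMENT_SECONDS = 5.0


@dataclass(frozen=True)
class ROIPolygon:
    label: str
    vertices: np.ndarray  # (V, 2) float, V in 4..6
    role: str  # "measurement" | "noise"

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or not (4 <= v.shape[0] <= 6):
            raise ValueError(f"ROI {self.label}: polygon must have 4-6 (x, y) vertices")
        object.__setattr__(self, "vertices", v)


@dataclass(frozen=True)
class ROILayout:
    """One frame's ROI geometry: 30 measurement + 4 noise polygons."""

    measurement_rois: tuple[ROIPolygon, ...]
    noise_rois: tuple[ROIPolygon, ...]

    def __post_init__(self):
        if len(self.measurement_rois) != N_MEASUREMENT_ROIS:
            raise ValueError(
                f"layout must contain exactly {N_MEASUREMENT_ROIS} measurement ROIs"
            )
        if len(self.noise_rois) != len(NOISE_ROI_LABELS):
            raise ValueError("layout must contain exactly 4 noise ROIs")

    @property
    def all_rois(self) -> tuple[ROIPolygon, ...]:
        return self.measurement_rois + self.noise_rois


# time series of per-frame optional face boxes: list of (x, y, w, h) or None
FaceDetectionSeries = list


@dataclass(frozen=True)
class TimeFrameSegment:
    start_index: int
    end_index: int  # inclusive
    duration: float  # seconds

    def __len__(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class RawROISignals:
    """Per-ROI raw signal bundle over one segment.

    All series share the segment length T: mean color per channel, pixel
    count, per-vertex coordinates (T, V, 2) and the polygon center of mass.
    """

    label: str
    role: str
    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    pixel_count: np.ndarray
    landmarks: np.ndarray  # (T, V, 2)
    center_of_mass: np.ndarray  # (T, 2)

    def channel(self, name: str) -> np.ndarray:
        return {"R": self.red, "G": self.green, "B": self.blue}[name]

    @property
    def n_vertices(self) -> int:
        return self.landmarks.shape[1]


def default_layout_template() -> list[dict]:
    """The default 30-region template in face-box-relative coordinates.

    Three forehead rows of six columns plus a 2x6 cheek grid give 30 quads;
    the nostril and eye noise regions sit at their anatomical positions.
    Coordinates are fractions of the face box, (0, 0) = top-left.
    """
    template = []
    # forehead: rows y in [0.08, 0.32], 3 rows x 6 cols
    fx = np.linspace(0.15, 0.85, 7)
    fy = np.linspace(0.08, 0.32, 4)
    for r in range(3):
        for c in range(6):
            template.append(
                {
                    "label": f"forehead-r{r}c{c}",
                    "vertices": [
                        [fx[c], fy[r]],
                        [fx[c + 1], fy[r]],
                        [fx[c + 1], fy[r + 1]],
                        [fx[c], fy[r + 1]],
                    ],
                    "role": "measurement",
                }
            )
    # cheeks: two bands (left and right of the nose), 2 rows x 3 cols each
    cy = np.linspace(0.55, 0.75, 3)
    for side, (x0, x1) in (("left", (0.10, 0.34)), ("right", (0.66, 0.90))):
        cx = np.linspace(x0, x1, 4)
        for r in range(2):
            for c in range(3):
                template.append(
                    {
                        "label": f"cheek-{side}-r{r}c{c}",
                        "vertices": [
                            [cx[c], cy[r]],
                            [cx[c + 1], cy[r]],
                            [cx[c + 1], cy[r + 1]],
                            [cx[c], cy[r + 1]],
                        ],
                        "role": "measurement",
                    }
                )
    noise = {
        "nostril-center": [[0.44, 0.60], [0.56, 0.60], [0.56, 0.68], [0.44, 0.68]],
        "nostril-right": [[0.56, 0.60], [0.64, 0.60], [0.64, 0.68], [0.56, 0.68]],
        "eye-center": [[0.38, 0.40], [0.62, 0.40], [0.62, 0.48], [0.38, 0.48]],
        "eye-right": [[0.64, 0.40], [0.88, 0.40], [0.88, 0.48], [0.64, 0.48]],
    }
    for label, verts in noise.items():
        template.append({"label": label, "vertices": verts, "role": "noise"})
    return template


def layout_from_bbox(
    bbox: tuple[float, float, float, float], template: Optional[list[dict]] = None
) -> ROILayout:
    """Instantiate a relative template at a concrete face box (pixel coords)."""
    if template is None:
        template = default_layout_template()
    x, y, w, h = bbox
    meas, noise = [], []
    for item in template:
        rel = np.asarray(item["vertices"], dtype=float)
        abs_verts = np.column_stack([x + rel[:, 0] * w, y + rel[:, 1] * h])
        poly = ROIPolygon(item["label"], abs_verts, item["role"])
        (meas if item["role"] == "measurement" else noise).append(poly)
    return ROILayout(tuple(meas), tuple(noise))


def save_layout_template(template: list[dict], path) -> None:
    with open(path, "w") as fh:
        json.dump(template, fh, indent=1)


def load_layout_template(path) -> list[dict]:
    with open(path) as fh:
        template = json.load(fh)
    for item in template:
        if item.get("role") not in ("measurement", "noise"):
            raise ValueError(f"template entry {item.get('label')}: bad role")
    return template


def detect_face_series(
    frames: Sequence[StabilizedFrame], detector: FaceDetectorContract
) -> FaceDetectionSeries:
    """Run the face detector on every frame; absences are recorded as None."""
    if len(frames) == 0:
        raise ValueError("empty frame sequence")
    return [detector.detect(f.image) for f in frames]


def segment_timeframes(
    series: FaceDetectionSeries,
    frame_rate: float,
    min_duration: float = MIN_SEGMENT_SECONDS,
) -> list[TimeFrameSegment]:
    """Maximal runs of consecutive detections lasting at least ``min_duration``.

    Duration is counted in frames: a run survives iff it spans at least
    ``ceil(min_duration * frame_rate)`` frames. An empty result signals that
    the heart-rate assessment fails for this recording.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    min_frames = int(math.ceil(min_duration * frame_rate))
    segments = []
    start = None
    for i, det in enumerate(list(series) + [None]):  # sentinel closes last run
        if det is not None and start is None:
            start = i
        elif det is None and start is not None:
            length = i - start
            if length >= min_frames:
                segments.append(
                    TimeFrameSegment(start, i - 1, duration=length / frame_rate)
                )
            start = None
    return segments


def _polygon_mask(vertices: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Pixels whose centers lie inside the polygon (even-odd rule)."""
    h, w = shape
    xmin = max(int(math.floor(vertices[:, 0].min())), 0)
    xmax = min(int(math.ceil(vertices[:, 0].max())) + 1, w)
    ymin = max(int(math.floor(vertices[:, 1].min())), 0)
    ymax = min(int(math.ceil(vertices[:, 1].max())) + 1, h)
    mask = np.zeros((h, w), dtype=bool)
    if xmax <= xmin or ymax <= ymin:
        return mask
    xs, ys = np.meshgrid(np.arange(xmin, xmax), np.arange(ymin, ymax))
    pts = np.column_stack([xs.ravel() + 0.5, ys.ravel() + 0.5])
    path = MplPath(vertices, closed=True)
    inside = path.contains_points(pts)
    mask[ymin:ymax, xmin:xmax] = inside.reshape(ymax - ymin, xmax - xmin)
    return mask


def extract_roi_signals(
    frames: Sequence[StabilizedFrame],
    segment: TimeFrameSegment,
    layout_provider: LandmarkProviderContract,
    detections: Optional[FaceDetectionSeries] = None,
) -> list[RawROISignals]:
    """Extract per-ROI mean-color series and tracking side-channels.

    For every frame in the segment, the layout provider yields the ROI
    polygons; each ROI's R, G, B means over pixels whose centers fall inside
    the polygon are recorded along with vertex coordinates, center of mass
    (the vertex average) and pixel count. ROIs whose polygon degenerates to
    zero pixels in any frame are dropped for the whole segment.
    """
    idxs = range(segment.start_index, segment.end_index + 1)
    per_roi: dict[str, dict] = {}
    dropped: set[str] = set()
    for k, i in enumerate(idxs):
        bbox = detections[i] if detections is not None else None
        layout = layout_provider.layout(i, bbox)
        img = frames[i].image.astype(np.float64)
        for poly in layout.all_rois:
            if poly.label in dropped:
                continue
            mask = _polygon_mask(poly.vertices, img.shape[:2])
            count = int(mask.sum())
            if count == 0:
                dropped.add(poly.label)
                continue
            means = img[mask].mean(axis=0)
            slot = per_roi.setdefault(
                poly.label,
                {
                    "role": poly.role,
                    "R": [],
                    "G": [],
                    "B": [],
                    "n": [],
                    "lm": [],
                    "com": [],
                    "first_k": k,
                },
            )
            slot["R"].append(means[0])
            slot["G"].append(means[1])
            slot["B"].append(means[2])
            slot["n"].append(count)
            slot["lm"].append(poly.vertices.copy())
            slot["com"].append(poly.vertices.mean(axis=0))
    out = []
    T = len(list(idxs))
    for label, slot in per_roi.items():
        if label in dropped or len(slot["R"]) != T:
            continue
        out.append(
            RawROISignals(
                label=label,
                role=slot["role"],
                red=np.asarray(slot["R"]),
                green=np.asarray(slot["G"]),
                blue=np.asarray(slot["B"]),
                pixel_count=np.asarray(slot["n"], dtype=float),
                landmarks=np.asarray(slot["lm"]),
                center_of_mass=np.asarray(slot["com"]),
            )
        )
    return out


def roi_signals_to_frame(signals: Sequence[RawROISignals]):
    """Long-format DataFrame of extracted signals (one row per frame/ROI/channel)."""
    import pandas as pd

    rows = []
    for sig in signals:
        T = sig.red.size
        for ch_name in ("R", "G", "B"):
            ch = sig.channel(ch_name)
            for t in range(T):
                row = {
                    "frame": t,
                    "roi": sig.label,
                    "channel": ch_name,
                    "mean": ch[t],
                    "pixel_count": sig.pixel_count[t],
                    "com_x": sig.center_of_mass[t, 0],
                    "com_y": sig.center_of_mass[t, 1],
                }
                for vi in range(sig.n_vertices):
                    row[f"v{vi}x"] = sig.landmarks[t, vi, 0]
                    row[f"v{vi}y"] = sig.landmarks[t, vi, 1]
                rows.append(row)
    return pd.DataFrame(rows)
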