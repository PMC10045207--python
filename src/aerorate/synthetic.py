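"""Synthetic flight-scene simulator with exact ground truth.

Emulates the data a drone hovering in front of a person produces: gimbal
and flight-sensor logs driven by smooth wind-like processes, a face-box
trajectory with jitter and dropouts, per-ROI color traces composed exactly
as the de-noising model assumes (pulse modulation + a linear mixture of the
nuisance design columns + white noise), small rendered frames with a
skin-colored face patch, a linear clipped camera for the exposure loop, and
a 100 Hz reference pleth trace.

Everything is deterministic for a fixed seed. Defaults describe a calm
hover: 15 fps, 20 s, a resting pulse at 70 bpm with a G-dominant pulsatile
color direction, gimbal roll jitter of a few degrees, and nuisance
fluctuations a few 8-bit units strong — several times the pulse amplitude,
so de-noising is load-bearing rather than cosmetic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, sosfiltfilt

from . import denoise as _dn
from .flight_sync import FrameRecord, GimbalSample, match_sensor_to_frames
from .roi import RawROISignals, default_layout_template, layout_from_bbox

__all__ = [
    "SceneConfig",
    "GroundTruth",
    "GimbalLog",
    "FlightLog",
    "RecordingBundle",
    "simulate_flight_logs",
    "simulate_roi_signals",
    "simulate_frames",
    "simulate_reference_pleth",
    "SyntheticCamera",
    "SyntheticFaceDetector",
    "BBoxLayoutProvider",
]


@dataclass(frozen=True)
class SceneConfig:
    """Scene parameters; the defaults describe a calm-hover recording."""

    true_hr: float = 70.0  # bpm, in [40, 200]
    hr_drift: float = 0.0  # bpm per second
    pulse_strength: float = 0.01  # relative G-channel modulation amplitude
    pulse_color: tuple[float, float, float] = (0.5, 1.0, 0.7)  # R, G, B ratios
    skin_base_color: tuple[float, float, float] = (170.0, 120.0, 100.0)
    background_color: tuple[float, float, float] = (60.0, 60.0, 60.0)
    nuisance_std: float = 2.0  # 8-bit units of mixed-noise fluctuation per channel
    white_noise_std: float = 0.3  # 8-bit units, per ROI-mean sample
    noise_mixing: Optional[np.ndarray] = None  # (K, 3) ground-truth weights
    roll_std_rad: float = 0.05  # gimbal roll jitter (~3 degrees)
    motion_bandwidth_hz: float = 0.4  # wind-like process cutoff (< 50 bpm band)
    bbox_jitter_px: float = 1.5
    dropout_windows: tuple[tuple[int, int], ...] = ()  # inclusive frame intervals
    frame_rate: float = 15.0
    duration: float = 20.0  # seconds
    sensor_rate_factor: float = 2.0  # sensor log rate relative to frame rate
    frame_size: tuple[int, int] = (120, 160)  # H, W of rendered frames
    harmonic_pulse: bool = False  # add a half-amplitude 2nd harmonic
    seed: int = 0

    def __post_init__(self):
        if not (40.0 <= self.true_hr <= 200.0):
            raise ValueError("true_hr must lie in [40, 200] bpm")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ValueError("frame_rate and duration must be positive")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class GroundTruth:
    hr_series: np.ndarray  # bpm per frame
    pulse_trace: np.ndarray  # unit-amplitude waveform per frame
    visibility: np.ndarray  # bool per frame
    nuisance: dict = field(default_factory=dict)  # roi -> (T, 3) mixed noise
    white_noise: dict = field(default_factory=dict)  # roi -> (T, 3)
    mixing: dict = field(default_factory=dict)  # roi -> (K, 3) weights
    bbox_series: Optional[np.ndarray] = None  # (T, 4) x, y, w, h
    roll_series: Optional[np.ndarray] = None  # radians per frame


@dataclass(frozen=True)
class GimbalLog:
    t: np.ndarray  # (N,)
    h: np.ndarray  # (N, 3)
    v: np.ndarray  # (N, 3)

    def __iter__(self):
        for i in range(self.t.size):
            yield GimbalSample(float(self.t[i]), self.h[i], self.v[i])

    def __len__(self):
        return self.t.size


@dataclass(frozen=True)
class FlightLog:
    t: np.ndarray
    height: np.ndarray
    longitude: np.ndarray
    latitude: np.ndarray
    velocity: np.ndarray  # (N, 3)


@dataclass
class RecordingBundle:
    frames: list  # list[FrameRecord]
    gimbal: GimbalLog
    flight: FlightLog
    frame_times: np.ndarray = None
    ground_truth: Optional[GroundTruth] = None


def _band_limited(rng, n: int, rate: float, cutoff_hz: float, std: float) -> np.ndarray:
    """Zero-mean Gaussian process low-passed at ``cutoff_hz``, rescaled to ``std``."""
    white = rng.standard_normal(n)
    if std == 0.0:
        return np.zeros(n)
    if cutoff_hz < rate / 2.0 and n > 18:  # sosfiltfilt needs some padding room
        sos = butter(4, cutoff_hz, fs=rate, output="sos")
        x = sosfiltfilt(sos, white)
    else:
        x = white
    x = x - x.mean()
    s = x.std()
    return x / s * std if s > 0 else x


def _phase(config: SceneConfig, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous rate (bpm) and accumulated phase at given times."""
    hr = config.true_hr + config.hr_drift * times
    f_hz = hr / 60.0
    # phi(t) = 2*pi * integral of f: closed form for the linear drift model
    phi = 2.0 * math.pi * (config.true_hr * times + 0.5 * config.hr_drift * times**2) / 60.0
    return hr, phi


def _pulse_waveform(config: SceneConfig, phi: np.ndarray) -> np.ndarray:
    w = np.sin(phi)
    if config.harmonic_pulse:
        w = w + 0.5 * np.sin(2.0 * phi)
    return w


def simulate_flight_logs(config: SceneConfig) -> tuple[GimbalLog, FlightLog]:
    """Gimbal and flight-sensor logs at ``sensor_rate_factor`` x frame rate.

    All processes are smooth band-limited Gaussians; the gimbal vectors are
    unit vectors built from a roll process with standard deviation
    ``roll_std_rad`` plus a small yaw wander, so ``atan2(h_z, v_z)``
    recovers the roll exactly.
    """
    rng = np.random.default_rng(config.seed)
    rate = config.frame_rate * config.sensor_rate_factor
    n = int(round(config.duration * rate)) + 1
    t = np.arange(n) / rate
    bw = config.motion_bandwidth_hz

    roll = _band_limited(rng, n, rate, bw, config.roll_std_rad)
    yaw = _band_limited(rng, n, rate, bw, 0.3 * config.roll_std_rad)
    ct, st = np.cos(roll), np.sin(roll)
    cy, sy = np.cos(yaw), np.sin(yaw)
    # roll about the forward axis, then yaw about the vertical: z-components
    # stay sin(roll) / cos(roll), so the roll is recoverable via atan2
    h = np.column_stack([-ct * sy, ct * cy, st])
    v = np.column_stack([st * sy, -st * cy, ct])

    motion_scale = 1.0 if config.roll_std_rad > 0 else 0.0
    height = 8.0 + _band_limited(rng, n, rate, bw, 0.15 * motion_scale)
    longitude = 11.5700 + _band_limited(rng, n, rate, bw, 2e-6 * motion_scale)
    latitude = 48.1500 + _band_limited(rng, n, rate, bw, 2e-6 * motion_scale)
    velocity = np.column_stack(
        [_band_limited(rng, n, rate, bw, 0.2 * motion_scale) for _ in range(3)]
    )
    return (
        GimbalLog(t=t, h=h, v=v),
        FlightLog(t=t, height=height, longitude=longitude, latitude=latitude, velocity=velocity),
    )


def frame_times(config: SceneConfig) -> np.ndarray:
    return np.arange(config.n_frames) / config.frame_rate


def _visibility(config: SceneConfig) -> np.ndarray:
    vis = np.ones(config.n_frames, dtype=bool)
    for a, b in config.dropout_windows:
        vis[max(a, 0) : min(b, config.n_frames - 1) + 1] = False
    return vis


def _bbox_series(config: SceneConfig, rng) -> np.ndarray:
    """Face box trajectory (x, y, w, h per frame) inside the frame."""
    H, W = config.frame_size
    w = int(round(0.45 * W))
    h = int(round(0.75 * H))
    x0, y0 = (W - w) / 2.0, (H - h) / 2.0
    n = config.n_frames
    jx = _band_limited(rng, n, config.frame_rate, config.motion_bandwidth_hz, config.bbox_jitter_px)
    jy = _band_limited(rng, n, config.frame_rate, config.motion_bandwidth_hz, config.bbox_jitter_px)
    out = np.column_stack([x0 + jx, y0 + jy, np.full(n, w, float), np.full(n, h, float)])
    out[:, 0] = np.clip(out[:, 0], 0, W - w)
    out[:, 1] = np.clip(out[:, 1], 0, H - h)
    return out


def _polygon_area(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _matched_logs(
    config: SceneConfig, gimbal: GimbalLog, flight: FlightLog, times: np.ndarray
) -> tuple[_dn.FrameMatchedGimbal, _dn.FrameMatchedFlight]:
    m = match_sensor_to_frames(times, gimbal.t)
    fm_g = _dn.FrameMatchedGimbal(h=gimbal.h[m], v=gimbal.v[m])
    m2 = match_sensor_to_frames(times, flight.t)
    fm_f = _dn.FrameMatchedFlight(
        height=flight.height[m2],
        longitude=flight.longitude[m2],
        latitude=flight.latitude[m2],
        velocity=flight.velocity[m2],
    )
    return fm_g, fm_f


def simulate_roi_signals(
    config: SceneConfig,
) -> tuple[list[RawROISignals], GroundTruth]:
    """Per-ROI color traces composed exactly as the de-noising model assumes.

    Measurement ROIs carry ``base * (1 + amplitude * pulse)`` plus a linear
    mixture of their own nuisance design columns plus white noise; the four
    noise ROIs (nostrils, eyes) carry the nuisance terms but no pulse. The
    nuisance mixture uses mean-centered design columns so the physically
    huge DC of e.g. longitude does not shift the color level; the exact
    mixed traces and white-noise draws are returned as ground truth.
    """
    rng = np.random.default_rng(config.seed + 1)
    gimbal, flight = simulate_flight_logs(config)
    times = frame_times(config)
    fm_g, fm_f = _matched_logs(config, gimbal, flight, times)
    T = times.size
    hr, phi = _phase(config, times)
    pulse = _pulse_waveform(config, phi)
    base = np.asarray(config.skin_base_color, dtype=float)
    amps = config.pulse_strength * np.asarray(config.pulse_color, dtype=float)

    bboxes = _bbox_series(config, rng)
    template = default_layout_template()
    layouts = [layout_from_bbox(tuple(bboxes[i]), template) for i in range(T)]

    def tracking_series(label: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        lms, coms, counts = [], [], []
        for lay in layouts:
            poly = next(p for p in lay.all_rois if p.label == label)
            lms.append(poly.vertices.copy())
            coms.append(poly.vertices.mean(axis=0))
            counts.append(max(int(round(_polygon_area(poly.vertices))), 1))
        return np.asarray(lms), np.asarray(coms), np.asarray(counts, dtype=float)

    gt = GroundTruth(
        hr_series=hr,
        pulse_trace=pulse,
        visibility=_visibility(config),
        bbox_series=bboxes,
        roll_series=None,
    )

    # noise ROIs first: their means feed the measurement-ROI design matrices
    noise_sigs: list[RawROISignals] = []
    latent = np.column_stack(
        [
            _band_limited(rng, T, config.frame_rate, config.motion_bandwidth_hz, 1.0)
            for _ in range(3)
        ]
    )
    for lay0_label in ("nostril-center", "nostril-right", "eye-center", "eye-right"):
        lm, com, cnt = tracking_series(lay0_label)
        wn = rng.standard_normal((T, 3)) * config.white_noise_std
        weights = rng.standard_normal((3, 3))
        chan = base * 0.8 + latent @ weights * config.nuisance_std + wn
        noise_sigs.append(
            RawROISignals(
                label=lay0_label,
                role="noise",
                red=chan[:, 0],
                green=chan[:, 1],
                blue=chan[:, 2],
                pixel_count=cnt,
                landmarks=lm,
                center_of_mass=com,
            )
        )

    meas_sigs: list[RawROISignals] = []
    meas_labels = [item["label"] for item in template if item["role"] == "measurement"]
    for label in meas_labels:
        lm, com, cnt = tracking_series(label)
        carrier = RawROISignals(
            label=label,
            role="measurement",
            red=np.zeros(T),
            green=np.zeros(T),
            blue=np.zeros(T),
            pixel_count=cnt,
            landmarks=lm,
            center_of_mass=com,
        )
        nuisance = np.zeros((T, 3))
        mixing_cols = []
        for c, ch in enumerate("RGB"):
            X = _dn.assemble_noise_matrix(carrier, noise_sigs, fm_f, fm_g, channel=ch)
            Xc = X.values - X.values.mean(axis=0)
            if config.noise_mixing is not None:
                w = np.asarray(config.noise_mixing, dtype=float)[:, c]
            else:
                w = rng.standard_normal(X.K)
            contrib = Xc @ w
            s = contrib.std()
            if config.noise_mixing is None and s > 0 and config.nuisance_std > 0:
                w = w * (config.nuisance_std / s)
                contrib = Xc @ w
            elif config.nuisance_std == 0.0 and config.noise_mixing is None:
                w = np.zeros(X.K)
                contrib = np.zeros(T)
            nuisance[:, c] = contrib
            mixing_cols.append(w)
        wn = rng.standard_normal((T, 3)) * config.white_noise_std
        Y = base * (1.0 + np.outer(pulse, amps)) + nuisance + wn
        meas_sigs.append(
            replace(
                carrier,
                red=Y[:, 0],
                green=Y[:, 1],
                blue=Y[:, 2],
            )
        )
        gt.nuisance[label] = nuisance
        gt.white_noise[label] = wn
        gt.mixing[label] = np.column_stack(mixing_cols)

    return meas_sigs + noise_sigs, gt


def _render_frame(
    config: SceneConfig,
    bbox: np.ndarray,
    visible: bool,
    face_gain: np.ndarray,
    lighting_gain: float,
    rng,
) -> np.ndarray:
    """One upright scene frame: background plus a skin-colored face patch.

    ``face_gain`` is a per-channel multiplier on the skin color (carries the
    chromatic pulse and common-mode lighting modulation). The nostril/eye
    noise regions are painted with ``lighting_gain`` only — like real
    nostrils and eyes they share the illumination but carry no blood-volume
    modulation (were they pulse-modulated, the GLM stage would regress the
    pulse itself away). Sub-LSB modulation survives ROI averaging because of
    the per-pixel dither noise added before 8-bit quantization.
    """
    H, W = config.frame_size
    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = np.asarray(config.background_color)
    if visible:
        x, y, w, h = bbox
        x0, y0 = int(round(x)), int(round(y))
        x1, y1 = x0 + int(round(w)), y0 + int(round(h))
        skin = np.asarray(config.skin_base_color)
        img[y0:y1, x0:x1] = skin * face_gain
        for item in default_layout_template():
            if item["role"] != "noise":
                continue
            rel = np.asarray(item["vertices"], dtype=float)
            # paint 2 px beyond the polygon so its interior never samples
            # pulsed face pixels at the boundary
            nx0 = int(round(x + rel[:, 0].min() * w)) - 2
            nx1 = int(round(x + rel[:, 0].max() * w)) + 2
            ny0 = int(round(y + rel[:, 1].min() * h)) - 2
            ny1 = int(round(y + rel[:, 1].max() * h)) + 2
            img[ny0:ny1, nx0:nx1] = skin * 0.8 * lighting_gain
    img += rng.standard_normal(img.shape) * 1.0  # sensor dither
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def simulate_frames(config: SceneConfig, rotate: bool = True) -> RecordingBundle:
    """Render a full recording bundle with known ground truth.

    Frames hold a face patch whose color is pulse-modulated and whose
    brightness wobbles with the simulated flight height (a lighting-like
    nuisance the de-noising stage can remove); each frame is rotated by the
    gimbal roll matched to its timestamp, so derotation recovers an
    axis-aligned face.
    """
    from scipy import ndimage

    rng = np.random.default_rng(config.seed + 2)
    gimbal, flight = simulate_flight_logs(config)
    times = frame_times(config)
    T = times.size
    hr, phi = _phase(config, times)
    pulse = _pulse_waveform(config, phi)
    vis = _visibility(config)
    bboxes = _bbox_series(config, rng)
    m = match_sensor_to_frames(times, gimbal.t)
    roll = np.arctan2(gimbal.h[m, 2], gimbal.v[m, 2])
    m2 = match_sensor_to_frames(times, flight.t)
    height_c = flight.height[m2] - flight.height[m2].mean()
    amps = config.pulse_strength * np.asarray(config.pulse_color, dtype=float)
    frames = []
    for i in range(T):
        lighting = 1.0 + 0.02 * height_c[i]
        gain = lighting + amps * pulse[i]
        img = _render_frame(config, bboxes[i], bool(vis[i]), gain, lighting, rng)
        if rotate and roll[i] != 0.0:
            img = ndimage.rotate(
                img.astype(np.float64),
                np.degrees(roll[i]),
                axes=(1, 0),
                reshape=False,
                order=1,
                mode="constant",
                cval=0.0,
            )
            img = np.clip(np.round(img), 0, 255).astype(np.uint8)
        frames.append(FrameRecord(index=i, t=float(times[i]), image=img))
    gt = GroundTruth(
        hr_series=hr,
        pulse_trace=pulse,
        visibility=vis,
        bbox_series=bboxes,
        roll_series=roll,
    )
    return RecordingBundle(
        frames=frames, gimbal=gimbal, flight=flight, frame_times=times, ground_truth=gt
    )


def simulate_reference_pleth(config: SceneConfig, rate_hz: float = 100.0) -> np.ndarray:
    """Contact-pleth reference trace sampled at ``rate_hz`` (default 100 Hz).

    A periodic waveform (fundamental plus a 30% second harmonic, which gives
    peak detectors a crisp systolic maximum) whose instantaneous rate tracks
    the scene's heart-rate profile.
    """
    n = int(round(config.duration * rate_hz))
    t = np.arange(n) / rate_hz
    _, phi = _phase(config, t)
    return np.sin(phi) + 0.3 * np.sin(2.0 * phi)


class SyntheticCamera:
    """Linear clipped camera: pixel = clip(gain * exposure * radiance).

    Radiance is a fixed scene map (background plus a brighter face patch);
    exposure is in milliseconds. Deterministic for a fixed construction.
    """

    def __init__(
        self,
        gain: float = 1.0,
        frame_size: tuple[int, int] = (120, 160),
        face_bbox: Optional[tuple[int, int, int, int]] = None,
        face_radiance: float = 10.0,
        background_radiance: float = 3.0,
        min_exposure_ms: float = 0.05,
        max_exposure_ms: float = 200.0,
    ):
        H, W = frame_size
        if face_bbox is None:
            w, h = int(0.45 * W), int(0.75 * H)
            face_bbox = ((W - w) // 2, (H - h) // 2, w, h)
        self.face_bbox = face_bbox
        self.gain = gain
        self.min_exposure_ms = min_exposure_ms
        self.max_exposure_ms = max_exposure_ms
        self._radiance = np.full((H, W), background_radiance, dtype=float)
        x, y, w, h = face_bbox
        self._radiance[y : y + h, x : x + w] = face_radiance

    def capture(self, exposure_time_ms: float) -> np.ndarray:
        img = self.gain * exposure_time_ms * self._radiance
        return np.clip(np.round(img), 0, 255).astype(np.uint8)


class SyntheticFaceDetector:
    """Skin-color face finder for rendered synthetic frames.

    Flags pixels whose red clearly exceeds blue (the skin patch, not the
    gray background or zero padding) and returns their bounding box; returns
    None when too few pixels qualify. A fixed box can be injected for
    camera-loop tests.
    """

    def __init__(self, fixed_bbox: Optional[tuple[int, int, int, int]] = None, min_pixels: int = 50):
        self.fixed_bbox = fixed_bbox
        self.min_pixels = min_pixels

    def detect(self, image: np.ndarray) -> Optional[tuple[int, int, int, int]]:
        if self.fixed_bbox is not None:
            return self.fixed_bbox
        img = np.asarray(image)
        if img.ndim != 3:
            return None
        r = img[:, :, 0].astype(np.int32)
        b = img[:, :, 2].astype(np.int32)
        mask = (r > b + 25) & (r > 80)
        if mask.sum() < self.min_pixels:
            return None
        ys, xs = np.nonzero(mask)
        x0, x1 = int(xs.min()), int(xs.max())
        y0, y1 = int(ys.min()), int(ys.max())
        return (x0, y0, x1 - x0 + 1, y1 - y0 + 1)


class BBoxLayoutProvider:
    """Layout provider anchoring the ROI template to a per-frame face box."""

    def __init__(self, detections: Sequence, template: Optional[list[dict]] = None):
        self.detections = list(detections)
        self.template = template if template is not None else default_layout_template()

    def layout(self, frame_index: int, bbox=None):
        box = bbox if bbox is not None else self.detections[frame_index]
        if box is None:
            raise ValueError(f"no face box available for frame {frame_index}")
        return layout_from_bbox(tuple(box), self.template)
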