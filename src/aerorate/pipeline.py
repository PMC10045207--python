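"""End-to-end orchestration: recording bundle in, single HR value out.

The estimate pipeline runs stabilization, face detection and segmentation,
ROI signal extraction, GLM de-noising, CHROM/POS mixing and spectral HR
fusion, and records per-stage counts plus the mean face exposure needed for
the evaluation splits.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from . import denoise as _dn
from .config import PipelineConfig
from .contracts import FaceDetectorContract
from .exposure import face_percentile_value
from .flight_sync import match_sensor_to_frames, stabilize_sequence
from .hr import HRResult, estimate_hr
from .roi import (
    RawROISignals,
    detect_face_series,
    extract_roi_signals,
    segment_timeframes,
)
from .rppg import mix_channels
from .synthetic import BBoxLayoutProvider, RecordingBundle, SyntheticFaceDetector

__all__ = ["Provenance", "run_estimate", "estimate_from_roi_signals"]


@dataclass
class Provenance:
    config_hash: str
    seed: int
    n_frames: int = 0
    n_detected: int = 0
    n_segments: int = 0
    total_valid_samples: int = 0
    n_rois: int = 0
    n_pulse_signals: int = 0
    mean_face_exposure: float = float("nan")
    stage_status: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "n_frames": self.n_frames,
            "n_detected": self.n_detected,
            "n_segments": self.n_segments,
            "total_valid_samples": self.total_valid_samples,
            "n_rois": self.n_rois,
            "n_pulse_signals": self.n_pulse_signals,
            "mean_face_exposure": self.mean_face_exposure,
            "stage_status": dict(self.stage_status),
        }


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _denoise_and_mix(
    signals: Sequence[RawROISignals],
    flight: _dn.FrameMatchedFlight,
    gimbal: _dn.FrameMatchedGimbal,
    config: PipelineConfig,
    segment_id: str,
) -> list:
    noise_rois = [s for s in signals if s.role == "noise"]
    meas_rois = [s for s in signals if s.role == "measurement"]
    pulses = []
    for raw in meas_rois:
        den, _ = _dn.denoise_roi(raw, noise_rois, flight, gimbal)
        restored = {
            ch: den.channel(ch) + den.channel_means[i] for i, ch in enumerate("RGB")
        }
        for method in config.rppg.methods:
            pulses.append(
                mix_channels(
                    method,
                    restored["R"],
                    restored["G"],
                    restored["B"],
                    roi_label=raw.label,
                    segment_id=segment_id,
                )
            )
    return pulses


def estimate_from_roi_signals(
    signals: Sequence[RawROISignals],
    flight: _dn.FrameMatchedFlight,
    gimbal: _dn.FrameMatchedGimbal,
    frame_rate: float,
    config: Optional[PipelineConfig] = None,
    segment_id: str = "seg0",
) -> tuple[HRResult, list]:
    """De-noise, mix and estimate from pre-extracted ROI signals.

    ``signals`` must contain the measurement ROIs and the four noise ROIs;
    the flight and gimbal series must already be frame-matched to the same
    segment. Returns the HR result and the pulse signals it pooled.
    """
    config = config or PipelineConfig()
    pulses = _denoise_and_mix(signals, flight, gimbal, config, segment_id)
    return estimate_hr(pulses, frame_rate, config.hr), pulses


def run_estimate(
    bundle: RecordingBundle,
    config: Optional[PipelineConfig] = None,
    detector: Optional[FaceDetectorContract] = None,
    layout_template: Optional[list[dict]] = None,
) -> tuple[HRResult, Provenance]:
    """Full pipeline over a recording bundle.

    Failures surface as result statuses (``failed_no_segments``,
    ``failed_no_accepted_spectra``), never exceptions, so a batch run over
    many recordings can always tabulate its outcomes.
    """
    config = config or PipelineConfig()
    detector = detector or SyntheticFaceDetector()
    prov = Provenance(config_hash=_config_hash(config), seed=config.seed)
    prov.n_frames = len(bundle.frames)

    stabilized = stabilize_sequence(bundle)
    prov.stage_status["stabilize"] = "ok"

    frame_times = np.array([f.t for f in bundle.frames])
    frame_rate = 1.0 / float(np.median(np.diff(frame_times))) if len(frame_times) > 1 else 1.0

    detections = detect_face_series(stabilized, detector)
    prov.n_detected = sum(d is not None for d in detections)
    segments = segment_timeframes(detections, frame_rate, config.min_segment_seconds)
    prov.n_segments = len(segments)
    prov.total_valid_samples = sum(len(s) for s in segments)
    prov.stage_status["segment"] = "ok" if segments else "no_segments"

    exposures = [
        face_percentile_value(stabilized[i].image, detections[i])
        for i in range(len(detections))
        if detections[i] is not None
    ]
    prov.mean_face_exposure = float(np.mean(exposures)) if exposures else float("nan")

    if not segments:
        return (
            HRResult(None, None, None, {}, status="failed_no_segments"),
            prov,
        )

    provider = BBoxLayoutProvider(detections, layout_template)
    all_pulses = []
    for si, seg in enumerate(segments):
        signals = extract_roi_signals(stabilized, seg, provider, detections)
        prov.n_rois = max(prov.n_rois, len(signals))
        seg_times = frame_times[seg.start_index : seg.end_index + 1]
        mg = match_sensor_to_frames(seg_times, bundle.gimbal.t)
        mf = match_sensor_to_frames(seg_times, bundle.flight.t)
        fm_g = _dn.FrameMatchedGimbal(h=bundle.gimbal.h[mg], v=bundle.gimbal.v[mg])
        fm_f = _dn.FrameMatchedFlight(
            height=bundle.flight.height[mf],
            longitude=bundle.flight.longitude[mf],
            latitude=bundle.flight.latitude[mf],
            velocity=bundle.flight.velocity[mf],
        )
        all_pulses.extend(
            _denoise_and_mix(signals, fm_f, fm_g, config, segment_id=f"seg{si}")
        )
    prov.n_pulse_signals = len(all_pulses)
    result = estimate_hr(all_pulses, frame_rate, config.hr)
    prov.stage_status["estimate"] = result.status
    return result, prov
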