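"""Agreement metrics against a contact-pleth reference.

Single-value HR estimates are compared with the mean reference HR over the
valid portions of each recording via RMSE and Bland-Altman statistics
(bias and 1.96-sigma limits of agreement), and split into subsets by usable
recording length (a proxy for motion: fewer than 225 valid samples, i.e.
15 s at 15 fps, counts as high motion) and by mean face exposure (inside
the closed [190, 250] band vs. under-/over-exposed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

__all__ = [
    "ComparisonRecord",
    "EvaluationReport",
    "reference_hr",
    "rmse",
    "bland_altman",
    "subset_split",
    "evaluate_records",
]

MOTION_THRESHOLD_SAMPLES = 225
EXPOSURE_BOUNDS = (190.0, 250.0)


@dataclass(frozen=True)
class ComparisonRecord:
    recording_id: str
    hr_estimated: float  # bpm
    hr_reference: float  # bpm
    total_valid_samples: int = 0  # frames inside usable segments
    mean_face_exposure: float = float("nan")  # mean 98th-percentile face value


@dataclass
class EvaluationReport:
    rmse: float
    bias: float
    loa_low: float
    loa_high: float
    subset_rmses: dict = field(default_factory=dict)  # label -> (n, rmse)

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "subsets": {k: {"n": n, "rmse": r} for k, (n, r) in self.subset_rmses.items()},
        }


def reference_hr(
    pleth: np.ndarray,
    valid_spans: Sequence[tuple[float, float]],
    rate_hz: float = 100.0,
) -> float:
    """Mean instantaneous HR of a pleth trace over the valid time spans.

    Beats are local maxima with a 0.33 s refractory period (caps detection
    at ~180 bpm); instantaneous HR is 60 / inter-beat-interval assigned to
    beat midpoints and linearly interpolated, then averaged over the spans.
    """
    x = np.asarray(pleth, dtype=float)
    if x.size == 0:
        raise ValueError("empty pleth trace")
    peaks, _ = find_peaks(x, distance=max(int(round(0.33 * rate_hz)), 1))
    beat_times = peaks / rate_hz
    if beat_times.size < 2:
        raise ValueError("insufficient reference: fewer than 2 beats detected")
    ibis = np.diff(beat_times)
    inst_hr = 60.0 / ibis
    mid_times = 0.5 * (beat_times[:-1] + beat_times[1:])
    samples = []
    for t0, t1 in valid_spans:
        if t1 < t0:
            raise ValueError("invalid span (end before start)")
        n = max(int(round((t1 - t0) * rate_hz)), 2)
        tt = np.linspace(t0, t1, n)
        samples.append(np.interp(tt, mid_times, inst_hr))
    if not samples:
        raise ValueError("insufficient reference: no valid spans")
    return float(np.concatenate(samples).mean())


def _differences(records: Sequence[ComparisonRecord]) -> np.ndarray:
    return np.array([r.hr_estimated - r.hr_reference for r in records], dtype=float)


def rmse(records: Sequence[ComparisonRecord]) -> float:
    """Root-mean-squared error of estimate vs. reference, in bpm."""
    if len(records) == 0:
        raise ValueError("no records")
    d = _differences(records)
    return float(np.sqrt(np.mean(d**2)))


def bland_altman(records: Sequence[ComparisonRecord]) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement (bias +- 1.96 * population std)."""
    if len(records) < 2:
        raise ValueError("Bland-Altman needs at least 2 records")
    d = _differences(records)
    bias = float(d.mean())
    sd = float(d.std())  # population std of the differences
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def subset_split(
    records: Sequence[ComparisonRecord],
    motion_threshold_samples: int = MOTION_THRESHOLD_SAMPLES,
    exposure_bounds: tuple[float, float] = EXPOSURE_BOUNDS,
) -> dict[str, list[ComparisonRecord]]:
    """Partition records by motion proxy and exposure band.

    A recording with fewer than ``motion_threshold_samples`` valid frames is
    labelled high motion; mean face exposure inside the closed
    ``exposure_bounds`` interval is labelled inside. The four cells plus the
    two-way margins are returned.
    """
    lo, hi = exposure_bounds
    cells: dict[str, list[ComparisonRecord]] = {
        "high_motion": [],
        "low_motion": [],
        "exposure_inside": [],
        "exposure_outside": [],
        "high_motion/exposure_inside": [],
        "high_motion/exposure_outside": [],
        "low_motion/exposure_inside": [],
        "low_motion/exposure_outside": [],
    }
    for r in records:
        motion = "high_motion" if r.total_valid_samples < motion_threshold_samples else "low_motion"
        exposure = (
            "exposure_inside" if lo <= r.mean_face_exposure <= hi else "exposure_outside"
        )
        cells[motion].append(r)
        cells[exposure].append(r)
        cells[f"{motion}/{exposure}"].append(r)
    return cells


def evaluate_records(records: Sequence[ComparisonRecord]) -> EvaluationReport:
    """Pooled RMSE, Bland-Altman statistics and per-subset RMSEs."""
    pooled = rmse(records)
    bias, lo, hi = bland_altman(records)
    subsets = {
        label: (len(rs), rmse(rs)) if rs else (0, float("nan"))
        for label, rs in subset_split(records).items()
    }
    return EvaluationReport(rmse=pooled, bias=bias, loa_low=lo, loa_high=hi, subset_rmses=subsets)
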