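"""Recording-bundle file layout.

A bundle directory holds numbered 8-bit PNG frames with a ``frames.csv``
index (``index,timestamp_s,filename``), a gimbal log ``gimbal.csv``
(``timestamp_s,hx,hy,hz,vx,vy,vz``), a flight-sensor log ``flight.csv``
(``timestamp_s,height_m,longitude_deg,latitude_deg,vel_u,vel_v,vel_w``) and
optionally ``ground_truth.json`` with the simulator's per-frame truth.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .flight_sync import FrameRecord
from .synthetic import FlightLog, GimbalLog, GroundTruth, RecordingBundle

__all__ = ["write_bundle", "read_bundle"]


def write_bundle(bundle: RecordingBundle, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for f in bundle.frames:
        name = f"frame_{f.index:06d}.png"
        iio.imwrite(out / name, f.image)
        rows.append({"index": f.index, "timestamp_s": f.t, "filename": name})
    pd.DataFrame(rows).to_csv(out / "frames.csv", index=False)
    g = bundle.gimbal
    pd.DataFrame(
        {
            "timestamp_s": g.t,
            "hx": g.h[:, 0], "hy": g.h[:, 1], "hz": g.h[:, 2],
            "vx": g.v[:, 0], "vy": g.v[:, 1], "vz": g.v[:, 2],
        }
    ).to_csv(out / "gimbal.csv", index=False)
    fl = bundle.flight
    pd.DataFrame(
        {
            "timestamp_s": fl.t,
            "height_m": fl.height,
            "longitude_deg": fl.longitude,
            "latitude_deg": fl.latitude,
            "vel_u": fl.velocity[:, 0],
            "vel_v": fl.velocity[:, 1],
            "vel_w": fl.velocity[:, 2],
        }
    ).to_csv(out / "flight.csv", index=False)
    if bundle.ground_truth is not None:
        gt = bundle.ground_truth
        payload = {
            "hr_series": gt.hr_series.tolist(),
            "pulse_trace": gt.pulse_trace.tolist(),
            "visibility": gt.visibility.astype(int).tolist(),
        }
        if gt.bbox_series is not None:
            payload["bbox_series"] = np.asarray(gt.bbox_series).tolist()
        if gt.roll_series is not None:
            payload["roll_series"] = np.asarray(gt.roll_series).tolist()
        (out / "ground_truth.json").write_text(json.dumps(payload))
    return out


def _sorted_log(df: pd.DataFrame, name: str) -> pd.DataFrame:
    if not df["timestamp_s"].is_monotonic_increasing:
        warnings.warn(f"{name} log is not time-sorted; sorting", stacklevel=3)
        df = df.sort_values("timestamp_s", kind="stable").reset_index(drop=True)
    return df


def read_bundle(bundle_dir) -> RecordingBundle:
    src = Path(bundle_dir)
    frames_df = pd.read_csv(src / "frames.csv")
    frames = []
    for _, row in frames_df.iterrows():
        img = np.asarray(iio.imread(src / row["filename"]))
        frames.append(FrameRecord(index=int(row["index"]), t=float(row["timestamp_s"]), image=img))
    frames.sort(key=lambda f: f.index)
    times = np.array([f.t for f in frames])
    if times.size and np.any(np.diff(times) <= 0):
        raise ValueError("frame timestamps must be strictly increasing with index")

    g = _sorted_log(pd.read_csv(src / "gimbal.csv"), "gimbal")
    gimbal = GimbalLog(
        t=g["timestamp_s"].to_numpy(float),
        h=g[["hx", "hy", "hz"]].to_numpy(float),
        v=g[["vx", "vy", "vz"]].to_numpy(float),
    )
    fl = _sorted_log(pd.read_csv(src / "flight.csv"), "flight")
    flight = FlightLog(
        t=fl["timestamp_s"].to_numpy(float),
        height=fl["height_m"].to_numpy(float),
        longitude=fl["longitude_deg"].to_numpy(float),
        latitude=fl["latitude_deg"].to_numpy(float),
        velocity=fl[["vel_u", "vel_v", "vel_w"]].to_numpy(float),
    )
    gt = None
    gt_path = src / "ground_truth.json"
    if gt_path.exists():
        payload = json.loads(gt_path.read_text())
        gt = GroundTruth(
            hr_series=np.asarray(payload["hr_series"], float),
            pulse_trace=np.asarray(payload["pulse_trace"], float),
            visibility=np.asarray(payload["visibility"], bool),
            bbox_series=(
                np.asarray(payload["bbox_series"], float) if "bbox_series" in payload else None
            ),
            roll_series=(
                np.asarray(payload["roll_series"], float) if "roll_series" in payload else None
            ),
        )
    return RecordingBundle(
        frames=frames, gimbal=gimbal, flight=flight, frame_times=times, ground_truth=gt
    )
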