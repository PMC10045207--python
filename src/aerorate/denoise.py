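"""GLM de-noising of raw ROI color signals.

Each ROI color channel is modeled as a linear mixture of known nuisance
series plus the pulse and an unknown residual, ``Y = X M + P + E``. The
design matrix ``X`` collects 15 nuisance sources per ROI: the tracking
side-channels (vertex coordinates, center of mass, pixel count), the flight
sensors (height, longitude, latitude, 3-component velocity), the two gimbal
view vectors, the mean colors of the four pulse-free facial regions
(nostrils, eyes), and the first derivatives of the landmark, center-of-mass
and gimbal series. With 4-6 vertices per polygon the complete set yields
K = 4V + 27 = 43-51 columns.
``M`` is the least-squares solution, and the de-noised signal is the
residual ``Y - X M`` — the orthogonal projection of ``Y`` off the nuisance
column space.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .roi import RawROISignals

__all__ = [
    "NoiseMatrix",
    "MixingSolution",
    "DenoisedROISignals",
    "FrameMatchedFlight",
    "FrameMatchedGimbal",
    "first_derivative",
    "assemble_noise_matrix",
    "glm_denoise",
    "denoise_roi",
]

NOISE_SOURCE_NAMES = (
    "height",
    "longitude",
    "latitude",
    "velocity",
    "gimbal-h",
    "gimbal-v",
    "landmarks",
    "center-of-mass",
    "pixel-count",
    "nostrils",
    "eyes",
    "d/dt landmarks",
    "d/dt center-of-mass",
    "d/dt gimbal-h",
    "d/dt gimbal-v",
)


@dataclass(frozen=True)
class FrameMatchedFlight:
    """Flight-sensor series already matched to segment frames."""

    height: np.ndarray  # (T,)
    longitude: np.ndarray  # (T,)
    latitude: np.ndarray  # (T,)
    velocity: np.ndarray  # (T, 3) u, v, w


@dataclass(frozen=True)
class FrameMatchedGimbal:
    """Gimbal view vectors already matched to segment frames."""

    h: np.ndarray  # (T, 3)
    v: np.ndarray  # (T, 3)


@dataclass(frozen=True)
class NoiseMatrix:
    values: np.ndarray  # (T, K)
    column_labels: tuple[str, ...]
    degenerate_columns: tuple[str, ...] = ()

    def __post_init__(self):
        if self.values.shape[1] != len(self.column_labels):
            raise ValueError("label count must match column count")

    @property
    def K(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class MixingSolution:
    M: np.ndarray  # (K, C) per-channel noise weights
    residual_norms: np.ndarray  # (C,)
    column_labels: tuple[str, ...]


@dataclass(frozen=True)
class DenoisedROISignals:
    label: str
    red: np.ndarray
    green: np.ndarray
    blue: np.ndarray
    channel_means: np.ndarray  # raw DC removed by centering, (3,)

    def channel(self, name: str) -> np.ndarray:
        return {"R": self.red, "G": self.green, "B": self.blue}[name]


def first_derivative(series: np.ndarray) -> np.ndarray:
    """Same-length first derivative: central differences on the interior,
    one-sided differences at the two ends, unit step (frames)."""
    s = np.asarray(series, dtype=float)
    if s.shape[0] < 2:
        raise ValueError("need at least 2 samples to differentiate")
    return np.gradient(s, axis=0, edge_order=1)


def assemble_noise_matrix(
    raw: RawROISignals,
    noise_rois: Sequence[RawROISignals],
    flight: FrameMatchedFlight,
    gimbal: FrameMatchedGimbal,
    channel: str = "G",
) -> NoiseMatrix:
    """Build the T x K design matrix for one measurement ROI and one channel.

    Column order (fixed): vertex coordinates (2V), their derivatives (2V),
    center of mass (2), its derivative (2), pixel count (1), height (1),
    longitude (1), latitude (1), velocity u/v/w (3), the four noise-region
    means in the matching color channel (4), gimbal h (3), gimbal v (3),
    dh/dt (3), dv/dt (3); K = 4V + 27, i.e. 43 for quads up to 51 for
    hexagons. Constant columns are kept but flagged (the minimum-norm solver
    tolerates rank deficiency).
    """
    T = raw.red.size
    V = raw.n_vertices
    lm = raw.landmarks.reshape(T, 2 * V)  # v0x, v0y, v1x, v1y, ...
    cols, labels = [], []

    def add(block: np.ndarray, names: list[str]):
        block = np.atleast_2d(np.asarray(block, dtype=float))
        if block.shape[0] != T:
            block = block.T
        if block.shape[0] != T:
            raise ValueError(f"column block {names[0]}: length mismatch ({block.shape})")
        cols.append(block)
        labels.extend(names)

    add(lm, [f"landmark-v{i // 2}{'xy'[i % 2]}" for i in range(2 * V)])
    add(first_derivative(lm), [f"d/dt landmark-v{i // 2}{'xy'[i % 2]}" for i in range(2 * V)])
    add(raw.center_of_mass, ["com-x", "com-y"])
    add(first_derivative(raw.center_of_mass), ["d/dt com-x", "d/dt com-y"])
    add(raw.pixel_count.reshape(T, 1), ["pixel-count"])
    add(flight.height.reshape(T, 1), ["height"])
    add(flight.longitude.reshape(T, 1), ["longitude"])
    add(flight.latitude.reshape(T, 1), ["latitude"])
    add(flight.velocity, ["vel-u", "vel-v", "vel-w"])
    by_label: Mapping[str, RawROISignals] = {r.label: r for r in noise_rois}
    for name in ("nostril-center", "nostril-right", "eye-center", "eye-right"):
        if name not in by_label:
            raise ValueError(f"missing noise ROI {name!r}")
        add(by_label[name].channel(channel).reshape(T, 1), [f"{name}-{channel}"])
    add(gimbal.h, ["h-x", "h-y", "h-z"])
    add(gimbal.v, ["v-x", "v-y", "v-z"])
    add(first_derivative(gimbal.h), ["d/dt h-x", "d/dt h-y", "d/dt h-z"])
    add(first_derivative(gimbal.v), ["d/dt v-x", "d/dt v-y", "d/dt v-z"])

    X = np.hstack(cols)
    degenerate = tuple(
        lab for lab, col in zip(labels, X.T) if np.ptp(col) == 0.0
    )
    return NoiseMatrix(values=X, column_labels=tuple(labels), degenerate_columns=degenerate)


def glm_denoise(Y: np.ndarray, X: NoiseMatrix | np.ndarray):
    """Remove the least-squares nuisance contribution from each column of Y.

    Y (T, C) and the design columns are mean-centered before solving
    (equivalent to an intercept); the solution uses minimum-norm
    least-squares semantics so rank-deficient designs are tolerated. Returns
    the zero-mean residual ``Yc - Xc M`` and the mixing solution.

    Raises if the system is not over-determined (T <= K): lengthen the
    segment or drop noise sources.
    """
    labels = X.column_labels if isinstance(X, NoiseMatrix) else None
    Xv = X.values if isinstance(X, NoiseMatrix) else np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    T, K = Xv.shape
    if Y.shape[0] != T:
        raise ValueError("Y and X must have the same number of rows")
    if T <= K:
        raise ValueError(
            f"under-determined system (T={T} <= K={K}): lengthen the segment "
            "or reduce the number of noise sources"
        )
    Xc = Xv - Xv.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    M, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    resid = Yc - Xc @ M
    solution = MixingSolution(
        M=M,
        residual_norms=np.linalg.norm(resid, axis=0),
        column_labels=labels if labels is not None else tuple(f"x{i}" for i in range(K)),
    )
    return resid, solution


def denoise_roi(
    raw: RawROISignals,
    noise_rois: Sequence[RawROISignals],
    flight: FrameMatchedFlight,
    gimbal: FrameMatchedGimbal,
) -> tuple[DenoisedROISignals, dict[str, MixingSolution]]:
    """De-noise one measurement ROI's three channels.

    The design matrix is channel-matched: when de-noising channel c, the
    four noise-region columns carry that same channel's means (the remaining
    columns are shared across channels).
    """
    out = {}
    solutions = {}
    for ch in ("R", "G", "B"):
        X = assemble_noise_matrix(raw, noise_rois, flight, gimbal, channel=ch)
        resid, sol = glm_denoise(raw.channel(ch)[:, None], X)
        out[ch] = resid[:, 0]
        solutions[ch] = sol
    means = np.array([raw.red.mean(), raw.green.mean(), raw.blue.mean()])
    return (
        DenoisedROISignals(
            label=raw.label,
            red=out["R"],
            green=out["G"],
            blue=out["B"],
            channel_means=means,
        ),
        solutions,
    )


def mixing_solution_to_frame(solution: MixingSolution):
    """Mixing weights as a DataFrame (one row per design column)."""
    import pandas as pd

    M = np.atleast_2d(solution.M)
    cols = {f"m{c}": M[:, c] for c in range(M.shape[1])}
    return pd.DataFrame({"column": list(solution.column_labels), **cols})
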