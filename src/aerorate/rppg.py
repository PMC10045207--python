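"""CHROM and POS color mixing: turning R, G, B traces into pulse signals.

Both methods first divide each channel by its temporal mean (removing the
stationary skin tone and illumination level), then project the normalized
channels onto two fixed chrominance axes and combine the projections with a
data-driven ratio of standard deviations:

CHROM: ``Xs = 3 Rn - 2 Gn``, ``Ys = 1.5 Rn + Gn - 1.5 Bn``,
       ``S = Xs - (std Xs / std Ys) * Ys``.
POS:   ``S1 = Gn - Bn``, ``S2 = Gn + Bn - 2 Rn``,
       ``S = S1 + (std S1 / std S2) * S2``.

POS's axes are orthogonal to the common-mode intensity direction (1, 1, 1),
so pure brightness changes cancel exactly. Mixing is applied once per
time-frame segment; the spectral-analysis stage then slices the mixed
signal into windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PulseSignal", "chrom_signal", "pos_signal", "mix_channels"]

# relative std below this (vs. signal mean magnitude) counts as degenerate
_DEGENERATE_STD = 1e-12


@dataclass(frozen=True)
class PulseSignal:
    method: str  # "CHROM" | "POS"
    values: np.ndarray  # zero-mean pulse trace, length = segment length
    roi_label: str = ""
    segment_id: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("pulse signal must be finite")
        object.__setattr__(self, "values", v)


def _normalized_channels(R, G, B) -> np.ndarray:
    chans = [np.asarray(c, dtype=float) for c in (R, G, B)]
    n = chans[0].size
    if any(c.size != n for c in chans) or n < 2:
        raise ValueError("channels must share a length of at least 2")
    out = []
    for name, c in zip("RGB", chans):
        mu = c.mean()
        if abs(mu) < 1e-12:
            raise ValueError(
                f"channel {name} has (near-)zero mean; restore the DC level "
                "before mean-normalization"
            )
        out.append(c / mu)
    return np.vstack(out)  # (3, T)


def _ratio(num: np.ndarray, den: np.ndarray, scale: float) -> float:
    sd_num, sd_den = float(np.std(num)), float(np.std(den))
    if sd_den <= _DEGENERATE_STD * max(scale, 1.0):
        if sd_num <= _DEGENERATE_STD * max(scale, 1.0):
            return 0.0  # both branches flat: output will be ~0 anyway
        raise ValueError("degenerate chrominance projection (zero variance)")
    return sd_num / sd_den


def chrom_signal(R, G, B, roi_label: str = "", segment_id: str = "") -> PulseSignal:
    """Chrominance-based pulse extraction (alpha-tuned two-axis projection)."""
    C = _normalized_channels(R, G, B)
    Xs = 3.0 * C[0] - 2.0 * C[1]
    Ys = 1.5 * C[0] + C[1] - 1.5 * C[2]
    alpha = _ratio(Xs, Ys, scale=float(np.abs(C).mean()))
    S = Xs - alpha * Ys
    return PulseSignal("CHROM", S - S.mean(), roi_label, segment_id)


def pos_signal(R, G, B, roi_label: str = "", segment_id: str = "") -> PulseSignal:
    """Plane-orthogonal-to-skin pulse extraction.

    Both projection axes are orthogonal to (1, 1, 1), so a pure common-mode
    intensity modulation yields an identically zero output.
    """
    C = _normalized_channels(R, G, B)
    S1 = C[1] - C[2]
    S2 = C[1] + C[2] - 2.0 * C[0]
    ratio = _ratio(S1, S2, scale=float(np.abs(C).mean()))
    S = S1 + ratio * S2
    return PulseSignal("POS", S - S.mean(), roi_label, segment_id)


_METHODS = {"CHROM": chrom_signal, "POS": pos_signal}


def mix_channels(method: str, R, G, B, roi_label: str = "", segment_id: str = "") -> PulseSignal:
    """Dispatch to a mixing method by name ("CHROM" or "POS")."""
    try:
        fn = _METHODS[method.upper()]
    except KeyError:
        raise ValueError(f"unknown mixing method {method!r}") from None
    return fn(R, G, B, roi_label=roi_label, segment_id=segment_id)
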