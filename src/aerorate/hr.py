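"""Single-value heart-rate estimation from pooled windowed spectra.

Every pulse signal is sliced into overlapping 45-sample windows with a
stride of 2. Each window's power spectrum (zero-padded to a <= 1 bpm grid)
must pass two gates to count toward the estimate: a prominence-detected
peak in the 50-180 bpm target band with a band-power SNR of at least 2.5%,
and no spectral maximum in the 0-50 bpm low band exceeding the target-band
maximum (which rejects harmonics of strong drift). Accepted spectra are
pooled per mixing method — all ROIs, segments and windows together — into a
per-frequency median spectrum; each method's HR is the median spectrum's
argmax over the target band, and the final HR is the mean of the CHROM and
POS values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .rppg import PulseSignal

__all__ = [
    "HRConfig",
    "SpectrumWindow",
    "HRResult",
    "window_signal",
    "compute_spectrum",
    "peak_snr",
    "accept_spectrum",
    "median_spectrum",
    "estimate_hr",
]


@dataclass(frozen=True)
class HRConfig:
    """Spectral-analysis parameters (defaults are the method's constants)."""

    window_samples: int = 45
    stride_samples: int = 2
    snr_min: float = 0.025  # 2.5%
    alpha_bpm: float = 3.0  # half-width of the peak band in the SNR ratio
    band_bpm: tuple[float, float] = (50.0, 180.0)
    grid_bpm: float = 1.0  # maximum spectral grid spacing after zero-padding


@dataclass(frozen=True)
class SpectrumWindow:
    freqs_bpm: np.ndarray
    power: np.ndarray
    method: str = ""
    roi_label: str = ""
    segment_id: str = ""
    start_index: int = 0


@dataclass(frozen=True)
class HRResult:
    hr_pos: Optional[float]
    hr_chrom: Optional[float]
    hr_final: Optional[float]
    accepted_window_counts: dict = field(default_factory=dict)
    status: str = "ok"  # ok | failed_no_segments | failed_no_accepted_spectra

    def to_dict(self) -> dict:
        return {
            "hr_final": self.hr_final,
            "hr_pos": self.hr_pos,
            "hr_chrom": self.hr_chrom,
            "accepted_counts": dict(self.accepted_window_counts),
            "status": self.status,
        }


def window_signal(
    pulse: PulseSignal | np.ndarray, window: int = 45, stride: int = 2
) -> list[np.ndarray]:
    """Overlapping sub-signals: floor((L - window) / stride) + 1 of them."""
    values = pulse.values if isinstance(pulse, PulseSignal) else np.asarray(pulse, float)
    L = values.size
    if L < window:
        return []
    starts = range(0, L - window + 1, stride)
    return [values[s : s + window] for s in starts]


def compute_spectrum(
    sub_signal: np.ndarray, frame_rate: float, grid_bpm: float = 1.0, **tags
) -> SpectrumWindow:
    """Power spectrum of a window on a bpm grid no coarser than ``grid_bpm``.

    The window is mean-removed and zero-padded so the DFT bin spacing
    ``frame_rate / n_fft`` is at most ``grid_bpm / 60`` Hz; power is the
    squared transform magnitude over the nonnegative-frequency bins.
    Zero-padding interpolates the spectrum to bpm resolution without adding
    information.
    """
    x = np.asarray(sub_signal, dtype=float)
    if x.size < 2:
        raise ValueError("window must contain at least 2 samples")
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    x = x - x.mean()
    n_min = int(math.ceil(60.0 * frame_rate / grid_bpm))
    n_fft = max(x.size, n_min)
    spec = np.fft.rfft(x, n=n_fft)
    power = np.abs(spec) ** 2
    freqs_bpm = np.fft.rfftfreq(n_fft, d=1.0 / frame_rate) * 60.0
    return SpectrumWindow(freqs_bpm=freqs_bpm, power=power, **tags)


def peak_snr(spectrum: SpectrumWindow, peak_bpm: float, alpha: float = 3.0) -> float:
    """Band-power SNR of a spectral peak.

    Ratio of the power within ``peak_bpm +- alpha`` to all power outside
    that band. Returns +inf when the band holds all the energy.
    """
    f, p = spectrum.freqs_bpm, spectrum.power
    in_band = (f >= peak_bpm - alpha) & (f <= peak_bpm + alpha)
    band = float(p[in_band].sum())
    rest = float(p.sum()) - band
    if rest <= 0.0:
        return math.inf
    return band / rest


def _band_mask(f: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (f >= lo) & (f <= hi)


def accept_spectrum(spectrum: SpectrumWindow, config: HRConfig = HRConfig()) -> bool:
    """The two gates a window spectrum must pass to enter the pooled median.

    (a) some prominence-detected local maximum inside the target band has a
    band-power SNR of at least ``snr_min``; (b) the maximum power over the
    0-50 bpm low band (DC excluded) does not exceed the maximum over the
    target band.
    """
    f, p = spectrum.freqs_bpm, spectrum.power
    lo, hi = config.band_bpm
    target = _band_mask(f, lo, hi)
    low = (f > 0.0) & (f < lo)
    if not target.any():
        return False
    # (b) low-frequency rejection
    low_max = p[low].max() if low.any() else 0.0
    if low_max > p[target].max():
        return False
    # (a) SNR gate on prominence-detected peaks within the target band
    peak_idx, _ = find_peaks(p)
    peak_idx = peak_idx[target[peak_idx]]
    for i in peak_idx:
        if peak_snr(spectrum, float(f[i]), config.alpha_bpm) >= config.snr_min:
            return True
    return False


def median_spectrum(accepted: Sequence[SpectrumWindow]) -> SpectrumWindow:
    """Per-frequency median over accepted windows (even count: mid mean)."""
    if len(accepted) == 0:
        raise ValueError("no accepted spectra to combine")
    f0 = accepted[0].freqs_bpm
    for s in accepted[1:]:
        if s.freqs_bpm.shape != f0.shape or not np.allclose(s.freqs_bpm, f0):
            raise ValueError("accepted spectra must share one frequency grid")
    stack = np.vstack([s.power for s in accepted])
    return SpectrumWindow(
        freqs_bpm=f0, power=np.median(stack, axis=0), method=accepted[0].method
    )


def _argmax_band(spectrum: SpectrumWindow, band: tuple[float, float]) -> float:
    mask = _band_mask(spectrum.freqs_bpm, *band)
    f, p = spectrum.freqs_bpm[mask], spectrum.power[mask]
    return float(f[np.argmax(p)])  # argmax takes the first (lowest) frequency on ties


def estimate_hr(
    pulse_signals: Sequence[PulseSignal],
    frame_rate: float,
    config: HRConfig = HRConfig(),
) -> HRResult:
    """Pool windowed spectra per method and fuse the two HR readings.

    Returns a failure status instead of raising: ``failed_no_segments`` when
    there are no pulse signals at all, ``failed_no_accepted_spectra`` when
    every window fails the gates.
    """
    signals = list(pulse_signals)
    if not signals:
        return HRResult(None, None, None, {}, status="failed_no_segments")
    accepted: dict[str, list[SpectrumWindow]] = {}
    counts: dict[str, int] = {}
    for sig in signals:
        method = sig.method
        counts.setdefault(method, 0)
        for w_i, sub in enumerate(
            window_signal(sig, config.window_samples, config.stride_samples)
        ):
            spec = compute_spectrum(
                sub,
                frame_rate,
                grid_bpm=config.grid_bpm,
                method=method,
                roi_label=sig.roi_label,
                segment_id=sig.segment_id,
                start_index=w_i * config.stride_samples,
            )
            if accept_spectrum(spec, config):
                accepted.setdefault(method, []).append(spec)
                counts[method] += 1
    hr_by_method: dict[str, float] = {}
    for method, specs in accepted.items():
        hr_by_method[method] = _argmax_band(median_spectrum(specs), config.band_bpm)
    hr_pos = hr_by_method.get("POS")
    hr_chrom = hr_by_method.get("CHROM")
    present = [h for h in (hr_pos, hr_chrom) if h is not None]
    if not present:
        return HRResult(None, None, None, counts, status="failed_no_accepted_spectra")
    hr_final = float(np.mean(present))
    return HRResult(hr_pos, hr_chrom, hr_final, counts, status="ok")
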