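"""GLM de-noising of one facial ROI and CHROM/POS pulse extraction.

Generates signal-level ROI traces (pulse + a linear mixture of flight,
gimbal and tracking nuisance columns + white noise), removes the nuisance
by least squares, and shows how much of the pulse the residual retains.
"""

import numpy as np

from aerorate.denoise import denoise_roi
from aerorate.rppg import chrom_signal, pos_signal
from aerorate.synthetic import (
    SceneConfig,
    _matched_logs,
    frame_times,
    simulate_flight_logs,
    simulate_roi_signals,
)

scene = SceneConfig(true_hr=70.0, seed=11)
signals, truth = simulate_roi_signals(scene)
gimbal, flight = simulate_flight_logs(scene)
fm_gimbal, fm_flight = _matched_logs(scene, gimbal, flight, frame_times(scene))

noise_rois = [s for s in signals if s.role == "noise"]
roi = next(s for s in signals if s.role == "measurement")

corr_raw = np.corrcoef(roi.green, truth.pulse_trace)[0, 1]
denoised, mixing = denoise_roi(roi, noise_rois, fm_flight, fm_gimbal)
corr_clean = np.corrcoef(denoised.green, truth.pulse_trace)[0, 1]

print(f"ROI {roi.label}: design matrix K = {mixing['G'].M.shape[0]} columns")
print(f"pulse correlation of raw G channel      : {corr_raw:+.3f}")
print(f"pulse correlation after GLM de-noising  : {corr_clean:+.3f}")

restored = {
    ch: denoised.channel(ch) + denoised.channel_means[i]
    for i, ch in enumerate("RGB")
}
for sig in (chrom_signal(restored["R"], restored["G"], restored["B"]),
            pos_signal(restored["R"], restored["G"], restored["B"])):
    spec = np.abs(np.fft.rfft(sig.values, 4096)) ** 2
    f_bpm = np.fft.rfftfreq(4096, 1 / scene.frame_rate) * 60
    peak = f_bpm[np.argmax(spec)]
    print(f"{sig.method:5s} pulse signal dominant frequency : {peak:.1f} bpm")
# De-noising lifts the pulse correlation from near the noise floor to ~0.9
# on a single ROI; both color-mixing methods then peak at the true 70 bpm.
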