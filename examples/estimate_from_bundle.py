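"""End-to-end heart-rate estimation from a rendered recording bundle.

Simulates a 10 s drone hover in front of a person (frames + gimbal and
flight-sensor logs), then runs the full pipeline: derotation, face
detection and segmentation, ROI extraction, GLM de-noising, CHROM/POS
mixing and spectral fusion.
"""

from aerorate.pipeline import run_estimate
from aerorate.synthetic import SceneConfig, simulate_frames

scene = SceneConfig(true_hr=72.0, duration=10.0, pulse_strength=0.05, seed=5)
bundle = simulate_frames(scene)
result, provenance = run_estimate(bundle)

print(f"true HR            : {scene.true_hr:.1f} bpm")
print(f"estimated HR       : {result.hr_final:.1f} bpm (final = mean of POS and CHROM)")
print(f"  POS / CHROM      : {result.hr_pos:.1f} / {result.hr_chrom:.1f} bpm")
print(f"segments used      : {provenance.n_segments} "
      f"({provenance.total_valid_samples} valid frames)")
print(f"accepted windows   : {result.accepted_window_counts}")
print(f"mean face exposure : {provenance.mean_face_exposure:.0f} (8-bit 98th percentile)")
# The estimate lands within the ~1 bpm spectral grid of the true rate; the
# accepted-window counts show how many 45-sample spectra passed the SNR and
# low-frequency gates per mixing method.
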