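"""Face-aware automatic exposure adjustment against a linear clipped camera.

The controller drives the 98th percentile of the face-region pixels into
the (190, 230) band — as bright as possible without clipping the pulse
signal — using the multiplicative update l <- 420 / (2 v) * l.
"""

from aerorate.exposure import adjust_exposure
from aerorate.synthetic import SyntheticCamera, SyntheticFaceDetector

for gain, l0 in [(1.0, 10.0), (0.2, 2.0), (5.0, 20.0)]:
    camera = SyntheticCamera(gain=gain, face_radiance=10.0, max_exposure_ms=500.0)
    detector = SyntheticFaceDetector(fixed_bbox=camera.face_bbox)
    res = adjust_exposure(camera, detector, initial_exposure=l0)
    print(
        f"gain {gain:4.1f}, start {l0:5.1f} ms -> exposure {res.exposure_time:7.2f} ms, "
        f"face value {res.final_face_value:3d}, "
        f"{res.iterations_used} iteration(s), converged={res.converged}"
    )
# For an unclipped linear sensor a single step lands the face value at the
# band center 210; saturated or very dim starts take a few more iterations.
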