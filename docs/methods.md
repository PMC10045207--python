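# Methods

## Model

A skin pixel's color is modulated by blood volume at the cardiac frequency
with a relative amplitude of order 10⁻². From a hovering drone, the
measured per-ROI mean color `y` of a facial region over one tracked
time-frame is modeled as

```
y_c = X m_c + p_c + e_c            (per color channel c ∈ {R, G, B})
```

— a linear mixture of known nuisance series `X`, the pulse `p`, and an
unmodeled residual `e`. Everything upstream exists to make this model
workable (stable geometry, adequate exposure, aligned sensor series);
everything downstream assumes the residual `y − X m̂` is pulse-dominated.

## Stages, parameters and defaults

**Sensor matching.** Gimbal and flight logs are sampled asynchronously from
the camera; each frame uses the sensor sample minimizing the absolute time
difference. Ties break to the earliest index achieving the minimum (this
also covers duplicate timestamps and float-equidistant neighbors), which
makes matching deterministic. No temporal interpolation is applied.

**Derotation.** The two-axis gimbal leaves a roll `atan2(h_z, v_z)` of the
optical plane; `atan2` is scale-invariant so the view vectors are not
normalized first. Frames are centered in a zero-padded square of side
max(H, W) and rotated by the negated roll about the canvas center
((S−1)/2, (S−1)/2) with bilinear interpolation; quarter turns are exact
index permutations, and round trips through arbitrary angles stay below
~2 gray levels mean absolute error on smooth interiors (the tolerance the
round-trip tests use).

**Exposure control.** Target: the face-box 98th percentile (nearest-rank
convention on the sorted pixels — deterministic for 8-bit data) strictly
inside (190, 230). Update: `l ← 420/(2v) · l`, which lands a linear
unclipped sensor at the band center 210 in one step; at most 10 iterations.
Exposures are clamped to the camera's bounds and flagged rather than
failing; a fully dark capture (v = 0), where the multiplicative rule is
undefined, jumps to the maximum exposure. When the sensor saturates the
shrink factor is bounded by 210/255 per step, so starts more than
(255/210)¹⁰ ≈ 6.9× above the feasible exposure cannot converge within the
loop bound — a genuine property of the bounded loop, asserted as such.
Color captures are grayed by the R/G/B mean. Mid-loop detection failures
reuse the last box and flag it; failure on the first capture is an error.

**Segmentation and ROI geometry.** Runs of consecutive detections of at
least ceil(5 s × fps) frames are kept; none ⇒ the recording's assessment
fails (a status, not an exception). The 30 measurement polygons are a
configurable template anchored to the face box (default: 3×6 forehead grid
plus two 2×3 cheek grids, all quads) with 4 noise polygons at the nostril
and eye positions; any template with 30 regions of 4–6 vertices is valid
input, since the published region set is not specified at mesh-index
level. A pixel belongs to a polygon iff its center lies inside (even-odd
rule); a region that degenerates to zero pixels in any frame is dropped for
the whole segment. Center of mass = vertex average; pixel count, vertex
coordinates and COM are recorded as de-noising inputs.

**Design matrix.** Fixed column order: vertex coords (2V), their
derivatives (2V), COM (2), its derivative (2), pixel count (1), height (1),
longitude (1), latitude (1), velocity u/v/w (3), four noise-region means in
the matching channel (4), h (3), v (3), dh/dt (3), dv/dt (3). K = 4V + 27,
i.e. 43 (quads) to 51 (hexagons); the complete 15-source enumeration is
used even though its total is one above the commonly quoted 42–50 range,
which no consistent component count reproduces. Derivatives are central
differences with one-sided ends, unit step in frames. The four noise-region
columns are channel-matched: de-noising channel c uses those regions' c
series (lighting physics is per-channel; the other columns are shared).
Flight series are frame-matched by the same nearest-timestamp rule as the
gimbal.

**Least squares.** Y and all columns are mean-centered before solving
(equivalent to an intercept, and it keeps physically huge DCs — longitude
≈ 11.57° — from absorbing weights); the solver is `lstsq` with min-norm
semantics, so constant or collinear columns are tolerated and merely
flagged. T ≤ K raises with advice to lengthen the segment. The residual is
exactly the orthogonal projection of Y off the centered column space:
idempotent, variance non-increasing, and verified entrywise against an
independent SVD projector (the test oracle avoids forming XᵀX, whose
squared conditioning breaks down at the design's 10⁻⁶…10¹ column scales).
Known failure mode, reproduced in tests: a nuisance column correlated with
the pulse removes the pulse.

**Color mixing.** CHROM rows (3, −2, 0)/(1.5, 1, −1.5), POS rows
(0, 1, −1)/(−2, 1, 1) on mean-normalized channels, combined by the
standard-deviation ratio; both applied once per segment (the windowing
stage slices afterward). Mean-normalization needs a physical DC, so the
channel means removed by centering are restored before mixing. Stds below
10⁻¹² × scale count as degenerate. POS is exactly invariant to common-mode
intensity; both methods are invariant to per-channel gain.

**Spectral estimation.** Windows of 45 samples, stride 2 (the 45-sample
figure is the operative constant; at 15 fps it spans 3 s). Each window is
mean-removed and zero-padded so the DFT grid is ≤ 1 bpm (1024 points at
15 fps) — interpolation of the spectrum, no new information, but needed for
bpm-level output from 20 bpm raw bins. Gates: (a) some strictly-local
maximum (any positive prominence) in [50, 180] bpm has band-power SNR ≥
0.025, where SNR = power within ±3 bpm of the peak over power outside it
(∃-reading: requiring *every* peak to pass would reject nearly all real
spectra); (b) the maximum over (0, 50) bpm — DC excluded — does not exceed
the maximum over [50, 180], which rejects harmonics of strong drift.
Accepted spectra pool across all ROIs, segments and windows per method;
per-frequency median (even count: mid mean); HR per method = argmax over
[50, 180] with ties to the lower frequency; final HR = mean of the two
methods when both yield one. Failures are statuses
(`failed_no_segments`, `failed_no_accepted_spectra`), never exceptions.

**Evaluation.** Reference HR = mean instantaneous rate from pleth peaks
(0.33 s refractory ≈ 180 bpm cap, inter-beat intervals interpolated) over
the valid spans. Bland–Altman limits = bias ± 1.96 × population SD of the
differences. Subsets: < 225 valid samples ⇒ high motion (shorter usable
footage indicates more motion); mean face exposure inside the closed
[190, 250] ⇒ inside-exposure. Pooled MSE equals the n-weighted mean of
subset MSEs on any partition (tested as an exact identity).

## What the simulator emulates — and what it does not

`synthetic` generates gimbal/flight logs as band-limited Gaussian processes
(default cutoff 0.4 Hz ≈ 24 bpm, i.e. below the 50 bpm band edge so drift
stresses the low-frequency gate), gimbal unit vectors from a roll process
(default SD 0.05 rad) with yaw wander, sensor logs at 2× frame rate to
exercise nearest matching, a face-box trajectory with jitter and dropout
windows, and per-ROI signals composed *exactly* as the GLM assumes:
base color × (1 + pulse amplitude × sinusoid) + centered-design × mixing +
white noise. Defaults describe a calm 20 s hover at 15 fps: pulse strength
1 % on G with chromatic direction (0.5, 1.0, 0.7) — G-dominant, as in skin
reflectance — nuisance fluctuation 2.0 8-bit units per channel (several
times the ~1.2-unit pulse, so de-noising is load-bearing) and white noise
0.3 units per ROI-mean sample (≈ a few LSB of per-pixel sensor noise
averaged over ~10² pixels). The nuisance mixture uses mean-centered design
columns so longitude-scale DCs don't shift colors; the exact mixed traces
and noise draws are returned as ground truth, making the decomposition
testable to machine precision.

Rendered frames are a flat skin-colored rectangle on gray background with
per-pixel dither (which lets sub-LSB modulation survive ROI averaging and
8-bit quantization); the nostril/eye areas are painted with the lighting
term but no pulse, with a 2 px margin beyond their polygons so boundary
pixels never leak pulse into the noise columns — real nostrils/eyes are
pulse-free, and leaking them would make the GLM regress the pulse away.
Not emulated: real facial geometry and specularity, perspective change,
rolling shutter, video-codec artifacts, true skin optics. Passing tests
therefore demonstrate the pipeline's correctness and its noise-rejection
mechanics under the stated noise model, not field accuracy on human
recordings.

## Problem sizes

The test suite and the acceptance script run signal-level scenes of 300
frames (20 s × 15 fps) with all 34 ROIs, frame-level scenes of 150 frames
at 160×120, a 6-rate × 5-seed recovery grid, and a 10-recording cohort —
sizes at which every stage, including the ~7700-window spectral pool of a
full run, completes in seconds while still exercising the method's
operating constants unchanged.

## Known limitations

- The GLM absorbs a few percent of pulse energy by chance correlation with
  ~43 finite-window columns (measurably more when columns contain wideband
  noise); the usual remedy — longer segments — applies.
- The exposure loop cannot recover from extreme over-exposure within its
  10-iteration bound (see above); a real deployment would re-enter the loop.
- Reference-pleth beat detection assumes a clean synthetic waveform; it is
  not a general PPG beat detector.
- The face detector and landmark provider shipped here are synthetic-scene
  tools behind the pluggable contracts; real deployments must supply their
  own (e.g. a Haar cascade and a face-mesh network).
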