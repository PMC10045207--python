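# aerorate

Contact-free heart-rate assessment from a camera drone, for triage-style
vital-sign screening where attaching a sensor is impossible or too slow.
`aerorate` implements the full remote-photoplethysmography (rPPG) pipeline
such a platform needs: the cardiac pulse modulates skin color by a fraction
of a percent, and a hovering drone adds gimbal roll, wind-driven motion,
tracking jitter and lighting changes on top of it.

## Method

Given timestamped RGB frames, a gimbal log (left-facing and down-facing
view vectors *h⃗*, *v⃗*) and a flight-sensor log:

1. **Stabilization** — each frame is paired with the gimbal sample nearest
   in time; the residual roll of the optical plane, *y = atan2(h_z, v_z)*,
   is removed by rotating the frame by *−y* (bilinear interpolation) inside
   a zero-padded square canvas.
2. **Exposure control** (live capture only) — the 98th percentile *v* of
   the face-box pixels is driven into (190, 230) on the 8-bit scale by the
   update *l ← (190+230)/(2v)·l*, at most 10 iterations.
3. **ROI tracking** — a face box per frame; runs of consecutive detections
   ≥ 5 s become usable segments; 30 forehead/cheek polygons plus 4 pulse-free
   noise polygons (nostrils, eyes) are anchored to the box and reduced to
   mean R, G, B series with tracking side-channels.
4. **GLM de-noising** — per ROI and channel, *Y = X·M + P + E*: the design
   matrix *X* holds 15 nuisance sources (landmarks, center of mass, pixel
   count, height, longitude, latitude, velocity, gimbal vectors, the four
   noise-region colors, and first derivatives of the landmark/COM/gimbal
   series; K = 4V+27 = 43–51 columns for V = 4–6 vertices). *M* is the
   least-squares solution and the de-noised signal is the residual *Y − X·M*.
5. **Color mixing** — CHROM (*S = Xs − α·Ys* with *Xs = 3Rn − 2Gn*,
   *Ys = 1.5Rn + Gn − 1.5Bn*, *α = σ(Xs)/σ(Ys)*) and POS
   (*S = S1 + (σ(S1)/σ(S2))·S2* with *S1 = Gn − Bn*, *S2 = Gn + Bn − 2Rn*)
   on mean-normalized channels.
6. **HR estimation** — 45-sample windows with stride 2; each window's
   zero-padded power spectrum must contain a peak in 50–180 bpm with
   band-power SNR ≥ 2.5 % (±3 bpm band) and no dominant 0–50 bpm component;
   accepted spectra are pooled per method into a per-frequency median; the
   final HR is the mean of the CHROM and POS spectral peaks.

A synthetic flight-scene simulator generates all inputs with exact ground
truth (pulse trace, nuisance mixture, visibility, roll), and an evaluation
module computes RMSE, Bland–Altman limits of agreement and motion/exposure
subset splits against a simulated 100 Hz reference pleth.

## Worked example

```bash
python examples/estimate_from_bundle.py
```

```
true HR            : 72.0 bpm
estimated HR       : 71.9 bpm (final = mean of POS and CHROM)
  POS / CHROM      : 71.9 / 71.9 bpm
segments used      : 1 (150 valid frames)
accepted windows   : {'CHROM': 1590, 'POS': 1590}
mean face exposure : 130 (8-bit 98th percentile)
```

A 10 s hover at 72 bpm is rendered to frames, stabilized, tracked and
estimated blind; the answer lands within the ~1 bpm spectral grid. The
window counts say how many 45-sample spectra (pooled over 30 ROIs) passed
both acceptance gates per method. Other examples cover the GLM step
(`denoise_and_mix.py`), the exposure loop (`exposure_loop.py`) and cohort
evaluation (`evaluate_cohort.py`).

The same pipeline is scriptable from the shell:

```bash
aerorate simulate --seed 5 --out bundle/      # write a synthetic bundle
aerorate estimate bundle/ --out result.json   # single-value HR + provenance
aerorate evaluate --pred preds.json --ref refs.csv --out report.json
```

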