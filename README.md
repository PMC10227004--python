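# voltmap

Analysis pipeline for **cardiac optical mapping**: panoramic voltage-dye
movies of paced, perfused hearts are turned into activation maps, APD80
maps, single-vector conduction velocities, APD restitution curves, and
nonparametric group statistics. A synthetic excitable-tissue movie
generator with exact ground truth makes every stage of the chain
verifiable by parameter recovery.

It is written for cardiac electrophysiologists and methods developers
who record voltage-sensitive-dye movies (e.g. RH237 on a
Langendorff-perfused heart under blebbistatin) with a high-speed camera
— the emulated geometry is a 128 × 128 detector over a 30 × 30 mm field,
2 ms frames, 2 s recordings — and pace at fixed cycle lengths
(CL = 400/300/250/200/150 ms).

## What it measures

For each pixel trace *V(t)* within a beat window:

- **Activation time** `t_act` — the steepest phase-0 upstroke,
  `argmax dV/dt`, refined below the 2 ms frame interval by parabolic
  interpolation of the discrete-derivative peak.
- **APD80** — from `t_act` to the first time the signal recovers to
  20 % of its beat amplitude (pre-stimulus baseline to peak), linearly
  interpolated; the per-CL value is the mean of three consecutive
  paced beats.
- **Diastolic interval** — `DI = CL − APD80`.
- **Conduction velocity (CV)** — the two-point (single-vector) method:
  Euclidean distance between two probe points on the apparent
  longitudinal propagation axis divided by their activation-time
  difference, in cm/s. Probe placement is automatic (mean
  activation-gradient direction) or manual.
- **APD restitution slope** — APD80 vs DI across CLs; the maximum
  segmentwise chord slope ΔAPD/ΔDI (an exponential fit
  `APD = A − B·e^(−DI/τ)` is also available). Slopes approaching 1 are
  the classical alternans/arrhythmia-susceptibility criterion.
- **Group statistics** — per-CL mean ± SD tables compared by
  Kruskal–Wallis (exact/permutation null at small n), Dunn's rank-based
  post hoc (unadjusted and Holm-adjusted), and a general-linear-model
  trend test across CLs; Teichholz M-mode ejection fraction
  `V(D) = 7.0/(2.4 + D)·D³` for the echocardiography arm.

The synthetic side provides two generators: closed-form plane-wave
movies (exact CV and APD80 at every pixel) and a two-variable
Aliev–Panfilov-class reaction–diffusion simulation with `control` and
`hf` (tachycardia-cardiomyopathy-like) phenotype presets — the `hf`
preset conducts more slowly and repolarizes later, reproducing the
qualitative ordering seen in such models.

## Worked example

Simulate a failing-heart preparation paced at four cycle lengths, then
analyze the movie from disk:

```sh
$ voltmap simulate --phenotype hf --cls 400,300,250,200 --beats 4 \
      --snr 20 --grid 64 --seed 7 --out demo
wrote demo/hf_seed7.tif

$ voltmap analyze --movie demo/hf_seed7.tif --out demo_out
CL    400 ms   CV   35.34 cm/s   APD80  106.51 ms
CL    300 ms   CV   34.93 cm/s   APD80   97.47 ms
CL    250 ms   CV   34.62 cm/s   APD80   90.62 ms
CL    200 ms   CV   33.79 cm/s   APD80   81.45 ms
max restitution slope: 0.225
```

Each row is one pacing cycle length: the conduction velocity from the
automatically placed single vector and the ROI-mean APD80 averaged over
three consecutive beats. APD80 shortens as pacing accelerates (normal
restitution) and the maximum chord slope of the restitution curve is
well below 1. `demo_out/` holds the activation/APD80 maps as CSV grids,
isochrone-map PNGs, a tidy `measurements.csv`, and a run log.

The same chain is available as a library:

```python
import voltmap as vm

movie, truth = vm.plane_wave_movie(cv=60.0, apd80=75.0)
noisy = vm.add_acquisition_noise(movie, snr=10.0, seed=1)
result = vm.analyze_movie(noisy)
result.cv_by_cl[400.0]    # ~60 cm/s
result.apd_by_cl[400.0]   # ~75 ms
```

Real recordings enter through `vm.read_movie("movie.tif")` — a
multi-page TIFF stack plus a JSON sidecar with `frame_interval_ms`,
`pixel_pitch_mm`, `polarity`, `stimulus_times_ms` and
`cycle_lengths_ms`.

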