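# Methods

## Scope and data model

The package implements the measurement chain of panoramic cardiac
optical mapping — per-pixel activation and repolarization timing from
voltage-dye fluorescence movies — together with a synthetic movie
generator that provides ground truth for every stage. The common
currency is the `VoltageMovie`: a (time × row × col) float stack with
pixel pitch (mm), frame interval (ms), dye polarity, and the pacing
metadata (stimulus times and their cycle lengths). Coordinates are
0-based (row, col); ROI rectangles are half-open; all times are ms from
the first frame.

The emulated acquisition is a 128 × 128 detector over 30 × 30 mm
(pitch 30/128 = 0.234375 mm/px), 2 ms frames, at least 1000 frames
(2 s) per recording, constant pacing at cycle lengths
400/300/250/200/150 ms with 3 ms pulses delivered as a line stimulus at
the left edge. Four stimuli are delivered per cycle length; the first
beat after a rate change is discarded as a transient and the next three
consecutive beats are measured and averaged.

## Event definitions

**Activation** is the steepest phase-0 upstroke: the maximum of the
central-difference first derivative within the beat window, searched
from the stimulus onward, refined below the frame interval by parabolic
interpolation of the three derivative samples around the discrete peak.
The refinement is clipped to ±1 frame; with a 1–2 ms upstroke sampled
at 2 ms the residual quantization is a periodic ±0.3 ms ripple along
the propagation direction.

**APD80** measures from activation to the first post-peak crossing of
`baseline + 0.2 × (peak − baseline)`, linearly interpolated between
samples. Baseline is the mean of the strictly pre-stimulus samples of
the *same* beat window (each window carries a 10 ms pre-stimulus
margin), which makes the level reference robust to slow drift; peak is
the in-window maximum after activation. A trace that never recovers to
the 20 % level inside its window (beat fusion) is missing, not an
error. First crossing (not last) is used: 80 % repolarization is an
event time.

**Pixel validity.** A pixel contributes only if its beat amplitude
reaches 30 % of its full recording range and its peak derivative
exceeds 5× the pre-stimulus derivative noise; pixels whose overall
amplitude/noise ratio is below 3 are masked before mapping. These
thresholds reject non-captured and dead pixels, where derivative-based
detection is unreliable.

**Single-vector CV** is the Euclidean distance between two probe points
times the pixel pitch, divided by |Δ activation time|, in cm/s.
Activation differences under 0.5 ms (a quarter frame after
interpolation) are refused — quantization would dominate. Each
endpoint's activation time is read as the mean over a 9-pixel segment
through the point along the probe axis: the segment average is
unbiased for a locally linear wavefront and cancels the sub-frame
quantization ripple, which otherwise contributes up to ~7 % error at
fast conduction; pass `endpoint_halfwidth=0` to read bare pixels. The
"apparent longitudinal axis" is operationalized in `auto_probe` as the
mean unit direction of the smoothed activation-time gradient over the
ROI, with the probe spanning ≥ 60 % of the ROI through its center;
fields whose gradient directions have circular variance > 0.5 (e.g. a
centered point source) are refused in favor of a manual probe.

**APD analysis window.** APD80 is computed at CLs ≥ 200 ms by default;
at 150 ms repolarization routinely overlaps the next upstroke and the
measurement is unreliable, so that CL is reported for CV only (the
threshold is a `RunConfig` field, and `build_maps(apd_min_cl=0)`
overrides it).

## Preprocessing

Polarity is corrected from metadata (fluorescence-down dye signals are
inverted so depolarization is positive), then each pixel is linearly
rescaled to [0, 1] by its robust 1st/99th-percentile extrema — an
affine map, hence idempotent; percentiles rather than min/max so noise
spikes cannot set the scale. Flat pixels (amplitude < 2 % of the median
pixel amplitude) are flagged and left untouched; an entirely flat movie
is an error.

Smoothing is a spatial Gaussian (σ = 1 px) followed by a temporal
Savitzky–Golay filter (window 5 frames, order 2). It is applied only
when the median pixel SNR is below 20, and the decision is logged —
clean data are not silently smoothed. The (0, 1) setting is the
identity, bit for bit.

## Synthetic tissue

### Plane-wave generator (analytic oracle)

Pixels at distance *x* from the stimulated edge activate at
`t_stim + x/v`. The stereotyped action potential is C1-smooth: a
half-cosine upstroke of 1.5 ms width whose steepest slope defines
t = 0, handing over to a raised-cosine repolarization that reaches zero
with zero slope at a finite support end (consecutive beats can never
overlap). The raised cosine passes its 20 % level at the fixed fraction
`acos(−0.6)/π ≈ 0.7048` of its span, so the support is solved in closed
form to put the 80 % crossing exactly `apd80` ms after the upstroke —
ground truth is exact by construction. Waveform smoothness matters:
a hard rise/plateau corner is unphysiological and makes quadratic
smoothing filters overshoot the peak, biasing downstream amplitude
estimates.

### Reaction–diffusion simulator

A two-variable phenomenological excitable medium (Aliev–Panfilov
class):

    ∂u/∂t = D ∇²u + [k u (u − a)(1 − u) − u w] / t_s
    ∂w/∂t = r (ε₀ + μ₁ w / (u + μ₂)) [−w − k u (u − a − 1)] / t_s

with a = 0.15, μ₁ = 0.2, μ₂ = 0.3, ε₀ = 0.002, time scale
t_s = 2.6 ms per model unit, isotropic diffusion with no-flux (mirror)
boundaries, and explicit Euler stepping. The `repol_rate` multiplier
`r` scales the whole recovery-gate rate: scaling ε₀ alone barely moves
APD because the μ₁ term dominates during the plateau. This model class
reproduces what the pipeline measures — finite conduction velocity,
rate-dependent APD (restitution), capture — without ionic detail,
which is deliberately out of scope.

The nominal internal step is 0.05 ms (the upstroke must be resolved
well below the frame interval), reduced automatically to
`0.9·h²/(4D)` when explicit-Euler diffusion stability requires it; the
substep count divides the 2 ms frame interval exactly so output frames
land on the acquisition clock. Non-finite state aborts with a
diagnostic. A seeded, spatially smoothed ±2 % multiplicative
excitability heterogeneity makes preparations individually distinct
while keeping runs bit-reproducible given (params, protocol, seed).

Ground-truth activation/APD80 fields are measured from the noise-free
resampled frames with the same event definitions the analysis chain
uses; a stimulus whose wave fails to reach the far quarter of the sheet
is flagged non-captured.

**Phenotype presets** (stored in the `PHENOTYPES` config dict, not
hard-coded in the integrator) were tuned once so the measured values
land in the physiological rabbit range and then frozen:

| preset  | D (mm²/ms) | repol_rate | CV @ CL 400 | APD80 @ CL 400 |
|---------|-----------:|-----------:|------------:|---------------:|
| control | 0.40       | 0.70       | ~103 cm/s   | ~75 ms         |
| hf      | 0.16 (×0.4)| 0.42 (×0.6)| ~49 cm/s    | ~111 ms        |

The failing-heart preset is the control with diffusivity ×0.4 and
repolarization rate ×0.6 — slower conduction, longer APD, steeper
restitution, the signature of tachycardia-induced cardiomyopathy.
Measured CV depends on grid resolution (the depolarization front is a
few pixels wide), so coarser grids read lower absolute CV: the control
preset measures ~103 cm/s at 128², ~96 at 96², ~66 at 64². Phenotype
*ordering* is preserved at every resolution; cohort-level runs use 64²
to keep a ten-subject, five-CL study inside a few minutes of CPU.

**Acquisition noise** adds per-pixel white noise of standard deviation
(robust amplitude)/SNR, a slow sinusoidal baseline drift (default 2 %
of amplitude, period 1–3 s, random phase per pixel), and flips the
signal to the fluorescence-down dye convention so the analysis side
must handle polarity. SNR 20 is the cohort default (a good dye
loading); SNR 10 is used in the recovery acceptance grid. Capture is
treated as guaranteed: the stimulus current is far above threshold,
and pacing amplitude is not modelled.

**Cohorts** jitter diffusivity (±5 %, 1σ) and repolarization rate
(±3 %) per subject around the preset, emulating animal-to-animal
variability. Study-design sample sizes (two cohorts of five here;
5/5/4/4 in the statistical calibration) mirror small-animal practice.

What the generator does *not* emulate: anisotropic fiber architecture,
3-D geometry and breakthrough patterns, motion artifact (the real
protocol uncouples contraction pharmacologically), photobleaching
trends beyond slow drift, and ionic-current pharmacology. Passing
recovery tests therefore demonstrates correctness of the measurement
chain under idealized planar propagation with realistic sampling and
noise — not robustness to fiber curvature or motion.

## Statistics

Group tables report per-CL mean ± SD (n−1 denominator) and n per
group. The omnibus comparison is Kruskal–Wallis with tie correction.
Its p-value uses the exact permutation null (full enumeration) for
total n ≤ 8, a seeded Monte-Carlo permutation null (100 000 draws,
cached per group-size tuple) for tie-free samples up to n = 30, and
the chi-square approximation above that. The exact/permutation routes
exist because the chi-square approximation is materially off at
small-animal cohort sizes: up to 0.1 absolute error in p at n = 8, and
a true type-I error of ~0.035 at nominal 0.05 for groups of 5/5/4/4;
the permutation p restores ~0.049. `method="chi2"` forces the
classical behaviour.

Dunn's post hoc compares pairs on pooled ranks,
`z = (R̄ᵢ − R̄ⱼ)/√((N(N+1)/12 − T)(1/nᵢ + 1/nⱼ))` with tie term
`T = Σ(t³−t)/(12(N−1))`, two-sided normal p-values. It is gated on
omnibus p < 0.05 (overridable), and both unadjusted and Holm-adjusted
matrices are reported, clearly labelled — small-animal studies often
report unadjusted Dunn p-values, and the choice should be visible
rather than silent. Implemented in-package (with a closed-form
two-group identity z² = H used as an independent test oracle).

The trend test regresses the measurement on the cycle-length rank
(equally spaced ordinal scores, longest CL first) by OLS with subjects
as replicates, reporting the two-sided p of the slope and its sign.
Subject-level (not mean-level) observations are used. A perfect
zero-residual trend reports p = 0.

Teichholz: `V(D) = 7.0/(2.4 + D)·D³` (D in cm, V in mL),
`LVEF = 100·(V_ED − V_ES)/V_ED`; EF is strictly decreasing in LVESD at
fixed LVEDD and 0 when the diameters coincide.

The restitution slope default is segmentwise (maximum chord slope over
adjacent DI-sorted points) for transparency; the three-parameter
exponential fit is exposed as an alternative and falls back to
segmentwise with a warning when it fails to converge.

## Numerical choices and degenerate inputs

- Level crossings: linear interpolation; derivative peaks: parabolic
  refinement — appropriate when the 2 ms sampling is coarse relative
  to the few-ms effects of interest.
- Beat windows are `[t_stim − 10 ms, t_stim + CL − 10 ms)`; windows of
  one train tile exactly. A CL with fewer than two delivered stimuli is
  flagged unanalyzable rather than fatal.
- A movie's per-stimulus CLs can be derived from inter-stimulus
  intervals when the sidecar lacks them (last stimulus inherits the
  preceding interval).
- TIFF I/O quantizes to 16 bits with offset/scale recorded in the
  sidecar, so round-trips are exact to one quantum.
- All randomness (simulation heterogeneity, subject jitter, noise,
  permutation nulls) flows from explicit seeds; identical inputs give
  bit-identical outputs.

## Problem sizes used in the shipped verification

The test-suite and acceptance-script workloads were sized as a desk
study: plane-wave recovery over the 6 × 4 (CV × APD80) grid at the
native 128² geometry; diffusivity-scaling runs at 128²; two simulated
cohorts of five subjects at 64² over the full five-CL protocol; 2000
Monte-Carlo replicates for the type-I-error calibration. These choices
keep a full from-scratch reproduction within minutes on one CPU while
exercising every code path at the native acquisition geometry at least
once.

## Known limitations

- Absolute simulated CV is grid-dependent (front width of a few
  pixels); cross-resolution comparisons of absolute CV are not
  meaningful, within-resolution contrasts are.
- The single-vector CV is the method of record here by design; it
  ignores wavefront curvature and anisotropy, and no multi-vector or
  surface-fitting estimator is provided.
- APD at CL 150 ms is excluded by default (beat fusion), mirroring the
  practical limit of 80 %-repolarization measurements at fast pacing.
- The trend test assumes independent observations across CLs within a
  subject (no repeated-measures correlation structure), matching the
  simple general-linear-model convention it implements.
- Four-view panoramic reconstruction is not attempted; each movie is
  analyzed independently.
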