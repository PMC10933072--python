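# Methods

## Scientific problem

Walking speed changes both how load is distributed across the sole of the
foot and how regular the gait rhythm is. Given an 8-sensor plantar-pressure
insole sampled at 100 Hz, the analysis implemented here answers two
questions:

1. **Loading** — how does the peak pressure in the hindfoot, midfoot and
   forefoot regions (normalized by body weight) change with treadmill speed?
2. **Stability** — how complex is the stride-interval rhythm, quantified by
   multi-scale sample entropy (MSE), at each speed? A more stable gait has a
   more self-similar stride sequence and lower entropy, particularly at
   small time scales.

The pipeline is: fuse the 8 channels into three regional signals and a
whole-foot total → detect hindfoot pressure peaks, one per stride → form the
stride-interval time series → compute the MSE profile and its band
summaries → compare conditions. A Bland–Altman module quantifies agreement
between the insole total and a paired force-plate-style measurement.

## Sample entropy and multi-scale entropy

For a series `x(1..N)`, embedding dimension `m` and tolerance `r`,
sample entropy is

    SampEn(m, r) = -ln(A / B)

where `B` counts ordered template pairs `(i, j), i != j` whose length-`m`
subsequences have Chebyshev distance strictly below `r`, and `A` the same at
length `m + 1`. Both template sets contain `N - m` vectors (the standard
Richman–Moorman construction), so every `(m+1)`-match is also an `m`-match,
`A <= B`, and a defined SampEn is never negative. If either count is zero
the entropy is undefined and reported as NaN, never ±inf; aggregation then
treats it as a missing cell (with a warning) rather than poisoning means.

Multi-scale entropy coarse-grains the series at scale `s` — element `j` of
the coarse series is the mean of the `j`-th non-overlapping window of `s`
samples, trailing remainder dropped — and computes SampEn per scale.
Defaults: `m = 2`, `r = 0.25 × SD`, scales 1–6, with two band summaries:
MSE_S (mean of scales 1–3, short-time irregularity) and MSE_L (mean of
scales 4–6, structure that survives averaging).

Numerical conventions worth stating:

* matching uses strict `d < r`;
* `SD` is the sample SD (ddof = 1) of the **original** series, held fixed
  across scales (`r_convention="fixed_from_original_SD"`); recomputing the
  SD per scale is selectable but changes the profile's interpretation;
* a constant series under the SD-fraction convention gives `r = 0`, which is
  rejected with a message recommending an absolute tolerance (with an
  explicit `r`, a constant series has entropy exactly 0);
* the vectorized implementation is checked to 1e-12 against a deliberately
  naive O(N²) pure-Python template-counting oracle in the test suite.

## Gait events

Stride intervals are the times between adjacent peaks of the fused hindfoot
trace (one heel-loading peak per stride): `interval[i] =
(peak[i+1] - peak[i]) / fs`. The peak detector (scipy `find_peaks`) uses a
minimum separation of half the nominal stride — so the two stance sub-peaks
of a whole-foot trace cannot be double-counted — and a prominence floor of
0.2 × the trace range, which makes detection invariant under positive
amplitude scaling. "Mean processing" of the hindfoot channels is the
regional mean performed by fusion; an optional moving-average smoother
exists but is off by default, and its use is recorded in run manifests.

Stance morphology on the whole-foot total is summarized by five landmarks:
contact start/end (crossings of 5% of the episode peak) and, inside them,
the loading peak, mid-stance valley and push-off peak (the two most
prominent maxima and the minimum between them). Fewer than two prominent
interior peaks is a morphology error, e.g. for an all-zero swing segment.

The amplitude–pressure ratio of a region is the mean over contact episodes
of the per-episode peak pressure, divided by body weight; in the
generator's units (see below) it is dimensionless and of order 1.

## Agreement analysis

Limits of agreement are the classic Bland–Altman construction
`mean(d) ± 1.96 × SD(d)` for paired differences `d = x - y` — a predictive
interval for differences, not a confidence interval of the mean difference.
Reported alongside: the fraction of differences inside the limits (≈0.95
for Gaussian differences at large n) and the Pearson correlation of the
raw pairs with its two-sided p-value (NaN-flagged for constant inputs).
Traces are compared after peak-amplitude normalization onto a common
101-point (percent-of-stance) grid; a peaks-only mode compares just the
three stance landmarks.

## Synthetic data generator

No public insole recordings accompany this analysis, so the generator
produces recordings with the statistical structure the pipeline assumes.
What it emulates, and how:

* **Stride structure.** Each stride is a stance phase (0.6 of the stride, a
  standard gait value) followed by zero-pressure swing. Cycle boundaries
  are realized on the sample grid from cumulative continuous durations, so
  rounding errors do not accumulate.
* **Waveforms.** Each sensor contributes one raised-cosine (compact
  support) bump per stance. Hindfoot bumps are narrow (half-width 0.12 of
  stance, centered at 15%) — a sharp loading transient; midfoot (center
  45%, half-width 0.45, lower amplitude) and forefoot (center 75%,
  half-width 0.32) are wide and overlapping, so the summed trace is
  genuinely bimodal: loading peak, mid-stance valley, push-off peak.
  Bump timing is anchored to the *nominal* stride's stance — peaks occur at
  a fixed time after heel strike rather than stretching with each cycle's
  jitter — and centers are snapped to the sample grid. Both choices make
  the discrete hindfoot peak location exact, which is what lets the
  event detector recover programmed stride durations to within one sample
  period, the generator's ground-truth contract.
* **Amplitudes.** Pressure units are "kg-equivalents": a regional
  multiplier of 1.0 places the regional mean peak near the subject's body
  weight. Per-sensor factors (e.g. MTH1 > MTH5) keep the 8 channels
  distinguishable. The default sensor layout (2 heel, 2 arch, 4 forefoot
  sensors) is an explicit assumption, configurable via a YAML layout file.
* **Stride-time variability.** Stride durations are `mean + jitter`, where
  jitter is white Gaussian or an AR(1) process with coefficient φ and
  stationary SD `jitter_sd_s` (truncated at −0.5 × mean so durations stay
  positive). Autocorrelated jitter is the physiological case: real stride
  series are strongly persistent, which is why their SampEn is far below
  white-noise levels.
* **Sensor noise.** Additive Gaussian noise per channel, clipped at zero
  pressure.

### Speed presets

The three study conditions (treadmill speeds):

| preset | stride (s) | jitter SD (s) | AR(1) φ | hind / mid / fore amplitude |
|-------:|-----------:|--------------:|--------:|-----------------------------|
| 2 km/h | 1.40 | 0.010 | 0.99 | 0.95 / 0.45 / 0.90 |
| 4 km/h | 1.10 | 0.026 | 0.92 | 1.05 / 0.45 / 1.02 |
| 6 km/h | 0.90 | 0.032 | 0.30 | 1.15 / 0.45 / 1.1403 |

Faster walking means shorter strides, larger and less persistent
stride-time fluctuation (a less regular rhythm), and heavier hindfoot /
forefoot loading. The forefoot multipliers are calibrated so the 6 km/h
amplitude–pressure ratio exceeds the 2 km/h one by 26.7%
(0.90 × 1.267 = 1.1403). Sensor noise defaults to SD 0.4 pressure units
(~0.6% of a 70 kg subject's regional peak). All fields are overridable.

The φ / jitter-SD values were fixed by design-phase simulation of the whole
stride-interval → MSE pathway. The controlling subtlety is quantization: at
100 Hz, extracted intervals live on a 10 ms grid, and SampEn behavior
changes sharply when `r = 0.25 × SD` crosses a coarse-grain step (10 ms at
scale 1, 5 ms at scale 2). The preset SDs are placed so the realized `r`
stays on a fixed side of those steps, making the entropy ordering
SampEn(2) < SampEn(4) < SampEn(6) and MSE_S(2) < MSE_S(4) < MSE_S(6) a
stable generator property (~98% of independent 200-cycle triples) rather
than a knife-edge.

### What the generator does not emulate

No musculoskeletal forward simulation; no absolute Newton calibration; no
left/right asymmetry; no fatigue drift or nonstationarity; no missing
contacts or sensor dropout. Passing tests therefore demonstrate that the
pipeline correctly recovers the structure this model encodes — regional
loading ratios, programmed stride statistics, entropy ordering by
irregularity — not that real insole data from any particular device would
reproduce a specific entropy table.

## Paired plate surrogate

The force-plate surrogate for agreement testing applies to an insole total
trace: an additive bias, Gaussian measurement noise, and a rescaled
push-off peak (linear blend from the mid-stance valley so the trace stays
continuous; the loading peak is untouched). The push-off rescaling reflects
that insoles under-read late-stance load where few sensors sit under the
rolling forefoot.

## Problem sizes and run parameters

Default analyses use 200 gait cycles per condition (≈199 stride intervals,
comparable to a 3-minute treadmill recording) and scales 1–6. The
acceptance script (`scripts/acceptance.py`) uses 40 replicate triples for
condition summaries, 50 noiseless cycles for the loading calibration, 20
seeds for agreement statistics, and 25 random series for the oracle
cross-check. At ~199 intervals, entropy at scales 4–6 rests on 33–49
coarse-grained points; occasional undefined (zero-match) cells there are
expected and are excluded from summaries with a warning and an
`n_undefined_cells` count.

## Known limitations

* Interval quantization at 10 ms means entropy values are those of a
  discretized series; they are internally consistent but not comparable to
  entropies of continuous-time interval measurements.
* MSE_L at 200 cycles is noisy (short coarse-grained series); treat it as
  qualitative.
* The stance fraction is fixed at 0.6 of the stride rather than decreasing
  with speed, which real gait shows; only stride *timing* statistics carry
  the speed effect on rhythm here.
* Whether a whole-foot "total" should be the sum or the mean of the three
  regional signals is a convention; the default is the sum (mimics
  whole-foot load), with mean selectable.
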