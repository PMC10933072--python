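# gaitmse

Walking-speed effects on gait stability, from 8-channel plantar-pressure
insole recordings: regional pressure fusion, stride-interval extraction,
multi-scale sample entropy, and Bland–Altman method agreement — plus a
seeded synthetic-data generator so the whole pipeline is testable without
access to laboratory recordings.

Intended for researchers in gait biomechanics and biomedical signal
processing who want a tested, reproducible implementation of the
stride-interval complexity analysis, or a controllable synthetic testbed
for insole processing pipelines.

## The analysis

1. **Fusion.** The 8 sensor channels are averaged within three anatomical
   regions (hindfoot, midfoot, forefoot); the whole-foot total is the sum
   of the regional signals and shows the classic double-peaked vertical
   load shape during stance (loading peak, mid-stance valley, push-off
   peak).
2. **Events.** Stride intervals are the times between adjacent hindfoot
   pressure peaks. Per-region loading is the amplitude–pressure ratio:
   mean per-contact peak pressure divided by body weight.
3. **Complexity.** The stride-interval series x(1..N) is coarse-grained at
   scales s = 1..6 (non-overlapping window means) and sample entropy

       SampEn(m, r) = −ln(A / B)

   is computed per scale with m = 2 and r = 0.25 × SD of the original
   series (A, B = counts of template pairs matching at lengths m+1 and m,
   Chebyshev distance, strict inequality, self-matches excluded). Band
   summaries: MSE_S = mean over scales 1–3, MSE_L = mean over scales 4–6.
   A more stable gait has a more self-similar stride sequence and lower
   entropy, especially at small scales.
4. **Agreement.** Insole-vs-force-plate consistency via Bland–Altman
   limits of agreement (mean ± 1.96 SD of paired differences) and Pearson
   correlation on amplitude-normalized, 101-point resampled traces.

See `docs/methods.md` for the model details, generator design and
limitations.

## Worked example

Run the built-in three-speed comparison (2/4/6 km/h presets, 5 replicate
recordings of 200 gait cycles each, master seed 1):

```bash
gaitmse report --seed 1 -o demo_out
```

which prints (to stderr) the entropy summary table:

```text
condition  n_series  n_undefined_cells  sampen_mean  sampen_sd  mse_s_mean  mse_s_sd  mse_l_mean  mse_l_sd
     2kmh         5                  1     0.562497   0.088588    0.824649  0.120355    1.344185  0.399121
     4kmh         5                  1     1.438160   0.176519    1.316553  0.157040    1.435623  0.251424
     6kmh         5                  0     2.343453   0.257984    1.908301  0.134456    1.557213  0.223984
```

Reading it: slow walking (2 km/h) has the most regular stride rhythm —
lowest sample entropy (0.56) and lowest small-scale MSE (0.82) — and
entropy rises monotonically with speed; the large-scale band (MSE_L)
separates the speeds much less, i.e. the speed effect on rhythm lives at
short time scales. `n_undefined_cells` counts replicate × scale cells where
entropy was undefined (zero template matches at a coarse scale); these are
excluded from the means. The run directory also contains the per-region
loading table `amplitude_pressure_ratios.csv`:

```text
condition,hindfoot,midfoot,forefoot
2kmh,0.9262957737912322,0.4304422266048694,0.8199473298034572
4kmh,1.0238388240937957,0.42929750395947375,0.938943590979952
6kmh,1.1212759546032394,0.42815199584496993,1.0364898450626046
```

— hindfoot and forefoot load grow with speed (forefoot +26% from 2 to
6 km/h) while midfoot load is flat, plus per-replicate stride-interval and
MSE-profile CSVs, the pairwise MSE_S differences, and a `manifest.json`
with seeds, parameters and SHA-256 checksums of every output.

Other subcommands: `gaitmse simulate` (write a synthetic recording CSV),
`fuse`, `events`, `entropy` (stage-by-stage processing of recording CSVs)
and `gaitmse validate` (insole-vs-plate Bland–Altman run). Everything is
also available as library calls (`gaitmse.run_speed_comparison`,
`gaitmse.mse`, ...), with YAML run configuration via
`gaitmse.RunConfig.from_yaml`.

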