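# nadhcycle

Analysis pipeline for dynamic single-cell NAD(P)H measurements in bacteria.

NADH and NADPH autofluoresce under UVA excitation, which makes label-free,
time-lapse measurement of a cell's redox state possible — but the signal is
weak (cell signal ≈ 45% of the device background), rides on a camera offset
and uneven illumination, and the UVA dose itself slows growth.  `nadhcycle`
implements the full quantification chain for such experiments and the
statistics needed to ask whether NAD(P)H levels oscillate with the cell
division cycle, together with a synthetic-data generator (lineage simulator
plus image renderer) so that every stage can be exercised and validated
without microscope data.

**Who it is for:** microscopists and modelers analyzing single-cell
fluorescence time-lapse data of growing bacteria — ROI intensity tables or
raw TIFF stacks — who need flat-field correction, growth rates,
division-cycle phase alignment, and artifact controls.

## What it computes

* **Flat-field correction.**  With a blank field (no cells) acquired in the
  same round and a CCD baseline *B* (500 AU by default):

  `corrected = (experimental − blank) / (blank − B) × mean(blank)`

  which removes background additively and shading multiplicatively.
* **ROI intensities** on corrected frames: pixels below the background noise
  (median over frames of the 90th-percentile intensity of a >5000-pixel
  cell-free region; 10 AU default) are discarded and a normal distribution is
  fitted to the rest — or, on raw frames, ROI mean minus surrounding mean.
  A zero-crossing interpolation against NADPH standard solutions (0.2–1.0 mM)
  converts intensities to intracellular concentration.
* **Growth rates.**  The observed ROI area is doubled once per past division
  (one sister is followed, so the area halves at division), and log(area) is
  regressed on time over hours 4–10; photodamage is summarized as ΔGR, the
  mean decrease of exposed cells' rates below the unexposed mean GR₀.
* **Division-cycle statistics.**  Each track is detrended (quotient of a
  cubic smoothing spline, p = 0.004, or residual of the endpoint line per
  cycle), cut at divisions, resampled to 21 phase points (19 interpolated +
  2 endpoints), and summarized by the columnwise median, optionally extended
  10% into adjacent cycles (25 points).  Two null controls certify a
  cycle-locked pattern: re-segmentation at fixed 60–110 min pseudo division
  times must flatten the profile, and ten ±1-frame boundary-jitter tests
  must preserve it.  k-means (4 clusters) summarizes per-cycle heterogeneity.
* **Perturbation responses.**  Medium arrival is detected from a tracer-dye
  channel (midpoint crossing between plateaus); responses are quantified as
  the fold change at a horizon after arrival (e.g. a 2-fold rise within
  20 min of a glucose upshift).
* **Synthetic data.**  Log-normal interdivision times calibrated so 80%
  fall in 60–110 min (median 82 min), exponential growth at 0.6 h⁻¹ reduced
  by an exposure-energy/interval photodamage model (10% at 9 μJ/15 min up to
  89% at 56 μJ/5 min), an "increase-drop" intra-cycle intensity shape
  peaking at phase 0.65, slow drift, frame noise, and rendered 16-bit-style
  images with baseline 500, uneven illumination and matching blank positions.

## Worked example

```python
from nadhcycle import RunConfig, run_pipeline

summary = run_pipeline(RunConfig(seed=3), "runs/demo")
print(summary)
```

which prints (abbreviated):

```
n_cycles: 188                  # complete division cycles from 30 tracks
peak_phase: 0.65               # profile maximum at 65% of the cycle
amplitude: 0.0477              # peak minus endpoint mean, quotient units
is_increase_drop: True         # peak interior and amplitude > threshold
threshold: 0.0342              # 3 x worst fixed-division-null deviation
null_flatness: 0.004 - 0.011   # six fixed-division profiles: flat
shift_tests_pattern_retained: 10  # of 10 boundary-jitter tests
fraction_second_half: 0.670    # cycles whose maximum lies at phase > 0.5
median_growth_rate_per_h: 0.264   # 0.6 x (1 - 0.56) at 45 uJ / 10 min
```

The run directory holds `tracks.csv`, `growth.csv`, `cycle_matrix.csv`,
`null_profiles.csv`, `clusters.csv`, `report.json` and a `run_record.json`
that reproduces the outputs byte-for-byte.  The same stages are available on
the command line (`nadhcycle simulate | correct | measure | growth |
perturb | cycles | run`) for user-supplied TIFF stacks, label masks and
track tables; see `nadhcycle --help`.

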