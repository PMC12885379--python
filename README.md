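# drgquant

Quantification pipeline for dorsal-root-ganglion (DRG) axon-regeneration
assays in larval zebrafish, with seeded synthetic-data generators standing
in for the microscope. The package implements, as tested and reusable code,
the measurement procedures behind a set of live-imaging assays:

- **reentry** — classify a regenerated axon as *entered* / *not entered* from
  a dual-channel intensity profile along an 8 µm medial→lateral line across
  the axon-tip / spinal-cord-boundary junction (axon peak strictly medial of
  the boundary peak ⇒ entered), and aggregate per-group proportions.
- **invadopodia** — background-subtract growth-cone actin traces (5-min
  sampling), threshold each trace against its own mean, detect maximal runs
  of ≥ 4 consecutive supra-threshold frames (≥ 20 min) as invadopodia
  formations, classify durations (transient 20–35 min, intermediate
  40–55 min, stable 60+ min), compile per-group and at-DREZ duration pools,
  and measure orthogonal basal widths (FWHM).
- **glia** — migration metrics from object tracks: per-frame dorsal offsets
  against the DRG dorsal border, 140-timepoint window means, t0→t140 total
  migration, and target-plot distances.
- **calcium** — per-cell z-scores against each cell's own full-trace mean and
  sample SD; activation at z ≥ 2.0; rapid-synchronous (active at the first
  cold-water frame, frame 16) vs delayed (first crossing at frame 17+) vs
  none; per-animal synchrony summaries with the ≥ 1-rapid-DRG inclusion rule.
- **behavior** — shivering quantification over the first 400 frames (50 ms
  intervals, 20 s) after immersion: head movement without net centroid
  locomotion, with explicit, configurable thresholds.
- **hcr** — puncta detection / density inside polygon masks, background-
  corrected mean grey of traced regions, and 200 µm² floor-plate box means.
- **stats** — Fisher exact (probability-ordering two-sided), Mann–Whitney,
  Kruskal–Wallis, Welch and Brown–Forsythe ANOVA, paired t, chi-squared.
- **synthetic** — seeded generators for every input above, each returning a
  ground-truth sidecar so downstream modules can be verified to recover
  planted truth exactly at noise 0.

## CLI

A single executable with per-assay subcommands:

```sh
drgquant simulate lifeact --spec spec.yaml --seed 7 --out sim/
drgquant invadopodia detect sim/trace.csv
drgquant invadopodia compile --group control traces/*.csv
drgquant reentry score profiles/*.csv --group 2dpf
drgquant glia summarize tracks.csv --start-frame 1 --n 140
drgquant calcium score recording.csv
drgquant behavior score track.csv --condition 4C
drgquant hcr puncta img.tif --mask mask.json --pixel-size 0.1
drgquant stats fisher 1 7 2 16
drgquant report study.json part1.json part2.json
```

Global options `--config cfg.yaml`, `--seed N`, `--log-level LEVEL` come
before the subcommand. Inputs are plain CSV with `# key=value` header lines
for per-file metadata (sampling interval, schedule frames, medial-end
declaration); outputs are JSON with embedded provenance (version, seed,
config hash).

Conventions: frame indices are 1-based everywhere; the analysis coordinate
frame has +y dorsal with positions in µm; profile files must declare the
medial end at coordinate 0.

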