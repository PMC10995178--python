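# organgrowth

Lineage-based quantification of cellular growth and differentiation
gradients on growing plant-organ surfaces, together with a seeded synthetic
growing-tissue generator that emulates confocal time-lapse series of
segmented epidermal cell layers.

The package takes a time series of segmented cell polygons (labels, outline
coordinates in µm, region and cell-state tags) plus child→parent lineage
maps between consecutive time points, and computes:

- **per-lineage growth**: percent area expansion
  (`[daughter area sum / mother area − 1] × 100`), principal stretches and
  growth anisotropy from a least-squares linear fit to tracked cell-junction
  positions, and directional expansion along organ axes defined by Bezier
  curves;
- **axis coordinates and distances**: a curvilinear `(u, v)` organ frame
  from manually placed Bezier control points, and geodesic cell distances
  (shortest path on the cell adjacency graph, centroid-to-centroid weights)
  with explicit per-domain normalization;
- **gradient read-outs**: binned mean ± SD profiles versus normalized
  distance, Spearman rank-correlation gradient statistics with permutation
  p-values, dominant-axis classification (longitudinal vs mediolateral),
  onset-time detection for sustained gradients, stomata distributions, and
  cell-size profiles;
- **lineage algebra**: composition of parent relations across intervals,
  reverse tracing of late region assignments into early sectors (with
  explicit "mixed" reporting), and proliferation counts.

Because the original imaging data is not required, a first-class simulator
(`organgrowth.synthetic_tissue`) generates growing, dividing,
differentiating cell tessellations under prescribed stretch-rate,
differentiation-onset, and stomata fields, with per-cell ground truth for
every interval. Five scenario presets (`gynoecium`, `valveless`, `sepal`,
`carpelized_sepal`, `split_mutant`) encode qualitatively distinct gradient
structures that the quantification pipeline recovers in the test suite.

## Test

```sh
python -m pytest -q tests/
```

The suite includes `tests/test_acceptance.py`, which checks formula and
tensor fidelity against independent oracles, exact shortest-path agreement
with a brute-force Bellman–Ford implementation, lineage-algebra laws,
permutation-null calibration, simulator conservation (per-cell area vs
imposed field within 1%), determinism, and recovery of the imposed
two-gradient structure (early mediolateral valve gradient, late
longitudinal style gradient) from a ~500-cell simulated organ series. The
full run takes a few minutes; most of it is the session-scoped simulation
fixture.

## CLI

```sh
# run a synthetic scenario and write snapshots + lineages + ground truth
organgrowth simulate --scenario gynoecium --seed 1 --out out/sim

# validate a snapshot/lineage series
organgrowth validate out/sim/snapshot_*.json --lineage out/sim/lineage_*.csv

# full pipeline: simulate/load -> validate -> growth maps -> distances ->
# profiles, gradient stats, onsets -> stomata histograms
organgrowth run --config config.yaml --seed 1 --out out/run
```

`config.yaml` holds a `PipelineConfig` (see
`organgrowth.io_cli.config`): scenario name and overrides or input file
paths, axis control points, bin counts, statistic parameters
(`alpha`, `delta`, `min_consecutive`, `n_permutations`), seed, and output
directory. Every output CSV carries the config hash and seed in a header
comment; identical configs reproduce outputs byte-for-byte.

File formats: snapshots as JSON cell-outline files (schema documented in
`organgrowth/io_cli/formats.py`) or ASCII PLY with a per-face integer
`cell_label` attribute; lineages as two-column CSV with `# t0=`/`# t1=`
header comments.

## Package layout

```
src/organgrowth/
  core_model.py        domain types, series validation
  synthetic_tissue/    tessellation, growth fields, simulator, presets
  lineage.py           compose, reverse trace, proliferation
  growth_quant.py      area expansion, growth tensors, directional growth
  axes_distance.py     Bezier axis grids, geodesic cell distances
  gradients.py         profiles, gradient stats, onsets, stomata
  io_cli/              formats, config, pipeline driver, CLI
```
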