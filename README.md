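# meristemsim

Stochastic lineage-competition modeling and quantitative lineage/image
analysis for *de novo* meristem formation in fern gametophytes.

During male-to-hermaphrodite conversion, a single meristem progenitor cell
(MPC) lineage comes to dominate an initially equivalent pool of marginal
cells. This package implements:

- **`meristemsim.model`** — a five-lineage SDE model tracking outer
  (marginal) and inner cell counts per lineage. Outer cells divide at rate
  `r` (anticlinal/periclinal equally likely), inner cells at `gamma*r`, and
  a piecewise Hill-type term inhibits division in two variants: a
  **threshold** version (inhibition by the lineage leading all others by
  `alpha` marginal cells) and a **mutual** version (every lineage inhibited
  by the pooled marginal count of the others). Integrated with
  Euler–Maruyama, counts clamped at zero.
- **`meristemsim.ensemble`** — seeded ensembles, the rank-sort-and-average
  post-processing (lineages sorted by final total per run, averaged by
  rank), an "aphidicolin" perturbation (r halved), metric sweeps over
  `sigma`/`gamma`.
- **`meristemsim.lineage`** — analytics on per-nucleus tracking tables:
  cells per lineage over time, divided/undivided window maps, per-root
  progeny division totals, Welch's unequal-variance t-test for
  outer-vs-inner layer activity, and exact binomial tests of
  anticlinal/periclinal frequencies.
- **`meristemsim.segment`** — nuclei segmentation (Gaussian blur → adaptive
  local-mean threshold → distance transform → inverted watershed → circle
  fit) plus programmatic merge/split/delete label edits.
- **`meristemsim.synth`** — a seeded branching-process generator producing
  lineage tables (Phase I uniform division, Phase II single-lineage
  dominance, antheridium drop-out) and rendered nuclei image series, each
  with an exact ground-truth ledger.
- **`meristemsim.io` / `meristemsim.cli`** — CSV/YAML/TIFF readers and
  writers and the `meristemsim` command-line tool.

## CLI

```sh
# one stochastic trajectory (CSV: time_h, lineage, outer, inner)
meristemsim simulate --version threshold --seed 1 --out trajectory.csv

# 1000-run ensemble, rank-sorted summary (+ optional band plot)
meristemsim ensemble --n-sims 1000 --version threshold --out summary.csv --plot bands.png

# parameter sweep
meristemsim sweep --param sigma --values 0.001,0.01,0.05,0.1 --metric dominance_ratio --out sweep.csv

# synthetic data with ground-truth ledgers
meristemsim synth table --seed 7 --out table.csv
meristemsim synth images --seed 7 --out frames/

# quantification of a lineage table
meristemsim quantify counts --table table.csv --out counts.csv
meristemsim quantify divisions --table table.csv --window 12 --out divisions.csv
meristemsim quantify layers --table table.csv --start 54 --out layers.csv
meristemsim quantify orientation --table table.csv --out orientation.json

# nuclei segmentation of a grayscale TIFF
meristemsim segment frames/frame_t000.tif --out detections.csv
```

Every run writes a `*.run.yaml` record of the resolved parameters and seed
next to its outputs. Model defaults (calibrated so that the baseline
threshold ensemble yields one dominant lineage in ≥95% of runs) live in
`src/meristemsim/data/defaults.yaml`.

## Lineage table format

CSV with columns
`nucleus_id,time_h,x_px,y_px,lineage_id,layer,is_antheridium,parent_id`:
one row per nucleus per frame; `layer` is `outer` or `inner`;
`parent_id` is set only on the first frame after a division (two daughter
rows per dividing parent); antheridium-flagged rows are excluded from all
division statistics.

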