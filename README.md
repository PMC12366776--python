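# dropmorph

Morphometry and encapsulation statistics for droplet-confined organoid
cultures, built around 2-D binary label masks (label 1 = hydrogel droplet,
labels ≥ 2 = organoid structures).

The package provides:

- **`dropmorph.mask_geometry`** — mask I/O (16-bit label TIFF / PNG) and
  per-component primitive geometry: area, Crofton perimeter, moment-ellipse
  axes, equivalent diameter, compactness `4πA/P²` and the shape
  irregularity index `P / (2√(πA))`.
- **`dropmorph.organoid_morphometry`** — skeleton-based branch census
  (calibrated geodesic lengths, spur pruning), the spheroid/branched
  classifier (major axis < 60 μm, OR minor axis > a/2, OR fewer than 2
  branches ≥ 30 μm ⇒ spheroid), polydispersity index, branched-fraction and
  growth summaries.
- **`dropmorph.droplet_dynamics`** — droplet contraction over time with
  percentile-bootstrap CIs, normalized organoid-to-boundary minimal
  distance, radial positioning, compactness time series.
- **`dropmorph.encapsulation_model`** — spherical droplet volumes,
  production rates, Poisson occupancy (λ = concentration × volume),
  organoid-formation efficiency and a seeded percentile-bootstrap utility.
- **`dropmorph.synthetic_data`** — a deterministic, ground-truthed phantom
  generator (droplet masks with contraction/deformation schedules,
  spheroid/branched organoid phantoms, Poisson cell seeding) so the whole
  pipeline is testable without microscopy data.
- **`dropmorph.pipeline` / CLI** — config-driven orchestration producing
  tidy CSV tables and a JSON run report.

## Test

```bash
python -m pytest -q tests/
```

## CLI

```bash
# write a synthetic dataset (TIFF masks + manifest.csv + ground_truth.json)
dropmorph generate --out data/small --preset small --seed 1 --n-droplets 10

# analyze a mask dataset (or run synthetically with --preset/--config)
dropmorph analyze --out results/small --input-dir data/small
dropmorph analyze --out results/large --preset large --n-droplets 10 --seed 1

# print the per-day summary and occupancy report
dropmorph report results/small
```

`analyze` writes `features.csv` (one row per structure per day),
`summary_by_day.csv` (major axis, SII, PDI, branched fraction, droplet
diameter/compactness, contraction with bootstrap CI, normalized distances)
and `run_report.json`. Outputs are byte-identical for a fixed config and
seed.

## Conventions

- All public quantities are in micrometres (μm, μm²); pixel→μm conversion
  happens once at feature-extraction time.
- `a`/`b` are full major/minor axis lengths of the moment-matched ellipse.
- Perimeter uses the 4-direction Crofton estimator (digital disk of radius
  ≥ 50 px gives compactness 1.00 ± 0.02).
- Skeleton geodesics use calibrated step weights (0.948 orthogonal, 1.340
  diagonal); branches are measured from the body anchor (maximal inscribed
  radius) to skeleton endpoints, spurs < 10 μm pruned.
- Droplet holes are filled before droplet features; organoid labels are
  measured as-is. Structures touching the image border are flagged and
  excluded from population statistics.
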