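# shapescreen

Analysis toolkit for microscopy-based cell-shape siRNA screens, as used to
find regulators of microglial morphology. It covers the full desk-side
pipeline:

- **morphometry** — per-cell circularity (`4*pi*area/perimeter^2`) from
  fluorescence fields: median filter (disk footprint), global threshold
  (Otsu by default), hole filling, connected-component labelling, sub-pixel
  outline measurement, and exclusion of border-touching cells.
- **screen_stats** — per-experiment normalisation to the scrambled control,
  log2 differential circularity, one-sample moderated-t (empirical-Bayes
  variance shrinkage with a moment-matched prior) or Student-t tests,
  Benjamini–Hochberg FDR, hit classification, and ≥2-of-N same-sign
  multi-siRNA gene validation.
- **scratch_assay** — wound-width measurement from local-variance texture
  maps, percent closure at 24 h relative to 1 h, and control-normalised
  migration (control ≡ 1.0 per experiment).
- **expression** — ΔΔCt relative quantification (`2^-ΔΔCt`, optional
  efficiency-adjusted mode) and loading-control-normalised densitometry.
- **synthetic_data** — seeded generators for everything the pipeline
  consumes, with analytic ground truth: cell fields (disks, ellipses,
  ramified cells with closed-form circularities), table-level screens with
  planted log2 effects, scratch image pairs with known band widths, and Ct
  tables with planted fold changes.
- **cli_io** — strict config/layout schemas, the end-to-end `run-screen`
  pipeline with a run manifest, and the CLI.

## CLI

All commands are under a single entry point:

```bash
# generate synthetic inputs with ground truth
shapescreen simulate --preset field   --seed 1 --out demo/
shapescreen simulate --preset screen  --seed 1 --out demo/
shapescreen simulate --preset scratch --seed 1 --out demo/
shapescreen simulate --preset qpcr    --seed 1 --out demo/

# per-cell circularity for a directory of images + layout CSV
shapescreen quantify --images imgs/ --layout layout.csv --out per_cell.csv

# screen statistics from per-cell or aggregated CSV
shapescreen screen-stats --input per_cell.csv --alpha 0.05 --test moderated_t --out stats/

# full pipeline (images or a pre-aggregated table)
shapescreen run-screen --images imgs/ --layout layout.csv --out run/
shapescreen run-screen --table demo/screen_table.csv --out run/

# scratch assay and expression
shapescreen scratch --layout scratch_layout.csv --out records.csv
shapescreen qpcr --input ct_table.csv --out expression.csv
shapescreen densitometry --input lanes.csv --out densitometry.csv
```

Layout CSVs have columns `image, gene, sirna, experiment, field`; Ct tables
`sample, gene, replicate, ct`; scratch layouts
`condition, experiment, t1_path, t24_path`. A YAML config (see
`shapescreen.cli_io.PipelineConfig`) controls every stage and rejects
unknown keys.

## Python API

```python
from shapescreen import synthetic_data as sd
from shapescreen.screen_stats import run_screen_stats

design = sd.ScreenDesign(n_genes=157, noise_sd=0.2,
                         effect_map={"G001": 2.0, "G002": -1.8}, seed=0)
table = sd.generate_screen_tables(design)
results, validation, prior = run_screen_stats(table)
```

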