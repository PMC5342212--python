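# morphoscape

Intra-specific wing-morphometry variability analysis: generalized Procrustes
shape statistics, population diversity/differentiation metrics, inverse
distance-weighted interpolation surfaces, and a two-stage MRDM/LR framework
with commonality analysis testing geographic, genetic and environmental
predictors.

## What it does

- **landmark_io** — read/write TPS landmark files (tps-DIG dialect, `LM=`,
  `ID=`, `IMAGE=`, `SCALE=` keys; `_R`/`_L` side suffixes on IDs), select one
  wing per specimen (right preferred, left mirrored), read/validate the
  specimen metadata CSV.
- **shape** — iterative generalized least-squares Procrustes superimposition
  (proper rotations only), partial Procrustes distances, tangent-space
  projection and the slope/correlation adequacy diagnostic, centroid size,
  principal coordinates analysis.
- **popmetrics** — inter-population mean distances (mD/wsD/IID2-style
  aggregation), within-population mean pairwise diversity (md), mean wing
  size (wsM), covariate difference matrices, multi-locus per-site sequence
  mismatch distances and nucleotide diversity from FASTA alignments.
- **surfaces** — great-circle (haversine, R = 6371 km) distance matrices,
  Delaunay connectivity networks with edge midpoints, residual distances
  from regression on geographic distance, IDW rasters (exponent *a*,
  default set {1, 5, 10}; 10-arcmin cells), point extraction and
  cross-surface correlation. Rasters are written as ESRI ASCII grids.
- **regression** — multiple regression on unfolded distance matrices with
  permutation inference (response-matrix label permutation, add-one
  p-values, exact enumeration available for small n), standardized linear
  regression with parametric tests, all-subsets commonality analysis
  (U/C/T), total-suppressor detection (opposite-sign or counterbalanced
  negative-common rules), Benjamini–Hochberg correction, and batch
  suppressor removal with a second-stage refit.
- **synthetic_data** — deterministic generators for complete study systems
  (TPS + CSV + per-locus FASTA + truth record) with tunable
  isolation-by-distance/-environment shape effects, size–temperature
  slopes, planted suppressor structure, and distance-driven sequence
  divergence. Named fixtures: `null`, `ibd`, `ibe_precipitation`,
  `suppressor`, `bergmann`.
- **pipeline** — per-species orchestration producing population tables,
  surfaces, cross-species diversity correlations at combined localities,
  the four two-stage regression reports (mD, wsD, md, wsM) and the pooled
  PCoA; CSV/JSON report bundle.

## CLI

```sh
# generate a synthetic study system
morphoscape simulate --fixture ibd --seed 2 --out demo/

# run the full analysis
cat > cfg.yaml <<EOF
tps_path: demo/wings.tps
specimen_csv: demo/specimens.csv
fasta_dir: demo/loci
out_dir: demo_out
EOF
morphoscape run --config cfg.yaml --n-perm 1000 --seed 1
```

Outputs land under `out_dir/`: `reports/bundle.json`, per-species
Table-1-shaped regression CSVs (r, β, U, C, T per predictor, initial and
final stages), population tables, interpolation rasters (`surfaces/*.asc`)
and the pooled PCoA coordinates.

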