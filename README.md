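# subparc

Connectivity-based subcortical parcellation and diffusion-MRI
microstructure biomarkers, with a synthetic phantom/cohort generator so the
whole pipeline is testable without clinical data.

The package covers, end to end:

- **`subparc.synthio`** — phantom probabilistic atlases (smooth blobs for
  VTA / SNc / striatum per hemisphere), six cortical target patches per
  hemisphere, geometric streamline simulation with per-vertex target
  profiles, MD/FA scalar maps with injectable subregion-specific group
  shifts, and cohort tables (group, age, sex, site, MoCA, MDS-UPDRS-III,
  RBD score, disease duration).
- **`subparc.surface`** — marching-cubes isosurfacing of probability
  volumes (optionally trilinearly upsampled), quadric edge-collapse
  decimation, affine/displacement transforms, per-vertex seeding spheres,
  PLY/GIFTI I/O.
- **`subparc.parcellation`** — streamline terminal labelling, per-vertex
  termination counting, winner-take-all assignment with a minimum
  fibre-count limit and configurable tie policies.
- **`subparc.features`** — bundle MD/FA (mean over voxels traversed by a
  subregion's streamline bundle) and surface MD/FA (mean of the map
  sampled at subregion surface vertices), assembled into a
  subject × feature table with hemisphere pooling.
- **`subparc.stats`** — Levene-gated ANCOVA vs Kruskal–Wallis + Dunn,
  Bonferroni (default family size 96) and Benjamini–Hochberg corrections,
  BIC-approximated Bayes factors for group equivalence, Spearman
  correlations with exact permutation p for n ≤ 9.
- **`subparc.classify`** — class-balanced random forests, stratified
  80/20 hold-out (largest-remainder per class, ceiling total), TPE-style
  cross-validated hyperparameter search, ROC/AUC, F1-optimal thresholding,
  200-resample bootstrap stability, impurity feature importances.
- **`subparc.pipeline`** — YAML-configured end-to-end runner with
  content-hash stage caching, scoped child seeds, JSON-lines logging and
  provenance manifests.

## CLI

```sh
subparc simulate  --out atlas/ --grid 48             # phantom atlas
subparc fixtures  --out study/                       # toy BIDS-like study
subparc surface   --prob atlas/snc_R_prob.nii.gz --threshold 0.3 \
                  --upsample 200 --out snc.ply
subparc parcellate --streams sub-001_snc_R.tck \
                  --labels atlas/cortical_labels.nii.gz \
                  --n-targets 4 --min-count 10 --out parc.csv
subparc stats     --features features.csv --cohort cohort.csv \
                  --correction bonferroni --family 96 --out stats.csv
subparc classify  --features features.csv --cohort cohort.csv \
                  --positive iRBD --feature-cols snc_caudal_motor_surface_md,age,sex,moca \
                  --trials 100 --boot 200 --seed 7 --out report.json
subparc run       --config config.yaml               # all stages
```

Exit codes: 0 ok, 2 configuration error, 3 data error, 4 statistical
precondition failure.

## Conventions

All geometry is world millimetres; the NIfTI affine is the only
voxel↔world authority; voxel indices are 0-based voxel centres. Cortical
targets are enumerated 1–6 (limbic, executive, rostral motor, caudal
motor, parietal, occipital); VTA and SNc use the first four, the striatum
all six. Feature columns follow
`<structure>_<subregion>_<bundle|surface>_<md|fa>[_<l|r>]`, MD in mm²/s.
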