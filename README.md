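# voxelage

Control-only voxel-wise linear age detrending for spatially normalized
grey-matter (GM) maps, together with the two evaluation engines needed to
validate such a correction:

- **Age detrending** (`voxelage.age_detrend`): per masked voxel, an
  ordinary-least-squares line `y = b0 + b_age * age` is fit on *healthy
  controls only*, and the age-explained component `b_age * age_i` is
  subtracted from every subject (patients included). A strict
  cross-validated variant fits one model per control half and applies each
  model only to data it has never seen.
- **Mass-univariate inference** (`voxelage.mass_univariate`): voxel-wise
  GLM t contrasts with covariates, voxel-wise age correlation in controls,
  and cluster-extent family-wise-error correction by Freedman–Lane
  permutation of the maximum suprathreshold cluster size.
- **Classification harness** (`voxelage.classification`): stratified
  split-half linear-SVM cross-validation, repeated-split accuracy
  distributions compared across feature conditions, and a misclassified-
  subject age comparison that exposes age-driven misclassification.

Supporting modules: NIfTI stack / TSV cohort I/O with strict grid checks
(`io_cohort`), probability-template masking and Gaussian smoothing
(`masking`), summary-statistics utilities — pooled t, chi-square, one-way
ANOVA with Bonferroni post-hocs (`summary_stats`) — and a seeded phantom
cohort generator with exact ground truth (`synthetic`), so the whole
pipeline is testable without any imaging data download.

## CLI

One entry point, `voxelage`, with subcommands `simulate`, `mask`,
`smooth`, `fit`, `apply`, `fit-apply-cv`, `vbm`, `classify` and `stats`.
Every command writes a JSON run manifest (parameters, seeds, input hashes,
version) next to its primary output. A complete phantom round trip:

```sh
voxelage simulate --spec spec.json --out-dir phantoms/
voxelage mask --template-a tpl_a.nii --template-b tpl_b.nii --threshold 0.2 --out mask.nii
voxelage fit --cohort phantoms/cohort.tsv --images-dir phantoms/ --mask mask.nii --out model.nii
voxelage apply --cohort phantoms/cohort.tsv --images-dir phantoms/ --model model.nii --out-dir corrected/
voxelage vbm --cohort phantoms/cohort.tsv --images-dir corrected/ --mask mask.nii \
    --voxel-p 0.001 --n-perm 1000 --seed 1 --out-prefix results/vbm
voxelage classify --cohort phantoms/cohort.tsv --images-dir phantoms/ \
    --images-dir-b corrected/ --mask mask.nii --repeats 60 --seed 1 --out results/clf.json
```

`--spec` is a JSON mirror of `voxelage.synthetic.PhantomSpec` (grid shape,
group sizes, age range, age-slope field, atrophy region, noise, seed).
Cohort tables are TSV with columns `subject_id`, `group`, `age`, `sex`
(extra columns preserved). Volumes must share one grid; nothing is ever
resampled implicitly.

## Conventions

- Mask construction keeps a voxel only if its probability **strictly
  exceeds** the threshold (default 0.2) in both templates.
- Smoothing sigma is `FWHM / (voxel_size * 2 * sqrt(2 * ln 2))` per axis,
  plain zero-padded convolution at the boundary.
- The corrected value subtracts `b_age * age` with *uncentered* age by
  default (`--center-age` switches to mean-centered subtraction; the two
  differ only by a per-voxel constant and leave group contrasts
  unchanged).
- Corrected GM values are not clipped to be nonnegative.
- Cluster-level correction is permutation-based (maximum cluster extent,
  `(1 + count) / (1 + n_perm)` p-values), not random-field theory;
  connectivity defaults to 18, one-tailed in the contrast direction.
- t-maps report nominal residual df by default; `--df-adjust` subtracts
  degrees of freedom consumed by a detrending pre-regression.
- SVM: linear kernel, `C = 1` by default, no feature scaling by default;
  each repeat makes a fresh stratified half-split with seed `base + r`,
  shared across feature conditions.

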