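# epics3d

Open/closed chromatin-domain characterization from 3D super-resolution
image stacks.

High-resolution 3D microscopy of chromatin — electron microscopy with in
situ hybridization (dark voxels = more chromatin, ~5–7 nm in plane) or
structured illumination microscopy (bright voxels = more chromatin,
~40 nm) — captures physical chromatin domains directly in single cells.
This package reconstructs those domains from raw z-stacks, describes each
one with a small set of explainable shape and intensity metrics, labels it
**open (A)** — sparse, near-spherical, little material — or **closed (B)**
— dense, asymmetric, lots of material — and fits an interpretable model of
what separates the two states. It is aimed at imaging groups who want
A/B-compartment-like calls, with physical units attached, from image data
rather than from Hi-C.

## Method

Per stack (one multi-page grayscale TIFF, with voxel size, signal
polarity and batch id):

1. **Reconstruction** — Gaussian smoothing with a physically isotropic
   kernel; polarity unification (dark-is-signal stacks are inverted for
   thresholding only); a guarded 3-class Otsu threshold separating
   background from both chromatin populations; linear z-interpolation to
   near-cubic voxels; 26-connected component segmentation (optional
   watershed for dense fields).
2. **Features** — per domain, 19 candidate metrics *m₁…m₁₉*: white/black
   encircled-image counts and their shape proportion SP (domain volume
   over the cube circumscribing its exact minimum enclosing sphere),
   covariance eigenvalues E1 ≥ E2 ≥ E3 (nm²), Wadell sphericity
   Ψ = π^⅓(6V)^⅔/A, marching-cubes surface area A (nm²), and eleven
   intensity statistics of the domain's own voxels (mean, SD, median, Q1,
   Q3, max, min, skewness, excess kurtosis, % > 24000, % > 30000). The two
   exceedance metrics apply to dark-is-signal data only (17 metrics in
   bright mode).
3. **States** — per feature *q* and batch *j*, z-normalization
   (D<sub>q,j</sub> − μ̂<sub>q,j</sub>)/σ̂<sub>q,j</sub>; k-means with
   k = 2 per batch; the cluster whose Mean-intensity average indicates
   more material (lower raw mean under dark-is-signal, higher under
   bright-is-signal) becomes closed (B). Stability is verified by
   bootstrap reclustering (Jaccard index, accuracy, balanced accuracy
   after optimal label matching).
4. **Model** — stratified 70/30 split; L1-penalized logistic path with
   10-fold cross-validated deviance and the one-standard-error rule for
   λ; then an unpenalized logistic refit on the selected features in
   their original physical units:

   log P(C=B|x) / P(C=A|x) = β₀ + βᵀx,

   so each coefficient reads as the change in log-odds of being closed
   per physical unit; odds = e^β. Variable importance is the absolute
   Wald z-value, reported relative to the largest.

## Worked example

Everything runs from the CLI on a synthetic dataset with planted truth
(no downloads needed):

```bash
epics3d simulate --outdir demo/data --n-open 40 --n-closed 40 --seed 11
epics3d run --config demo/data/config.json --outdir demo/run --seed 11
epics3d report demo/run
```

prints

```
# Chromatin domain classification report

Domains: 80 (39 closed / 41 open)

## Model
- penalty policy: one_se (lambda = 0.0563543)
- training accuracy: 1.000 (95% CI 0.936-1.000, n=56)
- validation accuracy: 1.000 (95% CI 0.858-1.000, n=24)
- note: z-values flagged unreliable (possible separation)

## Features by relative variable importance
- sd_int: relative VI 1.000, log-odds 0.3151, odds 1.370
- q1_int: relative VI 0.360, log-odds -0.05392, odds 0.948
- eigen1: relative VI 0.290, log-odds 0.07838, odds 1.082
- min_int: relative VI 0.065, log-odds 0.01097, odds 1.011

## Cluster stability (bootstrap)
- mean Jaccard index: 0.931
- mean accuracy: 0.963
- mean balanced accuracy: 0.964
```

Reading this: 80 domains were segmented from 40 stacks and split 39/41
between closed and open by per-batch clustering. The penalized model kept
four of the 19 candidate metrics; intensity spread (`sd_int`) dominates —
each unit of intensity SD multiplies the odds of a domain being closed by
1.370. Validation accuracy of 1.000 is measured against the unsupervised
state labels; the bootstrap numbers say those labels are stable under
resampling. (Accuracies this high reflect the cleanly separated synthetic
populations; the separation warning means z-based importance should be
read qualitatively here.)

The same `run` command works on real data: write a `config.json` listing
your TIFF stacks with their voxel sizes (dz, dy, dx in nm), polarity
(`dark_is_signal` or `bright_is_signal`) and batch ids.

The library mirrors the CLI with scikit-learn-style estimators
(`StackReconstructor`, `DomainFeaturizer`, `BatchZScorer`,
`TwoStateKMeans`, `LassoLogisticModel`) plus functional wrappers
(`reconstruct_stack`, `extract_features`, `batch_normalize`,
`assign_states`, `select_features_lasso`, …).

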