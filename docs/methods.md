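# Methods

## Model and procedure

The pipeline classifies RGB leukocyte images into four classes (neutrophil,
eosinophil, monocyte, lymphocyte in the reference setting) in four stages.

**Augmentation.** One GAN is trained per class on that class's training
images only. The generator maps Gaussian noise `z ∈ R^100` through a dense
projection and a stack of nearest-neighbour ×2-upsample / convolution /
batch-norm / LeakyReLU / dropout blocks to a tanh image in `[−1, 1]`; the
discriminator stacks convolution / LeakyReLU / 2×2-max-pool / batch-norm /
dropout blocks into a sigmoid scalar. Training alternates `S` discriminator
ascent steps on the empirical value
`(1/n) Σ [ln D(x_i) + ln(1 − D(G(z_i)))]` with one generator descent step on
`(1/n) Σ ln(1 − D(G(z_i)))` (the literal minimax objective, not the
non-saturating variant). Sampled images are rescaled to `[0, 255]`, tagged
`synthetic`, and appended to the training split; test splits are never
augmented, and provenance tags make that violation impossible to construct
through the public API.

**Feature learning.** A convolutional trunk ending in global pooling is
frozen; six appended layers (`FC128`, `ReLU`, `BN`, `FC4`, `Softmax`,
`Classification`) are trained by mini-batch cross-entropy with Adam.
Because the trunk never moves, its pooled outputs are computed once and the
optimization runs only on the ~263k head parameters (for a 2048-wide
trunk). After fine-tuning, the last five head layers are dropped and the
128-dimensional `FC128` activation (pre-ReLU) becomes the feature vector.
The tap point is configurable in principle, but pre-ReLU is the default
because the downstream classifiers supply their own nonlinearity.

**Classification.** Three randomized networks are trained on the same
feature matrix with independent seeds. Hidden parameters are i.i.d.
`U[−1, 1]`; the default activation is the logistic sigmoid and the default
hidden width is `Z = 400`. Output weights solve
`min_P ‖A P − Y‖_F` in closed form with `A = H` (ELM), `A = [X | H]`
(RVFL), or `A = [H | 1]` (SNN, last row of the solution being the output
bias). The solver is `pinv` with SVD cutoff `rcond = ε · max(N, Z)`; an
optional ridge `λ > 0` switches to `(AᵀA + λI)⁻¹AᵀY`, off by default. An
all-zero design degenerates to `P = 0` with a warning. Predictions are the
row argmax of the raw output, ties resolved toward the lowest class index.

**Ensemble.** Per sample, if any two member labels agree the agreed label
is returned; if all three differ, the ELM label is. The asymmetric fallback
is treated as normative; swapping the RVFL and SNN streams provably never
changes a vote. Member seeds default to `(seed, seed+1, seed+2)` from one
pipeline seed.

**Evaluation.** One-vs-rest counts per class feed the five metrics
(accuracy, sensitivity, precision, specificity, F1). Macro averages are
unweighted arithmetic means over classes even under class imbalance. A
zero denominator yields NaN with a warning and NaN propagates into the
macro mean — silently substituting 0 would fabricate a score. Multi-run
aggregation is the element-wise mean of per-class metrics over runs, with
macro averages recomputed from the aggregated table; the aggregated F1 is
the mean of per-class F1 values, not the F1 of averaged precision and
sensitivity. Two-decimal rounding happens only when a report is printed.
ROC curves group tied scores into single threshold steps, so the
trapezoidal area equals the pairwise-concordance (midpoint tie) estimator;
a test verifies that identity to 1e-10 and cross-checks scikit-learn.
The ensemble ROC uses a configurable member's continuous outputs, ELM by
default; voting produces labels, not scores, so some such choice is forced.

## Reference result tables

`dlbcnet.reference_results` ships the per-run, per-class percentages
reported for this method on the public four-class blood-cell dataset, as
plain data. They are inputs to the aggregation arithmetic (and the worked
example of it), not outputs of this package: reproducing the underlying
runs needs the external image set and a pre-trained ResNet-scale trunk.
One cell of the published summary table (eosinophil specificity, 90.16) is
inconsistent with the mean of its own published run values, which is
exactly 90.10; the tests assert the arithmetic's answer and record the
0.06 discrepancy explicitly.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `Z` | 400 | hidden nodes per randomized network |
| activation | sigmoid | hidden nonlinearity `g` (sigmoid/tanh/relu) |
| `ridge` | 0 | optional Tikhonov term in the output solve |
| mini-batch | 10 | head fine-tuning batch size |
| max-epoch | 1 | fine-tuning epochs (deliberately short: the frozen trunk carries the representation and longer schedules overfit small sets) |
| learning rate | 1e-4 | Adam step size for head and GAN |
| `noise_dim` | 100 | GAN latent dimension |
| `gen_blocks` | 5 | generator upsampling blocks; filter widths double toward the bottleneck from `base_filters` |
| `kernel_size` | 5 | conv kernels in both GAN networks; ≥4 enforced since large kernels smear the checkerboard artifacts of naive upsampling |
| `dropout_rate` | 0.3 | dropout in both GAN networks |
| `leaky_slope` | 0.2 | LeakyReLU negative slope |
| `T`, `S` | 200, 1 | GAN iterations and discriminator steps per iteration |
| `n_synthetic_per_class` | 3000 reference / 50 fixture | synthetic images mixed into training |

The reference experimental setting is mini-batch 10, one epoch, learning
rate 1e-4, `Z = 400`, 3000 synthetic images per class on a dataset of
~2175 training and ~933 test images per class (the class-exact split for a
3120-image class being 2184 train / 936 test, with the mixed training set
then holding 5184).

## Design choices where the design was open

- The fine-tuning optimizer and loss are Adam and categorical
  cross-entropy; the activation of the randomized networks is sigmoid and
  their initialization `U[−1, 1]`. These follow the conventions of the
  transfer-learning and ELM literatures rather than any stated requirement.
- Freezing covers the entire pre-trained trunk; all six appended head
  layers train. Descriptions of freezing "all but the last three layers"
  conflict with a six-layer appended head, and freezing the whole trunk is
  the reading consistent with standard transfer learning.
- The RVFL solve uses the concatenated design `[X | H]` (the defining
  feature of direct links); `direct_links=False` exposes the H-only solve
  for comparison.
- The SNN output bias is found jointly with the weights by augmenting the
  design with a constant-1 column, the unique least-squares-consistent
  completion of an under-determined description.
- GANs are per-class rather than label-conditional: per-class training is
  the simpler mechanism that delivers class-labelled synthetic output.
- The GAN works at 64×64 (reference) or 32×32 (fixture preset) and samples
  are bilinearly resized to the classifier input; generator upsampling is
  nearest-neighbour + convolution rather than transposed convolution,
  which combined with kernel 5 suppresses checkerboard artifacts.
- Multi-run repetition re-draws only the randomized-network seeds; the
  augmentation and fine-tuned features are computed once and shared, since
  hidden-layer randomness is the variance source the repetition targets.
  A flag re-runs fine-tuning per run if wanted.

## Synthetic data: what it does and does not emulate

`make_synthetic_cell_images` renders class `k` as `k+1` hue-coded
elliptical "nuclei" with size jitter on a pale textured background — enough
structure that classes are separable by color/shape statistics (a
mean-color nearest-centroid classifier exceeds 0.90 held-out accuracy,
which the suite verifies before trusting the fixture) while staying instant
to generate and bit-reproducible. `make_gaussian_features` places
unit-variance isotropic clouds at `separation · u_k` along fixed
orthonormal-ish directions. Neither fixture reproduces stain variability,
touching cells, focus blur, or the label noise of real smears; green tests
on fixtures demonstrate that the machinery is correct and deterministic,
not that real-data accuracy will match the reference tables.

## Problem sizes and numerical choices

The test suite and the acceptance script run at desk scale by choice:
feature-path pipelines use 4 × 120 samples at separation 10 with `Z = 400`
(macro accuracy ≥ 0.90 expected and achieved), GAN smoke runs use 16×16
images, 3 generator blocks, 8 base filters and 50 iterations, and
closed-form-optimality checks use 50 random 20×5 instances per variant.
Scores at exactly 0 or 1 entering the GAN value function are clamped to
`[1e-7, 1 − 1e-7]` with a warning. BatchNorm uses momentum 0.9 and
`eps = 1e-5`, with running statistics (never batch statistics) at
inference, so feature extraction is a pure function of weights and image.
Max-pool gradients split equally across tied maxima. All generators,
dropout masks, noise streams and batch orders derive from explicit integer
seeds, and pipeline reruns produce byte-identical report CSVs.

## Known limitations

- The numpy networks are CPU-bound and single-threaded beyond BLAS; the
  pipeline is not meant for ImageNet-scale trunks or datasets, and no
  pre-trained trunk weights ship with the package (the `TinyConvTrunk`
  stand-in is a frozen random trunk).
- GAN training at the reference resolution is slow at default iteration
  counts; the fixture preset is the practical default.
- No GAN sample-quality scoring (FID/IS), no conditional-GAN labels, no
  stacking or weighted voting, no confidence intervals on metrics.
- With fewer feature dimensions than classes the Gaussian fixture
  directions cannot be mutually orthogonal (documented "orthogonal-ish").
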