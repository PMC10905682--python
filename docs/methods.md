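# Methods

## Problem setting

The package predicts a binary histological label (lymphovascular invasion,
LVI) from three co-registered breast-MR volumes plus sixteen
clinico-radiological covariates, and compares four model families on the
same cohort: a clinico-radiological logistic model, a radiomics signature
built from a precomputed feature table, an image-only 3D CNN, and the
prior-conditioned 3D CNN that consumes the covariates as sixteen constant
image channels. Volumes are assumed resampled to 1 mm isotropic, so the
32 mm patch side equals 32 voxels; resampling itself (and registration and
VOI delineation, which are manual/tool procedures upstream) is out of scope.

## Synthetic cohort generator

Real LVI cohorts are private, so all experiments run on synthetic cohorts
with known planted structure.

**Covariates.** The sixteen features are drawn independently from marginals
matched to a published 239-patient training cohort (binary and ordinal
proportions taken from its counts; age ~ Normal(52, 9²) truncated to
[25, 85] years; axillary-node short-axis ~ Gamma(k=2, θ=0.3) cm, median
≈ 0.5). Independence is a simplification — the source reports only
marginals — and a `correlation_hook` lets users impose joint structure.

**Labels.** y ~ Bernoulli(σ(β₀ + Σ β_f x_f)) with default planted effects
β = log 7.5 (peritumoral edema), log 4.3 (DWI rim sign), log 2.1 (adjacent
vessel sign), zero elsewhere, mirroring the dominant univariate structure of
the reference cohort. The intercept β₀ is calibrated by monotone root
search so the cohort-mean probability equals the target prevalence
(default 59/239 ≈ 0.247) to 1e-6.

**Volumes.** Each case renders one additive ellipsoidal lesion (semi-axes
uniform in 4–8 voxels) at the VOI center of three 48³ background volumes,
with modality-specific lesion contrast (1.0, 0.7, 1.2). Two image-borne
signals are tied to the label-driving features: a bright shell at
normalized radius ≈ 1.25 on the third modality iff the DWI rim sign is
present (contrast 0.2), and a wider halo at radius ≈ 1.8 on the second
modality iff peritumoral edema is present (contrast 0.18). Gaussian noise
(sd 1.0) is added and intensities clipped at zero. One master seed fans out
to per-case substreams, so cohorts are reproducible and extensible.

The image signal-to-noise deserves comment. Image information about the
label flows only through the rim/halo renderings of two binary features, so
the image-only Bayes AUC is capped by the two-feature AUC (≈ 0.77 at
population scale, vs ≈ 0.79 for all three prior effects). The default
contrasts and noise are chosen so that recovering those features from
texture is genuinely partial for a small CNN trained on ~100 cases, while
the prior planes carry them exactly — the regime in which conditioning on
prior features should pay off. What passing the fusion experiment shows is
therefore that the architecture can exploit tabular information injected as
constant channels when that information is cleaner than the image evidence;
it does not show anything about real MRI texture, anatomy, or scanner
physics, which the renderer makes no attempt to model.

## Preprocessing

Per-volume intensity normalization clips negatives to zero and divides by
the volume maximum (all-zero volumes pass through); normalization happens
before cropping, and the non-commutativity of the two orders is pinned by a
test. Patches are half-open windows [c−16, c+16) per axis, zero-padded out
of bounds. Prior features are min-max scaled to [0, 1] on training rows
only (held-out values clipped; training-constant features map to 0) so the
constant planes are commensurate with image intensities. Multi-level
categorical features enter as single ordinal channels — the fixed 16-plane
layout leaves no room for one-hot expansion. Augmentation reverses each
spatial axis independently with probability 1/2, all 19 channels together,
so constant planes are invariant and labels are preserved. Stratified 7:3
splits support two per-stratum rounding rules (`floor_validation`, the
default, and `largest_remainder`) because realized published counts follow
no single rule.

## Network and training

Head: 3³ convolution to `head_channels`, channel-wise batch normalization,
ReLU, factor-`pool` max pooling. Body: `n_rcab` residual channel-attention
blocks at constant width, y = x + CA(conv(ReLU(conv(x)))), with the second
convolution zero-initialized so every block starts as the identity —
stabilizing small-data training. CA is a squeeze-and-excitation gate with
reduction `attention_reduction` (hidden width = channels/reduction); its
sigmoid keeps channel weights strictly in (0, 1). Tail: 1³ convolution to
2 classes followed by global average pooling and softmax. Reference
configuration: 19→64 channels, 4 RCABs, reduction 8, pool 2. Kernel sizes,
widths and pooling extent are configurable because the source architecture
fixes only the component inventory.

The layers are implemented in numpy (float32, NCDHW). 3³ convolutions run
in the frequency domain — rfftn over the spatial axes, channel contraction
as a batched matrix product per frequency bin, irfftn, then slicing to the
same-padded window; the weight gradient is the circular cross-correlation
of stored input spectra with the output-gradient spectra sampled at the
kernel lags, and the input gradient is the spectral product with the
unflipped kernel. On one CPU this outperforms im2col gathering by roughly
3× at these volume sizes and matches a direct-convolution oracle to 1e-5.
All gradients are verified against central differences in the test suite.

Loss: L = mean(−w_y log p_y), ε-clamped at 1e-12, with default
(w₋, w₊) = (0.25, 0.75); at equal weights it is half the unweighted
cross-entropy. Optimizer: Adam, β = (0.9, 0.999), no weight decay, no
schedule; lr 1e-4 and batch 48 (auto-clamped to the dataset size) for the
reference configuration. Training is fully deterministic given the config
seed (initialization from the model seed; shuffling and flip masks from the
trainer seed). Checkpoints: `min_train_loss` (the reference rule) or
`min_val_loss`; ties break toward the earlier epoch. Batch-norm running
averages are frozen at inference.

## Baselines

Univariate logistic fits use maximum likelihood with Wald standard errors,
CIs and p-values (Wald matches odds-ratio intervals that are symmetric on
the log scale); for a binary covariate the fitted OR equals the 2×2
cross-product ratio to machine precision, which the tests enforce.
Multi-level variables use ordinal 1..k trend coding — one printed OR per
variable implies one degree of freedom. Complete separation is flagged, not
silently estimated. The clinical chain screens at p < 0.1 and fits the
survivors jointly. The radiomics chain consumes a precomputed feature
table: z-score normalization (population sd, fit on training rows,
constant columns dropped with a warning), univariate filter at p < 0.01,
greedy correlation pruning at |r| ≥ 0.90 scanning features in ascending
univariate-p order (keeping the more label-associated member of a redundant
pair; Pearson when both columns pass a normality screen, Spearman
otherwise, logged per removal), then L1-penalized logistic regression over
a log-spaced penalty grid with λ* at the minimum mean 5-fold stratified
cross-validated deviance (ties toward the heavier penalty). Stage outputs
are nested by construction. No multiple-testing correction is applied at
any stage, matching the source procedure.

The reference-cohort per-level counts are embedded as input data
(`baselines.REFERENCE_COUNTS`). Expanding them per variable reproduces
every univariate fit exactly; the expansion's joint structure is arbitrary,
so multivariate fits on the expanded table are not meaningful and are not
used. Two covariates (age, node short-axis) are continuous with only
medians published; both have univariate p ≥ 0.4, so screening results are
unaffected by their absence from the expansion.

## Evaluation

AUC is the Mann–Whitney U statistic with midrank ties, identical to the
trapezoidal area under the empirical ROC curve (asserted to 1e-12).
Operating points maximize Youden's J with ties toward the lower threshold;
how the source chose its operating thresholds is unstated, so Youden is
adopted and documented. The DeLong paired test estimates Var(AUC_a −
AUC_b) from placement values (structural components) and refers
ΔAUC/√Var to a two-sided normal; identical score vectors return p = 1
with a degenerate flag. Calibration is checked three ways: exhaustive
pairwise comparison on random small instances, a 2000-replicate bootstrap
variance on n = 60, and a 2000-replicate null rejection rate at α = 0.05.

## The fusion-benefit experiment

`experiments.fusion_benefit_experiment` is the package's headline study,
sized for a single CPU: per seed, a 150-case cohort at the default
prevalence, effects and SNR; stratified 7:3 split; 32³ patches; a narrow
backbone (8 head channels, 2 RCABs, reduction 4, factor-4 head pooling);
batch 16, 15 epochs of Adam at lr 1e-3; and the 19-channel network against
the 3-channel ablation with identical seeds and schedules. At this cohort
size the 19-channel network overfits its 16-dimensional tabular input
within a few epochs while training loss keeps falling, so both networks use
`min_val_loss` checkpoint selection, applied symmetrically; selecting and
evaluating on the same validation fold inflates both AUCs equally and
leaves the paired difference interpretable. The experiment reports per-seed
validation AUCs, their means, paired DeLong p-values, and the trained
network's sensitivity to full spatial flips (reported, not asserted).

## Known limitations

- The generator's independence of covariates and geometric lesion model
  carry no anatomical realism; conclusions transfer to real data only at
  the level of architecture and pipeline correctness.
- Odds ratios from univariate fits of a multi-effect logistic model are
  attenuated by non-collapsibility; recovery tests therefore plant single
  effects.
- The numpy backbone targets desk-scale cohorts; it is single-device and
  unsuited to full-scale imaging studies.
- `min_train_loss` checkpoint selection — the reference rule and the
  trainer default — invites overfitting on small cohorts; the experiments
  use `min_val_loss` and say so.
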