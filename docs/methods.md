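# Methods

## The model

`proteobridge` addresses cross-platform proteomics imputation: two affinity
platforms (an antibody/PEA panel reporting NPX on a log2 scale, and an
aptamer panel reporting RFU) measure overlapping but non-identical probe
sets on the same plasma samples, and per-protein agreement between them is
often modest. The package learns a *joint* variational autoencoder over
paired measurements and uses it to predict either platform's full profile
from the other.

Let x_i^A ∈ R^{d_A}, x_i^B ∈ R^{d_B} be one sample's standardized profiles.
Two encoders produce diagonal-Gaussian posteriors in a shared latent space:

    (μ_•,i, log σ_•,i²) = f_enc^•(x_i^•),   • ∈ {A, B},  z ∈ R^{d_z}

Latent draws use the reparameterisation z = μ + σ ⊙ ε, ε ~ N(0, I). Two
decoders map z back to either data space, so z_A can be decoded by the B
decoder (cross-reconstruction) and vice versa. The training objective is

    L_total = λ_rec·L_rec + λ_KL·L_KL + λ_align·L_align + λ_cross·L_cross

with

* **L_rec** = (1/2N) Σ_i (‖x_i^A − x̂_i^A‖² + ‖x_i^B − x̂_i^B‖²) —
  self-reconstruction under a unit-variance Gaussian observation model;
* **L_cross** — the same form with x̃_i^A = f_dec^A(z_B,i) and
  x̃_i^B = f_dec^B(z_A,i);
* **L_KL** = ½(L_KL^A + L_KL^B), each term
  (1/2N) Σ_i [‖μ‖² + exp(log σ²) − 1 − log σ²] summed over latent
  dimensions — the closed-form KL to the N(0, I) prior;
* **L_align** — the unbiased U-statistic estimator of the squared maximum
  mean discrepancy between the two *aggregated posteriors* (one Monte Carlo
  draw per sample, the same draws that feed the cross term), with RBF
  kernel k_γ(u,v) = exp(−‖u−v‖²/2γ²). It may be slightly negative, as
  unbiased MMD² estimators are. γ is set per minibatch by the median
  heuristic over Euclidean distances in the pooled {z_A} ∪ {z_B} cloud
  (cross-platform pairs included, since that pooled set is what is being
  aligned; a flag restricts to within-set pairs). A 1e-8 floor guards the
  degenerate all-coincident batch.

Note the KL convention: the per-platform term carries the printed 1/2N
factor *and* the two platform terms are averaged with another ½. Any
constant-factor ambiguity is absorbed by λ_KL, which is tiny by design —
each sample contributes thousands of reconstruction errors but only d_z
latent dimensions.

Default weights: λ_rec = 0.90, λ_cross = 1.4, λ_KL = 1.4e-4, λ_align = 1.9.
These are stored in `LossWeights` and are ordinary tunables.

### Architecture

Each encoder/decoder is a three-layer residual MLP: an input projection to
the hidden width, one *dual-head residual block* (y = x + h₁(x) + h₂(x),
each head Linear → BatchNorm → ReLU → Dropout), and an output layer (two
heads, μ and log σ², for encoders). Defaults: hidden 512, dropout 0.1,
batchnorm on, d_z 128. All of this is `NetworkConfig`; setting
`activation="identity"`, `n_res_blocks=0`, no batchnorm/dropout yields a
purely affine network whose imputation map has a closed form — this
configuration is used throughout the tests as an analytic oracle. The exact
full-scale block dimensioning is a declared default, not a recovered one.

### Numerical core

The networks, losses and attribution run on a compact reverse-mode
automatic-differentiation engine over numpy arrays
(`proteobridge.autodiff`): tensors record their parents and a gradient
closure; broadcasting is inverted by summation; a single backward pass
differentiates the whole objective, or a model output with respect to its
inputs. The engine implements only the primitives the model composes
(arithmetic, matmul, exp/log/tanh/relu, reductions, clip, concat) and is
verified against central finite differences. log σ² is clamped to
[−15, 15] before exponentiation (standard VAE guard); batchnorm keeps
running statistics so eval-mode inference is batch-independent and defined
for single samples.

## Training protocol

AdamW (decoupled weight decay 1e-4, applied to weight matrices only) with
learning rate 4e-4, minibatches of 256 (capped at the training-set size),
Xavier/Glorot-initialised weights and zero biases, at most 200 epochs.
Data are split 60/10/10/20 into train / early-stop / tune / test (floor
each fraction, remainders assigned in declared order — deterministic and
exhaustive). Early stopping monitors the *total weighted loss* on the
early-stop split, evaluated deterministically with zero-noise draws
(z = μ); training stops after 10 epochs without improvement and the
best-epoch weights are restored (argmin of the early-stop loss, never a
later epoch). Minibatch order and noise draws are reseeded per epoch from
the master seed, so a fixed seed reproduces the run bit-identically.

Hyperparameter search (`tune_hyperparameters`) takes a declared space over
learning rate, widths, dropout and loss weights and scores each candidate
on the tuning split (total loss by default; median feature-wise
cross-imputation r by flag). The sampler is a seeded random search with an
exhaustive-grid option. After tuning, the recommended pipeline retrains the
winning configuration from scratch.

### The scaled-down reference study

All shipped end-to-end results use a desk-scale configuration chosen once:
the synthetic *medium* cohort (N = 3000 samples, d_A = d_B = 300 probes,
K = 30 latent factors, default noise), a reduced model (d_z = 16, hidden
128) and at most 60 epochs. At this schedule (~480 optimizer steps) the
small network takes a larger step size well; the reduced configuration
uses learning rate 3e-3, while 4e-4 remains the full-scale default. One
training run takes well under a minute on a single CPU.

## Preprocessing

The aptamer platform's RFU values are log2-transformed (strictly positive
input enforced, offending probes listed); the PEA platform is already on a
log2 scale. Both are then feature-wise Z-scored. Standardisation uses the
*sample* SD (ddof = 1) — a documented convention, as either choice is
defensible. Parameters are fit on the training split only and applied to
all splits (a `fit_on="all"` flag mimics fit-on-everything). Zero-variance
probes are an error listing the probes, not a silent drop, so the feature
universe is always explicit. Missing values: evaluation paths drop whole
samples (with a count); training paths error.

**Own-distribution rule.** Standardisation parameters applied to a cohort
are always fit on that cohort's own distribution. `apply_external` fits on
the external cohort itself, requires every model input probe to be present
(no silent zero-fill), and can de-standardise the imputed output into
target-cohort units. `guard_cohort_params` refuses foreign parameters
unless explicitly overridden.

## Imputation

The default point estimate decodes the posterior mean
(x̂^B = f_dec^B(μ_A(x^A))) — the lowest-variance deterministic prediction.
`mode="sample"` decodes one seeded reparameterised draw for uncertainty
exploration. Correlation-based evaluation is done on the standardized
scale (Pearson r is scale-invariant); de-standardisation is available for
effect-size analyses.

## Baselines

**KNN.** For each query, the k nearest training samples in source space
contribute a Gaussian-kernel-weighted average of their target rows,
w_j = exp(−d_j²/2h²); if all weights underflow the average falls back to
uniform over the k neighbours. k and h come from 5-fold CV maximising the
mean held-fold median feature-wise r; the bandwidth grid is
{0.5, 1, 2, 4} × the median nearest-neighbour distance (the reference
full-panel operating points are k = 15 for PEA→aptamer and k = 30 for the
reverse).

**WNN/sPCA.** (1) PCA per modality (100 components, lowered with a warning
when the data cannot support it). (2) Per-sample modality weights in the
Seurat-v4 spirit: for each modality, the sample's embedding is predicted
from its own k = 20 neighbours (within) and from the other modality's
neighbours (cross); Gaussian affinities of those two prediction errors
(per-sample bandwidth = distance to the 20th neighbour) form a ratio score
regularised by 1e-5, and a softmax over the two modalities yields weights
in [0, 1] summing to 1. Duplicated modalities get exactly 0.5 by symmetry;
an uninformative modality is down-weighted. (3) A core graph per sample:
candidates are the union of 400 nearest neighbours from each modality,
scored by the modality-weighted sum of per-modality Gaussian affinities,
refined to the 40 best; the +1e-5-regularised weights are normalised so
smoothing rows sum to one exactly. PCA of the smoothed data gives the
supervised-PCA basis per platform. (4) A Gaussian-kernel regressor over
the 50 nearest training samples in source sPCA space predicts target
values; its bandwidth is the median distance to the 50th neighbour.
Formula-level parity with the R/Seurat release is out of scope; the
implementation is held to its symmetry and ordering properties.

**Permuted control.** Platform B's rows are shuffled by a seeded
permutation: each modality's covariance is preserved exactly while the
cross-platform pairing is destroyed. On concordant synthetic data at
N = 500 the median per-probe |r| of this control is well under 0.1.

## Evaluation battery

Per-probe r (across samples) and per-sample r (across probes) with
undefined correlations (constant vectors) excluded and counted, never set
to 0. Distribution comparisons: Mann-Whitney U, Levene, paired win-rate
with a two-tailed binomial test, Wilcoxon signed-rank. PCA diagnostics fit
on the measured data only and project imputed matrices onto those PCs,
with seeded k-means (k = 6) cluster colours.

Phenotype associations adjust for sex and age: continuous phenotypes are
residualised on sex + age and then fit per probe by OLS (residualising a
binary outcome is ill-defined, so binary phenotypes keep sex + age as
covariates in a per-probe logistic model; the effect is the protein
log-odds). q-values are Benjamini-Hochberg within each phenotype across
probes (a flag for a global family exists); significance at 5% FDR.
Concordance between measured-data and imputed-data results: MAE and
Pearson r of effect estimates over truth-significant pairs, and recovery =
|truth-sig ∩ imputed-sig| / |truth-sig|, stratified by truth-hit counts.

**Meta-analysis.** Samples are randomly assigned to two pseudo-cohorts
(repeated; seeded): cohort 1 keeps native target-platform data, cohort 2
only source-platform data. *Classic* tests each cohort on the probes
shared across platforms (cohort 2 on its native source measurements) and
combines per-probe z-scores by unweighted Stouffer (equal pseudo-cohort
sizes; weights optional). *Imputation-separate* imputes cohort 2 into the
target platform, tests it separately, and z-combines. *Imputation-combined*
concatenates imputed cohort 2 with cohort 1 and tests once. Truth is the
analysis of the full native target data; recovery is per phenotype at 5%
FDR. Because the probe overlap is partial, classic meta-analysis cannot
reach associations outside the shared panel — the structural advantage the
imputation workflows quantify.

## Interpretability

The analysed function is the deterministic mean-path imputation. For each
output probe, per-sample attributions over input probes are computed
against a baseline input — the zero vector, i.e. the cohort mean in
standardized units — and aggregated as the mean absolute attribution,
giving the directed importance matrix I_{q→p} restricted on both axes to
one-to-one mapped probes. Three methods are provided on the autodiff
engine: gradient × input (which coincides with DeepLIFT's Rescale rule on
locally linear maps), integrated gradients (midpoint rule; satisfies
completeness), and gradient SHAP (noisy background baselines, seeded). On
an affine model all three agree up to rank.

Self-importance is the diagonal read through the probe map;
cross-importance the off-diagonal. Symmetric pair scores take the maximum
|importance| over both directions and both orders; an optional family rule
(regex, default: strip trailing digits) merges same-prefix probes by max.
Enrichment against a reference edge set (e.g. STRING pairs pre-mapped to
probe IDs; self-edges removed; restricted to matrix probes) uses
precision-recall over 16 logarithmically spaced thresholds from the
maximum score down to the smallest *positive* score (log-spacing cannot
reach 0), with AUPRC by trapezoid over recall-sorted points. Note the
curve starts at the recall attained by the most stringent threshold, so a
perfect separator's AUPRC approaches 1 only as the positive count grows.
Significance: membership labels are re-drawn uniformly over all unordered
non-self mapped-probe pairs (positive count preserved), the full PR curve
is rebuilt each iteration, and p = (k + 1)/(n + 1) with k the number of
null AUPRCs ≥ observed. Node importance is the mean per-column rank of
each input (ties get the average rank), with a cumulative edge-density
enrichment over the node-score ordering.

## Synthetic data

The generator plants everything the pipeline is later asked to recover.
Latent factors Z ~ N(0, I_K) load sparsely onto each platform: every probe
has one dominant factor (Zipf-weighted assignment, P(k) ∝ 1/(k+1), so
factor "modules" have realistically unequal sizes and the covariance
spectrum decays) plus 0–2 minor factors at 30–50% weight. Concordant
probes share identical loadings across platforms; their expected
cross-platform r under the linear generator is

    r = (w_A·w_B) / sqrt((‖w_A‖² + σ_A²)(‖w_B‖² + σ_B²))

Per-probe noise SD is noise_level × ‖w‖ with U(0.6, 1.4) jitter; at the
default noise_level 0.5 the expected concordant r is 0.8 on average,
comparable to real cross-platform agreement. A configurable fraction of
probes is *discordant* (platform-A loadings on factors disjoint from the
B support — probe pairs that nominally measure the same protein but track
different species), and the probe correspondence covers only a fraction
(default 0.6) of probes, as real panels overlap partially. Planted edges
are concordant probe pairs sharing a dominant factor. Phenotypes are
factor-driven (y = Zc + 0.5·sex + 0.02·age + ε; binary via a logistic
link), with the truth set recorded as the shared target-platform probes
whose dominant factor drives the phenotype. A second-cohort generator
reuses the loadings with fresh latent draws and location/scale shifts.
Matrices are returned on vendor-like scales (additive log2-like for A,
2^(raw+10) for B) so the preprocessing path is exercised end to end.

What the generator does **not** emulate: batch/plate effects, limits of
detection, heavy-tailed assay noise, genotype-driven structure, or
vendor-realistic signal distributions. An optional tanh saturation mimics
dynamic-range compression, but the shipped results use the linear
generator. Passing tests therefore demonstrate correct recovery of the
planted statistical structure, not performance on real cohorts.

## Known limitations

* The engine is CPU/numpy; it is sized for the desk-scale study, not for
  full panels with thousands of probes and hundreds of latent dimensions.
* The thresholded PR convention truncates the curve at the most stringent
  threshold's recall (see above); compare AUPRCs only within the same
  convention.
* Logistic association fits fall back to NaN on separation failures rather
  than penalised estimation.
* Formal predictive intervals for imputed values are not provided;
  `mode="sample"` exposes posterior variability only.
* The two-head design is fixed; extending to more than two modalities
  would add one encoder/decoder pair per platform and generalise the
  alignment term to pairwise MMDs.
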