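# Methods

This note documents the models and procedures implemented in `aiopheno`,
the defaults chosen where the design was open, and what the synthetic-data
tests do and do not demonstrate.

## Population-structure correction

**Model.** Accessions from a structured germplasm panel share ancestry;
uncorrected, subpopulation membership confounds SNP–phenotype association.
The correction treats structure as a discrete grouping:

1. *Similarity.* s_ik = (1/m) Σ_j 1[x_ij = x_kj], the fraction of SNPs with
   identical dosage calls; equivalently 1 − Hamming distance / m. Computed
   as Σ_{g∈{0,1,2}} (X=g)(X=g)ᵀ / m to avoid the n²×m comparison tensor.
   Missing calls must be imputed first (per-SNP mode; ties toward the lower
   dosage) — the imputation is explicit, never silent.
2. *Embedding.* Classical MDS: eigendecomposition of B = HSH with
   H = I − (1/n)J Jᵀ. Only positive eigenvalues are retained; the all-ones
   direction is annihilated by H and never appears. Coordinates are
   eigenvectors scaled by √λ, so the coordinate Gram matrix reconstructs B
   restricted to the retained components. Default dimensionality: the
   smallest L whose eigenvalues cover ≥ 90% of the positive-eigenvalue
   mass, capped at 20 (structured panels concentrate variance in few axes;
   the cap keeps k-medoids distances meaningful).
3. *Clustering.* PAM-style k-medoids with a deterministic greedy BUILD step
   and exhaustive SWAP phase, ties toward the lowest index — the algorithm
   uses no randomness at all, so runs are exactly reproducible. The cluster
   count c is chosen over c = 1…c_max (default 10) at the maximum discrete
   second difference of within-cluster dispersion W(c); if W(1) ≈ 0
   (identical points) or the dispersion curve has no elbow, c = 1.
4. *Adjustment.* The phenotype is residualized on cluster-membership
   indicators, which equals per-cluster mean-centering; the residual is by
   construction orthogonal to every indicator. Adjustment is applied
   **within each environment** — pooling environments would let climate
   differences masquerade as structure. Only the phenotype is adjusted, not
   the genotype matrix. A single-member cluster residualizes to exactly 0
   and triggers a warning, since that accession then carries no signal.

## SNP selection

**Forest.** A regression random forest (the adjusted phenotype is
continuous) with out-of-bag R² as the internal quality measure.
Hyperparameters (n_estimators, max_depth, min_samples_split,
min_impurity_decrease, max_features) can be tuned by Bayesian optimisation:
a Gaussian-process surrogate (Matérn 5/2, unit-cube encoding) with
expected-improvement acquisition over random candidate batches, default
budget 50 evaluations, 10 of them random initialization. Tuning is off by
default in the selection estimator — for the panel sizes the tests use,
fixed sensible defaults (300 trees, sqrt feature subsampling) recover
planted signals as reliably as tuned forests at a fraction of the cost, and
the selection pipeline's correctness does not depend on the tuner.

**Importance measures.**

* *Gini (mean decrease impurity)* — per-SNP sum of variance reductions over
  all splits, averaged over trees, normalized to sum to 1.
* *SHAP* — exact path-dependent tree Shapley values, computed by the
  polynomial-time traversal that carries "one/zero fraction" permutation
  weights down each root-leaf path (numba-compiled; a pure-Python path of
  the identical code is used to cross-check the compiled one in tests).
  The conditional expectation for absent features is the tree's own cover
  distribution, so local accuracy Σ_j φ_j(x) = f(x) − E[f] holds to
  machine precision — asserted against brute-force subset enumeration on
  small trees. The global score is mean |φ| over accessions; subsampling
  accessions (`shap_sample`) trades only the Monte-Carlo precision of that
  mean, not the exactness of any individual attribution.
* *Boruta* — each iteration appends a column-shuffled shadow copy of every
  SNP, fits a forest on the doubled matrix, and scores a hit for every real
  SNP beating the best shadow importance. After max_iter (default 25;
  ≥ 10 enforced) iterations a two-sided binomial test at α = 0.05
  classifies SNPs as confirmed / rejected / tentative. Tentative SNPs are
  excluded from the selected set (conservative).

**Thresholding.** Gini and SHAP rankings are cut at the maximum discrete
second difference of the descending score curve; scores equal to the cutoff
value are included; ties in the second difference break toward the earliest
index. Note a deliberate property of this rule: it is stable to adding
another clearly-important score *within* the existing range, but an extreme
outlier far above the range creates a new dominant drop at the top and
legitimately shrinks the selection — the elbow then separates the outlier
from everything else.

**Set algebra.** cross = A∩B∩C; union = (A∩B) ∪ (A∩C) ∪ (B∩C), i.e. SNPs
found by at least two of the three methods. The union-of-pairwise reading
(rather than A∪B∪C) is a configuration choice: `combine_sets` takes the
three sets explicitly, so either rule is one expression away.

## AIO encoding

A 6 × (⌈K/6⌉ + 25) × 3 uint8 image per accession × environment.

* Genotype block: SNP k occupies row k mod 6, column k div 6 (column-major
  fill — the fill order is a convention of this format, recorded as a
  version tag `aio-v1-colmajor` in the PNG sidecar, because it is not
  recoverable from pixel content). Dosage one-hot: 0 → (255,0,0),
  1 → (0,255,0), 2 → (0,0,255); padding cells black.
* Climate block: row = factor (fixed order: day length h, min temp °C, max
  temp °C, precipitation mm, humidity %, solar radiation MJ/m²), column =
  day d + 4 for d ∈ {−4,…,+20} (the window starts 4 days before planting).
  v = round(|f|); R = v div 255, B = v mod 255, G = 0 if f > 0 else 255.
  Magnitudes up to 65 279 are encodable; the sign flag covers f ≤ 0, where
  div/mod would otherwise be ambiguous. Decoding recovers sign·v exactly.
* Channels are stored 8-bit; the network input divides by 255, making the
  one-hot genotype channels exactly 1.0.

The two pixel vocabularies overlap only at (0,0,0) (padding) vs a climate
pixel with R = B = 0 — resolved purely by block position, never by content.

## CNN classifier

Layers: 3×3 convolutions with shape-preserving same padding and stride 1;
2×2 max pooling with floor semantics (a trailing odd row/column is dropped:
height 6 → 3 → 1); optional per-channel batch normalization; flatten; dense
head with one output per flowering-time class. Loss is categorical
cross-entropy −Σ T_i log S_i on the softmax; optimizer Adam (lr 10⁻³).
The two reference architectures — conv(10)/pool/conv(50)/pool/flatten/
dense(45)/dense(classes) for 90-SNP images and conv(7)/…/conv(42)/… for
17-SNP images — carry 28 065 and 16 849 trainable parameters respectively
at widths 40 and 28; `count_params` computes these closed-form and
`build_model` asserts the built network matches.

**Protocol.** 90/10 stratified train/control split; stratified k-fold
cross-validation (default 10 folds, 100 epochs, validation_split 0.2 of the
training part as a per-epoch monitor); the best model over folds is the one
with maximal validation accuracy. Classes rarer than the fold count are
merged into their nearest populated neighbor for stratification only, with
a warning. Architecture tuning (`tune_architecture`) evaluates a discrete
candidate space (filter counts, activation, batch-normalization flag) by
short training runs under a fixed seed and budget.

**Evaluation.** Multiclass accuracy; per-class TP/TN/FP/FN; per-accession
error in days. The day value of a class is its **maximum** (the class
definition is "maximal time to flowering", so the bound is the class's
canonical representative); midpoints are available via
`representative="midpoint"`. Median absolute day error is reported, plus
Mann–Whitney U and Wilcoxon W rank tests comparing train vs validation
error distributions (identical constant samples short-circuit to p = 1,
where the test statistics are degenerate).

**Determinism.** All randomness (init, shuffling, splits) flows from the
config seed. Single-threaded NumPy runs reproduce bit-for-bit; with
threaded BLAS, floating-point reduction order may vary at the 1e-6 level.

## Explanation methods

* *Saliency* — |∂ logit(target class)/∂ input|, reduced over channels by
  max (L2 optional), normalized to [0,1] by the map's maximum; an all-zero
  gradient stays an all-zero map. Logits rather than softmax outputs are
  differentiated, so saturation of the softmax does not mask structure.
* *Score-CAM* — gradient-free: each activation map of a chosen convolution
  layer (default: the last) is upsampled to the input size with
  nearest-neighbor interpolation (preserving the blocky AIO geometry —
  maps are read pixel-wise, and bilinear smoothing would bleed attribution
  across the genotype/climate block boundary), min-max normalized, used to
  mask the input multiplicatively (all-zero baseline), and scored by a
  forward pass on the target class; softmax weights over the maps combine
  them, followed by ReLU and max-normalization. Constant activation maps
  are skipped (a warning and a zero map if all are constant).
* Maps are computed per accession and averaged elementwise per
  flowering-time class. `block_attribution_summary` splits a map's mass
  between the genotype and climate blocks — padding pixels excluded — and
  ranks pixels annotated with their SNP index or (factor, day).

## Synthetic data generator

The generator emulates the statistical shape of a multi-environment
flowering-time study: defaults of 1775 accessions, 5 subpopulations, 500
SNPs, 6 environments, phenotype clipped to [25, 120] days.

* *Genotypes* — Balding–Nichols divergence: ancestral frequency
  p ~ U(0.1, 0.9) per SNP; subpopulation frequency
  ~ Beta(p(1−F)/F, (1−p)(1−F)/F) with divergence F (default 0.1, enough
  for MDS + k-medoids to recover the subpopulations at ARI ≥ 0.9);
  dosages Binomial(2, p_s).
* *Climate* — day length from a smooth seasonal curve; temperatures as an
  AR(1) series with Tn < Tx enforced; zero-inflated gamma precipitation;
  humidity clipped to [0, 100]; positive solar radiation. All values are
  within the AIO-encodable range by construction.
* *Phenotype* — days = baseline + Σ additive SNP effects (centered) +
  Σ climate-summary effects + G×E terms + Gaussian noise, rounded and
  clipped to [25, 120]. Climate enters through window summaries (mean max
  temperature, total precipitation, mean day length) so the climate block
  of the AIO carries learnable signal; G×E terms couple a causal SNP's
  dosage to a summary. `noise_sd_for_heritability` calibrates the noise SD
  to a target narrow-sense h² from the simulated genetic variance.

**What the generator does not emulate:** linkage disequilibrium and
recombination maps (causal SNPs are independent of their neighbors —
real panels would surface correlated proxies alongside true signals),
admixed individuals (structure is discrete), genotyping error, and
missing-call patterns of real assays. Passing tests therefore demonstrate
that the pipeline's machinery is correct and that signals of the planted
form are recoverable — not that any particular real dataset has such
signals.

## Problem sizes in the test suite

Verification runs use scaled-down study shapes chosen to exercise every
code path with comfortable statistical margins: planted-SNP recovery at
n = 800 accessions × 500 SNPs with 5 causal SNPs at h² ≈ 0.5 over 10 seeds;
CNN learnability at 1500 AIOs (250 accessions × 6 environments) with
classes driven by 3 SNPs and one climate summary over 5 seeds; explanation
faithfulness on 12-SNP panels over 5 seeds. These sizes were fixed before
the thresholds were measured and are not tuned to them.

## Known limitations

* The selection stage ranks SNPs marginally through forest importances; in
  strong LD it selects representatives, not causal variants.
* The CNN sees only the 25-day window; phenology driven by later-season
  climate is out of scope by design.
* k-medoids with the exhaustive SWAP phase is O(c·n²) per iteration —
  adequate to a few thousand accessions, not to biobank scale.
* Path-dependent SHAP conditions on the tree's own cover distribution;
  under strongly dependent features its attributions differ from
  interventional Shapley values.
* Bit-exact training reproducibility assumes single-threaded execution;
  see Determinism above.
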