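# Methods

## Model and objectives

Each modality has an independent volumetric encoder (no weight sharing): a
DCGAN-style stack of kernel-4, stride-2 convolutions that halves the spatial
extent per block while doubling channels, followed by a full-extent
convolution to the d-dimensional global vector z.  With the default base of
32 channels a 64³ input yields a layer-3 local map of 128 channels over
8×8×8 locations; the block count adapts so that a 16³ input still has three
blocks (local map 2³).  Weights are Xavier-uniform with activation-matched
gain; encoder activations are leaky rectifiers (slope 0.2).

Mutual information between representation pairs is estimated by InfoNCE with
a scaled dot-product critic f(x, y) = xᵀy/√d.  The printed form of the
critic is ambiguous between division by d and by √d; we default to √d (the
scaled-dot-product convention, keeping score variance O(1) in d) and expose
the divisor.  The positive pair is excluded from the denominator sum, as
printed; a flag restores the conventional include-positive estimator (whose
value is bounded by log N).  Scores are clipped to c·tanh(s/c) with c = 20
and penalized by λ·mean(f²) with λ = 4e−2; the penalty is computed on raw
(pre-clip) scores and attaches to every InfoNCE term but not to CCA or
reconstruction terms.  Negatives come only from the same batch.

The four principal objectives — CR (intra-modal local↔global), XX
(cross-modal local↔global), RR (cross-modal global↔global), CC (cross-modal
local↔local with one location of the other modality sampled uniformly per
step) — compose by summation; symmetric composition computes both modality
orderings and sums them (the symmetric `loss_rr` convenience function sums
likewise, so a single-term composition equals the standalone loss plus the
regularizer).  The CCA term is the negative nuclear norm of the whitened
cross-covariance with ridge 1e−3 on both covariance diagonals — the
eigendecomposition-based analytic gradient avoids the numerical instability
canonical-correlation objectives are known for.  The reconstruction term is
the batch-mean per-sample squared Euclidean error of a transposed-convolution
decoder whose final activation is a sigmoid.

Local features are projected into the global d-dimensional space by a
residual 1×1×1-convolution block (two-layer path plus an identity-initialized
skip path); global vectors optionally pass a projection head with −1 (none),
0 (linear) or 1–3 hidden layers before scoring.  Probing and CKA always use
the pre-head z.

## Training protocol

Volumes are min–max rescaled to [0, 1] per volume (a constant volume maps to
zeros by convention), reflect-padded by 8 voxels and randomly cropped back to
the input size (crop offsets independent per modality by default; a flag
shares them).  The optimizer is RAdam, default lr 4e−4, default 500 epochs,
batch 16 at full scale.  After each epoch the training objective (penalty
included) is evaluated on the validation split — labels are never consulted
— and the 10 best checkpoints are retained; one checkpoint covers both
encoders of a multimodal objective.  Checkpoint selection for reporting takes
the argmax over checkpoints of the cross-modality mean probe metric, ties
broken toward the later epoch.

## Evaluation

*Linear probe.* Elastic-net logistic regression (SAGA) on frozen z, with C
log-uniform on [1e−6, 1e3] and the mixing parameter uniform on [0, 1],
selected on the validation split by ROC-AUC (binary) or macro one-vs-one
ROC-AUC (three classes; mean pairwise AUC over ordered class pairs, hence
insensitive to class imbalance).  The search is a seeded random search with
a 500-trial default budget (25 in tests).  Features are standardized with
training-split statistics before the solver — this affects only solver
conditioning, not the protocol.  Label efficiency retrains only the probe on
stratified nested subsets of 10/25/50/75/100 % of the training labels.

*Alignment.* Linear CKA, ‖Z_kᵀZ_m‖²_F / (‖Z_mᵀZ_m‖_F‖Z_kᵀZ_k‖_F), computed
after column centering (the uncentered ratio is not the cited statistic; a
flag disables centering).  An independent n×n Gram-matrix HSIC-ratio route
serves as a cross-check.

*Saliency.* Integrated gradients of each chosen representation dimension
(dimension selected by the largest positive and negative probe coefficients
by default), midpoint-Riemann discretized with 50 steps by default from an
all-zero baseline, both configurable.  A "cohort-mean" baseline (the
voxel-wise mean over the analysis subjects) is available and is what the
recovery studies use: because min–max rescaling leaves a constant intensity
offset at every voxel, zero-baseline attributions of a group-separating
dimension carry a small but consistent group shift *everywhere* — and a
rank statistic is blind to magnitude, so diffuse shifts can outrank the true
effect.  Subtracting the cohort mean cancels the attribution mass shared by
all subjects and localizes the maps on subject- and group-specific
deviations.  Signed attributions are kept as one map.  Maps are Gaussian-smoothed (σ = 1.5 voxels, reflect boundaries),
masked, compared voxel-wise between groups by a two-sided Mann–Whitney test
(normal approximation with tie and continuity corrections), thresholded by
Benjamini–Hochberg FDR at 0.05 across voxels per dimension, and summarized
per atlas ROI by the significant voxel of maximal |RBC| with its sign
(RBC = 2U/(n₁n₂) − 1; positive means the case group's attributions are
stochastically larger).  Voxels constant across both groups are declared
null (p = 1, RBC = 0).

*Links.* Spearman correlations between all latent-dimension pairs across
modalities, separately per group; within-group Benjamini–Hochberg FDR at
0.05; then a Fisher z-test z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))
over **all** d² entries, uncorrected — link counts therefore behave like
α·d² under the global null, which is documented, deliberate protocol
fidelity (an optional flag adds FDR on the z-test p-values).  Pairing takes,
per dimension, the strongest significant positive and negative correlation
(significance = z-test AND stage-1 FDR in the diagrammed group), in both row
and column directions; each paired dimension is represented by its top-|peak
RBC| ROI, and edges (weighted by the diagrammed group's correlation) are
sorted by |weight| with deterministic tie-breaks and truncated to the top
64.  Duplicate ROI pairs from different dimension pairs are kept as parallel
edges.

## Synthetic data

The generator emulates the structure the framework assumes: per subject,
shared factors u ~ N(0,1) load smooth Gaussian-blob patterns in both
modalities, modality-unique factors load one; a case-group mean shift of
amplitude 2.0 (in voxel-noise SD units, the generator's effect-size unit) is
added to designated atlas ROIs (ROI 1 in modality 1, ROI 2 in modality 2 by
default), ROI-mean-normalized so the planted ROI-mean group difference
equals the amplitude exactly; i.i.d. N(0, 1) voxel noise sits on a fixed
smooth anatomical background.  The toy atlas is a seeded arrangement of
disjoint boxes with ≥1-voxel gaps.  An optional third class is a mixture of
mild effects at random ROIs, emulating a heterogeneous long-tailed cohort.

The optional cross-modal link plants a factor with voxel-visible loadings
(1.5 noise-SD, matching the other factors) in ROI r₁ of modality 1 and ROI
r₂ of modality 2; the modality-1 loading flips sign in the case group, so
the within-group latent correlation is +r for controls and −r for cases —
group-discriminative by construction while leaving group means in those ROIs
untouched.  The target ROI-mean correlation is met analytically by
decorrelating the two modality factors after accounting for ROI noise-mean
attenuation.

Two constant intensity reference regions (a dark corner, a bright core) pin
each volume's minimum and maximum.  Real preprocessed anatomy has stable
extreme-intensity structures; without them, a volume's min–max rescale
factor is an extreme statistic of the noise — and of the group effect —
which both injects multiplicative noise across all voxels and leaks group
information into the global intensity scale, corrupting the attribution
analysis.  The generator is bitwise reproducible from its seed.

What the generator does **not** emulate: registration error, scanner/site
effects, spatially correlated physiological noise, nonlinear
intensity/anatomy interactions, and class-dependent covariate structure.
Passing recovery tests therefore demonstrate correctness of the machinery on
data satisfying the model's assumptions, not performance on real cohorts.

## Desk-scale configuration and problem sizes

Tests and the acceptance run use 16³ volumes, 8 base channels, 16 latent
dimensions, batch 32, lr 4e−3, padding 2/crop 16, and float32 arithmetic
(`EncoderConfig.desk()`), with 400 subjects for probe/alignment studies and
200 for the interpretability studies; pre-training runs 25 epochs for
alignment studies, 30 for probe studies and 40 for interpretability (the link factor needs the
longest to be encoded).  At this scale batch normalization is omitted: with
small cohorts its cross-sample coupling slows the contrastive objectives and
inflates the random-encoder CKA baseline; at full scale (64³) it remains the
default, following the reference architecture family.  Integrated-gradient
recovery runs use 8 path steps and 40 subjects per group — localization is
insensitive to more of either, while the completeness identity is verified
separately at 512 steps.  Float64 is the default everywhere else; all oracle
comparisons (1e−8 to 1e−12 tolerances) run in float64.

## Numerical choices and degenerate inputs

Masked log-sum-exp is max-shifted; the CCA gradient handles near-degenerate
eigenvalue pairs by the limiting difference quotient; correlations at |r| = 1
are clamped to 1 − 1e−7 (with a warning) before the Fisher transform;
constant columns yield ρ = 0, p = 1 in Spearman matrices; empty p-value
vectors give empty rejection masks; ROIs without significant voxels are
omitted from peak tables, and dimension pairs lacking ROI assignments are
dropped from link graphs with a warning.

## Known limitations

Pure-numpy training is single-threaded and memory-bound; full-scale (64³,
500-epoch) runs are out of desk reach, so the full-scale protocol is
implemented and unit-tested but its published-scale results are not
reproduced here.  The probe's random hyperparameter search replaces a
Bayesian optimizer; at the tested budgets the difference is negligible.
Only two modalities are supported per composition (the types permit more).
Model-comparison statistics across many objectives (rank tests with
multiplicity control) are out of scope.
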