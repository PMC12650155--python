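# Methods

This note documents the models implemented in `dcban`, the choices made
where the design was genuinely open, the numerical conventions, and what
the synthetic-data validation does and does not establish.

## Decoding model and assumptions

The decoder assumes a linear map from voxel responses to stimulus
features, `Y = Xβ + noise`, with `β` well approximated within a low-rank
voxel subspace. All three stages inherit that assumption:

* the nested network extracts a rank-`d` voxel basis, `d` being the PCA
  dimensionality of the targets;
* the fractional ridge solve shrinks componentwise in that basis, which
  is exactly classical ridge when the basis is the SVD of `X`;
* the conditioning schedule treats the decoded condition tensor as a
  noisy estimate whose influence should scale with its reliability and
  decay over sampling time.

Fraction semantics: δ (requested) and γ (achieved) are the ratio
‖regularized coefficients‖ / ‖OLS coefficients‖, so δ = 1 is the OLS
limit (α = 0, no regularization) and δ → 0 is total shrinkage. The
estimator maps δ = 1 to α = 0 exactly rather than to the smallest grid
point, so the no-regularization contract is exact.

## Nested low-rank network

**Layer shapes.** The per-layer MSE compares every layer output with the
PCA-reduced targets, so all layer outputs are kept at samples × d: a
trainable voxel→d input adapter produces `T₀`, layers 1..L−1 are width-3
one-channel convolutions *along the component axis* (zero padding 1), and
the final layer is fully connected d→d. The convolution axis was an open
choice; sliding along the component axis is the only option that keeps
the per-layer loss well-typed without inventing a spatial voxel geometry.

**What `Xlowrank` is.** The end-to-end *map* (adapter ∘ conv maps ∘ FC),
shape voxels × d — not the final activation matrix. The downstream
back-projection `β = V β̃_RR` requires `V` to be voxels × d, which forces
this reading. With the default identity activation the map is exact; the
ReLU mode (experimental) returns the training-set-averaged Jacobian.

**Gradients.** The leading singular pair of each `Tᵢ` is recomputed every
step but treated as a constant inside the loss (no gradient through the
factorization); differentiating through an SVD is unstable near
degenerate spectra, and the factorization is a forward measurement
feeding the loss. The leading pair uses a full SVD up to dimension 512
and 100-step power iteration (tol 1e−8) above; the sign is fixed by
making the first nonzero entry of the left vector positive so repeated
runs agree bit for bit.

**Loss balance and learning rate.** The matching term `(fᵀTg)²` is a
squared singular value — it scales like the *sum* of squared matrix
entries — while the data-fit term is an element *mean*. For the data-fit
quadratic to dominate the (concave) matching term, the weight ε must
exceed `L·n·d`; `eps_weight="auto"` selects `2·L·n·d`. With ε at the
default of 1 the matching term dominates the gradient
elementwise and training inflates the leading singular direction instead
of fitting the targets. Separately, Adam's per-step displacement is
bounded by ≈η per coordinate, so a 200-epoch full-batch run at the
default η = 1e−3 cannot traverse the O(1) distance from a small random
init to the least-squares adapter; the scaled validation configuration
uses η = 0.05. The stock settings (η = 1e−3, ε configurable, L = 57)
remain the config defaults.

**Sign of β₂.** β₂ defaults to −1 even though the magnitude term acts as
a penalty on the singular-vector norms — with unit singular pairs the
term is constant either way; the sign is configurable, and a positive β₂
triggers a runtime warning.

**Basis extraction.** `λⱼ` is the Euclidean norm of column j of
`Xlowrank` and `V` its normalized columns (zero columns stay zero with
λⱼ = 0). The induced sample basis is `uⱼ = Xvⱼ/‖Xvⱼ‖` over the training
responses: projecting targets as `Ỹ = UᵀY` restores the standard
singular-space geometry (the printed form `VᵀY` is dimensionally
inconsistent) while preserving λ and V everywhere else. Note a deliberate
asymmetry: the learned λ are *not* `‖Xvⱼ‖`, so in learned-basis mode the
componentwise "OLS" solve is scale-biased relative to exact OLS; in
classic mode the two coincide exactly, which is the bridge used by the
oracle tests.

**PCA dimensionality.** Default: smallest component count explaining 99%
of target variance, capped at 512.

## Fractional ridge with adaptive grid refinement

**α grid.** Log-spaced from `log₁₀(SMALL_BIAS·σ²_min)` to
`log₁₀(BIG_BIAS·σ²_max)` with step 0.2. The default biases
(SMALL_BIAS = 1e−2 > BIG_BIAS = 1e−3) invert the endpoints whenever
`σ_max/σ_min < √10`; the implementation orders endpoints ascending and
warns. A consequence of those biases is that the grid tops out at
`1e−3·σ²_max` — deep inside the weak-shrinkage regime (γ ≈ 1
everywhere). The fraction→α inversion therefore extends the curve grid
geometrically, one log-step at a time, until it brackets
γ ∈ [≈0.005, ≈0.999] before interpolating; a target outside the achieved
range still clamps to the nearest endpoint with a warning.

**Surrogate.** Gaussian process with squared-exponential kernel, fixed
hyperparameters (amplitude 1, length scale 1, observation noise 1e−6),
no marginal-likelihood refitting — determinism preferred over adaptivity.
Validation errors are z-scored before fitting so the unit prior amplitude
is appropriate; Cholesky solves escalate jitter (to 1e−4 relative) before
declaring the Gram matrix non-PD. Expected Improvement compares the
*predicted* means of candidate and incumbent (not the observed best), and
the incumbent moves only when the candidate's predicted mean improves.

**Refinement.** After each iteration the grid is redistributed as
`α_k = α_best + s·tanh(d·(2k−N)/N)` with radius s = 1.75 and focus d = 3;
values are clamped to ≥1e−10 and deduplicated (ridge penalties must be
positive). When the initial sweep collapses to only a few points the
refinement uses a floor of 21 grid points so the tanh placement has
resolution. The validation objective is a seeded 80/20 holdout inside the
training data; all initial grid points are swept before the 20 EI
iterations start.

**Fraction selection.** 5-fold CV over δ ∈ {0, 0.05, …, 1}; per fold the
basis is rebuilt on the training folds (exact SVD in classic mode; kept
V/λ with re-induced U in learned mode), the curve re-derived, and the
candidate solved and scored on the held-out fold. One global δ_best is
selected for all target features (a per-feature fraction would be a
different estimator); ties break toward larger δ, i.e. less
regularization. Components with λ = 0 are dropped everywhere — they
receive no coefficient mass and cause no division by zero.

## Conditioning schedule and mock backend

The confidence scorer is a frozen seed-initialized network
(flatten → rectified bottleneck → sigmoid). The bottleneck width
defaults to 128 — wide enough to summarize a 77×768 tensor — and is
configurable down to the minimal widths (e.g. 4) sometimes used for
such gates. Confidence is computed once per sample — the
condition tensor only changes across steps through ξ, so re-scoring per
step would add cost without information. The unconditional embedding u_C
defaults to the zero tensor for the mock backend; a real diffusion
adapter would use its empty-prompt embedding (documented, not shipped).
An optional calibration routine,
`dcaf.calibrate_confidence_net`, refits only the scorer's output layer so
its score tracks the cosine similarity between decoded and reference
conditions; it is an experimental extension and deliberately *not* part
of the default path.

The mock backend is synthetic by construction: it pools the per-step
dynamic conditions, concatenates the pooled vector with the semantic
features, and emits a sigmoid-squashed seeded linear read-out as an 8-bit
64×64 grayscale image. It exists to exercise the schedule/conditioning
path deterministically, not to produce meaningful images.

## Metrics

PixCorr and the feature correlation score are plain Pearson correlations
(constant inputs raise rather than returning a silent 0). SSIM uses the
standard published constants — 11×11 Gaussian window, σ = 1.5,
stabilizers C₁ = (0.01R)², C₂ = (0.03R)², exponents 1, map cropped to
fully interior windows — and is validated against scikit-image's
implementation to 1e−6. Identification reports both the strict-diagonal
row-maximum accuracy (N-way) and the pairwise (two-way) accuracy, since
published protocols vary.

## Synthetic data: what it emulates, what it does not

`make_linear_dataset` draws isotropic Gaussian responses, a rank-limited
coefficient matrix (product of Gaussian factors through a rank
bottleneck, keeping condition numbers moderate), and i.i.d. Gaussian
noise; `snr` sets the noise variance from the mean signal variance
across feature columns. `make_condition_set` mixes a shared signal
tensor with independent noise per the requested reliability.
`make_lowrank_matrix` builds matrices with an exact prescribed singular
spectrum (decay^j) from QR-orthonormalized Gaussian factors.

Real fMRI betas are none of these things: voxels are spatially
correlated, noise is heteroscedastic and temporally structured, and the
voxel-feature map is at best approximately linear. Passing tests
establish the *computational* contracts — oracle equivalence, fraction
calibration, convergence, determinism — not decoding performance on
brain data. Benchmark-scale results additionally require pretrained
encoders and a real diffusion model, both outside this package's scope.

## Problem sizes and seeds

Validation uses desk-scale problems chosen for tight oracle comparisons:
ridge oracle 60×10 over 20 seeds; fraction contract 40×6; basis recovery
200 samples × 50 voxels at rank 3 with a 4-layer network, d = 3, 200
epochs; fraction-selection behavior 100×20 with 20 pure-noise
replicates; identification chance level N = 100, d = 50 over 50
replicates; the end-to-end pipeline 200 + 50 samples, 60 voxels, 30
features, rank 5, SNR 10. Every generator and trainer is a pure function
of its arguments including the seed; the pipeline derives per-stage seeds
from one global seed by fixed offsets and records them in the run
manifest.

## Known limitations

* Learned-basis mode inherits the scale bias described above; classic
  mode is exact. On strongly nonlinear maps the averaged-Jacobian ReLU
  mode is a first-order summary only.
* GP hyperparameters are fixed; a pathological validation-error surface
  (sharp minima far narrower than the unit length scale) can slow
  refinement.
* The fraction is global across target features; heterogeneous per-
  feature noise levels would favor per-feature fractions.
* The mock backend shares no statistics with a latent diffusion model;
  image-quality metrics on its outputs are only plumbing checks.
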