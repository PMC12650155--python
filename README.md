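# dcban

Decoding visual-stimulus features from fMRI responses with
**fractional ridge regression in singular-value space**, an adaptive
Bayesian search over the regularization penalty, nested low-rank feature
extraction, and confidence-weighted dynamic conditioning for generative
image reconstruction.

The package is aimed at researchers who work with preprocessed fMRI beta
matrices (samples × voxels) and want a tested, fully seeded implementation
of this decoding stack that runs at desk scale: every component is
exercised on synthetic data with known ground truth, and the generative
backend is a pluggable protocol with a deterministic mock, so nothing
requires a neuroimaging download or pretrained diffusion weights.

## The model

Given responses `X ∈ ℝ^{n×v}` and target features `Y ∈ ℝ^{n×d}` (e.g.
autoencoder latents or text embeddings of the viewed images), decoding is
a penalized linear map `Y ≈ X β`. The stack has three stages:

**1. Low-rank basis (DeepSVD).** A stack of linear layers — a
voxel-to-component adapter, width-3 convolutions along the component
axis, and a final fully connected layer — is trained with Adam so every
layer output `Tᵢ` matches the PCA-reduced targets while a per-layer
penalty sharpens the leading singular structure:

    L_rank  = −β₁ Σᵢ (fᵢᵀ Tᵢ gᵢ)² + β₂ Σᵢ ‖fᵢ‖²‖gᵢ‖² + β₃ Σᵢ<ᵢ′ ⟨fᵢ,fᵢ′⟩⟨gᵢ,gᵢ′⟩
    L_total = L_rank + ε · L_MSE

with `(fᵢ, gᵢ)` the leading singular pair of `Tᵢ` (held fixed within each
step). Because the layers are linear, the trained network is a single map
`Xlowrank`; its column norms are the singular values `λ` and its
normalized columns the basis `V`. The classic alternative — the exact SVD
of `X` — is available as `basis_mode="classic"` and makes the stack
collapse to reference fractional ridge regression.

**2. Fractional ridge (BAFRR + ARSO + BAGO).** In the singular basis the
solve is componentwise: `β̃_OLS = (UᵀY)/λ` and
`β̃_RR = λ²/(λ²+α) ⊙ β̃_OLS`, `β = V β̃_RR`. Instead of picking `α`
directly, the decoder targets the *fraction*
`γ(α) = ‖β̃_RR‖_F / ‖β̃_OLS‖_F ∈ (0, 1]`; the `α` achieving a requested
fraction δ is found by linear interpolation on an `(α, γ)` curve. The
`α` grid is log-spaced from the spectrum extremes and refined by Bayesian
optimization: a Gaussian-process surrogate (squared-exponential kernel)
models held-out MSE as a function of `α`, Expected Improvement picks the
next candidate, and the grid is tanh-redistributed around the incumbent.
The fraction δ itself is selected by k-fold cross-validation over the
grid δ ∈ {0, 0.05, …, 1} (δ = 1 means no regularization).

**3. Confidence-weighted conditioning (DCAF).** A decoded text-condition
tensor `C ∈ ℝ^{77×768}` is scored by a small frozen network giving
`conf ∈ (0, 1)`; during `n_iter = 50` sampling steps the injected
condition is `C_dyn(n) = ξ(n)·C + (1−ξ(n))·u_C` with
`ξ(n) = conf · max(0, 1 − n/n_iter)`, so semantic guidance is strong
early and relaxes toward the generator prior late. Reconstruction
metrics (pixelwise correlation, SSIM, cosine-similarity identification)
are provided in `dcban.evaluate`.

## Worked example

```python
import numpy as np
from dcban import make_linear_dataset, BayesAdaptiveFractionalRidge

data = make_linear_dataset(200, 40, 20, rank=5, snr=10.0, seed=42)
X_train, X_test = data.X[:160], data.X[160:]

model = BayesAdaptiveFractionalRidge(basis_mode="classic", seed=42)
model.fit(X_train, data.Y[:160])
print(f"selected fraction delta_best = {model.delta_best_:.2f}")
print(f"matched penalty  alpha_delta = {model.alpha_delta_:.3f}")

Z = model.predict(X_test)
truth = X_test @ data.B_true
corr = [np.corrcoef(Z[:, j], truth[:, j])[0, 1] for j in range(20)]
print(f"median decoded-feature correlation = {np.median(corr):.3f}")
```

prints

```
selected fraction delta_best = 0.95
matched penalty  alpha_delta = 6.821
median decoded-feature correlation = 0.983
```

At a signal-to-noise ratio of 10 the cross-validation keeps 95% of the
OLS coefficient norm (mild shrinkage, matched by a penalty of ≈6.8 in the
singular space), and the decoded features correlate at 0.98 with the
noiseless ground-truth features of held-out samples.

The same pipeline is available from the shell:

```
dcban run --seed 42 --out run/          # simulate → decode → reconstruct → evaluate
dcban simulate --n-samples 200 --n-voxels 60 --n-features 30 --rank 5 --out data/
dcban bafrr-fit --x data/X.tsv --y data/Y.tsv --mode classic --out sol.h5
dcban decode --solution sol.h5 --x-test data/X.tsv --out Z.tsv
```

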