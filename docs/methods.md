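# Methods

`cxrtriad` implements a three-stage classification pipeline for
chest-radiograph-like grayscale images — autoencoder feature extraction,
metaheuristic wrapper feature selection, and a windowed-attention
transformer classifier — together with a synthetic-data generator that
provides controlled study conditions and an evaluation kit. This note
records the model assumptions, the parameters that matter, the numerical
choices, and what the tests do and do not establish.

## Numerical core

No GPU tensor framework is used: both networks run on a small
reverse-mode automatic-differentiation engine over numpy arrays
(`cxrtriad.nn`). The op set (broadcast arithmetic, matmul, ReLU/sigmoid,
reductions, reshape/transpose/gather/concat, stable softmax and
log-softmax) is exactly what the two architectures need. Every op's
gradient is validated against central finite differences in the test
suite; Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e−8) with classic L2 weight decay
is the only optimizer. All computation is float64 and fully seeded, so
identical configurations reproduce loss histories bitwise.

## Synthetic data generator

The generator emulates the *layout and statistical structure* of public
chest X-ray archives, not their appearance: 8-bit grayscale PNGs plus a
CSV whose `Finding Labels` column joins labels with `|` ("No Finding" for
the all-negative row; metadata columns for age, sex and view position are
populated with plausible draws).

Each image is a fixed two-lobe elliptical "lung field" on a darker plate.
Every positive label adds one class-specific structured opacity — the
shape family cycles Gaussian blob / ring / linear streak with the class
index, and its location and geometry are drawn from an rng keyed on the
class index alone, so patterns are reproducible and parameter-free.
Signal amplitude is `opacity_contrast` (default 0.5 on the [0, 1]
intensity scale), pixel noise is additive Gaussian with
`noise_sd = 0.05`, and with probability `artifact_rate = 0.1` a
high-frequency artifact (salt speckle or a bright line) is injected —
this is what the Gaussian prefilter is there to suppress.

Labels come from a Gaussian-copula threshold model: latent correlated
normals (correlation = the configured co-occurrence matrix, eigen-clipped
to PSD if necessary) thresholded at the per-class prevalence quantile.
That is the simplest model with controllable marginals *and* pairwise
co-occurrence. In single-label mode a categorical draw over the
(normalized) prevalence vector is used instead; the default prevalence is
geometric (½, ¼, …, renormalized), so class imbalance is present by
construction. Default conditions used throughout the tests: n = 300
images, 3 classes, 64→32 px sides, contrast 0.5, noise 0.05 — conditions
under which a 1-nearest-neighbor classifier on raw pixels is reliably
above 80 % held-out accuracy, i.e. the signal is learnable but not
trivial at the noise floor.

What passing tests show: the pipeline can recover class structure of this
kind — localized, class-consistent opacities with label noise-free
supervision. What they do not show: performance on real radiographs,
whose pathology appearance varies across patients, scanners and views,
and whose labels (text-mined) are themselves noisy.

## Preprocessing

Two dialects are implemented because the pipeline is described with two
front ends; neither is silently preferred.

* `zscore-224`: Gaussian filter → bilinear resize → per-image z-score.
* `imagenet-crop`: Gaussian filter → resize to 256 → seeded random crop
  224 → fixed-statistics normalization, default mean 0.449 / SD 0.226
  (the RGB ImageNet statistics collapsed to one channel).

The Gaussian kernel is the sampled `exp(−(u²+v²)/(2Z²))` on a
`(2·radius+1)²` support, renormalized to sum 1; the analytic `1/(2πZ²)`
prefactor is absorbed by the renormalization so constant images are
preserved (to summation round-off, ≈1e−15). Default radius is ⌈3Z⌉;
borders reflect. Resizing is bilinear with half-pixel centers, so outputs
are convex combinations of inputs and never exceed the input range.
Per-image z-scoring uses the population SD; a constant image maps to all
zeros by convention. Whether normalization statistics are per-image or
fixed is genuinely open in the pipeline description; per-image is the
default, fixed statistics are the `imagenet-crop` mode. Desk-scale tests
use `target_size = 16` rather than 224 — every operation is
resolution-agnostic and 16² keeps a few hundred training runs inside CPU
budgets.

## Augmentation

Five label-preserving transforms (rotate, flip, crop, shift, scale), all
returning the input shape: crops are resized back, scales are
center-cropped or zero-padded back, rotations/shifts fill with zeros,
positive rotation is counterclockwise. Defaults enable horizontal and
vertical flips at p = 0.5, rotations up to ±30°, and crops at 90–100 % of
the side; shift and scale default off. Augmentation *replaces* images
(one view per epoch) rather than appending, with per-image rng streams
keyed on (seed, epoch, index), so dynamic per-epoch augmentation is
reproducible under any loading order and never alters the label matrix.

## EnAE — stacked autoencoder with per-layer attention

Each stage is an affine map + ReLU followed by a self-attention block,
and the decoder mirrors the encoder with independent weights (untied by
default; a tied mode shares the transposed encoder weight). The attention
block treats the stage's features as width-1 tokens: learned projections
take each scalar feature to a query and key of width `attention_dim`
(default 8) and a scalar value; scores are the plain dot product `Q·Kᵀ`
(no √d scale — the score definition here has none), softmax-normalized
over keys with max-subtraction, and the output is the weighted value sum.
This realizes "feature reweighting by learned relevance" while preserving
width. The final decoder layer is linear (no ReLU) so standardized,
signed inputs are reproducible.

Training is greedy layerwise followed by joint fine-tuning. Stage *s*
minimizes `(1−λ)·MSE(stage input, stage recon) + λ·MSE(raw, raw recon)`,
where the raw reconstruction routes the stage output down through the
already-trained lower decoders; λ (`lambda_raw`) defaults to 0.5, and
λ = 0 recovers the classical stacked autoencoder. The joint phase
minimizes whole-stack raw reconstruction, where the two terms coincide.
A non-finite loss aborts with a stage-tagged diagnostic. The recorded
`loss_history` concatenates per-epoch means across phases with marked
phase boundaries.

Where the description leaves choices open: attention blocks do **not**
share weights across stages; feature extraction accepts any row matrix,
and the experiment driver feeds original + augmented rows stacked for
training while extracting features from originals.

## ChWO — chaotic whale optimization

The whale optimizer treats the incumbent best as prey. Per whale and
iteration, with `g ~ U[0,1]`, `M = 2mg − m`, `R = 2g`, and `m` shrinking
linearly 2 → 0:

* probability 0.5: spiral move `Q' = S'·e^{kq}·cos(2πq) + Q*`,
  `S' = |Q* − Q|`, `q ~ U[−1,1]`, k default 1;
* otherwise, if `|M| < 1`: encircle, `Q' = Q* − M·|R·Q* − Q|`;
* else: explore toward a random member, `Q' = Q_r − M·|R·Q_r − Q|`.

The chaotic ingredient is a per-whale, per-dimension auxiliary state
iterated by the Chebyshev map `q ← cos(X·arccos q)` (X default 4,
chaotic for X ≥ 2), advanced every iteration and affinely mapped from
[−1,1] onto the dimension's bounds. In the spiral (randomization) phase
the new position is `w·chaotic + (1−w)·spiral` with `w = blend_weight`
(default 0.5). The encircle and exploration branches are used unblended,
as printed; blending them too would bound the swarm's dispersion away
from zero and make convergence to e.g. 1e−2 on a 5-D sphere essentially
impossible. `blend_weight = 0` reduces the loop to vanilla WOA exactly —
same code path, same rng consumption, bit-for-bit — which is how the WOA
baseline is provided. Best-fitness updates are strictly-less (ties keep
the incumbent), so the best-so-far history is non-increasing by
construction; positions are clipped to bounds after every move.

**Measured limitation.** On the sphere benchmark (pop 20, 100
iterations, 10 paired seeds) the chaotic variant's median final fitness
is ~1e−6 versus ~1e−27 for vanilla WOA, and its median curve is above
WOA's from roughly iteration 3 onward. The cause is structural: the
blended chaotic term has a fixed, non-vanishing amplitude (the Chebyshev
invariant density is supported on all of [−1,1]), so late-stage swarm
dispersion — and with it the encircle step size — is bounded below by
O(m × chaos amplitude), while vanilla WOA's dispersion collapses
geometrically. The package reports both optimizers and their curves
(`evalkit.convergence_report`) rather than asserting a superiority the
update rule does not deliver.

A second numerical fact: the Chebyshev closed form
`Tₓⁿ(cos θ) = cos(Xⁿθ)` is verified to 1e−9 only while `Xⁿ` stays below
~2¹⁹. This is conditioning, not implementation: the map's Lyapunov
exponent is ln X, so per-step round-off is amplified like Xⁿ in any
double-precision evaluation, on both sides of the comparison.

**Feature selection.** A continuous score vector in [−1,1]^d is
optimized; feature j is kept iff `sigmoid(x_j) > 0.5` (equivalently
x_j > 0). Fitness is `α·cv_error + (1−α)·|mask|/d` with α (`fs_alpha`)
default 0.9 and `cv_error` the stratified 3-fold error of a
1-nearest-neighbor classifier on the selected columns — a wrapper
criterion chosen because the error signal the selection stage is asked to
minimize is otherwise unspecified. The all-zero mask scores 1.0 (worst);
if the optimum still decodes to an empty mask, the single best column is
selected. Fitness values are memoized by mask, which makes revisits free
and the whole selection run (pop 20, 40 iterations, d = 20, N = 120)
take a few seconds. On pure-noise data the in-sample CV error of the
*selected* subset is biased low by the search itself; chance-level
behavior is therefore asserted on an independent replicate of the null
distribution.

## IMSTrans — shifted-window transformer with dense-block MLPs

Input grids (preprocessed images, or selected-feature vectors zero-padded
to the next perfect square and reshaped with patch size 1) are patch-
embedded by a shared linear map. A learned absolute positional embedding,
**initialized at zero**, is added to the token grid: a freshly
initialized model therefore carries no positional information (swapping
window contents leaves pooled logits unchanged, which is tested), while
training can break the token-permutation symmetry — essential in
feature-vector mode, where each token is a width-1 scalar and the
*identity* of the feature is the signal. Relative position bias is off by
default and available by flag.

One block pair applies, with pre-norm LN and residuals in the printed
order:

    K̂r   = W-MSA(LN(Kr−1)) + Kr−1
    Kr   = D(LN(K̂r)) + K̂r
    K̂r+1 = SW-MSA(LN(K̂r)) + Kr
    Kr+1 = D(LN(K̂r+1)) + K̂r+1

(The shifted attention takes `LN(K̂r)` while the residual adds `Kr` —
that is the convention as printed, kept deliberately.) W-MSA is
multi-head scaled dot-product attention (`1/√d_head`) inside P×P token
windows; SW-MSA uses the efficient cyclic-shift formulation: roll by
⌊P/2⌋, attend with an additive mask that assigns −∞ to token pairs whose
pre-shift origins are not contiguous, roll back. Mask regions follow the
canonical band layout `[0, H−P), [H−P, H−s), [H−s, H)` on the *unrolled*
canvas. Token grids are zero-padded up to a window multiple; padded
tokens are masked out as attention keys and excluded from the global
average pool, and the diagonal is never masked so no softmax row is
entirely −∞.

`D` is the dense-block MLP: L (default 2) fully connected sub-layers,
each consuming the concatenation of the block input and all previous
sub-layer outputs and emitting g (default 8) features through
Linear → LayerNorm → ReLU; a transition layer projects the final
`C + L·g` width back to `C`. Layer normalization replaces batch
normalization in token mode so the model is batch-size-independent and
deterministic; the optional convolutional stem (3×3 dense conv block +
1×1 transition + 2×2 mean pool before patch embedding, off by default)
keeps batch norm as is conventional for convolutional dense blocks. Dense
connectivity gives every sub-layer a direct gradient path, which the
suite verifies by checking non-zero finite gradients per sub-layer after
one step.

The head is LN → masked GAP over valid tokens → fully connected, with
softmax probabilities (multi-class) or per-class sigmoids (multi-label,
decision threshold 0.5). Training uses cross-entropy or per-label BCE,
Adam, shuffled batches from a seeded rng, and records per-epoch train
(and optional validation) loss and accuracy; zero epochs returns the
initialization untouched.

## Training scalars at desk scale

The configuration defaults keep the published full-scale values
(learning rate 1e−4, batch 32, weight decay 1e−5, up to 100 epochs).
The desk-scale experiments in the tests and the acceptance script pass
`learning_rate = 1e−3` (and 3e−3 with 60 epochs for the feature-grid
classifier) explicitly: with 200–600 Adam steps in total and Adam's
per-step parameter motion ≈ lr, a 1e−4 rate bounds total parameter
displacement by ~0.06, an order of magnitude short of what fitting a
few hundred samples in 30 epochs requires. This is an a-priori step-size
argument, not tuning; the larger rates are part of the declared
desk-scale study conditions, alongside 16×16 inputs, (64, 32)
autoencoder stages, embed width 16, and one W/SW block pair.

## Evaluation

Metrics are computed from micro-pooled confusion counts by the
definitional formulas (accuracy, precision, recall, F, MCC), with macro
averaging by flag; any zero denominator yields 0 plus a named flag, never
NaN. MAE is the mean |y − ŷ| over all (sample, class) pairs with ŷ the
predicted *probability* (hard-label MAE by flag) — the definition is over
predicted values, so probabilities are the faithful default. Whether
published single-scalar multi-label metrics are micro or macro averaged
is unstated; micro is the documented default. The metric suite is
cross-checked in the tests against scikit-learn on expanded decision
arrays and against direct formula evaluation on random tables.

Splits are stratified by primary (first positive) label via seeded
`train_test_split`, at training percentages 50–90 (others allowed with a
warning). The experiment driver runs, per (percentage, seed): preprocess
→ augment (train only) → train EnAE on stacked original+augmented rows →
extract features → ChWO selection → per-column standardization by
training statistics → reshape to a grid → train IMSTrans → metrics on
the held-out split, plus an everything-selected ablation and optionally
a random equal-size mask. Reports serialize to JSON plus a metrics ×
training-percentage CSV and per-class confusion counts.

## Known limitations

* The generator's opacities are deterministic per class; real pathology
  variability (shape, multiplicity, severity) is not modeled, so
  absolute accuracy numbers on synthetic data say nothing quantitative
  about real datasets.
* The chaotic blend degrades, not improves, final convergence on smooth
  unimodal benchmarks (measured above); the claim that chaos accelerates
  convergence is not reproduced by this update rule.
* The convolutional stem and relative-position bias are exercised for
  shape/gradient correctness only, not at realistic scale.
* Multi-label experiments run through the same driver (sigmoid head),
  but the bundled end-to-end study conditions are the 3-class
  single-label setting.
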