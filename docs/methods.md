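# Methods

This note documents the models, the simulated study conditions, the
numerical choices, and what the tests do and do not establish.

## Forward model

The torso cross-section at bladder level is a 2D domain Ω with
element-wise constant conductivity σ. Injected currents obey
∇·(σ∇u) = 0 in Ω with Neumann boundary data. The solver uses standard
piecewise-linear (P1) Galerkin elements; the stiffness matrix is
symmetric positive-semidefinite with the constant vector as null space.

**Electrode model.** Electrodes are contiguous runs of boundary edges on
the front (lower) arc of the boundary — a wearable strip worn on one
side of the abdomen. We use the *gap* model: injected current is spread
over the source electrode's edges proportionally to edge length and
extracted likewise at the sink; a measured value is the length-weighted
mean nodal potential over the electrode, referenced to the zero-mean
ground. No contact impedance is modeled (the complete electrode model is
out of scope). Because the same nodal weight vector serves as Neumann
load and as measurement functional, discrete reciprocity holds to solver
precision — the suite checks ≤ 1e-8 relative on random conductivity
fields, and the solver itself verifies a 1e-10 relative residual.

**Verification.** Against the closed-form potential of two boundary
point sources on a homogeneous disk (each source coincides with its
image charge, so u = (I/πσ)·ln(|x−b|/|x−a|)), boundary potentials agree
within 2% at edge length ≤ radius/20, with monotone error decrease under
refinement; the measured error at radius/20 is ≈ 0.1%.

**Grounding.** The singular Neumann system is solved by pinning one node
(loads are compatible) and recentering to the unique zero-mean solution;
the sparse LU factorization is reused across all injections of a frame.

**Units and defaults.** Coordinates in meters; currents in amperes.
Default torso outline: superellipse |x/0.15|^2.5 + |y/0.10|^2.5 = 1
(plausible adult pelvis cross-section; config, not a claim). Background
conductivity 0.2 S/m (soft tissue), inclusion 1.0 S/m (urine is markedly
more conductive). Injection amplitude 1 mA.

**Protocol.** The published 2D setup fixes only the frame length m = 32
for 8 electrodes; the injection/measurement pattern is not stated.  Our
documented default: 4 opposite-style pairs (1,5), (2,6), (3,7), (4,8) at
1 mA, recording all 8 single-ended electrode potentials per injection,
m = 4×8 = 32. Any pair/measurement list is accepted, and the dataset
metadata records the protocol used. A two-row 16-electrode protocol
builder (m = 256) exists for bookkeeping only; 3D solving is out of scope.

**Noise.** Off by default (the training data are treated as noiseless).
`add_noise` adds white Gaussian noise calibrated so that
10·log10(signal power / noise variance) equals a requested per-frame SNR
in dB; a Monte-Carlo test verifies the calibration to 0.5 dB.

## Mesh generation

Boundary nodes are placed by arc length along the outline; interior
nodes start on a hexagonal lattice clipped by a negative buffer of the
outline polygon, are relaxed by a few Laplacian smoothing passes, and
are triangulated by Delaunay. Triangles are oriented counter-clockwise;
the boundary is recovered by edge census (edges on exactly one
triangle) and validated against the Euler relation V − E + F = 1 of a
triangulated disk. Meshes failing a 20° minimum-angle bound are
rejected. Halving the target edge length multiplies the element count by
≈ 4. The committed `tests/data/torso_fine.mesh` fixture (825 nodes, 1552
triangles, 8 electrodes) matches the density of the published mesh
(848 nodes / 1555 triangles) and is asserted at its recorded counts.

Electrodes: the front arc is the stretch of boundary (half the perimeter
by default) centered at the lowest boundary point; each of the
`electrode_count` electrodes occupies `electrode_arc_fraction` of its
pitch, mapped to whole boundary edges. Overlapping assignments raise a
configuration error.

## Phantom generator — what it emulates and what it does not

Each training sample is **one** bladder-like inclusion: a rotated
ellipse whose boundary radius is modulated by a random Fourier series of
order ≤ 3, r(θ) = r_ellipse(θ)·(1 + Σ_k c_k cos kθ + s_k sin kθ).
Element labels are *centroid-in-shape* (boundary counts as outside) —
the simplest deterministic rule; label prevalence therefore tracks the
expected inclusion area fraction, which a Monte-Carlo oracle confirms.

Defaults (chosen once; every value is configurable):

| parameter | default | rationale |
|---|---|---|
| center box | x ∈ ±0.27a, y ∈ [−0.65b, −0.20b] | the bladder is a midline organ of the lower pelvis and cannot touch the abdominal wall |
| semi-axes | uniform 18–38 mm | near-full bladder at a 0.15 m × 0.10 m cross-section |
| rotation | uniform [0, π) | no preferred orientation |
| Fourier coefficients | N(0, 0.03²), order 3 | mild, smooth shape irregularity |
| wall margin | 15% of half-axes | resample shapes crossing the shrunken outline |
| conductivities | 0.2 / 1.0 S/m | tissue vs urine |
| n | 5000 | the published training-set size |

The center box and size range were calibrated so that the simulated
frame ensemble reproduces two structural properties documented for the
original (unreleased) data: the first eight principal components carry
≥ 99% of the frame variance, and the discriminant/tree banks reach the
near-perfect reconstruction quality the published tables show. A wider
center box or smaller inclusions yield a measurably harder problem
(first-8-PC share ≈ 98.5%, CART AUC ≈ 0.88) than the published results
exhibit. Mean label prevalence under these defaults is ≈ 4–5% of the
cross-section vs ≈ 2% in the published illustrative frames — a deliberate
trade-off toward the fuller-bladder regime.

Not emulated: multiple simultaneous inclusions, anatomically segmented
tissue layers (bone, muscle, fat), contact-impedance and electrode-drift
effects, bladder filling dynamics, and measurement noise (unless
enabled). Passing tests therefore demonstrate correctness of the method
chain on idealized data, not clinical performance.

Reproducibility: sample i draws its generator from `(seed, i)`, so
datasets regenerate bit-exactly and independently of chunking.

## Classifiers

One classifier per mesh element, trained on (X, Y[:, e]). Elements whose
positive count is below a per-family minimum get an explicit constant
model predicting the observed base rate (defaults: QDA-type d+2 where d
is the feature dimension, LDA/RDA 4, logistic max(10, K), CART 1 — i.e.
only never/always-covered elements).

**Elastic-net logistic.** Features are standardized internally
(coefficients are reported on the original scale); the intercept is
unpenalized — without it the strong base-rate imbalance of per-element
labels is unlearnable. The optimizer is IRLS with an inner coordinate
descent on the weighted Gram matrix followed by an exact KKT solve on
the active set; single-λ fits enforce a 1e-6 scaled stationarity
tolerance (violations raise), path/CV fits run warm-started with capped
budgets. λ path: 50 points log-spaced over 4 decades down from
λ_max = max_j |x_jᵀ(y − ȳ)|/(n·max(α, 10⁻³)); K = 10 folds by default;
the selected λ maximizes mean CV accuracy at threshold 0.5 with ties
going to the larger λ.

**LDA/QDA/RDA.** Estimators exactly as printed in the source tables:
π_k = n_k/n, pooled covariance divisor n − 2, per-class divisor n_k − 1.
The QDA discriminant uses the standard −½ log det Σ_k term (the printed
−½ log det Σ_k⁻¹ appears to be a sign typo; the package implements the
standard form). σ² in the spherical shrinkage is tr(Σ)/m — the average
eigenvalue — so γ = 0 gives a spherical covariance of matched scale; the
default RDA is LDA + spherical shrinkage with γ chosen by 5-fold CV
accuracy on the grid {0, 0.25, 0.5, 0.75, 1}, ties toward stronger
shrinkage. Posteriors are max-subtracted softmaxes over the discriminant
scores, which equals Bayes' rule with Gaussian densities to 1e-10 in the
oracle tests; covariances are handled by Cholesky factorization, never
explicit inverses. Non-PD covariances raise with a pointer to shrinkage
or PCA.

**PCA.** SVD of the centered data; loading signs fixed by making each
column's largest-magnitude entry positive; retention by component count
or smallest count reaching a cumulative variance fraction (default
0.9999 — effectively "all of the variance", mirroring the observed
rank-8 structure while keeping a deterministic rule).

**CART.** Greedy binary splits on single features at midpoints between
consecutive distinct sorted values, minimizing size-weighted child Gini;
ties break toward the lowest feature index, then the lowest threshold.
Growth stops at depth 12, leaf size 5, or zero impurity decrease; no
pruning. Leaves predict their class-1 fraction. The split search agrees
with exhaustive enumeration on every tested instance.

## Evaluation

Thresholding is boundary-inclusive (ŷ = 1 iff p ≥ t, default t = 0.5).
Rates with zero denominators are reported as NaN sentinels. Cohen's κ
uses the 2(TP·TN − FN·FP)/[(TP+FP)(FP+TN) + (TP+FN)(FN+TN)] form,
verified algebraically equal to (p_o − p_e)/(1 − p_e). **Both** McNemar
conventions are always reported — raw (FP−FN)²/(FP+FN) and
continuity-corrected (|FP−FN|−1)²/(FP+FN) — because the published tables
mix the two (the logistic/discriminant tables are consistent with the
corrected form, the tree table with the raw form); the package
privileges neither. ROC thresholds are the distinct probabilities plus a
sentinel; AUC is the trapezoid, equal to the Mann-Whitney pair-counting
statistic with ties counted half.

Rasterization samples each per-element map on an N×N grid of pixel
centers over the mesh bounding box (pixels outside the domain are 0;
boundary ties go to the lowest element index). Image metrics follow the
printed definitions: MSE, MAE, PSNR = 10·log10(L²/MSE) with L the
dynamic range of the ground-truth image (1 for binary truth; the
printed "max x_i²" is ambiguous), and a *single global window* SSIM with
c₁ = (0.01L)², c₂ = (0.03L)² and population (ddof = 0) moments — not the
sliding-window SSIM, which is why values near 1.0 in sliding-window
reports are not comparable. MSE = 0 reports PSNR = +∞.

Rendered report tables round half-up to 3 decimals; raw doubles are
stored. One published table cell (balanced accuracy 0.973 for the tree
column) is a truncation of 0.97368 and is excluded from the
count-reconstruction constraints in the tests; similarly the PPV/precision
0.813/0.812 pair in the QDA column is two roundings of 26/32.

## Scaled study sizes

The default acceptance-scale study runs a ~535-element mesh (edge length
14.5 mm), n = 1000 frames, and an 80/20 split — sizes chosen so the full
chain (simulation, seven-family training, 200 held-out reconstructions)
completes in seconds while leaving the qualitative ranking of methods
intact. Under these conditions the held-out mean AUC/κ are ≈ 0.995/0.79
for QDA-PCA and ≈ 0.95/0.84 for CART; published per-instance values at
full scale (1555 elements, n = 5000) are higher (AUC 0.982–1.000, κ up
to 0.972) and are instance- and generator-specific, so they are not
reproduced number-for-number. The per-frame AUC of CART is intrinsically
tie-limited: hard 0/1 leaf probabilities put missed bladder elements at
probability 0, tied with most of the background.

## Known limitations

- Gap electrode model only; no contact impedance, no complex-valued
  (capacitive) conductivity.
- Single inclusion per frame; homogeneous background.
- The inverse (Gauss–Newton) reconstruction route is intentionally out
  of scope; the classifier banks are the reconstruction.
- Banks are retrained from (dataset, method, seed) rather than
  serialized parameter-by-parameter; the pipeline manifest records the
  recipe and hashes for bit-exact reruns.
- CV fold assignment is a seeded shuffle, not stratified; per-element
  positives can concentrate in few folds for rare elements (such
  elements fall back to constant models by the minimum-positive rule).
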