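# Methods

## The model

`fsvmsr` implements a fuzzy support vector machine whose per-sample weights
come from a Laplacian-regularized self-representation of the training set.
It targets small, imbalanced clinical tables — the motivating application is
risk stratification of vascular calcification in hemodialysis patients from
29 routine clinical and laboratory features — where the majority class tends
to accumulate noisy or mislabeled records that drag a standard SVM's
boundary into minority territory.

### Fuzzy SVM

Each training sample carries a membership weight s_i ∈ [0, 1] that scales
its slack penalty. The primal is

    min  ½‖w‖² + C Σ_i s_i ξ_i    s.t.  y_i (wᵀφ(x_i) + b) ≥ 1 − ξ_i,  ξ_i ≥ 0,

and the dual is the familiar box-and-equality quadratic program with a
per-sample upper bound:

    max  Σ_i α_i − ½ Σ_ij α_i α_j y_i y_j K(x_i, x_j)
    s.t.  0 ≤ α_i ≤ s_i C,   Σ_i α_i y_i = 0.

A sample with s_i = 0 is excluded from the support set outright; small s_i
caps how much a noisy sample can bend the boundary. K is the RBF kernel
exp(−γ‖x − x'‖²). The decision function is f(x) = sign(Σ_i y_i α_i K(x, x_i) + b).

Because the box is per-sample, stock unweighted solvers do not apply. The
dual is solved by a maximal-violating-pair SMO (LIBSVM's working-set rule
with the generalized box): pick the most violating pair (i, j), solve the
two-variable subproblem analytically, clip to the box, update the gradient;
stop when the duality-gap criterion m(α) − M(α) < tol. The bias b is the
mean of y_i − Σ_j α_j y_j K_ij over free vectors (0 < α_i < s_i C at
tolerance), or the midpoint of the KKT-implied interval when no vector is
free. Multiclass classification is one-against-one: one machine per class
pair (the lower class index is the +1 side), majority vote, ties broken by
the largest accumulated decision-value magnitude in the tied class's favor
and then by the smaller class index; sign(0) counts as +1.

### Self-representation memberships

Writing the standardized training matrix column-per-sample, X ∈ R^{d×N},
the coefficient matrix Z solves

    min_Z ‖XZ − X‖_F² + λ Tr(Z L Zᵀ),

where L = D^{−1/2}(D − W)D^{−1/2} is the symmetric normalized Laplacian of
a sample-similarity matrix W (by default the RBF Gram matrix of the
training fold, bandwidth `gamma_sim`, defaulting to the classifier's γ).
The stationarity condition is the Sylvester equation

    (XᵀX + δI) Z + λ Z L = XᵀX,

solved by Bartels–Stewart (`scipy.linalg.solve_sylvester`). The ridge
δ = 1e-8 · tr(XᵀX)/N guarantees a unique solution when N > d, the normal
situation for a tabular cohort (59 × 29 here), where XᵀX is rank-deficient;
δ is configurable and can be set to 0 when X has full column rank. Every
solve is self-checked against the residual tolerance
‖AZ + λZL − XᵀX‖_F < 1e-6 · (1 + ‖XᵀX‖_F).

The per-sample reconstruction error r_i = ‖X z̃_i − x_i‖² is mapped to a
membership by the affine min–max rule

    s_i = 1 − (r_i − r_min)/(r_max − r_min),

with all s_i = 1 when the errors are equal to within 1e-12 relative. The
map is invariant to positive rescaling of r and strictly order-reversing.
A configurable floor (default 0) can keep the worst sample from being
excluded entirely.

**Self-coefficient exclusion.** z̃_i above is z_i with its i-th entry
zeroed (`exclude_self=True`, the default): r_i measures how well sample i
is represented by the *other* training samples. This choice is load-bearing.
The unconstrained optimum lets every sample lean on its own column — z_i ≈ e_i
reconstructs x_i exactly no matter how atypical the sample is — and the
Laplacian penalty, which is the only force opposing that, vanishes
exactly on the samples that are similar to nobody. With the full Z, a
far outlier therefore attains the *lowest* error and full membership,
inverting the intended weighting; we verified this on planted-outlier
designs from N = 4 up to the 59 × 29 cohort scale, with the solver itself
validated against a Kronecker-vectorization brute force. Discounting the
self-coefficient restores the intended semantics: a 5-SD planted outlier
receives the maximum error and membership 0, and cohort rows displaced by
6 SDs rank in the worst 10% of errors. Setting `exclude_self=False`
reproduces the literal unconstrained chain.

### Defaults and parameters

| parameter | default | meaning |
|---|---|---|
| C | tuned by grid search | slack penalty (unitless) |
| γ | tuned by grid search | RBF bandwidth on standardized features |
| `gamma_sim` | = γ | similarity bandwidth for W |
| λ | 0.01 | Laplacian smoothing strength |
| ridge δ | 1e-8 · tr(XᵀX)/N | Sylvester uniqueness guard |
| tol | 1e-6 | SMO KKT tolerance |
| grid | C ∈ 2^−5…2^10, γ ∈ 2^−10…2^5, step ×2 | 16 × 16 = 256 cells |

Features are z-scored before every kernel or self-representation
computation — the cohort schema spans five orders of magnitude (serum
fetuin-A ~3·10⁵ pg/mL next to serum calcium ~2 mmol/L) and both the RBF
kernel and the reconstruction error are scale-sensitive. The standardizer,
the memberships, and the machines are all fitted on the training rows of
each fold only; memberships are computed once per training fold and sliced
for each pairwise subproblem, never recomputed per pair.

## Evaluation protocol

Accuracy is decomposed per class: whole ACC = 100 · ΣTP_i/M and
ACC_i = 100 · TP_i/M_i, so the whole accuracy is always the class-size-
weighted mean of the per-class accuracies; a class absent from a test fold
is reported as missing, never as 0. Cross-validation is stratified 10-fold
(per-class counts across folds differ by ≤ 1): with 11- and 17-member
classes out of 59, unstratified folds can lose a class from a training
fold entirely. Folds are deterministic given a seed, identical across grid
cells and across compared methods. The grid search scans the 256-cell
dyadic grid above and breaks ties toward smaller C, then smaller γ. ROC/AUC
for the two-class scheme uses the single machine's decision values pooled
over held-out folds; AUC is the normalized Mann–Whitney statistic (average
ranks give tied scores half credit). Method comparison runs 20 independent
10-fold CVs per method (fold seeds base+r, shared between methods) and
applies a two-sided Welch t-test to the per-repeat mean accuracies; if both
streams have zero variance the p-value is reported as exactly 1 (equal
means) or 0, flagged as degenerate.

## Synthetic cohorts

The generator emulates the published marginal structure of the study
cohort: 29 features with given means/SDs (six of them binary with given
prevalences), a 7-level ordinal risk label with the count profile
10/15/17/6/6/4/1 (N = 59), and per-feature Pearson correlations with the
risk level in roughly −0.43…0.48. Each continuous feature is drawn as
mean + SD·(ρ·z_ℓ + √(1−ρ²)·ε) with z_ℓ the standardized risk level — a
single shared latent rather than a full copula, because only marginal
moments and per-feature correlations are identifiable from the published
summaries. Binary features shift their log-odds linearly in z_ℓ with the
slope matched to the target point-biserial correlation to first order
(infeasible combinations raise a named error). Optional outliers displace
a fraction of the modal level's rows by a given number of SDs in a random
direction. Two smaller generators serve the tests: Gaussian blob classes,
and two noise-planting operations — `plant_label_noise` flips labels only
(useful for classifier-robustness experiments; provably invisible to the
feature-based membership function), and `plant_noise_samples` redraws the
features of majority-class rows at a given location while keeping their
label, which is the mislabeled/corrupted-record model that membership
weighting can actually detect.

What the generator does *not* model: realistic joint dependence between
clinical features beyond the shared risk latent, survival structure,
missingness, or measurement error. Passing tests therefore demonstrate the
algorithmic claims (solver correctness, leakage-free protocol, outlier
suppression) under controlled conditions, not clinical performance on real
dialysis cohorts — the study's patient-level data is not publicly
available, so its headline accuracies are not reproducible here and are
not asserted anywhere in the suite.

## Numerical choices and edge cases

- RBF distances use the ‖a‖² + ‖b‖² − 2a·b expansion with tiny negatives
  clamped to zero; Gram matrices are symmetrized and given an exact unit
  diagonal.
- W keeps its unit self-similarity diagonal, which guarantees strictly
  positive degrees; a zero-degree vertex raises a named error. L is
  symmetrized by averaging with its transpose.
- SMO's two-variable curvature is floored at 1e-12; iteration cap 1e5 by
  default (raise `max_iter` for tolerances below ~1e-8 on hard problems).
- Degenerate inputs have defined behavior throughout: all-equal
  reconstruction errors → all memberships 1; empty test matrix → empty
  prediction; identical accuracy streams → p = 1; single-class truth in
  ROC or a fold that loses a class → named errors.
- Problem sizes used by the test suite and the acceptance script (59 × 29
  cohorts, 59-sample blob cohorts, 20-sample QP instances, N ≤ 12
  Sylvester oracles, 20 CV repeats) match the study's own scale, which the
  method is designed for; the whole suite runs in well under a minute.

## GNRI utility

The geriatric nutritional risk index is computed in its canonical form
GNRI = 14.89 · albumin[g/dL] + 41.7 · (actual weight / ideal weight),
accepting albumin in g/L and converting internally. Published renderings
of the formula sometimes typeset the second term's product as a sum; the
canonical multiplicative form is implemented and the worked examples in
the tests pin it down (e.g. albumin 40 g/L at ideal weight → 101.26).

## Known limitations

- The membership function sees features only: a mislabeled but
  feature-typical record cannot be down-weighted by construction.
- With well-separated clusters and a local kernel, suppression of noise
  samples often leaves accuracy unchanged (the RBF boundary already
  localizes them); the benefit of weighting appears at the margin, which
  is why the weight-effect tests assert non-degradation rather than strict
  improvement.
- One-vs-one voting with c classes fits c(c−1)/2 machines; no probability
  calibration or one-vs-rest alternative is provided.
- The Sylvester solve is dense O(N³) per fold — fine for cohort-scale N,
  not intended for N in the tens of thousands.
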