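# Methods

This note documents the statistical model behind `segpower`, the
numerical conventions chosen where the mathematics leaves room, what the
built-in simulator does and does not emulate, and the package's known
limitations.

## Statistical model

A study compares segmentation algorithms A and B against a reference
standard L on n images of v voxels each, using a two-sided paired
Student's t-test on the per-image accuracy differences
d̄_k = (1/v) Σ_i D_{k,i}, where D_{k,i} = |B_{k,i} − L_{k,i}| −
|A_{k,i} − L_{k,i}| ∈ {−1, 0, 1}.  d̄_k is exactly the accuracy of A minus
the accuracy of B on image k, so testing E[d̄] = 0 tests equality of mean
accuracies.

The population model is nested:

1. **Inter-image variability.**  Each image draws a marginal vector
   O⃗_k for D from a prior with mean p⃗ = ⟨p₁, p₀, p₋₁⟩.  In the
   parametric special case the prior is Dirichlet with precision ω
   (concentration ω·p⃗): large ω means homogeneous images, small ω
   heterogeneous ones.  A key moment identity of this prior is
   var(O₁ − O₋₁) = (ψ − δ²)/(ω + 1), where δ = p₁ − p₋₁ and
   ψ = p₁ + p₋₁.
2. **Intra-image correlation.**  Given O⃗_k, the voxels of an image are
   a correlated categorical field with pairwise Pearson correlation
   ρ_ij of the ordinal −1/0/1 values.  Only the average
   ρ̄ = (Σ_ij ρ_ij)/v² enters the variance of d̄; the average runs over
   all *ordered* pairs including i = j, which is what makes the
   independent-voxel limit come out as ρ̄ = 1/v exactly.

Marginalizing gives the variance of d̄ used in the sample-size relation:

* moment route: σ_d̄² = ρ̄ (ψ − δ²) + (1 − ρ̄) σ²_{O₁−O₋₁}, valid for any
  prior;
* Dirichlet route: σ_d̄² = f (ψ − δ²) with the design factor
  f = (1 + ω ρ̄)/(ω + 1), the analogue of the design effect in
  cluster-randomized trials (each image is one cluster of correlated
  voxel observations).  f ranges from 1/v (independent voxels, no
  inter-image variability) to 1 (perfectly correlated voxels).

In the limit ρ̄ = 1/v, σ²_{O₁−O₋₁} = 0, the sample size times v equals
the classical McNemar paired-proportion sample size on n·v voxel pairs;
this is verified in the tests against an independently coded McNemar
formula.

## Sample-size solver

The two-critical-value relation n = (t_{α(2)} σ₀ + t_{β(1)} σ_alt)²/δ²_MDD
is circular because the t quantiles use df = n − 1.  Conventions chosen:

* damped fixed-point iteration (step 0.5) on the continuous df = n − 1,
  initialized at the normal-quantile closed form, converged to
  |Δn| < 10⁻⁶, df floored at 2;
* the headline n is ⌈n_continuous⌉ (conservative); the continuous
  solution is reported alongside for boundary analysis;
* δ_MDD enters squared, so signed input is accepted and |δ_MDD| used;
* σ₀ and σ_alt enter as standard deviations (t·√σ²), the dimensionally
  consistent reading;
* achieved power at integer n inverts the same relation:
  t_{β(1)} = (|δ_MDD| √n − t_{α(2)} σ₀)/σ_alt, power = P(T_{n−1} ≤ t_{β(1)}).
  This two-critical-value approximation — not exact noncentral-t power —
  is the package's contract throughout; at small n it understates exact
  normal-theory power by 1–2% (see Limitations).
* results with n < 9 carry a small-sample warning: the t-test is
  sensitive to non-normality at such sizes and the skew of d̄ under this
  model is nonzero whenever δ ≠ 0 and ω < ∞.

Solving n for a reference design table reproduces the expected grid;
cells near integer boundaries can round differently under other
df-iteration conventions (the continuous solutions are reported so users
can see how close a cell sits to a boundary).

## Reference-standard quality

When requirements are specified against a high-quality reference H but
the study scores against a cheaper L, the minimum detectable difference
translates additively:

δ_MDD = δ_MDD,H + 2 (p(a) − p(b)) (p(l) − p(h)) + 2 cov(A−B, L−H).

The first correction is systematic over/under-contouring by L interacting
with a difference in the algorithms' foreground proportions; the second
is reference errors biased toward one algorithm.  No clamping is applied;
if the corrected value crosses zero the package warns that the low-quality
reference reverses the apparent direction of the difference, which no
sample size can repair.  Note that with binary labels A − B =
D·(2L − 1) identically, which the synthetic-pilot generator exploits.

## Pilot estimation

Pooled estimators are the grand means/moments over all n′·v pilot voxels:
foreground probabilities, ψ̂, δ̂, and the error covariance with an
(n′v − 1) denominator.  The variance σ̂_d̄² is the unbiased sample variance
of the per-image means, and f̂ = σ̂_d̄²/(ψ̂ − δ̂²) (clipped to 1 with a
warning if sampling noise pushes it above).  When images have unequal
voxel counts, each image's d̄_k uses its own v; the pooled sums then
weight voxels rather than images, a documented deviation from the
equal-v formulas.

Two estimators need more care:

* **Conservative variance bound.**  Small-pilot variance estimates are
  noisy and right-skewed, which inflates the risk of an underpowered
  study.  The package reports the upper end of a γ% confidence interval
  on σ_d̄², computed by a calibrated (double) bootstrap: an outer
  bootstrap gives the percentile distribution of the variance; an inner
  layer estimates the nominal level whose actual coverage is γ%, and the
  bound is the outer quantile at that calibrated level.  Defaults:
  γ = 80%, 1000 outer × 200 inner replicates, seeded.  Coverage at
  n′ = 10 is verified by simulation in the test suite.
* **Dirichlet precision.**  ω is identified by removing intra-image
  correlation: voxels spaced x apart on the image lattice are treated as
  effectively uncorrelated given O⃗_k, so their per-image category counts
  are Dirichlet-multinomial.  ω̂ is the maximum-likelihood precision by
  the standard fixed-point iteration with the mean fixed at pooled
  proportions (full mean-and-precision fitting is deliberately not the
  default: the model uses a single precision parameter).  The default
  spacing is the smallest x with kernel correlation below 1%
  (x ≥ σ_ρ² ln 100) when σ_ρ is known, else 5 voxels.  A pre-check of
  the likelihood gradient at 10⁸ detects the no-inter-image-variability
  case (MLE at infinity) and returns a capped value (10⁹) with a warning.
  Identification needs enough sparse voxels per image: with ω ≈ 128,
  v ≈ 36 sparse samples leave the multinomial noise larger than the
  inter-image signal, and ω is practically unidentifiable; the package's
  recovery tests use 256 sparse voxels per image, a realistic yield for
  volumetric masks.  ρ̄̂ then inverts the Dirichlet variance identity,
  ρ̄̂ = (σ̂²(ω̂+1) − (ψ̂−δ̂²))/((ψ̂−δ̂²) ω̂), clipped to [0, 1] with a warning.

## Monte Carlo simulator

The simulator draws studies exactly from the assumed model: per-image
Dirichlet marginals, then v correlated ternary voxels, then the paired
t-test.  Design choices:

* **Spatial kernel.**  Voxels sit on an integer lattice (rows × cols; a
  scalar v is laid out √v × √v and must be a perfect square).  Distances
  are Euclidean; ρ_ij = exp(−Dist_ij/σ_ρ²); σ_ρ = 0 gives independent
  voxels.  ρ̄ is the grand mean of the kernel including the diagonal.
* **Correlation semantics.**  The target ρ_ij is the Pearson correlation
  of the ordinal (−1, 0, 1) values *conditional on the image's
  marginals*, matching the model's definition.  Sampling is NORTA-style:
  a latent multivariate normal is thresholded at the marginal quantiles
  (category order −1 < 0 < 1).  For each image, the monotone map from
  latent to ordinal correlation is evaluated on a fixed 64-node grid of
  latent correlations using a vectorized bivariate-normal routine
  (Genz/Drezner–Wesolowsky, accurate to ~10⁻¹³) and inverted by
  interpolation; the achieved ordinal correlation is within ~2·10⁻⁶ of
  target (verified against brute-force 2-D quadrature).  The calibrated
  matrix is Cholesky-factored, with nearest-PSD repair by eigenvalue
  clipping if needed; targets above the achievable maximum fall back to
  the target itself with a warning.
* **Reproducibility.**  A master seed spawns one independent stream per
  replicate study, so results are bit-identical for a given seed and
  independent of replicate order.
* **Problem sizes.**  Default 2,000 study replicates per scenario (95%
  binomial CI half-width about 1.8 points at 80% power); variance
  comparisons use 20,000 images so the Monte-Carlo uncertainty of a
  sample variance (≈1% relative) is small against the few-percent
  agreement being checked.

### Synthetic pilot masks

The generator reconstructs mask quadruples (A, B, L, H) from simulated
difference fields.  L is drawn conditionally on D so that pooled p(a),
p(b), p(l) match requested values (a "both wrong" rate on agreeing voxels
adds realism without touching D); A and B then follow deterministically.
H flips L with stratified rates — eps₁ = P(H=0|L=1) and eps₀ = P(H=1|L=0)
solved from p(h) and a nominal L–H disagreement rate (default 4%,
typical of a careful non-expert reference) — plus a modulation
proportional to each stratum's flip rate that carries the requested
cov(A−B, L−H).  p(h) and the covariance are matched exactly in
expectation; the realized disagreement rate shifts slightly (order
g·cov(A−B, L)) from the modulation.  Requests that would push any
conditional probability outside [0, 1] raise an error.

What the simulator does *not* emulate: anatomy or image intensities,
boundary-localized errors (errors are spatially stationary given the
kernel), inter-rater structure beyond the single L–H pair, and any
resampling of real data.  Tests passing on simulator output therefore
validate the formulas *under the assumed model*, and parameter recovery
under correct specification — not robustness to real-data violations
such as heavy-tailed or boundary-concentrated error fields.

## Known limitations

* The two-critical-value power approximation understates exact
  noncentral-t power by ~1.4% at n ≈ 9; combined with the skew of d̄
  (≈0.38 at δ = 10%, ψ = 15%, ω = 128), simulated power at the
  large-difference configuration exceeds the prediction by ≈4.4 points
  (measured with 20,000 replicate studies).  At the baseline δ = 3% the
  agreement is within half a point.  Conclusion unchanged from the
  model's own caution: for large detectable differences the solved n is
  small, the t-test's normality assumption bites, and a clustered exact
  test would be preferable.
* The pooled covariance estimator treats voxels as independent in its
  denominator; intra-image correlation inflates its sampling variance
  (not its expectation).
* The Dirichlet-precision estimator is the noisiest component
  (coefficient of variation ~15% even at 100 images × 256 independent
  voxels) and degrades quickly with fewer sparse voxels per image.
* The correlated sampler scales as O(v²)–O(v³) per image (kernel matrix
  and factorization), practical to v of a few thousand, far below real
  volume sizes — which is fine for its purpose (validating formulas and
  generating fixtures), since the formulas themselves are closed-form in
  v.
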