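# segpower

Statistical power, sample size and reference-standard quality for image
segmentation comparison studies.

## The problem

A segmentation study compares two algorithms, A and B, by scoring each
against a reference standard L on n images of v voxels and testing the
per-image accuracy differences with a paired Student's t-test.  How many
images are needed to detect a given accuracy difference with, say, 80%
power?  And if the study can only afford a cheaper, lower-quality
reference standard, how does that change the difference the study should
be designed to detect?  `segpower` answers both questions for researchers
designing validation studies in medical image analysis.

## The model

The unit of analysis is the per-voxel accuracy difference
D = |B − L| − |A − L| ∈ {−1, 0, 1}, with population marginals
p⃗ = ⟨p₁, p₀, p₋₁⟩, accuracy difference δ = p₁ − p₋₁ and disagreement
probability ψ = p₁ + p₋₁.  The general sample-size relation for the paired
t-test is

    n = (t_{α(2)} σ₀ + t_{β(1)} σ_alt)² / δ²_MDD

where σ₀² and σ_alt² are the variances of the per-image mean difference d̄
under the null and alternative hypotheses, and the t quantiles use n − 1
degrees of freedom (a fixed point in n, solved by damped iteration from
the normal-quantile closed form).  Two routes supply the variances:

* **moment route** (any prior on per-image marginals):
  σ_d̄² = ρ̄ (ψ − δ²) + (1 − ρ̄) σ²_{O₁−O₋₁},
  with ρ̄ the average intra-image inter-voxel correlation and
  σ²_{O₁−O₋₁} the inter-image variance of the marginals;
* **Dirichlet route**: with a Dirichlet(ω, p⃗) prior on per-image
  marginals, σ²_{O₁−O₋₁} = (ψ − δ²)/(ω + 1) and everything collapses into
  a *design factor* f = (1 + ω ρ̄)/(ω + 1):

      σ_d̄² = f (ψ − δ²),
      n = f (t_{α(2)} √(ψ/δ²_MDD) + t_{β(1)} √(ψ/δ²_MDD − 1))².

When requirements are set against a high-quality reference H but the
study will use a lower-quality L, the minimum detectable difference
translates as

    δ_MDD = δ_MDD,H + 2 (p(a) − p(b)) (p(l) − p(h)) + 2 cov(A−B, L−H).

Every parameter (ψ, δ, σ_d̄², f, ω, ρ̄, the label probabilities and the
error covariance) is estimable from a small pilot of co-registered masks;
a Monte Carlo simulator of spatially correlated voxel differences
(Dirichlet prior + Gaussian-copula ordinal sampling on an exponential
spatial kernel ρ_ij = exp(−Dist_ij/σ_ρ²)) validates the formulas and
generates synthetic pilot fixtures.

## Worked example

```bash
python examples/sample_size_basics.py
```

```
continuous solution : n = 64.53
required sample size: n = 65 images
critical values     : t_alpha(2) = 1.998, t_beta(1) = 0.847
power at n = 65  : 0.803
power at n = 75: 0.857
```

To detect a 5% accuracy difference between algorithms that disagree on
20% of voxels, with a design factor of 0.1 (moderate voxel correlation
and inter-image variability), the study needs 65 images; enrolling 65
(the ceiling of the continuous solution 64.53) achieves 80.3% power, and
ten further images would raise it to 85.7%.

The other examples cover the reference-quality trade-off
(`reference_quality_tradeoff.py`: a low-quality reference whose errors
covary with the algorithms shrinks the detectable difference from 5% to
4.38% and raises the required n from 10 to 13), full parameter estimation
from a synthetic pilot (`estimate_from_pilot.py`) and Monte Carlo
validation of the formulas (`validate_power_by_simulation.py`).

A thin CLI mirrors the library:

```bash
segpower samplesize --delta-mdd 0.05 --psi 0.20 --design-factor 0.1
segpower adjust-mdd --delta-mdd-h 0.05 --pa 0.246 --pb 0.195 --pl 0.210 --ph 0.214 --cov -0.0029
segpower design-table
segpower simulate --grid 6x6 --delta 0.03 --psi 0.15 --n-images 74 --reps 400 --seed 1
```

## Layout

| module | contents |
| --- | --- |
| `segpower.model` | domain types, voxel difference metrics, paired t-test |
| `segpower.power` | variance routes, sample-size solver, power, design table |
| `segpower.reference_quality` | δ_MDD translation between reference standards |
| `segpower.estimation` | pilot estimators, bootstrap variance bound, Dirichlet precision fit |
| `segpower.simulator` | spatial model, copula sampler, study simulation, synthetic pilots |
| `segpower.io` / `segpower.cli` | NIfTI/MetaImage/CSV I/O, reports, CLI verbs |

See `docs/methods.md` for the statistical details, numerical conventions
and known limitations.
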