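"""Cost of using a cheaper, lower-quality reference standard.

Accuracy requirements are naturally set against a high-quality reference H
(say, expert consensus), but the study may only afford a lower-quality
reference L.  The minimum detectable difference must then be translated
from H to L using label statistics estimated from a small pilot that has
both references.  The translated MDD and the (typically larger) variance
against L together determine the extra images the cheaper study needs.
"""

from segpower import (
    ReferenceQualityParams,
    StudyDesign,
    VarianceSpec,
    adjust_mdd,
    bias_decomposition,
    solve_sample_size,
)

# pilot estimates: foreground proportions of the algorithms and both
# references, and the covariance between reference errors and algorithm
# disagreement
params = ReferenceQualityParams(
    delta_mdd_H=0.05, pa=0.246, pb=0.195, pl=0.210, ph=0.214, cov_ab_lh=-0.0029
)
contouring, covariance = bias_decomposition(params)
mdd_L = adjust_mdd(params)
print(f"MDD against H            : {params.delta_mdd_H:.4f}")
print(f"over/under-contour term  : {contouring:+.6f}")
print(f"error-covariance term    : {covariance:+.6f}")
print(f"MDD usable with L        : {mdd_L:.6f}")

# sample sizes under each scenario (variances from the same pilot)
n_high = solve_sample_size(VarianceSpec(0.00231, 0.00231), StudyDesign(delta_mdd=0.05))
n_low = solve_sample_size(VarianceSpec(0.00253, 0.00253), StudyDesign(delta_mdd=mdd_L))
print(f"n with high-quality ref  : {n_high.n}")
print(f"n with low-quality ref   : {n_low.n}")

# The low-quality reference "shrinks" the detectable difference here
# (its errors covary against algorithm A), so the cheaper study needs
# more images; whether that trade is worth it depends on the per-image
# cost of each reference standard.
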