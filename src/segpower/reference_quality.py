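"""Minimum-detectable-difference correction for imperfect reference standards.

Study requirements are naturally specified against a high-quality reference
standard H, but many studies can only afford a cheaper, lower-quality
reference L.  The accuracy difference measured against L differs from the
one measured against H by two estimable terms::

    delta_MDD = delta_MDD_H + 2 (p(a) - p(b)) (p(l) - p(h))
                            + 2 cov(A - B, L - H)

The first correction term is the interaction of systematic over- or
under-contouring by L with a difference in the algorithms' foreground
proportions; the second is the covariance between L's errors and the
algorithms' disagreement, i.e. reference errors biased in favour of one
algorithm.  The corrected delta_MDD is the value to feed into the sample
size formulas when the study will be scored against L.
"""

from __future__ import annotations

import warnings

from .model import ReferenceQualityParams, SegpowerWarning

__all__ = ["adjust_mdd", "bias_decomposition"]


def bias_decomposition(params: ReferenceQualityParams) -> tuple[float, float]:
    """The two additive correction terms, separately.

    Returns ``(contouring_term, covariance_term)`` where the contouring
    term is ``2 (p(a) - p(b)) (p(l) - p(h))`` and the covariance term is
    ``2 cov(A - B, L - H)``.
    """
    contouring = 2.0 * (params.pa - params.pb) * (params.pl - params.ph)
    covariance = 2.0 * params.cov_ab_lh
    return contouring, covariance


def adjust_mdd(params: ReferenceQualityParams) -> float:
    """delta_MDD usable with the low-quality reference L.

    Warns if the corrected value crosses zero relative to ``delta_mdd_H``:
    the reference errors are then large enough to reverse the apparent
    direction of the difference, and a study against L cannot address the
    original requirement.  No clamping is applied.
    """
    contouring, covariance = bias_decomposition(params)
    adjusted = params.delta_mdd_H + contouring + covariance
    if adjusted * params.delta_mdd_H < 0 or (
        adjusted == 0.0 and params.delta_mdd_H != 0.0
    ):
        warnings.warn(
            f"adjusted delta_MDD ({adjusted:.4g}) has the opposite sign of "
            f"delta_MDD_H ({params.delta_mdd_H:.4g}): the low-quality reference "
            "reverses the apparent direction of the difference",
            SegpowerWarning,
            stacklevel=2,
        )
    return adjusted
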