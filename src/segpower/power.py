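"""Sample-size and power formulas for paired segmentation comparisons.

The analysis is a two-sided paired t-test on per-image accuracy differences
``d_bar``.  The generic sample-size relation is the classic two-critical-
value approximation

    n = (t_{alpha(2)} * sigma_0 + t_{beta(1)} * sigma_alt)^2 / delta_MDD^2

with ``sigma_0^2`` and ``sigma_alt^2`` the variances of ``d_bar`` under the
null and alternative hypotheses, and t quantiles taken at n - 1 degrees of
freedom, which makes the relation a fixed point in n.  Two routes supply
the variances:

* a moment-based route valid for any prior on the per-image marginals:
  ``sigma_Dbar^2 = rho_bar (psi - delta^2) + (1 - rho_bar) sigma_{O1-O-1}^2``
* a Dirichlet-prior route where the inter-image variance collapses into a
  single *design factor* ``f = (1 + omega rho_bar) / (omega + 1)``:
  ``sigma_Dbar^2 = f (psi - delta^2)``, giving
  ``n = f (t_{alpha(2)} sqrt(psi/delta_MDD^2) + t_{beta(1)} sqrt(psi/delta_MDD^2 - 1))^2``

In the limit rho_bar = 1/v with no inter-image variability, the Dirichlet
route reduces to McNemar's paired-proportion sample size with n*v voxel
samples.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .model import (
    PopulationModel,
    SampleSizeResult,
    SmallSampleWarning,
    SolverSettings,
    StudyDesign,
    VarianceSpec,
    design_factor,
)

__all__ = [
    "variance_moments",
    "variance_dirichlet",
    "solve_sample_size",
    "sample_size_moments",
    "sample_size_dirichlet",
    "power_at_n",
    "design_table",
]

#: below this many images the t-test is fragile to non-normality
SMALL_SAMPLE_THRESHOLD = 9


def variance_moments(
    psi: float, delta: float, rho_bar: float, sigma2_O1mOm1: float
) -> float:
    """Variance of d_bar from prior moments (distribution-free route).

    ``rho_bar (psi - delta^2) + (1 - rho_bar) sigma_{O1-O-1}^2`` where
    ``sigma2_O1mOm1`` is the variance of O1 - O-1 across images.
    """
    if not (0.0 <= rho_bar <= 1.0):
        raise ValueError(f"rho_bar must be in [0, 1], got {rho_bar}")
    if sigma2_O1mOm1 < 0:
        raise ValueError(f"sigma2_O1mOm1 must be >= 0, got {sigma2_O1mOm1}")
    if psi < delta * delta:
        raise ValueError(f"require psi >= delta^2, got psi={psi}, delta={delta}")
    return rho_bar * (psi - delta * delta) + (1.0 - rho_bar) * sigma2_O1mOm1


def variance_dirichlet(
    psi: float,
    delta: float,
    f: float | None = None,
    *,
    omega: float | None = None,
    rho_bar: float | None = None,
) -> float:
    """Variance of d_bar under a Dirichlet per-image prior: f * (psi - delta^2).

    Pass the design factor ``f`` directly, or ``omega`` and ``rho_bar`` to
    form it as (1 + omega * rho_bar) / (omega + 1).
    """
    if f is None:
        if omega is None or rho_bar is None:
            raise ValueError("supply f, or both omega and rho_bar")
        f = design_factor(omega, rho_bar)
    elif omega is not None or rho_bar is not None:
        raise ValueError("supply either f or (omega, rho_bar), not both")
    if not (0.0 < f <= 1.0):
        raise ValueError(f"design factor must be in (0, 1], got {f}")
    if psi < delta * delta:
        raise ValueError(f"require psi >= delta^2, got psi={psi}, delta={delta}")
    return f * (psi - delta * delta)


def _critical_values(
    alpha: float, beta: float, df: float, use_t: bool
) -> tuple[float, float]:
    if use_t:
        return stats.t.ppf(1.0 - alpha / 2.0, df), stats.t.ppf(1.0 - beta, df)
    return stats.norm.ppf(1.0 - alpha / 2.0), stats.norm.ppf(1.0 - beta)


def _solve_fixed_point(sigma0: float, sigma_alt: float, design: StudyDesign) -> SampleSizeResult:
    """Damped fixed-point solve of n = (t_a sigma0 + t_b sigma_alt)^2 / dmdd^2."""
    dmdd = design.require_delta_mdd()
    s = design.solver
    if sigma0 == 0.0 and sigma_alt == 0.0:
        raise ValueError("sigma_0 and sigma_alt cannot both be zero")

    za, zb = _critical_values(design.alpha, design.beta, math.inf, use_t=False)
    n = (za * sigma0 + zb * sigma_alt) ** 2 / dmdd**2
    ta, tb = za, zb
    if s.use_t:
        converged = False
        for _ in range(s.max_iter):
            df = max(n - 1.0, s.min_df)
            ta, tb = _critical_values(design.alpha, design.beta, df, use_t=True)
            n_new = (ta * sigma0 + tb * sigma_alt) ** 2 / dmdd**2
            if abs(n_new - n) < s.tol:
                n = n_new
                converged = True
                break
            n = (1.0 - s.damping) * n + s.damping * n_new
        if not converged:
            raise RuntimeError(
                f"sample-size iteration did not converge in {s.max_iter} steps"
            )
    n_int = max(int(math.ceil(n - 1e-9)), 3)
    achieved = power_at_n(
        n_int, design, variances=VarianceSpec(sigma0**2, sigma_alt**2)
    )
    small = n_int < SMALL_SAMPLE_THRESHOLD
    if small:
        warnings.warn(
            f"computed sample size n={n_int} is small; the t-test is sensitive "
            "to violations of its assumptions at such sizes",
            SmallSampleWarning,
            stacklevel=3,
        )
    return SampleSizeResult(
        n_continuous=float(n),
        n=n_int,
        t_alpha2=float(ta),
        t_beta1=float(tb),
        power_at_n=float(achieved),
        small_sample=small,
    )


def solve_sample_size(variances: VarianceSpec, design: StudyDesign) -> SampleSizeResult:
    """Solve the generic sample-size relation for given variances.

    The iteration runs on continuous degrees of freedom n - 1 (floored at
    ``solver.min_df``), starting from the normal-quantile closed form, and
    the headline ``n`` is the ceiling of the converged continuous solution.
    """
    return _solve_fixed_point(
        math.sqrt(variances.sigma2_null), math.sqrt(variances.sigma2_alt), design
    )


def sample_size_moments(model: PopulationModel, design: StudyDesign) -> SampleSizeResult:
    """Sample size via the moment-based variance route.

    Uses ``model.sigma2_O1mOm1_null`` / ``_alt`` for the inter-image
    variance of O1 - O-1 under each hypothesis.
    """
    if model.sigma2_O1mOm1_null is None or model.sigma2_O1mOm1_alt is None:
        raise ValueError(
            "moment-based route requires sigma2_O1mOm1_null and sigma2_O1mOm1_alt"
        )
    dmdd = design.require_delta_mdd()
    s0 = variance_moments(model.psi, 0.0, model.rho_bar, model.sigma2_O1mOm1_null)
    s_alt = variance_moments(model.psi, dmdd, model.rho_bar, model.sigma2_O1mOm1_alt)
    return solve_sample_size(VarianceSpec(s0, s_alt), design)


def sample_size_dirichlet(
    psi: float,
    design: StudyDesign,
    f: float | None = None,
    *,
    omega: float | None = None,
    rho_bar: float | None = None,
) -> SampleSizeResult:
    """Sample size under the Dirichlet-prior variance model.

    Solves ``n = f (t_{alpha(2)} sqrt(psi/dmdd^2) + t_{beta(1)}
    sqrt(psi/dmdd^2 - 1))^2`` by the same fixed-point scheme as
    :func:`solve_sample_size`.
    """
    dmdd = design.require_delta_mdd()
    if psi < dmdd * dmdd:
        raise ValueError(
            f"require psi >= delta_mdd^2 (idealized efficiency >= 1), "
            f"got psi={psi}, delta_mdd={dmdd}"
        )
    s0 = variance_dirichlet(psi, 0.0, f, omega=omega, rho_bar=rho_bar)
    s_alt = variance_dirichlet(psi, dmdd, f, omega=omega, rho_bar=rho_bar)
    return solve_sample_size(VarianceSpec(s0, s_alt), design)


def power_at_n(
    n: float,
    design: StudyDesign,
    *,
    variances: VarianceSpec | None = None,
    psi: float | None = None,
    f: float | None = None,
) -> float:
    """Achieved power 1 - beta of a study with n images.

    Inverts the sample-size relation for the one-tailed critical value:
    ``t_{beta(1)} = (|delta_MDD| sqrt(n) - t_{alpha(2)} sigma_0) /
    sigma_alt`` and returns ``P(T_{n-1} <= t_{beta(1)})``.  Accepts either
    an explicit :class:`VarianceSpec` or ``(psi, f)`` for the Dirichlet
    route.  ``n`` may be continuous (used by round-trip checks).
    """
    if n < 3:
        raise ValueError(f"power is defined for n >= 3, got {n}")
    dmdd = design.require_delta_mdd()
    if variances is None:
        if psi is None or f is None:
            raise ValueError("supply variances, or psi and f")
        variances = VarianceSpec(
            variance_dirichlet(psi, 0.0, f), variance_dirichlet(psi, dmdd, f)
        )
    elif psi is not None or f is not None:
        raise ValueError("supply either variances or (psi, f), not both")
    sigma0 = math.sqrt(variances.sigma2_null)
    sigma_alt = math.sqrt(variances.sigma2_alt)
    if sigma_alt == 0.0:
        return 1.0
    df = n - 1.0
    if design.solver.use_t:
        ta = stats.t.ppf(1.0 - design.alpha / 2.0, df)
    else:
        ta = stats.norm.ppf(1.0 - design.alpha / 2.0)
    t_beta = (dmdd * math.sqrt(n) - ta * sigma0) / sigma_alt
    if design.solver.use_t:
        return float(stats.t.cdf(t_beta, df))
    return float(stats.norm.cdf(t_beta))


# (delta_mdd, [psi levels]) blocks of the reference design table
_DESIGN_TABLE_BLOCKS: list[tuple[float, list[float]]] = [
    (0.02, [0.02, 0.11, 0.20]),
    (0.05, [0.05, 0.125, 0.20]),
    (0.10, [0.10, 0.15, 0.20]),
]
_DESIGN_TABLE_F = [0.01, 0.05, 0.1]


def design_table(
    alpha: float = 0.05,
    beta: float = 0.20,
    small_sample_threshold: int = SMALL_SAMPLE_THRESHOLD,
) -> pd.DataFrame:
    """Reference grid of required sample sizes.

    27 cells of ``n`` over delta_MDD in {2%, 5%, 10%}, three disagreement
    levels psi per block, and design factors f in {0.01, 0.05, 0.1}.
    Cells with n below ``small_sample_threshold`` carry an asterisk in the
    ``flagged`` companion column (t-test assumptions fragile).  Returns a
    DataFrame indexed by (delta_mdd, psi) with one column per f holding
    integer n, and boolean columns ``flag_<f>``.
    """
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", SmallSampleWarning)
        for dmdd, psis in _DESIGN_TABLE_BLOCKS:
            for psi in psis:
                design = StudyDesign(alpha=alpha, beta=beta, delta_mdd=dmdd)
                row: dict[str, object] = {"delta_mdd": dmdd, "psi": psi}
                for f in _DESIGN_TABLE_F:
                    res = sample_size_dirichlet(psi, design, f)
                    row[f"n_f{f:g}"] = res.n
                    row[f"flag_f{f:g}"] = res.n < small_sample_threshold
                rows.append(row)
    return pd.DataFrame(rows).set_index(["delta_mdd", "psi"])
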