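"""Estimate sample-size model parameters from a segmented pilot dataset.

All pooled estimators are grand means or pooled sample moments over every
voxel of every pilot image:

* ``p_hat(x)``: pooled foreground proportion of one label source,
* ``psi_hat``: pooled proportion of voxels where A and B disagree,
* ``delta_hat``: pooled mean of the per-voxel accuracy difference,
* ``cov_hat(A-B, L-H)``: pooled sample covariance (n'v - 1 denominator)
  between algorithm differences and reference-standard errors,
* ``sigma2_hat``: unbiased sample variance of the per-image means d_bar,
* ``f_hat = sigma2_hat / (psi_hat - delta_hat^2)``: the design factor.

Because small pilots give noisy, right-skewed variance estimates, a
conservative upper bound on ``sigma2`` is also provided: the upper end of
a gamma% confidence interval estimated with a calibrated (double)
bootstrap.  To separate inter-image variability from intra-image
correlation, the Dirichlet precision ``omega`` is fitted by maximum
likelihood to category counts taken on a spatially sparse voxel lattice
(where residual correlation is negligible), and ``rho_bar`` is then
recovered from the variance identity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma

from .model import PilotDataset, SegpowerWarning, voxel_differences
from .reference_quality import adjust_mdd
from .model import ReferenceQualityParams

__all__ = [
    "EstimationConfig",
    "PilotEstimates",
    "estimate_foreground_prob",
    "estimate_error_covariance",
    "estimate_psi",
    "estimate_delta",
    "estimate_variance",
    "variance_upper_bound",
    "estimate_design_factor",
    "estimate_dirichlet_precision",
    "fit_dirichlet_multinomial_precision",
    "estimate_rho_bar",
    "estimate_all",
    "OMEGA_CAP",
]

#: precision above this is reported as "no detectable inter-image variability"
OMEGA_CAP = 1e9


@dataclass(frozen=True)
class EstimationConfig:
    """Settings for the variance bound and precision estimation.

    ``gamma`` is the confidence level (percent) of the conservative
    variance bound; ``boot_outer`` / ``boot_inner`` the double-bootstrap
    replicate counts; ``sparse_spacing`` the voxel spacing of the sparse
    lattice for precision fitting (None derives it from ``sigma_rho`` as
    the smallest spacing with kernel correlation below 1%).
    """

    gamma: float = 80.0
    boot_outer: int = 1000
    boot_inner: int = 200
    sparse_spacing: int | None = 5
    sigma_rho: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma < 100.0):
            raise ValueError(f"gamma must be in (0, 100), got {self.gamma}")
        if self.boot_outer < 100 or self.boot_inner < 100:
            raise ValueError("bootstrap replicate counts must be >= 100")
        if self.sparse_spacing is not None and self.sparse_spacing < 1:
            raise ValueError("sparse_spacing must be >= 1")

    def spacing(self) -> int:
        """Sparse-lattice spacing; derived from sigma_rho when known."""
        if self.sigma_rho is not None:
            # smallest x with exp(-x / sigma_rho^2) < 0.01
            derived = max(int(math.ceil(self.sigma_rho**2 * math.log(100.0))), 1)
            return derived
        return self.sparse_spacing if self.sparse_spacing is not None else 5


@dataclass(frozen=True)
class PilotEstimates:
    """Every model parameter estimated from one pilot dataset."""

    psi_hat: float
    delta_hat: float
    sigma2_hat: float
    sigma2_upper: float
    f_hat: float
    omega_hat: float | None = None
    rho_bar_hat: float | None = None
    pa_hat: float | None = None
    pb_hat: float | None = None
    pl_hat: float | None = None
    ph_hat: float | None = None
    cov_hat: float | None = None
    delta_mdd_hat: float | None = None
    warnings_: tuple[str, ...] = field(default_factory=tuple)


def _pooled(labels: tuple[np.ndarray, ...]) -> np.ndarray:
    if len(labels) == 0:
        raise ValueError("empty pilot dataset")
    return np.concatenate([np.asarray(img).ravel() for img in labels])


def estimate_foreground_prob(labels: tuple[np.ndarray, ...]) -> float:
    """Pooled foreground proportion over all voxels of all pilot images."""
    pooled = _pooled(labels)
    if pooled.size == 0:
        raise ValueError("label source contains no voxels")
    return float(pooled.mean())


def estimate_error_covariance(pilot: PilotDataset) -> float:
    """Pooled covariance between A - B and the reference error L - H.

    Sample covariance over all n'v voxels with an (n'v - 1) denominator.
    """
    if not pilot.has_H:
        raise ValueError("estimating cov(A-B, L-H) requires the high-quality reference H")
    x = _pooled(pilot.labels_A).astype(float) - _pooled(pilot.labels_B)
    y = _pooled(pilot.labels_L).astype(float) - _pooled(pilot.labels_H)
    n = x.size
    if n < 2:
        raise ValueError("need at least two voxels for a covariance")
    return float((x - x.mean()) @ (y - y.mean()) / (n - 1))


def estimate_psi(pilot: PilotDataset) -> float:
    """Pooled probability that A and B disagree on a voxel label."""
    a = _pooled(pilot.labels_A)
    b = _pooled(pilot.labels_B)
    return float(np.abs(a - b).mean())


def estimate_delta(pilot: PilotDataset, reference: str = "L") -> float:
    """Pooled mean per-voxel accuracy difference against the chosen reference."""
    diff = voxel_differences(pilot, reference)
    return float(diff.pooled.mean())


def variance_upper_bound(
    d_bar: np.ndarray,
    gamma: float = 80.0,
    boot_outer: int = 1000,
    boot_inner: int = 200,
    rng: np.random.Generator | None = None,
) -> float:
    """Calibrated-bootstrap upper confidence bound on var(d_bar).

    The percentile upper bound at nominal level gamma% is miscalibrated
    for small, skewed variance sampling distributions; a second bootstrap
    layer estimates the nominal level whose actual coverage is gamma%
    (percentile calibration), and the bound is the outer bootstrap
    quantile at that calibrated level.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    d_bar = np.asarray(d_bar, dtype=float)
    n = d_bar.size
    if n < 2:
        raise ValueError("need at least two images")
    theta_hat = d_bar.var(ddof=1)
    if theta_hat == 0.0:
        return 0.0
    outer_idx = rng.integers(0, n, size=(boot_outer, n))
    outer_samples = d_bar[outer_idx]
    theta_star = outer_samples.var(axis=1, ddof=1)
    # inner layer, chunked to bound memory
    u = np.empty(boot_outer)
    chunk = max(1, int(5e6 // (boot_inner * n)))
    for start in range(0, boot_outer, chunk):
        stop = min(start + chunk, boot_outer)
        block = outer_samples[start:stop]  # (m, n)
        inner_idx = rng.integers(0, n, size=(stop - start, boot_inner, n))
        inner = np.take_along_axis(block[:, None, :], inner_idx, axis=2)
        theta_inner = inner.var(axis=2, ddof=1)  # (m, boot_inner)
        u[start:stop] = (theta_inner <= theta_hat).mean(axis=1)
    level = float(np.quantile(u, gamma / 100.0))
    level = min(max(level, 1.0 / boot_outer), 1.0 - 1.0 / boot_outer)
    return float(np.quantile(theta_star, level))


def estimate_variance(
    pilot: PilotDataset,
    reference: str = "L",
    config: EstimationConfig | None = None,
) -> tuple[float, float]:
    """Unbiased sample variance of d_bar and its conservative upper bound."""
    if pilot.n_images < 2:
        raise ValueError("variance estimation needs at least two pilot images")
    if config is None:
        config = EstimationConfig()
    d_bar = voxel_differences(pilot, reference).d_bar
    sigma2 = float(d_bar.var(ddof=1))
    rng = np.random.default_rng(config.seed)
    upper = variance_upper_bound(
        d_bar, config.gamma, config.boot_outer, config.boot_inner, rng
    )
    return sigma2, upper


def estimate_design_factor(psi_hat: float, delta_hat: float, sigma2_hat: float) -> float:
    """Design factor f_hat = sigma2_hat / (psi_hat - delta_hat^2).

    Values above 1 (possible by sampling noise) are clipped to 1 with a
    warning.
    """
    denom = psi_hat - delta_hat * delta_hat
    if denom <= 0:
        raise ValueError(
            f"design factor undefined: psi_hat ({psi_hat}) must exceed "
            f"delta_hat^2 ({delta_hat**2})"
        )
    if sigma2_hat < 0:
        raise ValueError("sigma2_hat must be >= 0")
    f = sigma2_hat / denom
    if f > 1.0:
        warnings.warn(
            f"estimated design factor {f:.3f} exceeds 1; clipping to 1",
            SegpowerWarning,
            stacklevel=2,
        )
        f = 1.0
    return float(f)


def fit_dirichlet_multinomial_precision(
    counts: np.ndarray,
    mean: np.ndarray | None = None,
    tol: float = 1e-8,
    max_iter: int = 10000,
) -> float:
    """Maximum-likelihood precision of a Dirichlet-multinomial distribution.

    ``counts`` is an (images, categories) matrix of per-image category
    counts.  The mean vector is fixed (default: pooled proportions) and the
    precision is found by the standard fixed-point likelihood iteration.
    Returns ``OMEGA_CAP`` when the counts show no detectable inter-image
    variability (the likelihood increases without bound in omega).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need a 2-D count matrix with at least two images")
    col_tot = counts.sum(axis=0)
    keep = col_tot > 0
    if keep.sum() < 2:
        raise ValueError("need at least two categories with nonzero counts")
    if not keep.all():
        warnings.warn(
            "category absent from all images; fitting a reduced-dimension "
            "Dirichlet-multinomial",
            SegpowerWarning,
            stacklevel=2,
        )
        counts = counts[:, keep]
    if mean is None:
        mean = counts.sum(axis=0) / counts.sum()
    else:
        mean = np.asarray(mean, dtype=float)[keep] if not keep.all() else np.asarray(mean, float)
        mean = mean / mean.sum()
    nk = counts.sum(axis=1)

    def fp_ratio(w: float) -> float:
        num = (mean * (digamma(counts + w * mean) - digamma(w * mean))).sum()
        den = (digamma(nk + w) - digamma(w)).sum()
        return num / den if den > 0 else np.inf

    # when the MLE lies at or beyond the cap the fixed point still maps
    # upward there; detect that up front instead of creeping toward it
    probe = min(OMEGA_CAP, 1e8)
    if fp_ratio(probe) >= 1.0:
        warnings.warn(
            "no detectable inter-image variability; precision capped",
            SegpowerWarning,
            stacklevel=2,
        )
        return OMEGA_CAP

    w = 50.0
    for _ in range(max_iter):
        num = (mean * (digamma(counts + w * mean) - digamma(w * mean))).sum()
        den = (digamma(nk + w) - digamma(w)).sum()
        if den <= 0:
            return OMEGA_CAP
        w_new = w * num / den
        if not np.isfinite(w_new) or w_new >= OMEGA_CAP:
            warnings.warn(
                "no detectable inter-image variability; precision capped",
                SegpowerWarning,
                stacklevel=2,
            )
            return OMEGA_CAP
        if abs(w_new - w) < tol * w:
            return float(w_new)
        w = w_new
    raise RuntimeError(f"precision fixed point did not converge in {max_iter} iterations")


def _sparse_indices(grid_shape: tuple[int, ...], spacing: int) -> np.ndarray:
    """Flat (row-major) indices of a lattice subsampled every ``spacing`` voxels."""
    axes = [np.arange(0, s, spacing) for s in grid_shape]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.ravel_multi_index([m.ravel() for m in mesh], grid_shape)


def estimate_dirichlet_precision(
    pilot: PilotDataset,
    reference: str = "L",
    config: EstimationConfig | None = None,
) -> float:
    """Dirichlet precision omega fitted to sparsely sampled voxel differences.

    Voxels spaced ``config.spacing()`` apart on the image grid are treated
    as effectively uncorrelated given the per-image marginals, so their
    per-image category counts of D in {-1, 0, 1} follow a
    Dirichlet-multinomial law whose precision is the inter-image
    variability parameter.
    """
    if pilot.n_images < 2:
        raise ValueError("precision estimation needs at least two images")
    if config is None:
        config = EstimationConfig()
    spacing = config.spacing()
    diff = voxel_differences(pilot, reference)
    counts = np.zeros((pilot.n_images, 3))
    for k, d in enumerate(diff.d):
        if pilot.grid_shape is not None and int(np.prod(pilot.grid_shape)) == d.size:
            idx = _sparse_indices(pilot.grid_shape, spacing)
            sub = d[idx]
        else:
            sub = d[::spacing]
        counts[k] = [(sub == -1).sum(), (sub == 0).sum(), (sub == 1).sum()]
    return fit_dirichlet_multinomial_precision(counts)


def estimate_rho_bar(
    sigma2_hat: float, psi_hat: float, delta_hat: float, omega_hat: float
) -> float:
    """Average intra-image correlation from the Dirichlet variance identity.

    Inverts sigma2 = (1 + omega rho_bar) / (omega + 1) * (psi - delta^2):
    ``rho_bar = (sigma2 (omega + 1) - (psi - delta^2)) / ((psi - delta^2)
    omega)``.  Clipped to [0, 1] with a warning when sampling noise pushes
    it outside.
    """
    if omega_hat <= 0:
        raise ValueError("omega_hat must be positive")
    denom = psi_hat - delta_hat * delta_hat
    if denom <= 0:
        raise ValueError("require psi_hat > delta_hat^2")
    rho = (sigma2_hat * (omega_hat + 1.0) - denom) / (denom * omega_hat)
    if not (0.0 <= rho <= 1.0):
        warnings.warn(
            f"estimated rho_bar {rho:.4f} outside [0, 1]; clipping",
            SegpowerWarning,
            stacklevel=2,
        )
        rho = float(np.clip(rho, 0.0, 1.0))
    return float(rho)


def estimate_all(
    pilot: PilotDataset,
    delta_mdd_H: float | None = None,
    config: EstimationConfig | None = None,
    reference: str = "L",
) -> PilotEstimates:
    """Estimate every model parameter from a pilot dataset.

    When ``delta_mdd_H`` is given, the corrected minimum detectable
    difference for use with L is computed from the estimated label
    probabilities and error covariance; this requires H in the pilot.
    """
    if config is None:
        config = EstimationConfig()
    if delta_mdd_H is not None and not pilot.has_H:
        raise ValueError(
            "correcting delta_mdd_H requires the high-quality reference H "
            "in the pilot dataset"
        )
    collected: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always", SegpowerWarning)
        psi_hat = estimate_psi(pilot)
        delta_hat = estimate_delta(pilot, reference)
        sigma2_hat, sigma2_upper = estimate_variance(pilot, reference, config)
        if psi_hat <= delta_hat**2:
            raise ValueError(
                "pilot shows no usable disagreement between A and B "
                f"(psi_hat={psi_hat}, delta_hat={delta_hat}); the sample-size "
                "model is degenerate for identical algorithms"
            )
        f_hat = estimate_design_factor(psi_hat, delta_hat, sigma2_hat)
        omega_hat = estimate_dirichlet_precision(pilot, reference, config)
        rho_bar_hat = estimate_rho_bar(sigma2_hat, psi_hat, delta_hat, omega_hat)

        pa_hat = estimate_foreground_prob(pilot.labels_A)
        pb_hat = estimate_foreground_prob(pilot.labels_B)
        pl_hat = estimate_foreground_prob(pilot.labels_L)
        ph_hat = cov_hat = delta_mdd_hat = None
        if delta_mdd_H is not None and not pilot.has_H:
            raise ValueError(
                "correcting delta_mdd_H requires the high-quality reference H "
                "in the pilot dataset"
            )
        if pilot.has_H:
            ph_hat = estimate_foreground_prob(pilot.labels_H)
            cov_hat = estimate_error_covariance(pilot)
            if delta_mdd_H is not None:
                delta_mdd_hat = adjust_mdd(
                    ReferenceQualityParams(
                        delta_mdd_H=delta_mdd_H,
                        pa=pa_hat,
                        pb=pb_hat,
                        pl=pl_hat,
                        ph=ph_hat,
                        cov_ab_lh=cov_hat,
                    )
                )
        collected = [str(w.message) for w in wlist]
    return PilotEstimates(
        psi_hat=psi_hat,
        delta_hat=delta_hat,
        sigma2_hat=sigma2_hat,
        sigma2_upper=sigma2_upper,
        f_hat=f_hat,
        omega_hat=omega_hat,
        rho_bar_hat=rho_bar_hat,
        pa_hat=pa_hat,
        pb_hat=pb_hat,
        pl_hat=pl_hat,
        ph_hat=ph_hat,
        cov_hat=cov_hat,
        delta_mdd_hat=delta_mdd_hat,
        warnings_=tuple(collected),
    )
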