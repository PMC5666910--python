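"""Domain types and voxel-wise accuracy-difference metrics.

The unit of analysis throughout the package is the per-voxel accuracy
difference between two segmentation algorithms A and B, measured against a
reference standard::

    D = |B - L| - |A - L|  in {-1, 0, 1}

so that ``D = 1`` where A agrees with the reference and B does not,
``D = -1`` where B agrees and A does not, and ``D = 0`` where A and B
assign the same label.  Averaging D over the voxels of one image gives the
per-image accuracy difference ``d_bar``, which is exactly the accuracy of A
minus the accuracy of B on that image; a study compares the mean of
``d_bar`` to zero with a paired Student's t-test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PopulationModel",
    "StudyDesign",
    "SolverSettings",
    "VarianceSpec",
    "SampleSizeResult",
    "PilotDataset",
    "DifferenceField",
    "ReferenceQualityParams",
    "SegpowerWarning",
    "SmallSampleWarning",
    "voxel_differences",
    "paired_t_test",
]


class SegpowerWarning(UserWarning):
    """Base warning for study-design diagnostics."""


class SmallSampleWarning(SegpowerWarning):
    """Computed sample size is small enough that t-test assumptions are fragile."""


def design_factor(omega: float, rho_bar: float) -> float:
    """Design factor f = (1 + omega * rho_bar) / (omega + 1).

    The multiplier on the idealized per-image variance contributed jointly
    by intra-image voxel correlation (``rho_bar``, averaged over ordered
    voxel pairs including the diagonal) and inter-image variability (the
    Dirichlet precision ``omega``).  ``f`` ranges from 1/v (independent
    voxels, no inter-image variability) to 1 (each image a single
    perfectly-correlated cluster).
    """
    if not (0.0 <= rho_bar <= 1.0):
        raise ValueError(f"rho_bar must be in [0, 1], got {rho_bar}")
    if math.isinf(omega):
        return rho_bar if rho_bar > 0 else 0.0
    if omega <= 0:
        raise ValueError(f"omega must be positive, got {omega}")
    return (1.0 + omega * rho_bar) / (omega + 1.0)


@dataclass(frozen=True)
class PopulationModel:
    """Marginal model of the per-voxel accuracy difference D in {-1, 0, 1}.

    Parameters
    ----------
    p1, p0, pm1:
        Population-average marginal probabilities of D = 1, 0, -1.  They
        must lie on the probability simplex.  ``delta = p1 - pm1`` is the
        population accuracy difference; ``psi = p1 + pm1`` the probability
        that A and B disagree on a voxel.
    omega:
        Dirichlet precision of the per-image prior on the marginals
        (``math.inf`` means no inter-image variability).
    rho_bar:
        Average intra-image inter-voxel correlation of D, over all ordered
        pairs including i == j.
    sigma2_O1mOm1_null, sigma2_O1mOm1_alt:
        Variances of O1 - O-1 across images under the null and alternative
        hypotheses, for the moment-based (distribution-free) variance path.
        Optional; the Dirichlet path derives them from ``omega``.
    """

    p1: float
    p0: float
    pm1: float
    omega: float = math.inf
    rho_bar: float = 0.0
    sigma2_O1mOm1_null: float | None = None
    sigma2_O1mOm1_alt: float | None = None

    def __post_init__(self) -> None:
        probs = (self.p1, self.p0, self.pm1)
        if any(p < 0 for p in probs):
            raise ValueError(f"probabilities must be non-negative, got {probs}")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError(f"p1 + p0 + pm1 must equal 1, got {sum(probs)}")
        if not (0.0 <= self.rho_bar <= 1.0):
            raise ValueError(f"rho_bar must be in [0, 1], got {self.rho_bar}")
        if not math.isinf(self.omega) and self.omega <= 0:
            raise ValueError(f"omega must be positive, got {self.omega}")

    @classmethod
    def from_delta_psi(cls, delta: float, psi: float, **kwargs) -> "PopulationModel":
        """Build from the accuracy difference and disagreement probability."""
        if not (abs(delta) <= psi <= 1.0):
            raise ValueError(f"need |delta| <= psi <= 1, got delta={delta}, psi={psi}")
        p1 = (psi + delta) / 2.0
        pm1 = (psi - delta) / 2.0
        return cls(p1=p1, p0=1.0 - psi, pm1=pm1, **kwargs)

    @property
    def delta(self) -> float:
        return self.p1 - self.pm1

    @property
    def psi(self) -> float:
        return self.p1 + self.pm1

    @property
    def f(self) -> float:
        """Design factor implied by (omega, rho_bar)."""
        return design_factor(self.omega, self.rho_bar)

    @property
    def p_vec(self) -> np.ndarray:
        """Marginals ordered (p1, p0, pm1)."""
        return np.array([self.p1, self.p0, self.pm1])


@dataclass(frozen=True)
class SolverSettings:
    """Fixed-point iteration settings for the sample-size solver.

    ``use_t=False`` replaces Student-t critical values with standard normal
    quantiles (the df = infinity closed form).
    """

    tol: float = 1e-6
    max_iter: int = 500
    damping: float = 0.5
    use_t: bool = True
    min_df: float = 2.0


@dataclass(frozen=True)
class StudyDesign:
    """Error rates and minimum detectable difference for a planned study."""

    alpha: float = 0.05
    beta: float = 0.20
    delta_mdd: float = 0.0
    solver: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not (0.0 < self.beta < 1.0):
            raise ValueError(f"beta must be in (0, 1), got {self.beta}")

    def require_delta_mdd(self) -> float:
        if self.delta_mdd == 0.0:
            raise ValueError("delta_mdd must be nonzero to solve for a sample size")
        return abs(self.delta_mdd)


@dataclass(frozen=True)
class VarianceSpec:
    """Per-image accuracy-difference variances under the two hypotheses."""

    sigma2_null: float
    sigma2_alt: float

    def __post_init__(self) -> None:
        for name in ("sigma2_null", "sigma2_alt"):
            val = getattr(self, name)
            if not (0.0 <= val <= 2.0):
                raise ValueError(f"{name} must be in [0, 2], got {val}")


@dataclass(frozen=True)
class SampleSizeResult:
    """Solved sample size with the critical values used.

    ``n`` is the conservative headline value ``ceil(n_continuous)``;
    ``power_at_n`` is the achieved power when the study enrolls ``n``
    images.  ``small_sample`` flags n below the recommended minimum where
    the t-test is sensitive to non-normality.
    """

    n_continuous: float
    n: int
    t_alpha2: float
    t_beta1: float
    power_at_n: float
    small_sample: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        star = " *small sample*" if self.small_sample else ""
        return (
            f"n = {self.n} (continuous {self.n_continuous:.3f}, "
            f"power at n = {self.power_at_n:.3f}){star}"
        )


def _as_binary_images(
    labels: Sequence[np.ndarray] | np.ndarray, name: str
) -> tuple[np.ndarray, ...]:
    if isinstance(labels, np.ndarray) and labels.ndim == 2:
        images = tuple(np.asarray(row) for row in labels)
    else:
        images = tuple(np.asarray(img).ravel() for img in labels)
    for img in images:
        vals = np.unique(img)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"{name} labels must be binary 0/1, found values {vals}")
    return tuple(img.astype(np.int8) for img in images)


@dataclass(frozen=True)
class PilotDataset:
    """Co-registered voxel labels from a pilot study.

    ``labels_X`` are per-image binary label vectors for algorithms A and B,
    the study reference standard L, and optionally the high-quality
    reference H.  Images may have unequal voxel counts; ``grid_shape``
    optionally records the common voxel-lattice geometry (needed only for
    spatially sparse subsampling in the precision estimator).
    """

    labels_A: tuple[np.ndarray, ...]
    labels_B: tuple[np.ndarray, ...]
    labels_L: tuple[np.ndarray, ...]
    labels_H: tuple[np.ndarray, ...] | None = None
    grid_shape: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels_A", _as_binary_images(self.labels_A, "A"))
        object.__setattr__(self, "labels_B", _as_binary_images(self.labels_B, "B"))
        object.__setattr__(self, "labels_L", _as_binary_images(self.labels_L, "L"))
        if self.labels_H is not None:
            object.__setattr__(self, "labels_H", _as_binary_images(self.labels_H, "H"))
        n = len(self.labels_A)
        sources = [self.labels_B, self.labels_L] + (
            [self.labels_H] if self.labels_H is not None else []
        )
        if any(len(src) != n for src in sources):
            raise ValueError("all label sources must have the same number of images")
        for k in range(n):
            sizes = {len(self.labels_A[k]), len(self.labels_B[k]), len(self.labels_L[k])}
            if self.labels_H is not None:
                sizes.add(len(self.labels_H[k]))
            if len(sizes) != 1:
                raise ValueError(f"label vectors for image {k} differ in length")

    @property
    def n_images(self) -> int:
        return len(self.labels_A)

    @property
    def v(self) -> int | None:
        """Voxels per image when equal across images, else None."""
        sizes = {len(img) for img in self.labels_A}
        return sizes.pop() if len(sizes) == 1 else None

    @property
    def has_H(self) -> bool:
        return self.labels_H is not None

    def reference(self, which: str = "L") -> tuple[np.ndarray, ...]:
        which = which.upper()
        if which == "L":
            return self.labels_L
        if which == "H":
            if self.labels_H is None:
                raise ValueError(
                    "high-quality reference H was requested but is not present"
                )
            return self.labels_H
        raise ValueError(f"reference must be 'L' or 'H', got {which!r}")


@dataclass(frozen=True)
class DifferenceField:
    """Per-voxel accuracy differences and their per-image means."""

    d: tuple[np.ndarray, ...]
    d_bar: np.ndarray

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate(self.d)


@dataclass(frozen=True)
class ReferenceQualityParams:
    """Inputs for translating delta_MDD between reference standards.

    ``delta_mdd_H`` is the minimum detectable difference specified against
    the high-quality reference H; ``pa..ph`` are foreground probabilities
    p(X = 1) for a random voxel; ``cov_ab_lh`` is cov(A - B, L - H), the
    covariance between reference-standard errors and algorithm differences.
    """

    delta_mdd_H: float
    pa: float
    pb: float
    pl: float
    ph: float
    cov_ab_lh: float = 0.0

    def __post_init__(self) -> None:
        for name in ("pa", "pb", "pl", "ph"):
            val = getattr(self, name)
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {val}")
        if abs(self.cov_ab_lh) > 1.0:
            raise ValueError(f"|cov_ab_lh| cannot exceed 1, got {self.cov_ab_lh}")


def voxel_differences(pilot: PilotDataset, reference: str = "L") -> DifferenceField:
    """Per-voxel accuracy differences D = |B - ref| - |A - ref| per image.

    ``d_bar`` holds each image's mean difference, computed over that
    image's own voxel count.
    """
    ref = pilot.reference(reference)
    d = tuple(
        (np.abs(b - r) - np.abs(a - r)).astype(np.int8)
        for a, b, r in zip(pilot.labels_A, pilot.labels_B, ref)
    )
    d_bar = np.array([img.mean() for img in d])
    return DifferenceField(d=d, d_bar=d_bar)


def paired_t_test(
    d_bar: np.ndarray | Sequence[float], alpha: float = 0.05
) -> tuple[float, float, bool]:
    """One-sample t-test of the per-image accuracy differences against 0.

    Returns ``(t, p_two_sided, significant)``.  Degenerate zero-variance
    inputs follow a documented convention: all-zero samples give t = 0 and
    are not significant; constant nonzero samples are significant with
    p ~ 0 (the limit of vanishing variance).
    """
    d_bar = np.asarray(d_bar, dtype=float)
    if d_bar.ndim != 1 or d_bar.size < 2:
        raise ValueError("need at least two per-image differences")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if np.ptp(d_bar) == 0.0:
        if d_bar[0] == 0.0:
            return 0.0, 1.0, False
        t = math.copysign(math.inf, d_bar[0])
        return t, 0.0, True
    res = stats.ttest_1samp(d_bar, popmean=0.0, alternative="two-sided")
    t = float(res.statistic)
    p = float(res.pvalue)
    return t, p, bool(p < alpha)
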