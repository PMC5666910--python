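"""Vectorized standard bivariate normal orthant probabilities.

Implements the Drezner-Wesolowsky/Genz algorithm: 20-point Gauss-Legendre
quadrature over the arcsine-transformed correlation for |r| <= 0.925 and
Genz's asymptotic-plus-quadrature expansion for |r| > 0.925.  All inputs
broadcast; accuracy is ~1e-13 (validated against adaptive 2-D quadrature).

scipy exposes only a per-point multivariate normal CDF; the copula
calibration needs thousands of evaluations per simulated image, hence this
vectorized primitive.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

__all__ = ["bvn_upper", "bvn_cdf"]

_X, _W = np.polynomial.legendre.leggauss(20)


def bvn_upper(h, k, r):
    """P(X > h, Y > k) for a standard bivariate normal with correlation r."""
    h = np.asarray(h, float)
    k = np.asarray(k, float)
    r = np.asarray(r, float)
    h, k, r = np.broadcast_arrays(h, k, r)
    out = np.empty(h.shape)

    small = np.abs(r) <= 0.925
    if small.any():
        hs, ks, rs = h[small], k[small], r[small]
        asr = np.arcsin(rs)
        hk = hs * ks
        hs2 = (hs * hs + ks * ks) / 2.0
        sn = np.sin(asr[:, None] * (_X[None, :] + 1.0) / 2.0)
        integrand = np.exp((sn * hk[:, None] - hs2[:, None]) / (1.0 - sn * sn))
        val = (integrand * _W[None, :]).sum(axis=1) * asr / 2.0
        out[small] = val / (2.0 * np.pi) + norm.sf(hs) * norm.sf(ks)

    big = ~small
    if big.any():
        hb, kb, rb = h[big], k[big], r[big]
        neg = rb < 0
        k2 = np.where(neg, -kb, kb)
        hk = hb * k2
        a2 = (1.0 - rb) * (1.0 + rb)
        a = np.sqrt(np.maximum(a2, 0.0))
        b = np.abs(hb - k2)
        bs = b * b
        c = (4.0 - hk) / 8.0
        d = (12.0 - hk) / 16.0
        asq = a * a
        ok = a > 0
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            t1 = (
                a
                * np.exp(-(bs / np.where(ok, asq, 1.0) + hk) / 2.0)
                * (1.0 - c * (bs - asq) * (1.0 - d * bs / 5.0) / 3.0 + c * d * asq * asq / 5.0)
            )
            t1 = np.where(ok & (hk > -100.0), t1, 0.0)
            cond = ok & (-hk < 100.0) & (b > 0.0)
            t2 = np.where(
                cond,
                np.exp(-hk / 2.0)
                * np.sqrt(2.0 * np.pi)
                * norm.cdf(-b / np.where(ok, a, 1.0))
                * b
                * (1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0),
                0.0,
            )
            bvn = t1 - t2
            # quadrature over the residual correlation range
            xs = a[:, None] * (_X[None, :] + 1.0) / 2.0
            xs2 = xs * xs
            expo = -(bs[:, None] / np.where(xs2 > 0, xs2, 1.0) + hk[:, None]) / 2.0
            m2 = (expo > -100.0) & (xs2 > 0)
            rs2 = np.sqrt(np.maximum(1.0 - xs2, 0.0))
            sp = 1.0 + c[:, None] * xs2 * (1.0 + d[:, None] * xs2)
            ep = np.where(
                rs2 > 0,
                np.exp(-hk[:, None] * (xs2 / (1.0 + rs2) ** 2) / 2.0)
                / np.where(rs2 > 0, rs2, 1.0),
                0.0,
            )
            quad = np.where(m2, np.exp(expo) * (ep - sp), 0.0)
            bvn = bvn + (quad * _W[None, :] * a[:, None] / 2.0).sum(axis=1)
        bvn = -bvn / (2.0 * np.pi)
        res_pos = bvn + norm.sf(np.maximum(hb, k2))
        res_neg = -bvn + np.maximum(0.0, norm.sf(hb) - norm.sf(k2))
        out[big] = np.where(neg, res_neg, res_pos)

    return np.clip(out, 0.0, 1.0)


def bvn_cdf(a, b, r):
    """P(X <= a, Y <= b) for a standard bivariate normal with correlation r."""
    return bvn_upper(-np.asarray(a, float), -np.asarray(b, float), r)
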