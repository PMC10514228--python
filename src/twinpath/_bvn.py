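"""Bivariate standard-normal orthant probabilities and tetrachoric root solving.

The whole two-stage estimator reduces, at stage 1, to solving
``P(X > tau1, Y > tau2; rho) = p11`` for ``rho`` many times (once per 2x2
table, and once per table per bootstrap replicate).  The CDF here is built on
Owen's T function (scipy.special.owens_t), which is orders of magnitude faster
than generic multivariate-normal CDF routines and fully vectorized; its
accuracy is cross-checked in the test suite against scipy's Genz integrator.
"""
from __future__ import annotations

import math

import numpy as np
from scipy.special import ndtr, ndtri, owens_t

__all__ = ["bvn_cdf", "bvn_cdf_scalar", "bvn_pdf", "solve_tetrachoric_rho",
           "solve_tetrachoric_scalar"]

# |rho| beyond this is treated as the exact +-1 limit.
_RHO_LIMIT = 1.0 - 1e-10
# Arguments of Owen's T are capped; arctan saturates well inside 1e-9.
_A_CAP = 1e8


def bvn_pdf(h, k, rho):
    """Density of the bivariate standard normal with correlation ``rho``."""
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    omr2 = np.maximum(1.0 - rho * rho, 1e-300)
    z = (h * h - 2.0 * rho * h * k + k * k) / (2.0 * omr2)
    return np.exp(-z) / (2.0 * np.pi * np.sqrt(omr2))


def bvn_cdf(h, k, rho):
    """P(H <= h, K <= k) for bivariate standard normal with correlation rho.

    Vectorized over broadcastable ``h``, ``k``, ``rho``.  Uses the Owen (1956)
    identity  Phi2 = (Phi(h)+Phi(k))/2 - T(h,a_h) - T(k,a_k) - beta.
    """
    h, k, rho = np.broadcast_arrays(
        np.asarray(h, dtype=float), np.asarray(k, dtype=float), np.asarray(rho, dtype=float)
    )
    h = h.copy()
    k = k.copy()
    out = np.empty(h.shape, dtype=float)

    hi = rho >= _RHO_LIMIT
    lo = rho <= -_RHO_LIMIT
    mid = ~(hi | lo)
    if np.any(hi):
        out[hi] = ndtr(np.minimum(h[hi], k[hi]))
    if np.any(lo):
        out[lo] = np.maximum(0.0, ndtr(h[lo]) + ndtr(k[lo]) - 1.0)
    if np.any(mid):
        hm, km, rm = h[mid], k[mid], rho[mid]
        # nudge exact zeros off the removable singularity of a_h, a_k
        zh = hm == 0.0
        zk = km == 0.0
        both = zh & zk
        hm = np.where(zh, 1e-13, hm)
        km = np.where(zk, 1e-13, km)
        den = np.sqrt(np.maximum(1.0 - rm * rm, 1e-300))
        ah = np.clip((km - rm * hm) / (hm * den), -_A_CAP, _A_CAP)
        ak = np.clip((hm - rm * km) / (km * den), -_A_CAP, _A_CAP)
        beta = np.where((hm * km < 0) | ((hm * km == 0) & ((hm < 0) | (km < 0))), 0.5, 0.0)
        val = 0.5 * (ndtr(hm) + ndtr(km)) - owens_t(hm, ah) - owens_t(km, ak) - beta
        # exact special case h = k = 0
        val = np.where(both, 0.25 + np.arcsin(np.clip(rm, -1, 1)) / (2.0 * np.pi), val)
        out[mid] = np.clip(val, 0.0, 1.0)
    return out if out.ndim else float(out)


def bvn_cdf_scalar(h: float, k: float, rho: float) -> float:
    """Scalar Owen's-T bivariate CDF; float-only hot path for 1-D solves."""
    if rho >= _RHO_LIMIT:
        return float(ndtr(min(h, k)))
    if rho <= -_RHO_LIMIT:
        return float(max(0.0, ndtr(h) + ndtr(k) - 1.0))
    if h == 0.0 and k == 0.0:
        return 0.25 + math.asin(rho) / (2.0 * math.pi)
    if h == 0.0:
        h = 1e-13
    if k == 0.0:
        k = 1e-13
    den = math.sqrt(max(1.0 - rho * rho, 1e-300))
    ah = (k - rho * h) / (h * den)
    ak = (h - rho * k) / (k * den)
    ah = min(max(ah, -_A_CAP), _A_CAP)
    ak = min(max(ak, -_A_CAP), _A_CAP)
    beta = 0.5 if h * k < 0 else 0.0
    val = 0.5 * (ndtr(h) + ndtr(k)) - owens_t(h, ah) - owens_t(k, ak) - beta
    return float(min(max(val, 0.0), 1.0))


def solve_tetrachoric_scalar(p11: float, tau1: float, tau2: float) -> float:
    """Scalar counterpart of :func:`solve_tetrachoric_rho` (brentq-based)."""
    from scipy.optimize import brentq

    h, k = -tau1, -tau2
    p1, p2 = float(ndtr(h)), float(ndtr(k))
    lo_p = max(0.0, p1 + p2 - 1.0)
    hi_p = min(p1, p2)
    p11 = min(max(p11, lo_p + 1e-14), hi_p - 1e-14)
    f = lambda r: bvn_cdf_scalar(h, k, r) - p11
    lo, hi = -1.0 + 1e-9, 1.0 - 1e-9
    if f(lo) >= 0:
        return lo
    if f(hi) <= 0:
        return hi
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


def solve_tetrachoric_rho(p11, tau1, tau2, tol: float = 1e-12, max_newton: int = 30):
    """Solve P(X > tau1, Y > tau2; rho) = p11 for rho, vectorized.

    ``P(X > tau1, Y > tau2) = Phi2(-tau1, -tau2; rho)`` is strictly increasing
    in rho, so a safeguarded Newton iteration (derivative is the bivariate
    density at the thresholds) inside a bisection bracket converges fast and
    never escapes (-1, 1).  Inputs outside the Frechet bounds implied by the
    margins are clamped to the attainable open interval.
    """
    p11 = np.atleast_1d(np.asarray(p11, dtype=float)).copy()
    tau1 = np.broadcast_to(np.asarray(tau1, dtype=float), p11.shape).copy()
    tau2 = np.broadcast_to(np.asarray(tau2, dtype=float), p11.shape).copy()
    h = -tau1
    k = -tau2
    p1 = ndtr(h)
    p2 = ndtr(k)
    # Frechet bounds at rho = -1 / +1
    lo_p = np.maximum(0.0, p1 + p2 - 1.0)
    hi_p = np.minimum(p1, p2)
    eps = 1e-14
    p11 = np.clip(p11, lo_p + eps, hi_p - eps)

    lo = np.full(p11.shape, -1.0 + 1e-9)
    hi = np.full(p11.shape, 1.0 - 1e-9)
    # bisection to localize
    for _ in range(24):
        midr = 0.5 * (lo + hi)
        f = bvn_cdf(h, k, midr) - p11
        gt = f > 0
        hi = np.where(gt, midr, hi)
        lo = np.where(gt, lo, midr)
    rho = 0.5 * (lo + hi)
    # Newton polish with bracket safeguard
    for _ in range(max_newton):
        f = bvn_cdf(h, k, rho) - p11
        gt = f > 0
        hi = np.where(gt, rho, hi)
        lo = np.where(gt, lo, rho)
        d = bvn_pdf(h, k, rho)
        step = np.where(d > 1e-300, f / np.maximum(d, 1e-300), 0.0)
        cand = rho - step
        bad = (cand <= lo) | (cand >= hi) | ~np.isfinite(cand)
        rho = np.where(bad, 0.5 * (lo + hi), cand)
        if np.max(np.abs(step)) < tol:
            break
    return rho
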