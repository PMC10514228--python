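"""Stage 2: (diagonally) weighted least squares structural fitting.

``fit_wls`` minimizes F(theta) = sum_g (s_g - sigma_g(theta))' W_g (s_g -
sigma_g(theta)) over the unique correlation moments of every group, with
W_g the inverse per-moment variance (diagonal mode, the robust-WLS default
for categorical data), the inverse full bootstrap covariance (full mode), or
identity.  Thresholds stay fixed at their stage-1 estimates; their sampling
noise enters through the bootstrap covariance used by the sandwich and the
mean-adjusted fit statistic.

Nonconvergence is an ordinary reportable outcome (mirrors how model-ladder
results are tabulated), never an exception.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr, ndtri

from .data import GROUPS, TwinDataset
from .models import ModelSpec, VarianceDecomposition, standardize
from .moments import GroupMoments, polychoric_matrix

__all__ = ["FitResult", "BootstrapResult", "fit_wls", "sandwich_covariance",
           "bootstrap_ci", "population_moments"]

_VAR_FLOOR = 1e-10


def _kappa(gm: GroupMoments) -> float:
    return 1.0 if gm.zygosity == "MZ" else 0.5


@dataclass
class FitResult:
    """Outcome of one structural fit (estimates, discrepancy, diagnostics)."""

    spec: ModelSpec
    theta: np.ndarray
    f_min: float
    converged: bool
    reasons: tuple
    grad_norm: float
    n_iter: int
    boundary: bool
    weight_mode: str
    n_total: int
    groups_used: tuple
    moments: tuple
    mask: np.ndarray
    s: np.ndarray
    weights: np.ndarray  # stacked diagonal weights, or block-diagonal full W
    decomposition: Optional[VarianceDecomposition] = None
    cov: Optional[np.ndarray] = None

    def params(self) -> dict:
        return self.spec.theta_dict(self.theta)

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.cov)) if self.cov is not None else np.full(self.spec.n_free, np.nan)
        return pd.DataFrame({"estimate": self.theta, "se": se},
                            index=list(self.spec.free_names))


def _stack_moments(spec: ModelSpec, moments: Sequence[GroupMoments], weight_mode: str):
    for gm in moments:
        if tuple(gm.phenotypes) != spec.phenotypes:
            raise ValueError("phenotype sets of spec and moments disagree")
    s = np.concatenate([gm.values for gm in moments])
    var = np.concatenate([gm.variances for gm in moments])
    mask = np.isfinite(s) & np.isfinite(var)
    if weight_mode == "diagonal":
        W = 1.0 / np.clip(var, _VAR_FLOOR, None)
    elif weight_mode == "identity":
        W = np.ones_like(var)
    elif weight_mode == "full":
        m = len(s)
        W = np.zeros((m, m))
        off = 0
        for gm in moments:
            k = len(gm.values)
            if gm.acov is None:
                raise ValueError("weight_mode='full' needs bootstrap acov on every group")
            block = np.array(gm.acov)
            sub = np.isfinite(np.diag(block))
            blk = np.where(np.isfinite(block), block, 0.0)
            W[off:off + k, off:off + k] = np.linalg.pinv(blk, rcond=1e-10)
            off += k
    else:
        raise ValueError("weight_mode must be 'diagonal', 'full', or 'identity'")
    return s, var, mask, W


def _sqrt_weight_operator(W, mask, weight_mode):
    """Return L with ||L r||^2 = r' W r on the masked moment space."""
    if weight_mode in ("diagonal", "identity"):
        return np.sqrt(W[mask])  # vector
    Wm = W[np.ix_(mask, mask)]
    vals, vecs = np.linalg.eigh((Wm + Wm.T) / 2)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T  # symmetric square root, matrix


def _stacked_sigma(spec, theta, moments):
    return np.concatenate([spec.sigma(theta, _kappa(gm), gm.sex) for gm in moments])


def _stacked_jacobian(spec, theta, moments):
    return np.vstack([spec.jacobian(theta, _kappa(gm), gm.sex) for gm in moments])


def fit_wls(spec: ModelSpec, moments: Sequence[GroupMoments],
            weight_mode: str = "diagonal", n_starts: int = 5, seed: int = 0,
            start=None, extra_starts: Sequence = (), jitter: float = 0.2,
            max_nfev: int = 5000) -> FitResult:
    """Fit a structural spec to multi-group stage-1 moments by weighted LS.

    Multi-start trust-region least squares (analytic Jacobian) from a crude
    start plus ``n_starts - 1`` jittered copies (uniform +-``jitter``), plus
    any caller-supplied ``extra_starts`` (e.g. an embedded nested solution).
    Returns the best solution; ``converged=False`` (never an exception) when
    no start terminates cleanly.
    """
    moments = tuple(moments)
    if not moments:
        raise ValueError("no group moments supplied")
    s, var, mask, W = _stack_moments(spec, moments, weight_mode)
    n_used = int(mask.sum())
    if spec.n_free > n_used:
        raise ValueError(
            f"model not identified: {spec.n_free} free parameters but only "
            f"{n_used} distinct moments")
    if spec.kind in ("univariate_ace", "univariate_ace_by_sex", "bivariate_cholesky",
                     "ipm", "cpm"):
        zygs = {gm.zygosity for gm in moments}
        if len(zygs) < 2:
            raise ValueError("a and c are not separable without both MZ and DZ groups")
    L = _sqrt_weight_operator(W, mask, weight_mode)
    diag_mode = L.ndim == 1
    if spec.kind == "univariate_ace" and diag_mode:
        # the objective is a convex piecewise quadratic in (a^2, c^2):
        # solve it in closed form (exact minimizer of the same objective the
        # generic trust-region path optimizes) — this is the bootstrap hot path
        kap = np.concatenate([np.full(len(gm.values), _kappa(gm)) for gm in moments])
        x2, y2, f_min = _univariate_ace_closed_form(s[mask], kap[mask], L * L)
        theta = np.array([np.sqrt(x2), np.sqrt(y2)])
        e2 = 1.0 - x2 - y2
        return FitResult(
            spec=spec, theta=theta, f_min=f_min, converged=True, reasons=(),
            grad_norm=0.0, n_iter=1, boundary=bool(e2 < 1e-6),
            weight_mode=weight_mode,
            n_total=sum(gm.n_individuals for gm in moments),
            groups_used=tuple(gm.group for gm in moments), moments=moments,
            mask=mask, s=s, weights=W, decomposition=standardize(spec, theta))
    if spec.n_free == 0:  # e.g. the independence baseline: nothing to optimize
        theta = np.zeros(0)
        r_fit = (_stacked_sigma(spec, theta, moments) - s)[mask]
        f_min = float(r_fit @ (L * L * r_fit) if diag_mode else r_fit @ (L @ (L @ r_fit)))
        return FitResult(
            spec=spec, theta=theta, f_min=f_min, converged=True, reasons=(),
            grad_norm=0.0, n_iter=0, boundary=False, weight_mode=weight_mode,
            n_total=sum(gm.n_individuals for gm in moments),
            groups_used=tuple(gm.group for gm in moments), moments=moments,
            mask=mask, s=s, weights=W)

    def residuals(theta):
        r = (_stacked_sigma(spec, theta, moments) - s)[mask]
        r = L * r if diag_mode else L @ r
        pen, _ = spec.penalty_residuals(theta)
        return np.concatenate([r, pen])

    def jac(theta):
        J = _stacked_jacobian(spec, theta, moments)[mask]
        J = L[:, None] * J if diag_mode else L @ J
        _, Jp = spec.penalty_residuals(theta)
        return np.vstack([J, Jp])

    rng = np.random.default_rng(seed)
    base = np.asarray(start, float) if start is not None else spec.default_start()
    starts = [base]
    for _ in range(max(0, n_starts - 1)):
        starts.append(base + rng.uniform(-jitter, jitter, size=spec.n_free))
    starts.extend(np.asarray(x, float) for x in extra_starts)

    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(
                residuals, x0, jac=jac, method="trf", bounds=(-1.0, 1.0),
                xtol=1e-14, ftol=1e-14, gtol=1e-12, max_nfev=max_nfev)
        except Exception:  # pragma: no cover - defensive
            continue
        key = (res.status <= 0, res.cost)
        if best is None or key < (best.status <= 0, best.cost):
            best = res
        if res.status > 0 and res.cost < 1e-14:
            break
    if best is None:
        theta = base
        fr_kwargs = dict(f_min=np.inf, converged=False, reasons=("all starts failed",),
                         grad_norm=np.inf, n_iter=0)
    else:
        theta = spec.canonicalize(best.x)
        r_fit = (_stacked_sigma(spec, theta, moments) - s)[mask]
        f_min = float(r_fit @ (L * L * r_fit) if diag_mode else r_fit @ (L @ (L @ r_fit)))
        reasons = () if best.status > 0 else ("max function evaluations reached",)
        fr_kwargs = dict(f_min=f_min, converged=best.status > 0, reasons=reasons,
                         grad_norm=float(best.optimality), n_iter=int(best.nfev))
    boundary = False
    decomposition = None
    if spec.kind in ("univariate_ace", "bivariate_cholesky", "ipm", "cpm"):
        try:
            _, _, _, se2 = spec.component_matrices(theta)
            boundary = bool(np.any(se2 < 1e-6))
            decomposition = standardize(spec, theta)
        except ValueError:
            decomposition = None
    return FitResult(
        spec=spec, theta=theta, boundary=boundary, weight_mode=weight_mode,
        n_total=sum(gm.n_individuals for gm in moments),
        groups_used=tuple(gm.group for gm in moments), moments=moments,
        mask=mask, s=s, weights=W, decomposition=decomposition, **fr_kwargs)


def _univariate_ace_closed_form(s, kap, w):
    """Exact minimizer of sum w (s - kappa x - y)^2 (+ unit-variance penalty)
    over x = a^2, y = c^2 in [0, 1]^2.  Enumerates the stationary points of
    each active-set region of the convex piecewise-quadratic objective."""
    P2 = 100.0**2  # penalty weight squared, matching the generic path
    Swkk = float(w @ kap**2)
    Swk = float(w @ kap)
    Sw = float(w.sum())
    Swks = float(w @ (kap * s))
    Sws = float(w @ s)

    def obj(x, y):
        r = s - kap * x - y
        pen = P2 * max(0.0, x + y - 1.0) ** 2
        return float(w @ r**2) + pen

    cands = []
    A = np.array([[Swkk, Swk], [Swk, Sw]])
    b = np.array([Swks, Sws])
    try:
        cands.append(np.linalg.solve(A, b))
        cands.append(np.linalg.solve(A + P2 * np.ones((2, 2)), b + P2))
    except np.linalg.LinAlgError:
        pass
    if Sw > 0:
        cands.append(np.array([0.0, Sws / Sw]))
        cands.append(np.array([0.0, (Sws + P2) / (Sw + P2)]))
    if Swkk > 0:
        cands.append(np.array([Swks / Swkk, 0.0]))
        cands.append(np.array([(Swks + P2) / (Swkk + P2), 0.0]))
    cands.extend(np.array(c, dtype=float)
                 for c in ((0, 0), (1, 0), (0, 1), (1, 1)))
    best = None
    for c in cands:
        x, y = float(np.clip(c[0], 0.0, 1.0)), float(np.clip(c[1], 0.0, 1.0))
        q = obj(x, y)
        if best is None or q < best[2]:
            best = (x, y, q)
    x, y, _ = best
    r = s - kap * x - y
    return x, y, float(w @ r**2)


def stacked_gamma(moments: Sequence[GroupMoments], mask: np.ndarray) -> np.ndarray:
    """Block-diagonal stage-1 moment covariance over the masked moment space.

    Uses each group's full bootstrap acov when present, else the
    information-based diagonal.
    """
    m = sum(len(gm.values) for gm in moments)
    G = np.zeros((m, m))
    off = 0
    for gm in moments:
        k = len(gm.values)
        if gm.acov is not None:
            block = np.where(np.isfinite(gm.acov), gm.acov, 0.0)
        else:
            block = np.diag(np.where(np.isfinite(gm.variances), gm.variances, 0.0))
        G[off:off + k, off:off + k] = block
        off += k
    return G[np.ix_(mask, mask)]


def _weight_matrix(fit: FitResult) -> np.ndarray:
    if fit.weights.ndim == 1:
        return np.diag(fit.weights[fit.mask])
    return fit.weights[np.ix_(fit.mask, fit.mask)]


def sandwich_covariance(fit: FitResult, gamma: Optional[np.ndarray] = None,
                        ridge: float = 0.0) -> np.ndarray:
    """Robust covariance of theta-hat: Binv D'W Gamma W D Binv, B = D'WD.

    Gamma defaults to the stacked stage-1 covariance of the fitted moments
    (full bootstrap blocks where available).  Raises on a singular bread
    matrix, naming the non-identified parameter direction; ``ridge > 0`` adds
    ridge * max-eigenvalue to B instead, which leaves regular directions
    untouched and inflates the variance of flat (near-unidentified)
    directions — any Wald statistic along them shrinks toward zero, i.e. the
    test turns conservative rather than failing.
    """
    if not fit.converged:
        raise ValueError("sandwich covariance requires a converged fit")
    D = _stacked_jacobian(fit.spec, fit.theta, fit.moments)[fit.mask]
    W = _weight_matrix(fit)
    if gamma is None:
        gamma = stacked_gamma(fit.moments, fit.mask)
    B = D.T @ W @ D
    vals, vecs = np.linalg.eigh((B + B.T) / 2)
    if ridge > 0:
        vals = vals + ridge * max(vals[-1], 1.0)
    elif vals[0] <= 1e-12 * max(vals[-1], 1.0):
        direction = fit.spec.free_names[int(np.argmax(np.abs(vecs[:, 0])))]
        raise np.linalg.LinAlgError(
            f"singular information matrix; non-identified direction involves {direction!r}")
    Binv = vecs @ np.diag(1.0 / vals) @ vecs.T
    M = D.T @ W @ gamma @ W @ D
    V = Binv @ M @ Binv
    fit.cov = (V + V.T) / 2
    return fit.cov


def population_moments(spec: ModelSpec, theta, groups=GROUPS,
                       variances: float = 1.0) -> list:
    """Analytic GroupMoments implied by (spec, theta) — for self-consistency
    and oracle tests; all moment variances set to ``variances``."""
    from .models import expected_correlation_matrix

    theta = np.asarray(theta, float)
    out = []
    p = spec.p
    for g in groups:
        kappa = 1.0 if g[:2] == "MZ" else 0.5
        vals = spec.sigma(theta, kappa, g[2])
        corr = np.full((2 * p, 2 * p), np.nan)
        try:
            corr = expected_correlation_matrix(spec, theta, g[:2])
        except ValueError:
            pass
        m = len(vals)
        out.append(GroupMoments(
            group=g, phenotypes=spec.phenotypes,
            thresholds=np.zeros(p), threshold_se=np.full(p, np.nan),
            corr=corr, values=vals, variances=np.full(m, variances),
            n_eff=np.full(m, np.inf), n_pairs=0, n_individuals=0))
    return out


# ---------------------------------------------------------------------------
# Bias-corrected accelerated bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapResult:
    """BCa confidence intervals for parameters and variance proportions."""

    names: tuple
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n_requested: int
    n_converged: int
    n_nonconverged: int
    seed: int
    warnings: tuple = ()

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"point": self.point, "lower": self.lower,
                             "upper": self.upper}, index=list(self.names))

    def __getitem__(self, name):
        i = self.names.index(name)
        return float(self.point[i]), float(self.lower[i]), float(self.upper[i])


def _fit_statistics(ds: TwinDataset, spec: ModelSpec, weight_mode: str,
                    n_starts: int, seed: int, start=None):
    groups = [g for g in GROUPS if g in set(ds.groups)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        moments = [polychoric_matrix(ds, g) for g in groups]
        fit = fit_wls(spec, moments, weight_mode=weight_mode, n_starts=n_starts,
                      seed=seed, start=start)
    if not fit.converged:
        return None, fit
    values = [fit.theta]
    names = list(spec.free_names)
    if fit.decomposition is not None:
        dn, dv = fit.decomposition.flatten()
        names += dn
        values.append(dv)
    return (tuple(names), np.concatenate(values)), fit


def _group_resample_indices(rng, groups):
    idx = np.arange(len(groups))
    out = np.empty_like(idx)
    pos = 0
    for g in GROUPS:
        gi = idx[groups == g]
        if gi.size:
            out[pos:pos + gi.size] = rng.choice(gi, size=gi.size, replace=True)
            pos += gi.size
    return out[:pos]


def _jackknife_blocks(ds: TwinDataset, n_groups: int):
    """Stratified interleaved pair blocks for the grouped jackknife."""
    order = np.argsort([list(GROUPS).index(g) for g in ds.groups], kind="stable")
    blocks = [[] for _ in range(n_groups)]
    for rank, i in enumerate(order):
        blocks[rank % n_groups].append(i)
    return [np.array(b) for b in blocks if b]


def bootstrap_ci(ds: TwinDataset, spec: ModelSpec, B: int = 1000, seed: int = 0,
                 level: float = 0.95, weight_mode: str = "diagonal",
                 n_starts: int = 5, replicate_starts: int = 1,
                 resampler: Optional[Callable] = None,
                 n_jack_groups: int = 40) -> BootstrapResult:
    """Bias-corrected accelerated (BCa) bootstrap intervals.

    Pairs (and singletons) are resampled with replacement within each
    zygosity-sex group; each replicate reruns stage 1 and stage 2 in full,
    warm-started at the point estimate.  Acceleration comes from a pair-level
    jackknife, switching to a stratified grouped jackknife (``n_jack_groups``
    blocks) above 2000 pairs.  Deterministic given ``seed``.  ``resampler``
    (rng, ds) -> ds is a test hook replacing the within-group resampling.
    """
    if B < 100:
        raise ValueError("B must be at least 100")
    warn = []
    if B < 1000:
        warn.append(f"B = {B} < 1000 replicates")
    rng = np.random.default_rng(seed)
    stat, fit0 = _fit_statistics(ds, spec, weight_mode, n_starts, seed)
    if stat is None:
        raise ValueError("point fit did not converge; no intervals")
    names, point = stat
    reps = []
    bad = 0
    for _ in range(B):
        if resampler is not None:
            dsb = resampler(rng, ds)
        else:
            dsb = ds.subset_pairs(_group_resample_indices(rng, ds.groups))
        try:
            st, _ = _fit_statistics(dsb, spec, weight_mode, replicate_starts,
                                    seed, start=fit0.theta)
        except (ValueError, np.linalg.LinAlgError):
            st = None
        if st is None:
            bad += 1
        else:
            reps.append(st[1])
    if not reps:
        raise ValueError("no converged bootstrap replicates")
    reps = np.array(reps)
    if len(reps) < 0.9 * B:
        warn.append(f"only {len(reps)}/{B} replicates converged")
    if bad > 0.1 * B:
        warn.append("more than 10% nonconverged replicates; intervals use converged only")

    # acceleration via jackknife
    if ds.n_pairs > 2000:
        blocks = _jackknife_blocks(ds, n_jack_groups)
    else:
        blocks = [np.array([i]) for i in range(ds.n_pairs)]
    jacks = []
    all_idx = np.arange(ds.n_pairs)
    for b in blocks:
        keep = np.setdiff1d(all_idx, b, assume_unique=True)
        try:
            st, _ = _fit_statistics(ds.subset_pairs(keep), spec, weight_mode,
                                    replicate_starts, seed, start=fit0.theta)
        except (ValueError, np.linalg.LinAlgError):
            st = None
        if st is not None:
            jacks.append(st[1])
    jacks = np.array(jacks) if jacks else point[None, :]

    alpha = (1.0 - level) / 2.0
    z_lo, z_hi = ndtri(alpha), ndtri(1.0 - alpha)
    lower = np.empty(len(point))
    upper = np.empty(len(point))
    nb = len(reps)
    for i in range(len(point)):
        col = reps[:, i]
        prop = (np.sum(col < point[i]) + 0.5 * np.sum(col == point[i])) / nb
        z0 = ndtri(np.clip(prop, 1.0 / (2 * nb), 1.0 - 1.0 / (2 * nb)))
        d = jacks[:, i].mean() - jacks[:, i]
        denom = np.sum(d**2) ** 1.5
        a = np.sum(d**3) / (6.0 * denom) if denom > 1e-300 else 0.0
        q_lo = ndtr(z0 + (z0 + z_lo) / (1.0 - a * (z0 + z_lo)))
        q_hi = ndtr(z0 + (z0 + z_hi) / (1.0 - a * (z0 + z_hi)))
        lower[i] = np.quantile(col, np.clip(q_lo, 0.0, 1.0))
        upper[i] = np.quantile(col, np.clip(q_hi, 0.0, 1.0))
    return BootstrapResult(
        names=names, point=point, lower=lower, upper=upper, level=level,
        n_requested=B, n_converged=len(reps), n_nonconverged=bad, seed=seed,
        warnings=tuple(warn))
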