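"""Stage 1 of the two-stage weighted least squares estimator.

Per zygosity-sex group: sex-specific liability thresholds, the 2p x 2p
tetrachoric/polychoric correlation matrix (twin-within blocks constrained
equal by pooling, cross-twin block symmetrized by pooling both orientations),
and the sampling (co)variance of the estimated moments — the weight source
for stage 2.

Missingness is handled available-case per moment: thresholds and
within-person correlations use every observed individual (both twins pooled,
including members of incomplete pairs); cross-twin correlations use complete
pairs only.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.special import ndtr, ndtri

from ._bvn import (bvn_cdf, bvn_cdf_scalar, solve_tetrachoric_rho,
                   solve_tetrachoric_scalar)
from .data import GROUPS, TwinDataset

__all__ = [
    "GroupMoments",
    "TetrachoricResult",
    "moment_labels",
    "estimate_threshold",
    "tetrachoric_ml",
    "tetrachoric_oracle",
    "polychoric_matrix",
    "bootstrap_group_moments",
]

_R_CLAMP = 1.0 - 1e-8


def moment_labels(phenotypes: Sequence[str]):
    """Canonical order of the unique correlation moments of one group.

    Within-person pairs (j < m), then cross-twin same-trait (j), then
    cross-twin cross-trait pairs (j < m).  Every stage-2 moment vector in the
    package follows this order.
    """
    names = list(phenotypes)
    p = len(names)
    labels = []
    for j in range(p):
        for m in range(j + 1, p):
            labels.append(("within", names[j], names[m]))
    for j in range(p):
        labels.append(("cross", names[j], names[j]))
    for j in range(p):
        for m in range(j + 1, p):
            labels.append(("cross", names[j], names[m]))
    return labels


def n_moments(p: int) -> int:
    return p * p


class TetrachoricResult(NamedTuple):
    r: float
    se: float
    corrected: bool
    boundary: bool


def estimate_threshold(x) -> tuple:
    """Threshold estimate and delta-method standard error from a binary vector.

    tau is the upper-tail standard-normal quantile of the observed endorsement
    proportion; se(tau) = sqrt(p(1-p)/n) / phi(tau).
    """
    x = np.asarray(x, dtype=float)
    obs = x[np.isfinite(x)]
    n = obs.size
    if n == 0 or obs.min() == obs.max():
        raise ValueError("degenerate phenotype: needs at least one 0 and one 1")
    p = obs.mean()
    tau = float(-ndtri(p))
    phi = np.exp(-0.5 * tau * tau) / np.sqrt(2.0 * np.pi)
    se = float(np.sqrt(p * (1 - p) / n) / phi)
    return tau, se


def _table_from_codes(a, b):
    """2x2 table [[n11, n10], [n01, n00]] from paired binary vectors with NaN."""
    ok = np.isfinite(a) & np.isfinite(b)
    a = a[ok]
    b = b[ok]
    n11 = float(np.sum((a == 1) & (b == 1)))
    n10 = float(np.sum((a == 1) & (b == 0)))
    n01 = float(np.sum((a == 0) & (b == 1)))
    n00 = float(np.sum((a == 0) & (b == 0)))
    return np.array([[n11, n10], [n01, n00]])


def tetrachoric_ml(table) -> TetrachoricResult:
    """ML tetrachoric correlation from a 2x2 table [[n11, n10], [n01, n00]].

    Thresholds are fixed at their margin-implied values (two-step), making
    this a 1-D problem in rho solved from the (1,1)-cell orthant probability.
    A table containing a zero cell gets a flat +0.5 continuity correction and
    is flagged; |r| is clamped at 1 - 1e-8 with a boundary flag.  The standard
    error comes from the expected information with thresholds fixed.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0):
        raise ValueError("cell counts must be nonnegative")
    corrected = bool(np.any(t == 0))
    if corrected:
        t = t + 0.5
    n = t.sum()
    if n <= 0:
        raise ValueError("empty table")
    p1 = (t[0, 0] + t[0, 1]) / n  # P(X = 1)
    p2 = (t[0, 0] + t[1, 0]) / n  # P(Y = 1)
    if min(p1, 1 - p1, p2, 1 - p2) <= 0:
        raise ValueError("degenerate margin even after zero-cell correction")
    tau1 = -ndtri(p1)
    tau2 = -ndtri(p2)
    rho = solve_tetrachoric_scalar(t[0, 0] / n, tau1, tau2)
    boundary = abs(rho) > _R_CLAMP
    rho = float(np.clip(rho, -_R_CLAMP, _R_CLAMP))
    # expected information, thresholds fixed
    pi11 = bvn_cdf_scalar(-tau1, -tau2, rho)
    pi10 = max(p1 - pi11, 1e-12)
    pi01 = max(p2 - pi11, 1e-12)
    pi00 = max(1 - p1 - p2 + pi11, 1e-12)
    pi11 = max(pi11, 1e-12)
    omr2 = max(1.0 - rho * rho, 1e-300)
    dens = float(np.exp(-(tau1**2 - 2 * rho * tau1 * tau2 + tau2**2) / (2 * omr2))
                 / (2 * np.pi * np.sqrt(omr2)))
    info = n * dens**2 * (1 / pi11 + 1 / pi10 + 1 / pi01 + 1 / pi00)
    se = float(1.0 / np.sqrt(info)) if info > 0 else np.inf
    return TetrachoricResult(rho, se, corrected, boundary)


def _orthant_grid(tau1: float, tau2: float, rhos: np.ndarray, n_nodes: int = 48,
                  upper: float = 8.5) -> np.ndarray:
    """P(X > tau1, Y > tau2; rho) by 2-D Gauss-Legendre integration of the
    bivariate density, vectorized over a grid of rho values.  Used only by the
    brute-force oracle; deliberately independent of the Owen's-T CDF."""
    x, wx = np.polynomial.legendre.leggauss(n_nodes)
    a1, b1 = tau1, max(upper, tau1 + 1.0)
    a2, b2 = tau2, max(upper, tau2 + 1.0)
    u = 0.5 * (b1 - a1) * x + 0.5 * (b1 + a1)
    v = 0.5 * (b2 - a2) * x + 0.5 * (b2 + a2)
    wu = 0.5 * (b1 - a1) * wx
    wv = 0.5 * (b2 - a2) * wx
    U = u[:, None]
    V = v[None, :]
    rhos = np.asarray(rhos, dtype=float)
    omr2 = 1.0 - rhos**2
    out = np.empty(rhos.shape)
    for i, (r, o) in enumerate(zip(rhos, omr2)):
        dens = np.exp(-(U * U - 2 * r * U * V + V * V) / (2 * o)) / (2 * np.pi * np.sqrt(o))
        out[i] = float(wu @ dens @ wv)
    return out


def tetrachoric_oracle(table, tol: float = 1e-7) -> float:
    """Brute-force tetrachoric estimate by iteratively refined grid search.

    Maximizes the 4-cell multinomial likelihood (thresholds fixed at the
    margins, same estimand as ``tetrachoric_ml``) over a dense rho grid with
    orthant probabilities from 2-D numerical integration.  Test oracle only.
    """
    t = np.asarray(table, dtype=float)
    if np.any(t < 0):
        raise ValueError("cell counts must be nonnegative")
    if np.any(t == 0):
        t = t + 0.5
    n = t.sum()
    p1 = (t[0, 0] + t[0, 1]) / n
    p2 = (t[0, 0] + t[1, 0]) / n
    if min(p1, 1 - p1, p2, 1 - p2) <= 0:
        raise ValueError("degenerate margin even after zero-cell correction")
    tau1 = float(-ndtri(p1))
    tau2 = float(-ndtri(p2))

    def negll(rhos):
        # the density ridge near |rho| = 1 needs a much denser product rule
        nodes = 48 if np.max(np.abs(rhos)) <= 0.9 else 384
        pi11 = np.clip(_orthant_grid(tau1, tau2, rhos, n_nodes=nodes), 1e-12, 1.0)
        pi10 = np.clip(p1 - pi11, 1e-12, 1.0)
        pi01 = np.clip(p2 - pi11, 1e-12, 1.0)
        pi00 = np.clip(1 - p1 - p2 + pi11, 1e-12, 1.0)
        return -(t[0, 0] * np.log(pi11) + t[0, 1] * np.log(pi10)
                 + t[1, 0] * np.log(pi01) + t[1, 1] * np.log(pi00))

    lo, hi = -0.999, 0.999  # beyond this the product rule cannot resolve the ridge
    best = 0.0
    while (hi - lo) / 2 > tol:
        grid = np.linspace(lo, hi, 21)
        vals = negll(grid)
        i = int(np.argmin(vals))
        best = grid[i]
        step = grid[1] - grid[0]
        lo = max(-0.999, best - step)
        hi = min(0.999, best + step)
    return float(np.clip(best, -_R_CLAMP, _R_CLAMP))


@dataclass
class GroupMoments:
    """Stage-1 summary for one zygosity-sex group.

    ``values``/``variances`` follow the canonical :func:`moment_labels` order.
    ``acov`` is the full bootstrap covariance of the moment vector when
    requested; otherwise the diagonal of ``variances`` stands in.
    """

    group: str
    phenotypes: tuple
    thresholds: np.ndarray
    threshold_se: np.ndarray
    corr: np.ndarray
    values: np.ndarray
    variances: np.ndarray
    n_eff: np.ndarray
    acov: Optional[np.ndarray] = None
    n_pairs: int = 0
    n_individuals: int = 0
    dropped: tuple = ()
    flags: dict = field(default_factory=dict)

    @property
    def labels(self):
        return moment_labels(self.phenotypes)

    @property
    def zygosity(self) -> str:
        return self.group[:2]

    @property
    def sex(self) -> str:
        return self.group[2]

    def validate(self):
        p = len(self.phenotypes)
        c = self.corr
        if c.shape != (2 * p, 2 * p):
            raise ValueError("corr must be 2p x 2p")
        finite = np.isfinite(c)
        if not np.allclose(c[finite], c.T[finite]):
            raise ValueError("corr must be symmetric")
        return self

    def to_json(self, path=None):
        obj = {
            "group": self.group,
            "phenotypes": list(self.phenotypes),
            "thresholds": self.thresholds.tolist(),
            "threshold_se": self.threshold_se.tolist(),
            "corr": self.corr.tolist(),
            "values": self.values.tolist(),
            "variances": self.variances.tolist(),
            "n_eff": self.n_eff.tolist(),
            "acov": None if self.acov is None else self.acov.tolist(),
            "n_pairs": self.n_pairs,
            "n_individuals": self.n_individuals,
            "dropped": list(self.dropped),
        }
        if path is None:
            return json.dumps(obj)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(obj, fh)
        return None

    @classmethod
    def from_json(cls, source) -> "GroupMoments":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            obj = json.loads(source)
        else:
            with open(source, "r", encoding="utf-8") as fh:
                obj = json.load(fh)
        return cls(
            group=obj["group"],
            phenotypes=tuple(obj["phenotypes"]),
            thresholds=np.array(obj["thresholds"]),
            threshold_se=np.array(obj["threshold_se"]),
            corr=np.array(obj["corr"]),
            values=np.array(obj["values"]),
            variances=np.array(obj["variances"]),
            n_eff=np.array(obj["n_eff"]),
            acov=None if obj["acov"] is None else np.array(obj["acov"]),
            n_pairs=obj["n_pairs"],
            n_individuals=obj["n_individuals"],
            dropped=tuple(obj["dropped"]),
        )


def polychoric_matrix(ds: TwinDataset, group: str, acov: str = "diagonal",
                      n_boot: int = 200, seed: int = 0, strict: bool = False) -> GroupMoments:
    """Estimate one group's thresholds, correlation matrix, and moment (co)variances.

    ``acov='diagonal'`` keeps per-moment information-based variances (the
    diagonal WLS weight source); ``acov='bootstrap'`` adds the full moment
    covariance from a pair-level nonparametric bootstrap (``n_boot``
    replicates), needed for the mean-adjusted fit statistic and the sandwich.
    A phenotype with no variation in the group is dropped (NaN row/column)
    with a warning, or raises in ``strict`` mode.
    """
    if group not in set(ds.groups):
        raise ValueError(f"group {group!r} not present in dataset")
    x1, x2 = ds.group_arrays(group)
    p = len(ds.codebook)
    names = ds.phenotypes
    persons = np.concatenate([x1, x2])
    thresholds = np.full(p, np.nan)
    tse = np.full(p, np.nan)
    dropped = []
    for j in range(p):
        try:
            thresholds[j], tse[j] = estimate_threshold(persons[:, j])
        except ValueError:
            if strict:
                raise ValueError(f"degenerate phenotype {names[j]!r} in group {group}")
            warnings.warn(f"phenotype {names[j]!r} dropped in group {group}: no variation")
            dropped.append(names[j])
    ok = np.array([n not in dropped for n in names])

    labels = moment_labels(names)
    m = len(labels)
    values = np.full(m, np.nan)
    variances = np.full(m, np.nan)
    neff = np.zeros(m)
    flags = {}
    corr = np.full((2 * p, 2 * p), np.nan)
    corr[np.arange(2 * p), np.arange(2 * p)] = 1.0

    name_ix = {n: i for i, n in enumerate(names)}
    for i, (kind, a, b) in enumerate(labels):
        j, mm = name_ix[a], name_ix[b]
        if not (ok[j] and ok[mm]):
            continue
        if kind == "within":
            tab = _table_from_codes(persons[:, j], persons[:, mm])
        elif j == mm:
            tab = _table_from_codes(x1[:, j], x2[:, j])
        else:
            # pool both orientations, keeping trait j on the row margin
            tab = _table_from_codes(x1[:, j], x2[:, mm]) + _table_from_codes(x2[:, j], x1[:, mm])
        neff[i] = tab.sum()
        if tab.sum() < 4:
            continue
        try:
            res = tetrachoric_ml(tab)
        except ValueError:
            continue
        values[i] = res.r
        variances[i] = res.se**2
        if res.corrected or res.boundary:
            flags[(kind, a, b)] = {"corrected": res.corrected, "boundary": res.boundary}
        if kind == "within":
            for off1, off2 in ((0, 0), (p, p)):
                corr[off1 + j, off2 + mm] = corr[off1 + mm, off2 + j] = res.r
        else:
            corr[j, p + mm] = corr[p + mm, j] = res.r
            corr[mm, p + j] = corr[p + j, mm] = res.r

    complete = np.isfinite(x1).any(axis=1) & np.isfinite(x2).any(axis=1)
    gm = GroupMoments(
        group=group, phenotypes=tuple(names), thresholds=thresholds, threshold_se=tse,
        corr=corr, values=values, variances=variances, n_eff=neff,
        n_pairs=x1.shape[0],
        n_individuals=int(complete.sum()) * 2 + int((~complete).sum()),
        dropped=tuple(dropped), flags=flags,
    )
    if acov == "bootstrap":
        samples = bootstrap_group_moments(x1, x2, n_boot, seed)
        keep = np.isfinite(samples).all(axis=0)
        full = np.full((m, m), np.nan)
        if keep.any():
            sub = np.cov(samples[:, keep], rowvar=False)
            full[np.ix_(keep, keep)] = np.atleast_2d(sub)
        gm.acov = full
    elif acov != "diagonal":
        raise ValueError("acov must be 'diagonal' or 'bootstrap'")
    return gm.validate()


# ---------------------------------------------------------------------------
# Vectorized pair-level bootstrap of the moment vector
# ---------------------------------------------------------------------------

def _codes(a, b):
    """Pairwise cell codes in {-1, 0..3}; -1 marks a missing pair of values."""
    ok = np.isfinite(a) & np.isfinite(b)
    c = np.where(ok, 2 * np.nan_to_num(a) + np.nan_to_num(b), -1.0)
    return c.astype(np.int64)


def _replicate_counts(codes, idx):
    """(B, 4) cell counts per bootstrap replicate via offset bincount."""
    B = idx.shape[0]
    sel = codes[idx] + 1  # 0..4
    off = (np.arange(B) * 5)[:, None]
    cnt = np.bincount((sel + off).ravel(), minlength=B * 5).reshape(B, 5)
    return cnt[:, 1:].astype(float)


def bootstrap_group_moments(x1: np.ndarray, x2: np.ndarray, B: int, seed: int) -> np.ndarray:
    """(B, p*p) bootstrap samples of one group's correlation moment vector.

    Pairs (complete and incomplete) are resampled with replacement; every
    replicate recomputes margins, thresholds, and tetrachoric correlations
    exactly as the point estimator does (including the +0.5 zero-cell
    correction), but fully vectorized across replicates and moments.
    """
    n, p = x1.shape
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    counts = []  # per moment: (B, 4) with cells [n00, n01, n10, n11]
    for j in range(p):
        for m in range(j + 1, p):
            counts.append(_replicate_counts(_codes(x1[:, j], x1[:, m]), idx)
                          + _replicate_counts(_codes(x2[:, j], x2[:, m]), idx))
    for j in range(p):
        counts.append(_replicate_counts(_codes(x1[:, j], x2[:, j]), idx))
    for j in range(p):
        for m in range(j + 1, p):
            counts.append(_replicate_counts(_codes(x1[:, j], x2[:, m]), idx)
                          + _replicate_counts(_codes(x2[:, j], x1[:, m]), idx))
    C = np.stack(counts, axis=1)  # (B, m, 4); cell order c0..c3 = 00,01,10,11
    zero = (C == 0).any(axis=2, keepdims=True)
    C = np.where(zero, C + 0.5, C)
    N = C.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1 = (C[:, :, 2] + C[:, :, 3]) / N
        p2 = (C[:, :, 1] + C[:, :, 3]) / N
        p11 = C[:, :, 3] / N
    eps = 1e-9
    good = (N > 0) & (p1 > eps) & (p1 < 1 - eps) & (p2 > eps) & (p2 < 1 - eps)
    tau1 = -ndtri(np.clip(p1, eps, 1 - eps))
    tau2 = -ndtri(np.clip(p2, eps, 1 - eps))
    rho = solve_tetrachoric_rho(np.where(good, p11, 0.25).ravel(),
                                np.where(good, tau1, 0.0).ravel(),
                                np.where(good, tau2, 0.0).ravel()).reshape(N.shape)
    rho = np.clip(rho, -_R_CLAMP, _R_CLAMP)
    return np.where(good, rho, np.nan)
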