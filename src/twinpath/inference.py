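"""Tests of fit, fit indices, Wald constraint tests, sex analyses, and the
model-comparison ladder.

The test of overall fit is a mean-adjusted statistic for (diagonally)
weighted least squares: T = df * F_min / tr(U Gamma), where U is the
residual-weight operator and Gamma the stage-1 covariance of the sample
moments, so that E[T] is approximately df under a correct model.  Model
comparison within a ladder is by Wald tests of parameter restrictions on the
fuller model, never by chi-square differences (which are not properly scaled
for DWLS fits).

Fit-index conventions: RMSEA = sqrt(G * max(T - df, 0) / (df * N)) with G
groups and N total individuals, TLI and CFI against the independence
baseline (all correlations zero, thresholds free), with cutoff flags at
RMSEA < 0.05, TLI > 0.95, CFI > 0.95.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtri
from scipy.stats import chi2, ncx2

from .data import GROUPS, TwinDataset, group_sex
from .estimation import (FitResult, _stacked_jacobian, _weight_matrix, fit_wls,
                         sandwich_covariance, stacked_gamma)
from .models import (ModelSpec, build_cpm_spec, build_ipm_spec, independence_spec,
                     univariate_ace_by_sex_spec)
from .moments import estimate_threshold, polychoric_matrix

__all__ = [
    "TestStatistic", "FitIndices", "WaldResult", "LadderEntry", "ComparisonResult",
    "test_statistic", "fit_indices", "wald_test", "sex_difference_test",
    "sex_covariate_adjustment", "model_ladder", "preset_ladder",
    "RMSEA_CUTOFF", "TLI_CUTOFF", "CFI_CUTOFF",
]

RMSEA_CUTOFF = 0.05
TLI_CUTOFF = 0.95
CFI_CUTOFF = 0.95


class TestStatistic(NamedTuple):
    T: float
    df: int
    p: Optional[float]


def test_statistic(fit: FitResult, gamma: Optional[np.ndarray] = None) -> TestStatistic:
    """Mean-adjusted overall test of fit against the fitted moments.

    df = (distinct fitted moments) - (free parameters);
    T = df * F_min / tr(U Gamma) with U = W - W D (D'WD)^-1 D'W; p from the
    central chi-square upper tail.  df <= 0 (saturated or over-parameterized)
    yields no p-value.
    """
    if not fit.converged:
        raise ValueError("test statistic requires a converged fit")
    m = int(fit.mask.sum())
    df = m - fit.spec.n_free
    if df <= 0:
        return TestStatistic(0.0, df, None)
    if gamma is None:
        gamma = stacked_gamma(fit.moments, fit.mask)
    W = _weight_matrix(fit)
    if fit.spec.n_free:
        D = _stacked_jacobian(fit.spec, fit.theta, fit.moments)[fit.mask]
        WD = W @ D
        B = D.T @ WD
        # pinv: a path estimated at exactly zero spans no moment direction,
        # so it simply drops out of the projection
        U = W - WD @ np.linalg.pinv(B, rcond=1e-12, hermitian=True) @ WD.T
    else:
        U = W
    denom = float(np.trace(U @ gamma))
    if denom <= 0:
        raise ValueError("nonpositive trace in the mean adjustment")
    T = df * fit.f_min / denom
    return TestStatistic(float(T), int(df), float(chi2.sf(T, df)))


@dataclass
class FitIndices:
    """Fit statistic plus RMSEA (with 90% interval), TLI, and CFI."""

    T: float
    df: int
    p_value: Optional[float]
    rmsea: float
    rmsea_lo: float
    rmsea_hi: float
    tli: float
    cfi: float
    n_total: int
    n_groups: int
    meets_rmsea: bool = field(init=False)
    meets_tli: bool = field(init=False)
    meets_cfi: bool = field(init=False)

    def __post_init__(self):
        self.meets_rmsea = np.isfinite(self.rmsea) and self.rmsea < RMSEA_CUTOFF
        self.meets_tli = np.isfinite(self.tli) and self.tli > TLI_CUTOFF
        self.meets_cfi = np.isfinite(self.cfi) and self.cfi > CFI_CUTOFF


def _rmsea_from_ncp(lam: float, df: int, n_total: int, n_groups: int) -> float:
    return float(np.sqrt(n_groups * max(lam, 0.0) / (df * n_total)))


def _ncp_bound(T: float, df: int, q: float) -> float:
    """Noncentrality lambda with ncx2.cdf(T; df, lambda) = q (0 if impossible)."""
    if chi2.cdf(T, df) < q:
        return 0.0
    hi = max(T, 1.0)
    while ncx2.cdf(T, df, hi) > q:
        hi *= 2
        if hi > 1e8:
            break
    return float(optimize.brentq(lambda lam: ncx2.cdf(T, df, lam) - q, 0.0, hi))


def fit_indices(T: float, df: int, n_total: int, n_groups: int,
                T_baseline: float, df_baseline: int, ci: float = 0.90) -> FitIndices:
    """RMSEA (multi-group sqrt(G) convention, N = individuals), TLI, CFI."""
    if df_baseline < df:
        raise ValueError("baseline df must be >= model df")
    if df <= 0:
        return FitIndices(T, df, None, np.nan, np.nan, np.nan, np.nan, np.nan,
                          n_total, n_groups)
    p = float(chi2.sf(T, df))
    rmsea = _rmsea_from_ncp(T - df, df, n_total, n_groups)
    a = (1.0 - ci) / 2.0
    lo = _rmsea_from_ncp(_ncp_bound(T, df, 1.0 - a), df, n_total, n_groups)
    hi = _rmsea_from_ncp(_ncp_bound(T, df, a), df, n_total, n_groups)
    rb = T_baseline / df_baseline if df_baseline > 0 else np.nan
    rm = T / df
    tli = (rb - rm) / (rb - 1.0) if rb != 1.0 else np.nan
    num = max(T - df, 0.0)
    den = max(T_baseline - df_baseline, T - df, 0.0)
    cfi = 1.0 if den == 0.0 else 1.0 - num / den
    return FitIndices(float(T), int(df), p, rmsea, lo, hi, float(tli),
                      float(np.clip(cfi, 0.0, 1.0)), n_total, n_groups)


class WaldResult(NamedTuple):
    W: float
    df: int
    p: float
    warning: Optional[str]


def _constraint_matrix(spec: ModelSpec, constraints, r):
    if isinstance(constraints, np.ndarray):
        R = np.atleast_2d(np.asarray(constraints, float))
    else:
        R = np.zeros((len(constraints), spec.n_free))
        for i, name in enumerate(constraints):
            R[i, spec.param_index(name)] = 1.0
    rv = np.zeros(R.shape[0]) if r is None else np.asarray(r, float)
    return R, rv


def wald_test(fit: FitResult, constraints, r=None,
              gamma: Optional[np.ndarray] = None, scale: str = "path") -> WaldResult:
    """Wald chi-square test of restrictions on the fuller model.

    ``constraints`` is either a list of free-parameter names (tested = 0) or
    an explicit R matrix with W = (R theta - r)' (R V R')^-1 (R theta - r);
    V is the sandwich covariance (computed on demand).

    ``scale='squared'`` (name lists only, r = 0) tests the corresponding
    variance components theta_k^2 = 0 by the delta method.  Use it for
    drop-to-zero restrictions on paths that enter the covariance structure
    only through squares and products (drug-specific paths, whole general
    factors): the path-scale statistic is nonstandard and anticonservative
    exactly at the boundary, while the squared-scale statistic degrades
    conservatively (large p), matching how such ladder comparisons behave in
    practice.  Restrictions whose estimate already sits at zero contribute
    zero to W but still count toward df.
    """
    if not fit.converged:
        raise ValueError("Wald test requires a converged fit")
    R, rv = _constraint_matrix(fit.spec, constraints, r)
    if np.linalg.matrix_rank(R) < R.shape[0]:
        raise ValueError("restriction matrix R is not of full row rank")
    if fit.cov is not None:
        V = fit.cov
    else:
        try:
            V = sandwich_covariance(fit, gamma=gamma)
        except np.linalg.LinAlgError:
            # flat direction (e.g. a specific path estimated at zero): ridge
            # the bread so the test degrades conservatively instead of failing
            V = sandwich_covariance(fit, gamma=gamma, ridge=1e-10)
    df = R.shape[0]
    warning = ("restriction involves a boundary solution; test may be conservative"
               if fit.boundary else None)
    if scale == "path":
        d = R @ fit.theta - rv
        M = R @ V @ R.T
        Wstat = float(d @ np.linalg.solve(M, d))
        return WaldResult(Wstat, df, float(chi2.sf(Wstat, df)), warning)
    if scale != "squared":
        raise ValueError("scale must be 'path' or 'squared'")
    if isinstance(constraints, np.ndarray) or np.any(rv != 0):
        raise ValueError("scale='squared' needs a name list tested against zero")
    idx = np.array([fit.spec.param_index(n) for n in constraints])
    th = fit.theta[idx]
    live = np.abs(th) > 1e-8
    if not live.any():
        return WaldResult(0.0, df, 1.0, warning)
    G = np.zeros((int(live.sum()), fit.spec.n_free))
    for row, k in enumerate(idx[live]):
        G[row, k] = 2.0 * fit.theta[k]
    g = th[live] ** 2
    M = G @ V @ G.T
    Wstat = float(g @ np.linalg.solve(M, g))
    return WaldResult(Wstat, df, float(chi2.sf(Wstat, df)), warning)


# ---------------------------------------------------------------------------
# Sex analyses
# ---------------------------------------------------------------------------

@dataclass
class SexDifferenceResult:
    phenotype: str
    wald: WaldResult
    fit: FitResult

    @property
    def p(self):
        return self.wald.p


def sex_difference_test(ds: TwinDataset, phenotype: str, n_starts: int = 5,
                        seed: int = 0) -> SexDifferenceResult:
    """Wald test of quantitative sex differences in a univariate ACE model.

    Fits sex-specific a/c paths (thresholds always sex-specific; e implied by
    unit variance) and tests a_M = a_F, c_M = c_F — a 2-df test of whether
    the magnitudes of genetic and shared-environment influence differ.
    """
    sexes = {group_sex(g) for g in set(ds.groups)}
    if sexes != {"M", "F"}:
        raise ValueError("sex-difference test requires both male and female groups")
    sub = ds.select_phenotypes([phenotype])
    groups = [g for g in GROUPS if g in set(ds.groups)]
    moments = [polychoric_matrix(sub, g, strict=True) for g in groups]
    spec = univariate_ace_by_sex_spec(phenotype)
    fit = fit_wls(spec, moments, n_starts=n_starts, seed=seed)
    if not fit.converged:
        raise ValueError("sex-specific univariate fit did not converge")
    R = np.array([[1.0, 0.0, -1.0, 0.0], [0.0, 1.0, 0.0, -1.0]])
    wald = wald_test(fit, R)
    return SexDifferenceResult(phenotype, wald, fit)


@dataclass
class SexAdjustedFit:
    """Structural fit plus per-phenotype sex effects on the liability scale."""

    fit: FitResult
    effects: pd.DataFrame  # beta (threshold shift), var_explained


def sex_covariate_adjustment(ds: TwinDataset, spec: ModelSpec,
                             **fit_kwargs) -> SexAdjustedFit:
    """Fit with sex as a covariate via a per-phenotype liability threshold shift.

    beta_j is the male-female threshold difference (a probit regression of
    the phenotype on a male indicator); variance explained by sex is
    beta_j^2 v_s / (beta_j^2 v_s + 1) with v_s the indicator variance.  The
    within-group correlations are unchanged by a sex shift (groups are
    single-sex), so the structural stage fits the usual moments.
    """
    sexes = {group_sex(g) for g in set(ds.groups)}
    if sexes != {"M", "F"}:
        raise ValueError("sex-covariate adjustment requires both sexes")
    male = np.array([group_sex(g) == "M" for g in ds.groups])
    persons = np.concatenate([ds.values[:, 0, :], ds.values[:, 1, :]])
    person_male = np.concatenate([male, male])
    obs_any = np.isfinite(persons).any(axis=1)
    share_m = person_male[obs_any].mean()
    v_s = share_m * (1.0 - share_m)
    rows = []
    for j, name in enumerate(ds.phenotypes):
        tau_m, _ = estimate_threshold(persons[person_male, j])
        tau_f, _ = estimate_threshold(persons[~person_male, j])
        beta = tau_f - tau_m  # >0: males endorse more
        ve = beta**2 * v_s / (beta**2 * v_s + 1.0)
        rows.append((name, beta, ve))
    effects = pd.DataFrame(rows, columns=["phenotype", "beta", "var_explained"]
                           ).set_index("phenotype")
    groups = [g for g in GROUPS if g in set(ds.groups)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        moments = [polychoric_matrix(ds, g) for g in groups]
    fit = fit_wls(spec, moments, **fit_kwargs)
    return SexAdjustedFit(fit, effects)


# ---------------------------------------------------------------------------
# Model-comparison ladder
# ---------------------------------------------------------------------------

@dataclass
class LadderEntry:
    name: str
    spec: ModelSpec
    compare_to: tuple = ()   # names of fuller models already in the ladder
    drop: dict = field(default_factory=dict)  # fuller name -> param names tested 0


@dataclass
class LadderRow:
    name: str
    fit: Optional[FitResult]
    indices: Optional[FitIndices]
    comparisons: list  # (baseline_name, WaldResult | None, note)


@dataclass
class ComparisonResult:
    """Executable analogue of a published model-comparison table."""

    rows: list
    baseline: FitIndices  # independence-model statistic feeding TLI/CFI

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for row in self.rows:
            base = {
                "model": row.name,
                "chi2": row.indices.T if row.indices else np.nan,
                "df": row.indices.df if row.indices else np.nan,
                "p": row.indices.p_value if row.indices else np.nan,
                "rmsea": row.indices.rmsea if row.indices else np.nan,
                "rmsea_lo": row.indices.rmsea_lo if row.indices else np.nan,
                "rmsea_hi": row.indices.rmsea_hi if row.indices else np.nan,
                "tli": row.indices.tli if row.indices else np.nan,
                "cfi": row.indices.cfi if row.indices else np.nan,
                "converged": bool(row.fit.converged) if row.fit else False,
            }
            if row.comparisons:
                for vs, wr, note in row.comparisons:
                    rec = dict(base)
                    rec["vs"] = vs
                    rec["wald_chi2"] = wr.W if wr else np.nan
                    rec["wald_df"] = wr.df if wr else np.nan
                    rec["wald_p"] = wr.p if wr else np.nan
                    rec["note"] = note
                    recs.append(rec)
            else:
                rec = dict(base)
                rec.update({"vs": "", "wald_chi2": np.nan, "wald_df": np.nan,
                            "wald_p": np.nan, "note": ""})
                recs.append(rec)
        return pd.DataFrame(recs)

    def to_text(self) -> str:
        df = self.to_frame()
        lines = [f"{'model':<22}{'chi2':>10}{'df':>5}{'p':>7}{'RMSEA':>7}"
                 f"{'(90% CI)':>16}{'TLI':>7}{'CFI':>7}{'Wald':>9}{'df':>4}{'p':>7}  vs"]
        for _, r in df.iterrows():
            if not r["converged"]:
                chi = "   No convergence"
                lines.append(f"{r['model']:<22}{chi:<45}"
                             f"{r['wald_chi2']:>9.3f}{r['wald_df']:>4.0f}"
                             f"{r['wald_p']:>7.3f}  {r['vs']}"
                             if np.isfinite(r["wald_chi2"]) else
                             f"{r['model']:<22}{chi}")
                continue
            w = (f"{r['wald_chi2']:>9.3f}{r['wald_df']:>4.0f}{r['wald_p']:>7.3f}"
                 if np.isfinite(r["wald_chi2"]) else " " * 20)
            lines.append(
                f"{r['model']:<22}{r['chi2']:>10.3f}{r['df']:>5.0f}{r['p']:>7.3f}"
                f"{r['rmsea']:>7.3f}  ({r['rmsea_lo']:.3f}-{r['rmsea_hi']:.3f})"
                f"{r['tli']:>7.3f}{r['cfi']:>7.3f}{w}  {r['vs']}")
        return "\n".join(lines)


def model_ladder(source, entries: Sequence[LadderEntry], weight_mode: str = "diagonal",
                 acov: str = "bootstrap", n_boot: int = 200, seed: int = 0,
                 n_starts: int = 5) -> ComparisonResult:
    """Fit an ordered ladder of specs with fit indices and Wald comparisons.

    ``source`` is a TwinDataset (stage 1 run per group, bootstrap acov by
    default) or a prebuilt list of GroupMoments.  Nonconvergence is recorded
    as an outcome; a comparison whose fuller model did not converge is
    skipped with a notice.  Each Wald test runs on the *fuller* model with
    the entry's dropped parameters restricted to zero.
    """
    if isinstance(source, TwinDataset):
        groups = [g for g in GROUPS if g in set(source.groups)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            moments = [polychoric_matrix(source, g, acov=acov, n_boot=n_boot,
                                         seed=seed + 17 * i)
                       for i, g in enumerate(groups)]
    else:
        moments = list(source)
    phenos = moments[0].phenotypes
    base_fit = fit_wls(independence_spec(phenos), moments, weight_mode=weight_mode)
    Tb, dfb, _ = test_statistic(base_fit)
    n_total = base_fit.n_total
    G = len(moments)
    baseline = fit_indices(Tb, dfb, max(n_total, 1), G, Tb, dfb)

    fits = {}
    rows = []
    prev_theta = {}
    for entry in entries:
        extra = []
        # warm-start from any already-fitted fuller model (drop pattern known)
        for fuller in entry.compare_to:
            if fuller in prev_theta:
                fuller_spec, th = prev_theta[fuller]
                emb = _embed_theta(fuller_spec, th, entry.spec)
                if emb is not None:
                    extra.append(emb)
        fit = fit_wls(entry.spec, moments, weight_mode=weight_mode,
                      n_starts=n_starts, seed=seed, extra_starts=extra)
        fits[entry.name] = fit
        if fit.converged:
            prev_theta[entry.name] = (entry.spec, fit.theta)
        indices = None
        if fit.converged:
            T, df, _ = test_statistic(fit)
            indices = fit_indices(T, df, max(n_total, 1), G, Tb, dfb)
        comparisons = []
        for fuller in entry.compare_to:
            full_fit = fits.get(fuller)
            drop = entry.drop.get(fuller, ())
            if full_fit is None or not full_fit.converged:
                comparisons.append((fuller, None, "fuller model not converged"))
                continue
            try:
                wr = wald_test(full_fit, list(drop), scale="squared")
                comparisons.append((fuller, wr, ""))
            except (ValueError, np.linalg.LinAlgError) as exc:
                comparisons.append((fuller, None, str(exc)))
        rows.append(LadderRow(entry.name, fit, indices, comparisons))
    return ComparisonResult(rows, baseline)


def _embed_theta(fuller_spec: ModelSpec, theta, nested_spec: ModelSpec):
    """Project a fuller model's solution onto a nested spec's parameters."""
    if fuller_spec.kind != nested_spec.kind:
        return None
    vals = dict(zip(fuller_spec.free_names, theta))
    out = np.zeros(nested_spec.n_free)
    for i, name in enumerate(nested_spec.free_names):
        if name in vals:
            out[i] = vals[name]
        elif nested_spec.kind == "ipm" and ":" in name:
            # a factor renumbered after a drop (e.g. e1 in 1-0-1 from e1 in 1-1-1)
            out[i] = vals.get(name, 0.3)
        else:
            out[i] = 0.3
    return out


def preset_ladder(codebook=None) -> list:
    """The packaged model-comparison ladder for the 11-phenotype drug-use set.

    Reproduces the published comparison structure: the 2-2-2 independent
    pathway start, stepwise removal of second and then whole general factors,
    the reduced 1-0-1 model, and the one-factor common pathway model with its
    reduced form.  Requires the registry codebook phenotype names.
    """
    from .simulate import atr_codebook

    cb = codebook if codebook is not None else atr_codebook()
    spec222 = build_ipm_spec(cb, 2, 2, 2)
    spec122 = build_ipm_spec(cb, 1, 2, 2, name="IP 1-2-2")
    spec121 = build_ipm_spec(cb, 1, 2, 1, name="IP 1-2-1")
    spec112 = build_ipm_spec(cb, 1, 1, 2, name="IP 1-1-2")
    spec111 = build_ipm_spec(cb, 1, 1, 1, name="IP 1-1-1")
    spec101 = build_ipm_spec(cb, 1, 0, 1, name="IP 1-0-1")
    reduced_drops = _reduced_101_drops(cb)
    spec101r = build_ipm_spec(cb, 1, 0, 1, drops=reduced_drops, name="IP 1-0-1 (reduced)")
    cpm = build_cpm_spec(cb, name="CP-1")
    cpm_drops = _reduced_cpm_drops(cb)
    cpmr = build_cpm_spec(cb, drops=cpm_drops, name="CP-1 (reduced)")

    def gf(spec, comp, factor):
        return spec.general_factor_params(comp, factor)

    entries = [
        LadderEntry("IP 2-2-2", spec222),
        LadderEntry("IP 2-2-1", build_ipm_spec(cb, 2, 2, 1, name="IP 2-2-1"),
                    ("IP 2-2-2",), {"IP 2-2-2": gf(spec222, "e", 1)}),
        LadderEntry("IP 2-1-2", build_ipm_spec(cb, 2, 1, 2, name="IP 2-1-2"),
                    ("IP 2-2-2",), {"IP 2-2-2": gf(spec222, "c", 1)}),
        LadderEntry("IP 1-2-2", spec122,
                    ("IP 2-2-2",), {"IP 2-2-2": gf(spec222, "a", 1)}),
        LadderEntry("IP 1-2-1", spec121,
                    ("IP 1-2-2",), {"IP 1-2-2": gf(spec122, "e", 1)}),
        LadderEntry("IP 1-1-2", spec112,
                    ("IP 1-2-2",), {"IP 1-2-2": gf(spec122, "c", 1)}),
        LadderEntry("IP 0-2-2", build_ipm_spec(cb, 0, 2, 2, name="IP 0-2-2"),
                    ("IP 1-2-2",), {"IP 1-2-2": gf(spec122, "a", 0)}),
        LadderEntry("IP 1-1-1", spec111,
                    ("IP 1-2-1", "IP 1-1-2"),
                    {"IP 1-2-1": gf(spec121, "c", 1), "IP 1-1-2": gf(spec112, "e", 1)}),
        LadderEntry("IP 0-1-1", build_ipm_spec(cb, 0, 1, 1, name="IP 0-1-1"),
                    ("IP 1-1-1",), {"IP 1-1-1": gf(spec111, "a", 0)}),
        LadderEntry("IP 1-0-1", spec101,
                    ("IP 1-1-1",), {"IP 1-1-1": gf(spec111, "c", 0)}),
        LadderEntry("IP 1-1-0", build_ipm_spec(cb, 1, 1, 0, name="IP 1-1-0"),
                    ("IP 1-1-1",), {"IP 1-1-1": gf(spec111, "e", 0)}),
        LadderEntry("IP 0-0-1", build_ipm_spec(cb, 0, 0, 1, name="IP 0-0-1"),
                    ("IP 1-0-1",), {"IP 1-0-1": gf(spec101, "a", 0)}),
        LadderEntry("IP 1-0-0", build_ipm_spec(cb, 1, 0, 0, name="IP 1-0-0"),
                    ("IP 1-0-1",), {"IP 1-0-1": gf(spec101, "e", 0)}),
        LadderEntry("IP 1-0-1 (reduced)", spec101r,
                    ("IP 1-0-1",), {"IP 1-0-1": tuple(reduced_drops)}),
        LadderEntry("CP-1", cpm),
        LadderEntry("CP-1 (reduced)", cpmr, ("CP-1",), {"CP-1": tuple(cpm_drops)}),
    ]
    return entries


def _reduced_101_drops(cb):
    """Parameter drops of the reduced one-a/one-e pathway model: the cannabis
    general-e loading; specific a except the opioid and sedative phenotypes;
    specific c for the prescription phenotypes plus heroin, cocaine,
    hallucinogens, and dissociatives."""
    keep_sa = {"pom", "sedatives_rx"}
    keep_sc = {"cannabis", "stimulants_illicit", "inhalants", "solvents"}
    drops = ["e1:cannabis"]
    drops += [f"as:{n}" for n in cb.names if n not in keep_sa]
    drops += [f"cs:{n}" for n in cb.names if n not in keep_sc]
    return drops


def _reduced_cpm_drops(cb):
    """Parameter drops of the reduced common pathway model: specific a for six
    illicit phenotypes; specific c for the prescription phenotypes, cannabis,
    and inhalants."""
    drop_sa = {"heroin", "cocaine", "stimulants_illicit", "hallucinogens",
               "solvents", "dissociatives"}
    drop_sc = {"pom", "stimulants_rx", "sedatives_rx", "cannabis", "inhalants"}
    return [f"as:{n}" for n in cb.names if n in drop_sa] + \
           [f"cs:{n}" for n in cb.names if n in drop_sc]
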