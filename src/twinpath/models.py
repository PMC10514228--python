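"""Structural twin-model specifications and liability-scale expectation algebra.

Supported model kinds
---------------------
univariate_ace        a/c/e paths for one phenotype (e implied by unit variance)
univariate_ace_by_sex same, with separate male and female structural paths
bivariate_cholesky    triangular a/c/e decomposition of two phenotypes
ipm                   independent pathway: general a/c/e factors loading all
                      phenotypes plus drug-specific a/c/e residuals
cpm                   common pathway: one latent phenotype (itself decomposed
                      into a/c/e) mediating all shared variance
saturated             one free parameter per moment per zygosity
independence          all correlations fixed at zero

Every spec enforces unit liability variance per phenotype by *implying* the
drug-specific e path: se_j = sqrt(max(0, 1 - explained_j)), with a penalty as
the explained variance approaches 1 from above.  Cross-twin expectations use
the classical additive-genetic coefficient kappa = 1 (MZ) / 0.5 (DZ) and no
dominance term.

The moment order matches :func:`twinpath.moments.moment_labels`: within-person
pairs (j<m), cross-twin same-trait, cross-twin cross-trait pairs (j<m).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .data import PhenotypeCodebook
from .moments import moment_labels

__all__ = [
    "ModelSpec",
    "VarianceDecomposition",
    "FalconerResult",
    "univariate_ace_spec",
    "univariate_ace_by_sex_spec",
    "bivariate_cholesky_spec",
    "build_ipm_spec",
    "build_cpm_spec",
    "saturated_spec",
    "independence_spec",
    "expected_correlation_matrix",
    "standardize",
    "falconer_estimates",
]

_PENALTY_WEIGHT = 100.0
_KINDS = ("univariate_ace", "univariate_ace_by_sex", "bivariate_cholesky",
          "ipm", "cpm", "saturated", "independence")


def _moment_positions(p: int):
    within, cross_same, cross_pair = {}, {}, {}
    i = 0
    for j in range(p):
        for m in range(j + 1, p):
            within[(j, m)] = i
            i += 1
    for j in range(p):
        cross_same[j] = i
        i += 1
    for j in range(p):
        for m in range(j + 1, p):
            cross_pair[(j, m)] = i
            i += 1
    return within, cross_same, cross_pair, i


@dataclass
class ModelSpec:
    """A declarative structural model over a fixed phenotype set."""

    kind: str
    phenotypes: tuple
    free_names: tuple
    structure: dict = field(default_factory=dict)
    name: str = ""

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        if len(set(self.free_names)) != len(self.free_names):
            raise ValueError("free parameter names must be unique")
        self.phenotypes = tuple(self.phenotypes)
        self.free_names = tuple(self.free_names)
        if not self.name:
            self.name = self.kind

    # -- bookkeeping -------------------------------------------------------
    @property
    def p(self) -> int:
        return len(self.phenotypes)

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    @property
    def n_moments_per_group(self) -> int:
        return self.p * self.p

    def param_index(self, name: str) -> int:
        return self.free_names.index(name)

    def theta_dict(self, theta) -> dict:
        return dict(zip(self.free_names, np.asarray(theta, float)))

    # -- matrix assembly ---------------------------------------------------
    def _loadings(self, theta, comp):
        k = self.structure["k"][comp]
        lam = np.zeros((self.p, max(k, 1)) if k else (self.p, 0))
        for row, col, pix in self.structure["gen"][comp]:
            lam[row, col] = theta[pix]
        return lam

    def _specifics(self, theta, comp):
        s = np.zeros(self.p)
        for row, pix in self.structure["spec"].get(comp, ()):
            s[row] = theta[pix]
        return s

    def component_matrices(self, theta):
        """(A, C, E, implied_se2) liability covariance component matrices.

        A and C include the drug-specific variances on their diagonals; E
        includes the general-e part plus the implied specific-e diagonal, so
        A + C + E has a unit diagonal whenever theta is admissible.
        """
        theta = np.asarray(theta, dtype=float)
        p = self.p
        if self.kind == "univariate_ace":
            a, c = theta
            e2 = max(0.0, 1.0 - a * a - c * c)
            return (np.array([[a * a]]), np.array([[c * c]]), np.array([[e2]]),
                    np.array([e2]))
        if self.kind == "bivariate_cholesky":
            a11, a21, a22, c11, c21, c22, e21 = theta
            A = np.array([[a11**2, a11 * a21], [a11 * a21, a21**2 + a22**2]])
            C = np.array([[c11**2, c11 * c21], [c11 * c21, c21**2 + c22**2]])
            e11_2 = max(0.0, 1.0 - A[0, 0] - C[0, 0])
            e11 = np.sqrt(e11_2)
            e22_2 = max(0.0, 1.0 - A[1, 1] - C[1, 1] - e21**2)
            E = np.array([[e11_2, e11 * e21], [e11 * e21, e21**2 + e22_2]])
            return A, C, E, np.array([e11_2, e22_2])
        if self.kind == "ipm":
            La = self._loadings(theta, "a")
            Lc = self._loadings(theta, "c")
            Le = self._loadings(theta, "e")
            sa = self._specifics(theta, "a")
            sc = self._specifics(theta, "c")
            A = La @ La.T + np.diag(sa**2)
            C = Lc @ Lc.T + np.diag(sc**2)
            Eg = Le @ Le.T
            expl = np.diag(A) + np.diag(C) + np.diag(Eg)
            se2 = np.maximum(0.0, 1.0 - expl)
            return A, C, Eg + np.diag(se2), se2
        if self.kind == "cpm":
            aF = theta[self.structure["aF"]]
            cF = theta[self.structure["cF"]]
            lam = np.array([theta[i] for i in self.structure["lam"]])
            sa = self._specifics(theta, "a")
            sc = self._specifics(theta, "c")
            eF2 = max(0.0, 1.0 - aF**2 - cF**2)
            LL = np.outer(lam, lam)
            A = aF**2 * LL + np.diag(sa**2)
            C = cF**2 * LL + np.diag(sc**2)
            Eg = eF2 * LL
            expl = np.diag(A) + np.diag(C) + np.diag(Eg)
            se2 = np.maximum(0.0, 1.0 - expl)
            return A, C, Eg + np.diag(se2), se2
        raise ValueError(f"component matrices undefined for kind {self.kind!r}")

    # -- expected moments --------------------------------------------------
    def sigma(self, theta, kappa: float, sex: Optional[str] = None) -> np.ndarray:
        """Model-implied unique correlation moments for one group."""
        theta = np.asarray(theta, dtype=float)
        p = self.p
        m = self.n_moments_per_group
        if self.kind == "independence":
            return np.zeros(m)
        if self.kind == "saturated":
            g = ("MZ" if kappa == 1.0 else "DZ") + (sex or "M")
            i = self.structure["groups"].index(g)
            return theta[i * m:(i + 1) * m].copy()
        if self.kind == "univariate_ace_by_sex":
            aM, cM, aF_, cF_ = theta
            a, c = (aM, cM) if sex == "M" else (aF_, cF_)
            return np.array([kappa * a * a + c * c])
        A, C, E, _ = self.component_matrices(theta)
        within, cross_same, cross_pair, _ = _moment_positions(p)
        out = np.empty(m)
        W = A + C + E
        X = kappa * A + C
        for (j, mm), i in within.items():
            out[i] = W[j, mm]
        for j, i in cross_same.items():
            out[i] = X[j, j]
        for (j, mm), i in cross_pair.items():
            out[i] = X[j, mm]
        return out

    def jacobian(self, theta, kappa: float, sex: Optional[str] = None) -> np.ndarray:
        """Analytic Jacobian d sigma / d theta for one group, (m, n_free)."""
        theta = np.asarray(theta, dtype=float)
        p = self.p
        m = self.n_moments_per_group
        q = self.n_free
        J = np.zeros((m, q))
        within, cross_same, cross_pair, _ = _moment_positions(p)
        if self.kind == "independence":
            return J
        if self.kind == "saturated":
            g = ("MZ" if kappa == 1.0 else "DZ") + (sex or "M")
            i = self.structure["groups"].index(g)
            J[:, i * m:(i + 1) * m] = np.eye(m)
            return J
        if self.kind == "univariate_ace":
            a, c = theta
            J[0, 0] = 2 * kappa * a
            J[0, 1] = 2 * c
            return J
        if self.kind == "univariate_ace_by_sex":
            off = 0 if sex == "M" else 2
            a, c = theta[off], theta[off + 1]
            J[0, off] = 2 * kappa * a
            J[0, off + 1] = 2 * c
            return J
        if self.kind == "bivariate_cholesky":
            a11, a21, a22, c11, c21, c22, e21 = theta
            e11_2 = max(0.0, 1.0 - a11**2 - c11**2)
            e11 = np.sqrt(e11_2)
            iw = within[(0, 1)]
            i0, i1 = cross_same[0], cross_same[1]
            ix = cross_pair[(0, 1)]
            de11_da11 = -a11 / e11 if e11 > 1e-12 else 0.0
            de11_dc11 = -c11 / e11 if e11 > 1e-12 else 0.0
            # within(1,2) = a11 a21 + c11 c21 + e11 e21
            J[iw] = [a21 + de11_da11 * e21, a11, 0.0,
                     c21 + de11_dc11 * e21, c11, 0.0, e11]
            # cross same 1 = kappa a11^2 + c11^2 ; same 2
            J[i0, 0] = 2 * kappa * a11
            J[i0, 3] = 2 * c11
            J[i1, 1] = 2 * kappa * a21
            J[i1, 2] = 2 * kappa * a22
            J[i1, 4] = 2 * c21
            J[i1, 5] = 2 * c22
            # cross pair = kappa a11 a21 + c11 c21
            J[ix, 0] = kappa * a21
            J[ix, 1] = kappa * a11
            J[ix, 3] = c21
            J[ix, 4] = c11
            return J
        if self.kind == "ipm":
            lams = {comp: self._loadings(theta, comp) for comp in "ace"}
            xmul = {"a": kappa, "c": 1.0, "e": 0.0}
            for comp in "ace":
                L = lams[comp]
                xm = xmul[comp]
                for row, col, pix in self.structure["gen"][comp]:
                    for mm in range(p):
                        if mm == row:
                            continue
                        val = L[mm, col]
                        if val == 0.0:
                            continue
                        jlo, jhi = min(row, mm), max(row, mm)
                        J[within[(jlo, jhi)], pix] += val
                        if xm:
                            J[cross_pair[(jlo, jhi)], pix] += xm * val
                    if xm:
                        J[cross_same[row], pix] += xm * 2 * L[row, col]
            for comp, xm in (("a", kappa), ("c", 1.0)):
                for row, pix in self.structure["spec"].get(comp, ()):
                    J[cross_same[row], pix] += xm * 2 * theta[pix]
            return J
        if self.kind == "cpm":
            iaF, icF = self.structure["aF"], self.structure["cF"]
            aF, cF = theta[iaF], theta[icF]
            lam = np.array([theta[i] for i in self.structure["lam"]])
            interior = (1.0 - aF**2 - cF**2) >= 0.0
            ft = 1.0 if interior else aF**2 + cF**2
            xg = kappa * aF**2 + cF**2
            for j in range(p):
                J[cross_same[j], iaF] += kappa * 2 * aF * lam[j] ** 2
                J[cross_same[j], icF] += 2 * cF * lam[j] ** 2
            for (j, mm), i in cross_pair.items():
                J[i, iaF] += kappa * 2 * aF * lam[j] * lam[mm]
                J[i, icF] += 2 * cF * lam[j] * lam[mm]
            if not interior:
                for (j, mm), i in within.items():
                    J[i, iaF] += 2 * aF * lam[j] * lam[mm]
                    J[i, icF] += 2 * cF * lam[j] * lam[mm]
            for j, pix in enumerate(self.structure["lam"]):
                for mm in range(p):
                    if mm == j:
                        continue
                    jlo, jhi = min(j, mm), max(j, mm)
                    J[within[(jlo, jhi)], pix] += ft * lam[mm]
                    J[cross_pair[(jlo, jhi)], pix] += xg * lam[mm]
                J[cross_same[j], pix] += 2 * lam[j] * xg
            for comp, xm in (("a", kappa), ("c", 1.0)):
                for row, pix in self.structure["spec"].get(comp, ()):
                    J[cross_same[row], pix] += xm * 2 * theta[pix]
            return J
        raise ValueError(self.kind)

    # -- unit-variance penalty --------------------------------------------
    def penalty_residuals(self, theta):
        """Fixed-size residuals (and Jacobian) penalizing explained variance > 1.

        Inactive constraints contribute exact zeros so the residual dimension
        never changes during optimization.
        """
        theta = np.asarray(theta, dtype=float)
        q = self.n_free

        def _pack(pairs):
            res = np.zeros(len(pairs))
            rows = np.zeros((len(pairs), q))
            for i, (excess, grad) in enumerate(pairs):
                if excess > 0:
                    res[i] = _PENALTY_WEIGHT * excess
                    rows[i] = _PENALTY_WEIGHT * grad
            return res, rows

        if self.kind in ("saturated", "independence"):
            return np.zeros(0), np.zeros((0, q))
        if self.kind == "univariate_ace":
            a, c = theta
            return _pack([(a * a + c * c - 1.0, np.array([2 * a, 2 * c]))])
        if self.kind == "univariate_ace_by_sex":
            pairs = []
            for off in (0, 2):
                a, c = theta[off], theta[off + 1]
                row = np.zeros(q)
                row[off], row[off + 1] = 2 * a, 2 * c
                pairs.append((a * a + c * c - 1.0, row))
            return _pack(pairs)
        if self.kind == "bivariate_cholesky":
            a11, a21, a22, c11, c21, c22, e21 = theta
            return _pack([
                (a11**2 + c11**2 - 1.0, np.array([2 * a11, 0, 0, 2 * c11, 0, 0, 0.0])),
                (a21**2 + a22**2 + c21**2 + c22**2 + e21**2 - 1.0,
                 np.array([0, 2 * a21, 2 * a22, 0, 2 * c21, 2 * c22, 2 * e21])),
            ])
        # ipm / cpm: explained_j (excluding implied se) must stay <= 1
        p = self.p
        expl = np.zeros(p)
        grad = np.zeros((p, q))
        if self.kind == "ipm":
            for comp in "ace":
                L = self._loadings(theta, comp)
                for row, col, pix in self.structure["gen"][comp]:
                    expl[row] += L[row, col] ** 2
                    grad[row, pix] += 2 * L[row, col]
        else:
            iaF, icF = self.structure["aF"], self.structure["cF"]
            aF, cF = theta[iaF], theta[icF]
            lam = np.array([theta[i] for i in self.structure["lam"]])
            interior = (1.0 - aF**2 - cF**2) >= 0.0
            ft = 1.0 if interior else aF**2 + cF**2
            for j, pix in enumerate(self.structure["lam"]):
                expl[j] += ft * lam[j] ** 2
                grad[j, pix] += 2 * ft * lam[j]
                if not interior:
                    grad[j, iaF] += 2 * aF * lam[j] ** 2
                    grad[j, icF] += 2 * cF * lam[j] ** 2
        for comp in ("a", "c"):
            for row, pix in self.structure["spec"].get(comp, ()):
                expl[row] += theta[pix] ** 2
                grad[row, pix] += 2 * theta[pix]
        pairs = [(expl[j] - 1.0, grad[j]) for j in range(p)]
        if self.kind == "cpm":
            iaF, icF = self.structure["aF"], self.structure["cF"]
            row = np.zeros(q)
            row[iaF], row[icF] = 2 * theta[iaF], 2 * theta[icF]
            pairs.append((theta[iaF] ** 2 + theta[icF] ** 2 - 1.0, row))
        return _pack(pairs)

    # -- identification helpers -------------------------------------------
    def default_start(self) -> np.ndarray:
        st = {
            "univariate_ace": [0.55, 0.45],
            "univariate_ace_by_sex": [0.55, 0.45, 0.55, 0.45],
            "bivariate_cholesky": [0.55, 0.25, 0.45, 0.45, 0.2, 0.35, 0.2],
        }
        if self.kind in st:
            return np.array(st[self.kind])
        if self.kind in ("saturated", "independence"):
            return np.zeros(self.n_free)
        x = np.zeros(self.n_free)
        if self.kind == "ipm":
            base = {"a": 0.5, "c": 0.4, "e": 0.35}
            for comp in "ace":
                for row, col, pix in self.structure["gen"][comp]:
                    x[pix] = base[comp] if col == 0 else 0.25
            for comp in ("a", "c"):
                for row, pix in self.structure["spec"].get(comp, ()):
                    x[pix] = 0.35
        else:
            x[self.structure["aF"]] = 0.65
            x[self.structure["cF"]] = 0.5
            for pix in self.structure["lam"]:
                x[pix] = 0.65
            for comp in ("a", "c"):
                for row, pix in self.structure["spec"].get(comp, ()):
                    x[pix] = 0.3
        return x

    def canonicalize(self, theta) -> np.ndarray:
        """Resolve factor sign indeterminacy: within each factor, the first
        free loading is made nonnegative; pure-variance paths take |.|."""
        theta = np.asarray(theta, dtype=float).copy()
        if self.kind in ("saturated", "independence"):
            return theta
        if self.kind in ("univariate_ace", "univariate_ace_by_sex"):
            return np.abs(theta)
        if self.kind == "bivariate_cholesky":
            for lead, others in ((0, [1]), (3, [4])):  # a11, c11 columns
                if theta[lead] < 0:
                    theta[lead] = -theta[lead]
                    for o in others:
                        theta[o] = -theta[o]
            theta[2] = abs(theta[2])  # a22
            theta[5] = abs(theta[5])  # c22
            # e21 sign is identified through e11*e21 (e11 >= 0); leave it
            return theta
        if self.kind == "ipm":
            for comp in "ace":
                k = self.structure["k"][comp]
                for col in range(k):
                    entries = [(row, pix) for row, c_, pix in self.structure["gen"][comp]
                               if c_ == col]
                    if not entries:
                        continue
                    lead = min(entries)[1]
                    if theta[lead] < 0:
                        for _, pix in entries:
                            theta[pix] = -theta[pix]
            for comp in ("a", "c"):
                for row, pix in self.structure["spec"].get(comp, ()):
                    theta[pix] = abs(theta[pix])
            return theta
        # cpm: aF, cF enter squared; lambda has a global sign
        theta[self.structure["aF"]] = abs(theta[self.structure["aF"]])
        theta[self.structure["cF"]] = abs(theta[self.structure["cF"]])
        lam_ix = self.structure["lam"]
        if theta[lam_ix[0]] < 0:
            for pix in lam_ix:
                theta[pix] = -theta[pix]
        for comp in ("a", "c"):
            for row, pix in self.structure["spec"].get(comp, ()):
                theta[pix] = abs(theta[pix])
        return theta

    def general_factor_params(self, comp: str, factor: int):
        """Names of the free loadings of one general factor (for Wald drops)."""
        if self.kind != "ipm":
            raise ValueError("general factors exist only for ipm specs")
        return tuple(self.free_names[pix]
                     for row, col, pix in self.structure["gen"][comp] if col == factor)


# ---------------------------------------------------------------------------
# Spec builders
# ---------------------------------------------------------------------------

def univariate_ace_spec(phenotype: str, name: str = "") -> ModelSpec:
    return ModelSpec("univariate_ace", (phenotype,), ("a", "c"),
                     name=name or f"ACE[{phenotype}]")


def univariate_ace_by_sex_spec(phenotype: str) -> ModelSpec:
    return ModelSpec("univariate_ace_by_sex", (phenotype,),
                     ("a_M", "c_M", "a_F", "c_F"), name=f"ACExSex[{phenotype}]")


def bivariate_cholesky_spec(phen1: str, phen2: str) -> ModelSpec:
    return ModelSpec("bivariate_cholesky", (phen1, phen2),
                     ("a11", "a21", "a22", "c11", "c21", "c22", "e21"),
                     name=f"Cholesky[{phen1},{phen2}]")


def build_ipm_spec(codebook: PhenotypeCodebook, n_a: int, n_c: int, n_e: int,
                   pattern: str = "single", drops: Sequence[str] = (),
                   name: str = "") -> ModelSpec:
    """Independent pathway spec with the requested general-factor counts.

    ``pattern='single'`` gives echelon identification: the first factor of a
    component loads every phenotype, the second loads phenotypes 2..p (its
    first loading fixed to zero), so each extra factor carries p-1 free
    loadings.  ``pattern='by_class_tag'`` (requires the count = 2 for that
    component) loads prescription phenotypes on factor 1 and illicit on
    factor 2.  ``drops`` lists free-parameter names fixed to zero (general
    loadings like ``'e1:cannabis'`` or specifics like ``'as:heroin'``);
    dropping any specific-e is impossible by construction and rejected.
    """
    counts = {"a": n_a, "c": n_c, "e": n_e}
    for comp, k in counts.items():
        if k not in (0, 1, 2):
            raise ValueError(f"n_{comp} must be 0, 1, or 2")
    if pattern not in ("single", "by_class_tag"):
        raise ValueError("pattern must be 'single' or 'by_class_tag'")
    drops = set(drops)
    for d in drops:
        if d.startswith("es:") or d.startswith("se:"):
            raise ValueError("drug-specific e factors cannot be dropped")
    names = codebook.names
    p = len(names)
    free, gen, spec = [], {"a": [], "c": [], "e": []}, {"a": [], "c": []}
    if pattern == "by_class_tag":
        rx = codebook.class_mask("prescription")
        if not rx.any() or rx.all():
            raise ValueError("by_class_tag needs both prescription and illicit phenotypes")
    for comp in "ace":
        k = counts[comp]
        if pattern == "by_class_tag" and k == 1:
            raise ValueError("by_class_tag requires the factor count to be 2 (or 0)")
        if pattern == "by_class_tag" and k == 2:
            rowsets = [[j for j in range(p) if rx[j]], [j for j in range(p) if not rx[j]]]
        elif k == 2:
            rowsets = [list(range(p)), list(range(1, p))]
        elif k == 1:
            rowsets = [list(range(p))]
        else:
            rowsets = []
        for f, rows in enumerate(rowsets):
            for j in rows:
                pname = f"{comp}{f + 1}:{names[j]}"
                if pname in drops:
                    drops.discard(pname)
                    continue
                gen[comp].append((j, f, len(free)))
                free.append(pname)
    for comp in ("a", "c"):
        for j in range(p):
            pname = f"{comp}s:{names[j]}"
            if pname in drops:
                drops.discard(pname)
                continue
            spec[comp].append((j, len(free)))
            free.append(pname)
    if drops:
        raise ValueError(f"unknown parameters in drops: {sorted(drops)}")
    structure = {"k": {c: counts[c] for c in "ace"}, "gen": gen, "spec": spec}
    return ModelSpec("ipm", names, tuple(free), structure,
                     name=name or f"IP {n_a}-{n_c}-{n_e}")


def build_cpm_spec(codebook: PhenotypeCodebook, drops: Sequence[str] = (),
                   name: str = "") -> ModelSpec:
    """One-factor common pathway spec: latent phenotype decomposed into
    a_F/c_F (e_F implied), loadings lambda per phenotype, drug-specific a/c
    residuals (specific e implied).  ``drops`` as in :func:`build_ipm_spec`."""
    drops = set(drops)
    for d in drops:
        if d.startswith("es:") or d.startswith("se:"):
            raise ValueError("drug-specific e factors cannot be dropped")
    names = codebook.names
    free = ["aF", "cF"]
    lam_ix = []
    for n in names:
        lam_ix.append(len(free))
        free.append(f"lam:{n}")
    spec = {"a": [], "c": []}
    for comp in ("a", "c"):
        for j, n in enumerate(names):
            pname = f"{comp}s:{n}"
            if pname in drops:
                drops.discard(pname)
                continue
            spec[comp].append((j, len(free)))
            free.append(pname)
    if drops:
        raise ValueError(f"unknown parameters in drops: {sorted(drops)}")
    structure = {"aF": 0, "cF": 1, "lam": lam_ix, "spec": spec,
                 "k": {"a": 0, "c": 0, "e": 0}, "gen": {"a": [], "c": [], "e": []}}
    return ModelSpec("cpm", names, tuple(free), structure, name=name or "CP-1")


def saturated_spec(phenotypes: Sequence[str], groups: Sequence[str] = None) -> ModelSpec:
    """One free parameter per distinct correlation moment per group."""
    from .data import GROUPS

    phenotypes = tuple(phenotypes)
    groups = tuple(groups) if groups is not None else GROUPS
    labels = moment_labels(phenotypes)
    free = tuple(f"{g}:{kind}:{a}:{b}" for g in groups for kind, a, b in labels)
    return ModelSpec("saturated", phenotypes, free, {"groups": groups},
                     name="saturated")


def independence_spec(phenotypes: Sequence[str]) -> ModelSpec:
    return ModelSpec("independence", tuple(phenotypes), (), name="independence")


# ---------------------------------------------------------------------------
# Derived quantities
# ---------------------------------------------------------------------------

def expected_correlation_matrix(spec: ModelSpec, theta, zygosity: str) -> np.ndarray:
    """Model-implied 2p x 2p liability correlation matrix for MZ or DZ pairs."""
    if zygosity not in ("MZ", "DZ"):
        raise ValueError("zygosity must be 'MZ' or 'DZ'")
    kappa = 1.0 if zygosity == "MZ" else 0.5
    A, C, E, se2 = spec.component_matrices(np.asarray(theta, float))
    W = A + C + E
    if np.any(np.abs(np.diag(W) - 1.0) > 1e-8):
        raise ValueError("theta violates the unit liability-variance constraint")
    X = kappa * A + C
    p = spec.p
    out = np.empty((2 * p, 2 * p))
    out[:p, :p] = W
    out[p:, p:] = W
    out[:p, p:] = X
    out[p:, :p] = X.T
    return out


@dataclass
class VarianceDecomposition:
    """Standardized variance proportions per phenotype.

    Columns: general_a, general_c, general_e, specific_a, specific_c,
    specific_e; rows sum to 1.  For common pathway models the general_*
    columns are the through-factor shares (lambda_j^2 * a_F^2 etc.) and
    ``factor_shares`` holds (a_F^2, c_F^2, e_F^2).
    """

    phenotypes: tuple
    proportions: np.ndarray
    factor_shares: Optional[tuple] = None

    COLUMNS = ("general_a", "general_c", "general_e",
               "specific_a", "specific_c", "specific_e")

    def __post_init__(self):
        self.proportions = np.asarray(self.proportions, dtype=float)
        sums = self.proportions.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-8):
            raise ValueError("variance proportions must sum to 1 per phenotype")
        if self.proportions.min() < -1e-12:
            raise ValueError("variance proportions must be nonnegative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.proportions, index=list(self.phenotypes),
                            columns=list(self.COLUMNS))

    def flatten(self):
        names = [f"{col}:{ph}" for ph in self.phenotypes for col in self.COLUMNS]
        return names, self.proportions.reshape(-1)

    def __getitem__(self, key):
        ph, col = key
        return float(self.proportions[self.phenotypes.index(ph),
                                      self.COLUMNS.index(col)])


def standardize(spec: ModelSpec, theta) -> VarianceDecomposition:
    """Squared-path variance proportions implied by theta (sums to 1)."""
    theta = np.asarray(theta, dtype=float)
    p = spec.p
    out = np.zeros((p, 6))
    factor_shares = None
    if spec.kind == "univariate_ace":
        a, c = theta
        e2 = max(0.0, 1.0 - a * a - c * c)
        out[0] = [0, 0, 0, a * a, c * c, e2]
    elif spec.kind == "bivariate_cholesky":
        a11, a21, a22, c11, c21, c22, e21 = theta
        e11_2 = max(0.0, 1.0 - a11**2 - c11**2)
        e22_2 = max(0.0, 1.0 - a21**2 - a22**2 - c21**2 - c22**2 - e21**2)
        out[0] = [a11**2, c11**2, e11_2, 0, 0, 0]
        out[1] = [a21**2, c21**2, e21**2, a22**2, c22**2, e22_2]
    elif spec.kind == "ipm":
        for ci, comp in enumerate("ace"):
            L = spec._loadings(theta, comp)
            out[:, ci] = (L**2).sum(axis=1)
        sa = spec._specifics(theta, "a")
        sc = spec._specifics(theta, "c")
        out[:, 3] = sa**2
        out[:, 4] = sc**2
        out[:, 5] = np.maximum(0.0, 1.0 - out[:, :5].sum(axis=1))
    elif spec.kind == "cpm":
        aF = theta[spec.structure["aF"]]
        cF = theta[spec.structure["cF"]]
        eF2 = max(0.0, 1.0 - aF**2 - cF**2)
        lam2 = np.array([theta[i] ** 2 for i in spec.structure["lam"]])
        out[:, 0] = lam2 * aF**2
        out[:, 1] = lam2 * cF**2
        out[:, 2] = lam2 * eF2
        sa = spec._specifics(theta, "a")
        sc = spec._specifics(theta, "c")
        out[:, 3] = sa**2
        out[:, 4] = sc**2
        out[:, 5] = np.maximum(0.0, 1.0 - out[:, :5].sum(axis=1))
        factor_shares = (float(aF**2), float(cF**2), float(eF2))
    else:
        raise ValueError(f"standardize undefined for kind {spec.kind!r}")
    # absorb tiny negative rounding into specific e, then renormalize exactly
    out = np.maximum(out, 0.0)
    out /= out.sum(axis=1, keepdims=True)
    return VarianceDecomposition(spec.phenotypes, out, factor_shares)


class FalconerResult(NamedTuple):
    a2: float
    c2: float
    e2: float
    boundary: bool


def falconer_estimates(r_mz: float, r_dz: float) -> FalconerResult:
    """Closed-form univariate decomposition from MZ/DZ correlations.

    a2 = 2(r_mz - r_dz), c2 = 2 r_dz - r_mz, e2 = 1 - r_mz; values are
    reported raw (no truncation) with a boundary flag when any component is
    negative.  Serves as the analytic oracle for the univariate WLS fit.
    """
    if not (-1 <= r_mz <= 1 and -1 <= r_dz <= 1):
        raise ValueError("correlations must lie in [-1, 1]")
    a2 = 2.0 * (r_mz - r_dz)
    c2 = 2.0 * r_dz - r_mz
    e2 = 1.0 - r_mz
    return FalconerResult(a2, c2, e2, bool(min(a2, c2, e2) < 0))
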