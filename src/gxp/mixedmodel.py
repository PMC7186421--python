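"""GREML, reaction-norm and bivariate variance-component models.

Model zoo (V is the phenotypic covariance, A the GRM, D = diag(c) for a
standardized covariate c, I the identity):

* baseline   V = A vg0 + I ve0                                  (2 params)
* gxp        V = A vg0 + DAD vg1 + (AD + DA) cg01 + I ve0       (4 params)
* rxp        V = A vg0 + I ve0 + D^2 ve1 + 2 D ce01             (4 params)
* full       V = gxp genetic part + rxp residual part           (6 params)
* bivariate  per-group genetic (co)variances; cross-population layout fixes
  the residual covariance at 0 (disjoint samples), same-sample layout frees
  it (6 params vs 5)

All fits are unconstrained (variance components may go negative while V
stays positive definite), which is what allows out-of-parameter-space
estimates to surface and be excluded by :func:`check_validity`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .grm import GRMatrix
from .reml import (LinearStructure, REMLFit, ai_reml,
                   bivariate_samesample_spectral, greml_spectral)

__all__ = [
    "RNMComponents",
    "BivariateComponents",
    "FitResult",
    "ValidityCheck",
    "fit_greml",
    "snp_heritability",
    "fit_rnm",
    "check_validity",
    "fit_bivariate_greml",
]

_N_PARAMS = {"baseline": 2, "gxp": 4, "rxp": 4, "full": 6, "bivariate": 5}


@dataclass
class RNMComponents:
    """Variance/covariance estimates of a (reaction-norm) mixed model."""

    var_g0: float
    var_e0: float
    var_g1: float | None = None
    cov_g01: float | None = None
    var_e1: float | None = None
    cov_e01: float | None = None
    scale: dict = field(default_factory=dict)


@dataclass
class BivariateComponents:
    var_g1: float
    var_g2: float
    cov_g12: float
    var_e1: float
    var_e2: float
    cov_e12: float | None = None

    @property
    def rg(self) -> float:
        denom = self.var_g1 * self.var_g2
        if denom <= 0:
            raise ArithmeticError("genetic correlation undefined: a genetic "
                                  "variance estimate is <= 0")
        return self.cov_g12 / np.sqrt(denom)


@dataclass
class FitResult:
    """One REML fit: restricted loglik, estimates, SEs and convergence state."""

    model_tag: str
    loglik: float
    components: object
    se: dict
    converged: bool
    n_params: int
    n_iter: int = 0
    cov_theta: np.ndarray | None = None
    theta: np.ndarray | None = None
    rg: float | None = None
    rg_se: float | None = None


@dataclass
class ValidityCheck:
    valid: bool
    violated: list


def _as_matrix(A) -> np.ndarray:
    return A.values if isinstance(A, GRMatrix) else np.asarray(A, dtype=float)


def _from_reml(tag, fit: REMLFit, names, components, **extra) -> FitResult:
    return FitResult(
        model_tag=tag,
        loglik=fit.loglik,
        components=components,
        se=dict(zip(names, fit.se)),
        converged=fit.converged,
        n_params=len(names),
        n_iter=fit.n_iter,
        cov_theta=fit.cov_theta,
        theta=fit.theta,
        **extra,
    )


def fit_greml(y, A, method: str = "spectral", eig=None, tol: float = 1e-6,
              max_iter: int = 100) -> FitResult:
    """Baseline GREML: V = A sg2 + I se2, REML by average information.

    ``method='spectral'`` solves in the eigenbasis of A (O(n) per iteration
    after one eigendecomposition, which can be passed in via ``eig=(w, U)``);
    ``method='dense'`` runs the generic dense engine.  Both return identical
    restricted log-likelihoods up to numerical tolerance.
    """
    y = np.asarray(y, dtype=float)
    Av = _as_matrix(A)
    n = y.shape[0]
    if Av.shape[0] != n:
        raise ValueError("phenotype length does not match GRM dimension")

    if np.allclose(Av, np.eye(n), atol=1e-10):
        import warnings
        warnings.warn("GRM is (numerically) the identity: genetic and residual "
                      "components are not separately identifiable")

    names = ["var_g0", "var_e0"]
    if method == "spectral":
        if eig is None:
            w, U = linalg.eigh(Av)
        else:
            w, U = eig
        fit = greml_spectral(y, w, U, tol=tol, max_iter=max_iter)
    elif method == "dense":
        struct = LinearStructure([Av, np.eye(n)])
        vy = float(np.var(y, ddof=1))
        fit = ai_reml(y, np.ones((n, 1)), struct, [vy / 2, vy / 2],
                      tol=tol, max_iter=max_iter)
    else:
        raise ValueError(f"unknown method {method!r}")

    comp = RNMComponents(var_g0=float(fit.theta[0]), var_e0=float(fit.theta[1]))
    return _from_reml("baseline", fit, names, comp)


def snp_heritability(fit: FitResult):
    """SNP-heritability h2 = vg / (vg + ve) with a delta-method SE."""
    if fit.model_tag != "baseline":
        raise ValueError("snp_heritability expects a baseline fit")
    vg = fit.components.var_g0
    ve = fit.components.var_e0
    tot = vg + ve
    if tot <= 0:
        raise ArithmeticError("total variance estimate <= 0; h2 undefined")
    h2 = vg / tot
    grad = np.array([ve, -vg]) / tot ** 2
    var = float(grad @ fit.cov_theta[:2, :2] @ grad)
    return h2, float(np.sqrt(max(var, 0.0)))


def _rnm_structure(Av, c, mode):
    n = Av.shape[0]
    I = np.eye(n)
    ccT = np.outer(c, c)
    c1T = c[:, None] + c[None, :]        # c 1' + 1 c'
    genetic = [Av, Av * ccT, Av * c1T]
    residual = [I, np.diag(c ** 2), 2.0 * np.diag(c)]
    if mode == "gxp":
        return genetic + [I], ["var_g0", "var_g1", "cov_g01", "var_e0"]
    if mode == "rxp":
        return [Av] + residual, ["var_g0", "var_e0", "var_e1", "cov_e01"]
    if mode == "full":
        return genetic + residual, ["var_g0", "var_g1", "cov_g01",
                                    "var_e0", "var_e1", "cov_e01"]
    raise ValueError(f"unknown RNM mode {mode!r}")


def fit_rnm(y, A, c, mode: str = "gxp", tol: float = 1e-6, max_iter: int = 100,
            allow_degenerate_covariate: bool = False) -> FitResult:
    """Reaction-norm model fit (gxp, rxp or full) by AI-REML."""
    y = np.asarray(y, dtype=float)
    c = np.asarray(c, dtype=float)
    Av = _as_matrix(A)
    n = y.shape[0]
    if c.shape[0] != n or Av.shape[0] != n:
        raise ValueError("y, c and A dimensions must agree")
    if np.std(c) == 0 and not allow_degenerate_covariate:
        raise ValueError("covariate c is constant; the reaction-norm slope is "
                         "not identifiable")

    mats, names = _rnm_structure(Av, c, mode)
    struct = LinearStructure(mats)
    vy = float(np.var(y, ddof=1))
    theta0 = np.zeros(len(mats))
    theta0[names.index("var_g0")] = vy / 2
    theta0[names.index("var_e0")] = vy / 2
    fit = ai_reml(y, np.ones((n, 1)), struct, theta0, tol=tol, max_iter=max_iter)

    vals = dict(zip(names, (float(t) for t in fit.theta)))
    comp = RNMComponents(
        var_g0=vals["var_g0"],
        var_e0=vals["var_e0"],
        var_g1=vals.get("var_g1"),
        cov_g01=vals.get("cov_g01"),
        var_e1=vals.get("var_e1"),
        cov_e01=vals.get("cov_e01"),
        scale={"c_mean": float(c.mean()), "c_sd": float(c.std())},
    )
    return _from_reml(mode, fit, names, comp)


def check_validity(comp: RNMComponents) -> ValidityCheck:
    """Check reaction-norm estimates against the valid parameter space.

    Criteria: (1) var(g0) >= 0; (2) var(g1) >= 0;
    (3) |cov(g0, g1)| <= sqrt(var(g0) var(g1)).
    Criterion 3 is evaluated only when both variances are non-negative.
    """
    violated = []
    if comp.var_g0 < 0:
        violated.append(1)
    if comp.var_g1 is None:
        raise ValueError("check_validity needs a gxp/full fit with var_g1")
    if comp.var_g1 < 0:
        violated.append(2)
    if not violated:
        bound = np.sqrt(comp.var_g0 * comp.var_g1)
        cov = comp.cov_g01 if comp.cov_g01 is not None else 0.0
        if not (-bound <= cov <= bound):
            violated.append(3)
    return ValidityCheck(valid=not violated, violated=violated)


class _RgOneStructure:
    """V(a1, a2, e1, e2) = A o (q q') + diag residuals, q_i = a_{group(i)}.

    This is the bivariate cross-population model constrained to genetic
    correlation 1 (the heterogeneity-test null); nonlinear in (a1, a2).
    """

    n_params = 4

    def __init__(self, Av, d1, d2):
        self.A = Av
        self.d1 = d1
        self.d2 = d2

    def build(self, theta):
        a1, a2, e1, e2 = theta
        q = a1 * self.d1 + a2 * self.d2
        qq = np.outer(q, q)
        V = self.A * qq + np.diag(e1 * self.d1 + e2 * self.d2)
        dq1 = np.outer(self.d1, q)
        dq2 = np.outer(self.d2, q)
        dVs = [
            self.A * (dq1 + dq1.T),
            self.A * (dq2 + dq2.T),
            np.diag(self.d1),
            np.diag(self.d2),
        ]
        return V, dVs


def _attach_rg(res: FitResult, fit: REMLFit, names) -> FitResult:
    """Genetic correlation and its delta-method SE from a bivariate fit."""
    vg1 = res.components.var_g1
    vg2 = res.components.var_g2
    cg = res.components.cov_g12
    if vg1 > 0 and vg2 > 0:
        rg = cg / np.sqrt(vg1 * vg2)
        grad = np.zeros(len(names))
        grad[names.index("var_g1")] = -0.5 * rg / vg1
        grad[names.index("var_g2")] = -0.5 * rg / vg2
        grad[names.index("cov_g12")] = 1.0 / np.sqrt(vg1 * vg2)
        res.rg = float(rg)
        res.rg_se = float(np.sqrt(max(float(grad @ fit.cov_theta @ grad), 0.0)))
    return res


def fit_bivariate_greml(y1, y2, A, idx1=None, idx2=None,
                        layout: str = "cross_population",
                        constrain_rg_one: bool = False, eig=None,
                        tol: float = 1e-6, max_iter: int = 100) -> FitResult:
    """Bivariate GREML for two trait vectors sharing one GRM.

    ``cross_population``: y1 and y2 are the same trait measured on disjoint
    index sets of the GRM (two populations); the residual covariance is
    structurally 0.  ``same_sample``: two traits on identical individuals
    (``idx1``/``idx2`` default to everyone); the residual covariance is free.

    ``constrain_rg_one`` fits the genetic-correlation-1 null instead
    (cross-population layout only), for the heterogeneity LRT.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    Av = _as_matrix(A)
    n_all = Av.shape[0]

    if layout == "cross_population":
        if idx1 is None or idx2 is None:
            raise ValueError("cross_population layout needs idx1 and idx2")
        idx1 = np.asarray(idx1)
        idx2 = np.asarray(idx2)
        if np.intersect1d(idx1, idx2).size:
            raise ValueError("cross_population index sets must be disjoint")
    elif layout == "same_sample":
        if idx1 is None:
            idx1 = np.arange(n_all)
        idx2 = idx1 if idx2 is None else np.asarray(idx2)
        if not np.array_equal(idx1, idx2):
            raise ValueError("same_sample layout needs identical index sets")
    else:
        raise ValueError(f"unknown layout {layout!r}")

    n1, n2 = len(idx1), len(idx2)
    if y1.shape[0] != n1 or y2.shape[0] != n2:
        raise ValueError("trait lengths must match their index sets")

    if layout == "same_sample" and not constrain_rg_one and n1 == n_all:
        # spectral fast path: 2x2 blocks in the eigenbasis of A
        if eig is None:
            eig = linalg.eigh(Av)
        w, U = eig
        fit = bivariate_samesample_spectral(y1, y2, w, U, tol=tol,
                                            max_iter=max_iter)
        names = ["var_g1", "var_g2", "cov_g12", "var_e1", "var_e2", "cov_e12"]
        vals = dict(zip(names, (float(t) for t in fit.theta)))
        comp = BivariateComponents(**vals)
        res = _from_reml("bivariate", fit, names, comp)
        return _attach_rg(res, fit, names)
    y = np.concatenate([y1, y2])
    d1 = np.concatenate([np.ones(n1), np.zeros(n2)])
    d2 = 1.0 - d1
    X = np.column_stack([d1, d2])

    if layout == "cross_population":
        order = np.concatenate([idx1, idx2])
        Asub = Av[np.ix_(order, order)]
    else:
        # the same GRM underlies every 2x2 block of the stacked covariance
        Asub = np.block([[Av, Av], [Av, Av]])

    v1 = float(np.var(y1, ddof=1))
    v2 = float(np.var(y2, ddof=1))

    if constrain_rg_one:
        if layout != "cross_population":
            raise ValueError("rg=1 constraint implemented for the "
                             "cross_population layout")
        struct = _RgOneStructure(Asub, d1, d2)
        theta0 = np.array([np.sqrt(v1 / 2), np.sqrt(v2 / 2), v1 / 2, v2 / 2])
        fit = ai_reml(y, X, struct, theta0, tol=tol, max_iter=max_iter, n_em=0)
        a1, a2, e1, e2 = fit.theta
        comp = BivariateComponents(var_g1=float(a1 ** 2), var_g2=float(a2 ** 2),
                                   cov_g12=float(a1 * a2), var_e1=float(e1),
                                   var_e2=float(e2))
        names = ["a1", "a2", "var_e1", "var_e2"]
        res = _from_reml("bivariate_rg1", fit, names, comp)
        res.rg = 1.0 if a1 * a2 >= 0 else -1.0
        return res

    D11 = np.outer(d1, d1)
    D22 = np.outer(d2, d2)
    D12 = np.outer(d1, d2)
    mats = [Asub * D11, Asub * D22, Asub * (D12 + D12.T),
            np.diag(d1), np.diag(d2)]
    names = ["var_g1", "var_g2", "cov_g12", "var_e1", "var_e2"]
    theta0 = [v1 / 2, v2 / 2, 0.25 * np.sqrt(v1 * v2), v1 / 2, v2 / 2]
    if layout == "same_sample":
        # residual covariance only acts between the paired copies
        R12 = np.zeros((n1 + n2, n1 + n2))
        R12[np.arange(n1), n1 + np.arange(n2)] = 1.0
        mats.append(R12 + R12.T)
        names.append("cov_e12")
        c12 = float(np.cov(y1, y2)[0, 1])
        theta0.append(c12 / 2)

    struct = LinearStructure(mats)
    theta0 = np.asarray(theta0, dtype=float)
    cov_idx = [names.index(nm) for nm in ("cov_g12", "cov_e12") if nm in names]
    fit = None
    for _ in range(8):
        try:
            fit = ai_reml(y, X, struct, theta0, tol=tol, max_iter=max_iter,
                          n_em=2)
            break
        except ValueError:
            # shrink covariance starts toward 0 until V is positive definite
            theta0[cov_idx] *= 0.5
    if fit is None:
        theta0[cov_idx] = 0.0
        fit = ai_reml(y, X, struct, theta0, tol=tol, max_iter=max_iter, n_em=2)

    vals = dict(zip(names, (float(t) for t in fit.theta)))
    comp = BivariateComponents(var_g1=vals["var_g1"], var_g2=vals["var_g2"],
                               cov_g12=vals["cov_g12"], var_e1=vals["var_e1"],
                               var_e2=vals["var_e2"],
                               cov_e12=vals.get("cov_e12"))
    res = _from_reml("bivariate", fit, names, comp)
    return _attach_rg(res, fit, names)
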