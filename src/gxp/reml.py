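"""Average-information REML for linear covariance structures.

The restricted likelihood of y ~ N(Xb, V(theta)) is maximized over theta,
where V(theta) = sum_k theta_k * M_k for a list of symmetric matrices M_k
(the :class:`LinearStructure` case), or any differentiable V(theta) supplied
through a structure object exposing ``build(theta) -> (V, [dV_k])``.

Algorithm: a few EM warm-up iterations (linear structures only) followed by
average-information (AI) updates with step-halving, so the restricted
log-likelihood trajectory is monotone non-decreasing.  Estimation is
unconstrained — variance components are allowed to go negative as long as V
stays positive definite — which is what makes out-of-parameter-space
estimates observable downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg


@dataclass
class REMLFit:
    """Converged (or flagged) state of one REML maximization."""

    theta: np.ndarray
    loglik: float
    se: np.ndarray
    ai: np.ndarray          # average-information matrix at the optimum
    converged: bool
    n_iter: int
    message: str = ""
    history: list = field(default_factory=list)

    @property
    def cov_theta(self) -> np.ndarray:
        """Asymptotic covariance of theta (inverse AI, pseudo-inverse if singular)."""
        return np.linalg.pinv(self.ai)


class LinearStructure:
    """V(theta) = sum_k theta_k M_k with fixed symmetric matrices M_k."""

    def __init__(self, mats):
        self.mats = [np.asarray(M, dtype=float) for M in mats]
        self.n_params = len(self.mats)

    def build(self, theta):
        V = np.zeros_like(self.mats[0])
        for t, M in zip(theta, self.mats):
            V += t * M
        return V, self.mats


def reml_loglik_dense(y, X, V):
    """Brute-force restricted log-likelihood via explicit inverse and determinants.

    Used both internally and as the independent oracle in tests; kept free of
    any factorization shortcuts on purpose.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    s1, ld_V = np.linalg.slogdet(V)
    s2, ld_X = np.linalg.slogdet(XtViX)
    if s1 <= 0 or s2 <= 0:
        return -np.inf
    return -0.5 * (ld_V + ld_X + y @ P @ y + (n - p) * np.log(2 * np.pi))


def _reml_state(y, X, V):
    """Factorize V and return loglik plus the pieces AI-REML reuses.

    Returns None when V (or X'V^-1 X) is not positive definite, which the
    step-halving loop treats as a rejected step.
    """
    n, p = X.shape
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return None
    ld_V = 2.0 * np.sum(np.log(np.diag(c)))
    ViY = linalg.cho_solve((c, low), y, check_finite=False)
    ViX = linalg.cho_solve((c, low), X, check_finite=False)
    XtViX = X.T @ ViX
    try:
        cx = linalg.cho_factor(XtViX, check_finite=False)
    except linalg.LinAlgError:
        return None
    ld_X = 2.0 * np.sum(np.log(np.diag(cx[0])))
    XtViY = X.T @ ViY
    beta = linalg.cho_solve(cx, XtViY, check_finite=False)
    Py = ViY - ViX @ beta
    yPy = float(y @ Py)
    ll = -0.5 * (ld_V + ld_X + yPy + (n - p) * np.log(2 * np.pi))
    return {"chol": (c, low), "cx": cx, "ViX": ViX, "Py": Py, "ll": ll}


def _trace_P_dV(state, X, dVs):
    """tr(P dV_k) for each k, via the explicit V^-1 (one O(n^3) inversion)."""
    c, low = state["chol"]
    n = X.shape[0]
    Vi = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    ViX = state["ViX"]
    cx = state["cx"]
    traces = np.empty(len(dVs))
    for k, M in enumerate(dVs):
        t1 = float(np.sum(Vi * M))
        W = M @ ViX                      # n x p
        # tr((X'ViX)^-1 X'Vi M Vi X)
        t2 = float(np.trace(linalg.cho_solve(cx, ViX.T @ W, check_finite=False)))
        traces[k] = t1 - t2
    return traces


def _project(state, X, T):
    """P @ T for a stack of column vectors T (n x k)."""
    c, low = state["chol"]
    ViT = linalg.cho_solve((c, low), T, check_finite=False)
    cx = state["cx"]
    ViX = state["ViX"]
    return ViT - ViX @ linalg.cho_solve(cx, ViX.T @ T, check_finite=False)


class IIDTail:
    """Orthogonal-complement block with iid residual variance theta[idx].

    When the data, fixed effects and all structure matrices live in an
    M-dimensional subspace, the remaining ``nu`` dimensions contribute only
    -nu/2 * log theta to the restricted log-likelihood and nu/theta to
    tr(P dV) for the residual parameter — the reduction is exact.
    """

    def __init__(self, idx: int, nu: int):
        self.idx = idx
        self.nu = nu

    def ok(self, theta) -> bool:
        return theta[self.idx] > 0

    def loglik(self, theta) -> float:
        return -0.5 * self.nu * (np.log(theta[self.idx]) + np.log(2 * np.pi))

    def trace_add(self, theta, traces) -> None:
        traces[self.idx] += self.nu / theta[self.idx]


class PairedTail:
    """Complement block for two stacked traits with residual covariance.

    Each of the ``nu`` complement coordinates appears once per trait copy
    with 2x2 residual covariance K = [[t_i1, t_i12], [t_i12, t_i2]].
    """

    def __init__(self, i1: int, i2: int, i12: int, nu: int):
        self.i1, self.i2, self.i12 = i1, i2, i12
        self.nu = nu

    def _K(self, theta):
        return np.array([[theta[self.i1], theta[self.i12]],
                         [theta[self.i12], theta[self.i2]]])

    def ok(self, theta) -> bool:
        K = self._K(theta)
        return K[0, 0] > 0 and np.linalg.det(K) > 0

    def loglik(self, theta) -> float:
        sign, ld = np.linalg.slogdet(self._K(theta))
        return -0.5 * self.nu * (ld + 2 * np.log(2 * np.pi))

    def trace_add(self, theta, traces) -> None:
        Ki = np.linalg.inv(self._K(theta))
        traces[self.i1] += self.nu * Ki[0, 0]
        traces[self.i2] += self.nu * Ki[1, 1]
        traces[self.i12] += 2.0 * self.nu * Ki[0, 1]


def ai_reml(
    y,
    X,
    structure,
    theta0,
    max_iter: int = 100,
    tol: float = 1e-6,
    n_em: int = 3,
    max_halvings: int = 30,
    tails=(),
) -> REMLFit:
    """Maximize the restricted likelihood by EM warm-up + AI with step-halving.

    Parameters
    ----------
    y, X
        Response vector and fixed-effect design (an intercept column must be
        included by the caller).
    structure
        Object with ``n_params`` and ``build(theta) -> (V, [dV_k])``.
    theta0
        Starting values; must yield a positive-definite V.
    n_em
        Number of EM warm-up iterations (skipped for non-linear structures).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        X = X.T
    n = y.shape[0]
    theta = np.asarray(theta0, dtype=float).copy()
    K = structure.n_params
    if theta.shape[0] != K:
        raise ValueError(f"theta0 has {theta.shape[0]} entries, structure expects {K}")

    is_linear = isinstance(structure, LinearStructure)

    def tails_ok(th):
        return all(t.ok(th) for t in tails)

    def tail_ll(th):
        return sum(t.loglik(th) for t in tails)

    n_tot = n + sum((2 if isinstance(t, PairedTail) else 1) * t.nu
                    for t in tails)

    V, dVs = structure.build(theta)
    state = _reml_state(y, X, V) if tails_ok(theta) else None
    if state is None:
        raise ValueError("starting values give a non-positive-definite V")
    cur_ll = state["ll"] + tail_ll(theta)

    history = [cur_ll]
    converged = False
    message = "max iterations reached"
    ai = np.eye(K)
    n_iter = 0

    for it in range(max_iter):
        n_iter = it + 1
        Py = state["Py"]
        traces = _trace_P_dV(state, X, dVs)
        for t in tails:
            t.trace_add(theta, traces)
        T = np.column_stack([M @ Py for M in dVs])        # n x K
        PT = _project(state, X, T)
        quad = T.T @ Py                                   # y'P dV_k P y
        score = 0.5 * (quad - traces)
        ai = 0.5 * (T.T @ PT)
        ai = 0.5 * (ai + ai.T)

        if it < n_em and is_linear:
            # generalized EM step: theta_k += theta_k^2 (y'P M_k P y - tr(P M_k)) / n
            delta = (theta ** 2) * (quad - traces) / n_tot
        else:
            try:
                delta = np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(ai, score, rcond=None)[0]
            if not np.all(np.isfinite(delta)):
                delta = np.linalg.lstsq(ai, score, rcond=None)[0]

        # cap runaway steps from a near-singular AI matrix
        cap = 1e3 * (1.0 + float(np.linalg.norm(theta)))
        dn = float(np.linalg.norm(delta))
        if dn > cap:
            delta = delta * (cap / dn)

        # step-halving: accept the first step that does not decrease loglik;
        # if the AI direction fails entirely (near-singular AI), fall back to
        # a unit gradient step before giving up
        accepted = False
        grad_dir = score / max(np.linalg.norm(score), 1e-12)
        grad_dir = grad_dir * (1.0 + float(np.linalg.norm(theta)))
        for direction in (delta, grad_dir):
            step = 1.0
            for _ in range(max_halvings):
                cand = theta + step * direction
                if not tails_ok(cand):
                    step *= 0.5
                    continue
                Vc, dVc = structure.build(cand)
                st = _reml_state(y, X, Vc)
                if st is not None and np.isfinite(st["ll"]):
                    cand_ll = st["ll"] + tail_ll(cand)
                    if cand_ll >= cur_ll + 1e-12:
                        theta, state, dVs = cand, st, dVc
                        cur_ll = cand_ll
                        accepted = True
                        break
                step *= 0.5
            if accepted:
                break
        if not accepted:
            converged = True
            message = "no ascent step found (treated as converged)"
            break

        history.append(cur_ll)
        if abs(history[-1] - history[-2]) < tol and it >= n_em:
            converged = True
            message = "loglik change below tolerance"
            break

    # final AI at the accepted theta for standard errors
    Py = state["Py"]
    T = np.column_stack([M @ Py for M in dVs])
    PT = _project(state, X, T)
    ai = 0.5 * (T.T @ PT)
    ai = 0.5 * (ai + ai.T)
    cov = np.linalg.pinv(ai)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    return REMLFit(
        theta=theta,
        loglik=float(cur_ll),
        se=se,
        ai=ai,
        converged=converged,
        n_iter=n_iter,
        message=message,
        history=history,
    )


# ---------------------------------------------------------------------------
# spectral (eigen-rotated) solvers for models diagonalized by the GRM basis
# ---------------------------------------------------------------------------


def greml_spectral(y, eigvals, U, tol: float = 1e-6, max_iter: int = 100,
                   n_em: int = 3) -> REMLFit:
    """Baseline GREML (V = A sg2 + I se2) in the eigenbasis of A.

    After rotating by the eigenvectors U of A, V is diagonal with entries
    w_i sg2 + se2, so every REML iteration is O(n).  The returned restricted
    log-likelihood is identical to the dense parameterization (orthogonal
    rotations preserve it).
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    yt = U.T @ y
    Xt = U.T @ np.ones(n)
    w = np.asarray(eigvals, dtype=float)

    vy = float(np.var(y, ddof=1))
    theta = np.array([vy / 2.0, vy / 2.0])

    def state_at(th):
        d = w * th[0] + th[1]
        if np.any(d <= 0):
            return None
        ld_V = float(np.sum(np.log(d)))
        ViY = yt / d
        ViX = Xt / d
        xvx = float(Xt @ ViX)
        if xvx <= 0:
            return None
        beta = (Xt @ ViY) / xvx
        Py = ViY - ViX * beta
        yPy = float(yt @ Py)
        ll = -0.5 * (ld_V + np.log(xvx) + yPy + (n - 1) * np.log(2 * np.pi))
        return d, Py, ViX, xvx, ll

    st = state_at(theta)
    if st is None:
        theta = np.array([vy * 0.1, vy * 0.9])
        st = state_at(theta)
    d, Py, ViX, xvx, ll = st
    history = [ll]
    converged = False
    n_iter = 0
    ai = np.eye(2)

    mats = [w, np.ones(n)]  # diagonals of A and I in the rotated basis

    def project(t):
        return t / d - ViX * (float(Xt @ (t / d)) / xvx)

    for it in range(max_iter):
        n_iter = it + 1
        traces = np.array([float(np.sum(m / d)) - float((ViX * m) @ ViX) / xvx
                           for m in mats])
        T = np.column_stack([m * Py for m in mats])
        PT = np.column_stack([project(T[:, k]) for k in range(2)])
        quad = T.T @ Py
        score = 0.5 * (quad - traces)
        ai = 0.5 * (T.T @ PT)
        ai = 0.5 * (ai + ai.T)

        if it < n_em:
            delta = (theta ** 2) * (quad - traces) / n
        else:
            try:
                delta = np.linalg.solve(ai, score)
            except np.linalg.LinAlgError:
                delta = np.linalg.lstsq(ai, score, rcond=None)[0]

        accepted = False
        step = 1.0
        for _ in range(30):
            cand = theta + step * delta
            stc = state_at(cand)
            if stc is not None and stc[4] >= ll - 1e-10:
                theta = cand
                d, Py, ViX, xvx, ll = stc
                accepted = True
                break
            step *= 0.5
        if not accepted:
            converged = True
            break
        history.append(ll)
        if abs(history[-1] - history[-2]) < tol and it >= n_em:
            converged = True
            break

    traces = np.array([float(np.sum(m / d)) - float((ViX * m) @ ViX) / xvx
                       for m in mats])
    T = np.column_stack([m * Py for m in mats])
    PT = np.column_stack([project(T[:, k]) for k in range(2)])
    ai = 0.5 * (T.T @ PT)
    ai = 0.5 * (ai + ai.T)
    cov = np.linalg.pinv(ai)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return REMLFit(theta=theta, loglik=float(ll), se=se, ai=ai,
                   converged=converged, n_iter=n_iter, history=history)


def loglik_iid_null(y) -> float:
    """Restricted loglik of the sigma_g^2 = 0 model (V = I se2), closed form."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    ss = float(np.sum((y - y.mean()) ** 2))
    se2 = ss / (n - 1)
    return -0.5 * (n * np.log(se2) + np.log(n / se2) + ss / se2
                   + (n - 1) * np.log(2 * np.pi))


def bivariate_samesample_spectral(y1, y2, eigvals, U, theta0=None,
                                  tol: float = 1e-6, max_iter: int = 100,
                                  max_halvings: int = 30) -> REMLFit:
    """Same-sample bivariate REML in the eigenbasis of the GRM.

    Rotating both trait copies by the eigenvectors U of A turns the stacked
    2n x 2n covariance into n independent 2x2 blocks
    Sigma_i = w_i K_g + K_e, where K_g and K_e are the 2x2 genetic and
    residual (co)variance matrices.  Every iteration is O(n) with
    vectorized 2x2 algebra.  Parameter order:
    (vg1, vg2, cg12, ve1, ve2, ce12).
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n = y1.shape[0]
    w = np.asarray(eigvals, dtype=float)
    Y = np.column_stack([U.T @ y1, U.T @ y2])          # n x 2
    xt = U.T @ np.ones(n)                              # rotated intercept

    E = np.zeros((3, 2, 2))
    E[0, 0, 0] = 1.0
    E[1, 1, 1] = 1.0
    E[2, 0, 1] = E[2, 1, 0] = 1.0

    def sigma(theta):
        Kg = theta[0] * E[0] + theta[1] * E[1] + theta[2] * E[2]
        Ke = theta[3] * E[0] + theta[4] * E[1] + theta[5] * E[2]
        return w[:, None, None] * Kg + Ke              # n x 2 x 2

    def state_at(theta):
        S = sigma(theta)
        det = S[:, 0, 0] * S[:, 1, 1] - S[:, 0, 1] ** 2
        if np.any(det <= 0) or np.any(S[:, 0, 0] <= 0):
            return None
        Si = np.empty_like(S)
        Si[:, 0, 0] = S[:, 1, 1] / det
        Si[:, 1, 1] = S[:, 0, 0] / det
        Si[:, 0, 1] = Si[:, 1, 0] = -S[:, 0, 1] / det
        ld = float(np.sum(np.log(det)))
        ViY = np.einsum("nij,nj->ni", Si, Y)
        XtViX = np.einsum("n,nij->ij", xt ** 2, Si)
        XtViY = np.einsum("n,nij,nj->i", xt, Si, Y)
        try:
            C = np.linalg.inv(XtViX)
        except np.linalg.LinAlgError:
            return None
        s2, ldx = np.linalg.slogdet(XtViX)
        if s2 <= 0:
            return None
        b = C @ XtViY
        Py = np.einsum("nij,nj->ni", Si, Y - xt[:, None] * b)
        yPy = float(np.sum(Y * Py))
        ll = -0.5 * (ld + ldx + yPy + (2 * n - 2) * np.log(2 * np.pi))
        return {"Si": Si, "Py": Py, "C": C, "ll": ll}

    def project(st, T):
        Si = st["Si"]
        ViT = np.einsum("nij,nj->ni", Si, T)
        XtViT = np.einsum("n,ni->i", xt, ViT)
        return ViT - xt[:, None] * np.einsum("nij,j->ni", Si,
                                             st["C"] @ XtViT)

    if theta0 is None:
        v1 = float(np.var(y1, ddof=1))
        v2 = float(np.var(y2, ddof=1))
        c12 = float(np.cov(y1, y2)[0, 1])
        theta0 = np.array([v1 / 2, v2 / 2, c12 / 4, v1 / 2, v2 / 2, c12 / 4])
    theta = np.asarray(theta0, dtype=float).copy()
    st = state_at(theta)
    for _ in range(10):
        if st is not None:
            break
        theta[[2, 5]] *= 0.5
        st = state_at(theta)
    if st is None:
        raise ValueError("no positive-definite starting point found")

    history = [st["ll"]]
    converged = False
    n_iter = 0
    ai = np.eye(6)
    scale = np.concatenate([w[:, None] * np.ones((1, 3)),
                            np.ones((n, 3))], axis=1)   # n x 6 multipliers

    for it in range(max_iter):
        n_iter = it + 1
        Si, Py, C = st["Si"], st["Py"], st["C"]
        # traces and quadratic forms per parameter
        traces = np.empty(6)
        quad = np.empty(6)
        Ts = []
        SiX2 = xt[:, None, None] ** 2 * Si
        for k in range(6):
            Ek = E[k % 3]
            mult = scale[:, k]
            t1 = float(np.sum(mult * np.einsum("nij,ij->n", Si, Ek)))
            M_SiX = np.einsum("ij,njk->nik", Ek, Si)    # Ek Si
            inner = np.einsum("n,nij->ij", mult * xt ** 2,
                              np.einsum("nij,jk,nkl->nil", Si, Ek, Si))
            t2 = float(np.trace(C @ inner))
            traces[k] = t1 - t2
            Tk = mult[:, None] * np.einsum("ij,nj->ni", Ek, Py)
            Ts.append(Tk)
            quad[k] = float(np.sum(Py * Tk))
        score = 0.5 * (quad - traces)
        PT = [project(st, Tk) for Tk in Ts]
        ai = 0.5 * np.array([[float(np.sum(Ts[k] * PT[l])) for l in range(6)]
                             for k in range(6)])
        ai = 0.5 * (ai + ai.T)
        try:
            delta = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            delta = np.linalg.lstsq(ai, score, rcond=None)[0]
        cap = 1e3 * (1.0 + float(np.linalg.norm(theta)))
        dn = float(np.linalg.norm(delta))
        if dn > cap:
            delta *= cap / dn
        grad_dir = score / max(np.linalg.norm(score), 1e-12)
        grad_dir *= 1.0 + float(np.linalg.norm(theta))

        accepted = False
        for direction in (delta, grad_dir):
            step = 1.0
            for _ in range(max_halvings):
                cand = theta + step * direction
                stc = state_at(cand)
                if stc is not None and stc["ll"] >= st["ll"] + 1e-12:
                    theta, st = cand, stc
                    accepted = True
                    break
                step *= 0.5
            if accepted:
                break
        if not accepted:
            converged = True
            break
        history.append(st["ll"])
        if abs(history[-1] - history[-2]) < tol:
            converged = True
            break

    cov = np.linalg.pinv(ai)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return REMLFit(theta=theta, loglik=float(st["ll"]), se=se, ai=ai,
                   converged=converged, n_iter=n_iter, history=history)
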