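"""Profiled (RE)ML for the crossed random-effects linear mixed model.

The analysis model is

    y = X beta + Z_f b + Z_i u + e,
    b ~ N(0, s2_f I)                  (feeder intercepts, crossed)
    u_j = (u0_j, u1_j) ~ N(0, Psi)    (per-individual intercept and
                                       concentration slope, correlated)
    e ~ N(0, s2 I)

General mixed-model software either cannot express a correlated
intercept+slope crossed with a second grouping factor or pays a large
per-iteration cost for it, so this module implements the standard
profiled deviance directly.  Random-effect covariances are parameterized
relative to the residual variance through a scaled Cholesky factor
``Lambda(theta)`` (G = s2 * Lambda Lambda'), beta and s2 are profiled
out in closed form, and every objective evaluation reduces to dense
linear algebra on the q x q system ``A = I + Lambda' Z'Z Lambda`` with
q = n_feeders + 2 * n_individuals via the Woodbury identity — so the
cost per evaluation is independent of the number of observations once
the cross-products are accumulated.

Only the structure needed by the analysis is supported; this is a
purpose-built engine, not a general formula interface.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.optimize as sopt
import scipy.sparse as sp

_LOG2PI = np.log(2.0 * np.pi)


@dataclasses.dataclass
class LMMResult:
    """A fitted mixed model.

    ``loglik`` is the maximized log-likelihood under the requested
    criterion (ML deviance/-2 for ``method="ML"``, REML criterion
    otherwise).  ``vparams`` holds the variance components on the
    response scale: ``var_feeder``, ``var_ind_intercept``,
    ``var_ind_slope``, ``cov_ind`` (absent for the intercept-only
    structure) and ``var_residual``.  ``blups`` are the conditional
    modes of the random effects.
    """
    method: str
    coefficients: pd.Series
    se: pd.Series
    cov_fixed: pd.DataFrame
    loglik: float
    n: int
    n_fixed: int
    n_vparams: int
    vparams: dict[str, float]
    blups: pd.DataFrame
    converged: bool
    singular: bool
    random_slope: bool

    @property
    def k_params(self) -> int:
        """Parameter count for information criteria (marginal AIC):
        fixed effects + random-effect (co)variances + residual variance."""
        return self.n_fixed + self.n_vparams + 1


def _build_z(feeder_codes: np.ndarray, ind_codes: np.ndarray,
             conc: np.ndarray, random_slope: bool) -> tuple[sp.csr_matrix,
                                                            int, int]:
    n = len(feeder_codes)
    nf = int(feeder_codes.max()) + 1
    ni = int(ind_codes.max()) + 1
    rows = np.arange(n)
    if random_slope:
        cols = np.concatenate([feeder_codes,
                               nf + 2 * ind_codes,
                               nf + 2 * ind_codes + 1])
        data = np.concatenate([np.ones(n), np.ones(n), conc])
        rows3 = np.concatenate([rows, rows, rows])
        q = nf + 2 * ni
        Z = sp.csr_matrix((data, (rows3, cols)), shape=(n, q))
    else:
        cols = np.concatenate([feeder_codes, nf + ind_codes])
        data = np.ones(2 * n)
        rows2 = np.concatenate([rows, rows])
        q = nf + ni
        Z = sp.csr_matrix((data, (rows2, cols)), shape=(n, q))
    return Z, nf, ni


def _lambda_matrix(theta: np.ndarray, nf: int, ni: int,
                   random_slope: bool) -> sp.csr_matrix:
    """Relative covariance factor: blockdiag(s_f I_nf, I_ni x L)."""
    if random_slope:
        s_f, l11, l21, l22 = theta
        blocks = [s_f * sp.identity(nf, format="csr")]
        L = sp.csr_matrix(np.array([[l11, 0.0], [l21, l22]]))
        blocks.append(sp.kron(sp.identity(ni, format="csr"), L,
                              format="csr"))
    else:
        s_f, s_i = theta
        blocks = [s_f * sp.identity(nf, format="csr"),
                  s_i * sp.identity(ni, format="csr")]
    return sp.block_diag(blocks, format="csr")


class _Profile:
    """Precomputed cross-products and the profiled deviance."""

    def __init__(self, y, X, Z, nf, ni, random_slope):
        self.n, self.p = X.shape
        self.nf, self.ni = nf, ni
        self.random_slope = random_slope
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.ZtX = np.asarray((Z.T @ X))
        self.Zty = np.asarray(Z.T @ y).ravel()
        self.ZtZ = np.asarray((Z.T @ Z).todense())
        self.q = Z.shape[1]

    def _core(self, theta):
        Lam = _lambda_matrix(theta, self.nf, self.ni, self.random_slope)
        LtZtZL = np.asarray((Lam.T @ sp.csr_matrix(self.ZtZ) @ Lam).todense())
        A = LtZtZL + np.eye(self.q)
        cf = sla.cho_factor(A, lower=True, check_finite=False)
        logdetA = 2.0 * np.sum(np.log(np.diag(cf[0])))
        LtZtX = np.asarray(Lam.T @ self.ZtX)
        LtZty = np.asarray(Lam.T @ self.Zty).ravel()
        AinvC = sla.cho_solve(cf, np.column_stack([LtZtX, LtZty]),
                              check_finite=False)
        Ainv_LtZtX, Ainv_LtZty = AinvC[:, :-1], AinvC[:, -1]
        XtWX = self.XtX - LtZtX.T @ Ainv_LtZtX
        XtWy = self.Xty - LtZtX.T @ Ainv_LtZty
        ytWy = self.yty - LtZty @ Ainv_LtZty
        beta = sla.solve(XtWX, XtWy, assume_a="pos")
        rWr = max(ytWy - beta @ XtWy, 1e-12)
        return Lam, cf, logdetA, XtWX, beta, rWr, LtZtX, LtZty

    def deviance(self, theta, reml):
        try:
            with warnings.catch_warnings():
                # extreme search points can be near-singular; they are
                # rejected by the penalty below, not worth a warning
                warnings.simplefilter("ignore", sla.LinAlgWarning)
                _, _, logdetA, XtWX, _, rWr, _, _ = self._core(theta)
        except (np.linalg.LinAlgError, ValueError):
            return 1e10
        n, p = self.n, self.p
        if reml:
            sign, logdetXtWX = np.linalg.slogdet(XtWX)
            if sign <= 0:
                return 1e10
            df = n - p
            return (logdetA + logdetXtWX
                    + df * (1.0 + _LOG2PI + np.log(rWr / df)))
        return logdetA + n * (1.0 + _LOG2PI + np.log(rWr / n))

    def finish(self, theta, reml):
        Lam, cf, logdetA, XtWX, beta, rWr, LtZtX, LtZty = self._core(theta)
        n, p = self.n, self.p
        df = (n - p) if reml else n
        s2 = rWr / df
        cov_beta = s2 * sla.inv(XtWX)
        # Conditional modes: u_tilde = Lambda A^{-1} Lambda' Z' (y - X beta)
        resid_proj = LtZty - LtZtX @ beta
        u = Lam @ sla.cho_solve(cf, resid_proj, check_finite=False)
        loglik = -0.5 * self.deviance(theta, reml)
        return beta, cov_beta, s2, u, loglik


def fit_mixed(y: np.ndarray, X: np.ndarray, fixed_names: list[str],
              feeder_ids: np.ndarray, ind_ids: np.ndarray,
              conc: np.ndarray | None = None, method: str = "REML",
              random_slope: bool = True,
              fixed_theta: np.ndarray | None = None) -> LMMResult:
    """Fit the crossed-random-effects model by profiled (RE)ML.

    Parameters
    ----------
    y, X
        Response vector and fixed-effect design matrix (incl. intercept).
    fixed_names
        Column names of ``X``.
    feeder_ids, ind_ids
        Grouping labels per observation (any hashable values).
    conc
        Spatial-concentration covariate carrying the random slope;
        required when ``random_slope`` is True.
    method
        "REML" (default; used for coefficient inference and averaging)
        or "ML" (used for information-criterion comparison of fixed
        structures).
    fixed_theta
        Relative random-effect parameters ``(s_feeder, l11, l21, l22)``
        (or ``(s_feeder, s_ind)`` without the random slope) to hold
        fixed instead of optimizing — a GLS fit at known variance
        ratios, used as an exactly-unbiased oracle in simulation
        studies.
    """
    method = method.upper()
    if method not in ("ML", "REML"):
        raise ValueError("method must be 'ML' or 'REML'")
    if random_slope and conc is None:
        raise ValueError("conc is required for the random-slope structure")
    reml = method == "REML"

    y = np.asarray(y, float)
    X = np.asarray(X, float)
    feeders, f_codes = np.unique(feeder_ids, return_inverse=True)
    inds, i_codes = np.unique(ind_ids, return_inverse=True)
    conc_arr = np.asarray(conc, float) if random_slope else None
    Z, nf, ni = _build_z(f_codes, i_codes, conc_arr, random_slope)
    prof = _Profile(y, X, Z, nf, ni, random_slope)

    if random_slope:
        x0 = np.array([0.5, 0.5, 0.0, 0.5])
        bounds = [(0.0, None), (0.0, None), (None, None), (0.0, None)]
    else:
        x0 = np.array([0.5, 0.5])
        bounds = [(0.0, None), (0.0, None)]

    if fixed_theta is not None:
        theta = np.asarray(fixed_theta, float)
        converged = True
    else:
        res = sopt.minimize(prof.deviance, x0, args=(reml,),
                            method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500})
        # Polish with a simplex pass; the profiled surface can be flat
        # near variance boundaries where L-BFGS-B gradients are
        # unreliable.
        res2 = sopt.minimize(prof.deviance, res.x, args=(reml,),
                             method="Nelder-Mead",
                             options={"xatol": 1e-7, "fatol": 1e-9,
                                      "maxiter": 400})
        theta = res2.x if res2.fun <= res.fun else res.x
        theta = np.array([max(t, 0.0) if b[0] == 0.0 else t
                          for t, b in zip(theta, bounds)])
        converged = bool(res.success or res2.success)

    beta, cov_beta, s2, u, loglik = prof.finish(theta, reml)

    if random_slope:
        s_f, l11, l21, l22 = theta
        L = np.array([[l11, 0.0], [l21, l22]])
        psi = s2 * L @ L.T
        vparams = {"var_feeder": s2 * s_f ** 2,
                   "var_ind_intercept": psi[0, 0],
                   "var_ind_slope": psi[1, 1],
                   "cov_ind": psi[0, 1],
                   "var_residual": s2}
        n_vparams = 4
        u_ind = u[nf:].reshape(ni, 2)
        blups = pd.DataFrame({"tag_id": inds, "intercept": u_ind[:, 0],
                              "slope": u_ind[:, 1]})
        rel = np.array([s_f, l11, l22])
    else:
        s_f, s_i = theta
        vparams = {"var_feeder": s2 * s_f ** 2,
                   "var_ind_intercept": s2 * s_i ** 2,
                   "var_residual": s2}
        n_vparams = 2
        blups = pd.DataFrame({"tag_id": inds, "intercept": u[nf:]})
        rel = np.array([s_f, s_i])
    blups.attrs["feeder_blups"] = pd.DataFrame(
        {"feeder_id": feeders, "intercept": u[:nf]})
    singular = bool(np.any(rel < 1e-6))

    return LMMResult(
        method=method,
        coefficients=pd.Series(beta, index=fixed_names),
        se=pd.Series(np.sqrt(np.diag(cov_beta)), index=fixed_names),
        cov_fixed=pd.DataFrame(cov_beta, index=fixed_names,
                               columns=fixed_names),
        loglik=loglik, n=prof.n, n_fixed=prof.p, n_vparams=n_vparams,
        vparams=vparams, blups=blups, converged=converged,
        singular=singular, random_slope=random_slope)
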