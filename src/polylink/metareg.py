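"""Random-effects meta-regression over correlated outcome estimates.

Per-outcome MVR slopes are pooled while accounting for the phenotypic
correlation between outcome measures: the sampling covariance of two
estimates from the same cohort is approximated as V_ij = r_ij * se_i *
se_j.  Between-outcome heterogeneity enters as a single variance component
tau^2 (random effect u ~ N(0, tau^2 I)) estimated by restricted maximum
likelihood; fixed effects (the pooled mean, optionally a domain moderator)
are estimated by generalized least squares at the REML tau^2.  Cochran's Q
monitors residual heterogeneity; a binary domain moderator tests whether
pooled effects differ between outcome domains (P_mod).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MetaRegResult", "build_sampling_cov", "remlfit", "cochran_q",
    "domain_contrast",
]


@dataclass
class MetaRegResult:
    pooled_beta: float
    pooled_se: float
    pooled_p: float
    tau2: float
    q_stat: float
    q_df: int
    p_het: float
    moderator_beta: float | None = None
    moderator_se: float | None = None
    p_mod: float | None = None
    label: str = ""
    tau2_at_boundary: bool = False
    n_estimates: int = 0


def build_sampling_cov(ses: np.ndarray, pheno_corr: np.ndarray) -> np.ndarray:
    """Sampling covariance of same-cohort estimates: V_ij = r_ij se_i se_j."""
    se = np.asarray(ses, dtype=float)
    r = np.asarray(pheno_corr, dtype=float)
    if r.shape != (len(se), len(se)):
        raise ValueError("pheno_corr dimensions do not match the estimates")
    if not np.allclose(r, r.T, atol=1e-10):
        raise ValueError("pheno_corr must be symmetric")
    v = r * np.outer(se, se)
    return v


def _restricted_loglik(tau2: float, y: np.ndarray, X: np.ndarray,
                       V: np.ndarray) -> float:
    n, p = X.shape
    sigma = V + tau2 * np.eye(n)
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        return -np.inf
    logdet = 2.0 * np.log(np.diag(L)).sum()
    si_y = np.linalg.solve(sigma, y)
    si_X = np.linalg.solve(sigma, X)
    xtsx = X.T @ si_X
    sign, logdet_x = np.linalg.slogdet(xtsx)
    if sign <= 0:
        return -np.inf
    gamma = np.linalg.solve(xtsx, X.T @ si_y)
    resid = y - X @ gamma
    quad = float(resid @ np.linalg.solve(sigma, resid))
    return -0.5 * (logdet + logdet_x + quad)


def remlfit(estimates: np.ndarray, V: np.ndarray,
            moderator_design: np.ndarray | None = None,
            label: str = "") -> MetaRegResult:
    """REML random-effects meta-regression.

    ``moderator_design``, when given, is the full fixed-effect design
    matrix (first column the intercept, further columns moderators); the
    default is an intercept-only pooled mean.  tau^2 is found by bounded
    scalar maximization of the restricted log-likelihood; GLS at tau-hat^2
    gives the coefficients with Wald (normal) SE/P.  A tau^2 solution at 0
    is flagged as a boundary estimate.
    """
    y = np.asarray(estimates, dtype=float)
    n = len(y)
    X = np.ones((n, 1)) if moderator_design is None \
        else np.asarray(moderator_design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != n or V.shape != (n, n):
        raise ValueError("dimension mismatch among estimates, V and design")
    if n < X.shape[1] + 1:
        raise ValueError("need more estimates than fixed-effect parameters")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("moderator design is rank deficient")

    upper = max(10.0 * float(np.var(y, ddof=1)) + float(np.diag(V).max()), 1e-6)
    res = optimize.minimize_scalar(
        lambda t2: -_restricted_loglik(t2, y, X, V),
        bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-10, "maxiter": 500},
    )
    if not res.success:
        raise RuntimeError(f"REML optimization failed: {res.message}")
    tau2 = float(res.x)
    # the bounded optimizer never lands exactly on 0; snap when the
    # likelihood is non-increasing in tau2 at the origin
    if _restricted_loglik(0.0, y, X, V) >= _restricted_loglik(tau2, y, X, V) - 1e-10:
        tau2 = 0.0

    sigma = V + tau2 * np.eye(n)
    si_X = np.linalg.solve(sigma, X)
    xtsx_inv = np.linalg.inv(X.T @ si_X)
    gamma = xtsx_inv @ (si_X.T @ y)
    se = np.sqrt(np.diag(xtsx_inv))
    z = gamma / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    q, q_df, p_het = cochran_q(y, V, X)
    out = MetaRegResult(
        pooled_beta=float(gamma[0]), pooled_se=float(se[0]),
        pooled_p=float(pvals[0]), tau2=tau2, q_stat=q, q_df=q_df,
        p_het=p_het, label=label, tau2_at_boundary=(tau2 == 0.0),
        n_estimates=n,
    )
    if X.shape[1] > 1:
        out.moderator_beta = float(gamma[1])
        out.moderator_se = float(se[1])
        out.p_mod = float(pvals[1])
    return out


def cochran_q(estimates: np.ndarray, V: np.ndarray,
              design: np.ndarray | None = None) -> tuple[float, int, float]:
    """Cochran's Q at the fixed-effect (tau^2 = 0) GLS fit.

    Q = r' V^-1 r with r the GLS residuals; P from chi-square with
    df = n - rank(design).
    """
    y = np.asarray(estimates, dtype=float)
    n = len(y)
    X = np.ones((n, 1)) if design is None else np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    try:
        vi_y = np.linalg.solve(V, y)
        vi_X = np.linalg.solve(V, X)
    except np.linalg.LinAlgError as err:
        raise ValueError("singular sampling covariance V") from err
    gamma = np.linalg.solve(X.T @ vi_X, X.T @ vi_y)
    resid = y - X @ gamma
    q = float(resid @ np.linalg.solve(V, resid))
    df = n - int(np.linalg.matrix_rank(X))
    p = float(stats.chi2.sf(q, df)) if df > 0 else 1.0
    return q, df, p


def domain_contrast(estimates: np.ndarray, V: np.ndarray,
                    domain_tags: list[str] | np.ndarray,
                    focal: str | set[str], label: str = "") -> MetaRegResult:
    """Meta-regression with a binary domain moderator.

    ``focal`` names the domain(s) coded 1; all remaining outcomes form the
    reference level.  Returns the full result including the contrast
    estimate and its two-sided P_mod.  Fails if either level is empty.
    """
    tags = np.asarray(domain_tags)
    focal_set = {focal} if isinstance(focal, str) else set(focal)
    indicator = np.isin(tags, list(focal_set)).astype(float)
    if indicator.sum() == 0 or indicator.sum() == len(tags):
        raise ValueError("domain_contrast: both moderator levels need at "
                         "least one outcome")
    X = np.column_stack([np.ones(len(tags)), indicator])
    return remlfit(estimates, V, moderator_design=X, label=label)
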