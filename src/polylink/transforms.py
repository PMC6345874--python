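"""Phenotype preparation and multiple-testing geometry.

Outcome scores are pre-adjusted for covariates (sex, principal components,
optionally age) and then rank-transformed to a standard normal scale so
genetic effects are comparable across psychological instruments with
different native distributions.  The effective number of independent
phenotypes is estimated from the eigenvalue spectrum of their correlation
matrix (matrix spectral decomposition), which sets the experiment-wide
significance threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "rank_inverse_normal",
    "adjust_and_rank",
    "effective_tests",
    "experimentwide_alpha",
]


def rank_inverse_normal(scores: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Maps ranks r (average rank for ties) to Phi^-1((r - c) / (n + 1 - 2c))
    with c = 3/8.  NaN entries stay NaN; raises on a constant vector
    (ranks undefined for the purpose of normalization).
    """
    x = np.asarray(scores, dtype=float)
    out = np.full_like(x, np.nan)
    mask = ~np.isnan(x)
    vals = x[mask]
    if len(vals) == 0:
        return out
    if np.nanmax(vals) == np.nanmin(vals):
        raise ValueError("constant score vector: rank transform undefined")
    ranks = stats.rankdata(vals, method="average")
    n = len(vals)
    out[mask] = stats.norm.ppf((ranks - offset) / (n + 1.0 - 2.0 * offset))
    return out


def adjust_and_rank(scores: np.ndarray, covariates: pd.DataFrame | np.ndarray | None,
                    ) -> np.ndarray:
    """Residualize scores on covariates by OLS, then inverse-normal transform.

    Missing scores remain missing; covariates must be aligned to the
    individuals.  The output has mean ~0 and SD ~1 on non-missing entries.
    """
    x = np.asarray(scores, dtype=float)
    mask = ~np.isnan(x)
    if covariates is not None:
        c = np.asarray(covariates, dtype=float)
        if c.ndim == 1:
            c = c[:, None]
        if len(c) != len(x):
            raise ValueError("covariates not aligned to scores")
        design = np.column_stack([np.ones(mask.sum()), c[mask]])
        coef, *_ = np.linalg.lstsq(design, x[mask], rcond=None)
        resid = np.full_like(x, np.nan)
        resid[mask] = x[mask] - design @ coef
    else:
        resid = x
    return rank_inverse_normal(resid)


def effective_tests(pheno_corr: np.ndarray, method: str = "li-ji",
                    ) -> tuple[float, np.ndarray]:
    """Effective number of independent tests from a correlation matrix.

    ``li-ji`` (default): M_eff = sum_i [ I(lambda_i >= 1) + (lambda_i -
    floor(lambda_i)) ] over the eigenvalues.  ``nyholt``: M_eff = 1 +
    (M - 1) * (1 - Var(lambda) / M).  Returns (M_eff, eigenvalues).
    """
    m = np.asarray(pheno_corr, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("pheno_corr must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise ValueError("pheno_corr must be symmetric")
    lam = np.linalg.eigvalsh(m)[::-1]
    lam = np.clip(lam, 0.0, None)
    if method == "li-ji":
        # round before floor so eigenvalues that are integers up to
        # numerical jitter land in the right bin
        lam_r = np.round(lam, 10)
        meff = float(np.sum((lam_r >= 1).astype(float)
                            + (lam_r - np.floor(lam_r))))
    elif method == "nyholt":
        M = len(lam)
        meff = float(1 + (M - 1) * (1 - np.var(lam, ddof=1) / M))
    else:
        raise ValueError(f"unknown method {method!r}")
    return meff, lam


def experimentwide_alpha(fwer: float, m_eff: float) -> tuple[float, float]:
    """Per-test threshold controlling the family-wise rate over m_eff
    effectively independent tests: fwer / m_eff.

    Returns (threshold rounded to 3 significant figures, full precision).
    """
    if not (0 < fwer < 1):
        raise ValueError("fwer must lie in (0, 1)")
    if m_eff < 1:
        raise ValueError("m_eff must be >= 1")
    full = fwer / m_eff
    exponent = np.floor(np.log10(abs(full)))
    rounded = float(round(full, int(2 - exponent)))
    return rounded, full
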