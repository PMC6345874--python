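"""Polygenic scoring in the target cohort and score-phenotype association.

A polygenic score is the weighted allele-dosage sum over a clumped,
P-thresholded discovery set, Z-standardized across scored individuals.
Associations with prepared (covariate-adjusted, rank-transformed) outcomes
use ordinary least squares; with both variables standardized the slope is
the Pearson correlation and R^2 its square.  Data-missingness is related
to the score by logistic regression (attrition analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "PgsResult", "compute_pgs", "pgs_association", "missingness_association",
    "PGS_THRESHOLDS",
]

# threshold sweep; results presented at 0.1 by default
PGS_THRESHOLDS = (5e-8, 0.0015, 0.01, 0.05, 0.1, 0.5, 1.0)


@dataclass
class PgsResult:
    outcome: str
    beta: float        # outcome SD per SD of PGS
    se: float
    pvalue: float
    r2: float          # proportion of phenotypic variance
    n: int
    p_threshold: float
    discovery: str = ""


def compute_pgs(dosages: np.ndarray, variants: pd.DataFrame,
                weights, p_threshold: float = 0.1) -> np.ndarray:
    """Z-standardized weighted dosage sum.

    ``weights`` is a risk-oriented SumstatTable (or its data frame);
    variants are matched on identifier, restricted to P < p_threshold,
    and allele orientation is reconciled against the cohort's dosage
    convention (a weight whose effect allele is the cohort's other allele
    scores 2 - dosage).  Missing dosages (NaN) are mean-imputed to 2*EAF
    of the weight table.  Raises when no variants overlap or the raw
    score is constant.
    """
    wdf = weights.data if hasattr(weights, "data") else weights
    wdf = wdf[wdf["pvalue"] < p_threshold]
    vset = variants.set_index("variant_id")
    rows = wdf[wdf["variant_id"].isin(vset.index)]
    if len(rows) == 0:
        raise ValueError("compute_pgs: zero overlapping variants")
    logger.info("compute_pgs: scoring over %d variants (P < %g)",
                len(rows), p_threshold)

    cohort_rows = vset.loc[rows["variant_id"]]
    same = (rows["effect_allele"].to_numpy()
            == cohort_rows["effect_allele"].to_numpy())
    swapped = (rows["effect_allele"].to_numpy()
               == cohort_rows["other_allele"].to_numpy())
    if not np.all(same | swapped):
        n_bad = int((~(same | swapped)).sum())
        logger.warning("compute_pgs: dropping %d variants with "
                       "incompatible alleles", n_bad)
        rows = rows[same | swapped]
        cohort_rows = cohort_rows.loc[rows["variant_id"]]
        swapped = (rows["effect_allele"].to_numpy()
                   == cohort_rows["other_allele"].to_numpy())
    if len(rows) == 0:
        raise ValueError("compute_pgs: zero allele-compatible variants")

    pos = {v: i for i, v in enumerate(vset.index)}
    cols = np.array([pos[v] for v in rows["variant_id"]])
    x = dosages[:, cols].astype(float)
    if swapped.any():
        x[:, swapped] = 2.0 - x[:, swapped]
    if np.isnan(x).any():
        fill = 2.0 * rows["eaf"].to_numpy()
        nan_mask = np.isnan(x)
        x[nan_mask] = np.broadcast_to(fill, x.shape)[nan_mask]
        logger.info("compute_pgs: mean-imputed %d missing dosages",
                    int(nan_mask.sum()))
    raw = x @ rows["beta"].to_numpy()
    sd = raw.std()
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("compute_pgs: degenerate constant score, "
                         "cannot standardize")
    return (raw - raw.mean()) / sd


def pgs_association(outcome: np.ndarray, pgs: np.ndarray,
                    exclusion_mask: np.ndarray | None = None,
                    outcome_label: str = "", p_threshold: float = np.nan,
                    discovery: str = "") -> PgsResult:
    """OLS of a prepared outcome on the standardized PGS.

    NaN outcomes and (optionally) masked individuals are dropped; refuses
    to fit on fewer than 30 observations.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.asarray(pgs, dtype=float)
    keep = ~np.isnan(y) & ~np.isnan(x)
    if exclusion_mask is not None:
        keep &= ~np.asarray(exclusion_mask, dtype=bool)
    y, x = y[keep], x[keep]
    n = len(y)
    if n < 30:
        raise ValueError(f"pgs_association: only {n} observations after "
                         "masking; refusing unstable estimate")
    design = sm.add_constant(x)
    fit = sm.OLS(y, design).fit()
    return PgsResult(outcome=outcome_label, beta=float(fit.params[1]),
                     se=float(fit.bse[1]), pvalue=float(fit.pvalues[1]),
                     r2=float(fit.rsquared), n=n,
                     p_threshold=p_threshold, discovery=discovery)


def missingness_association(missing_indicator: np.ndarray, pgs: np.ndarray,
                            ) -> tuple[float, float, float]:
    """Logistic regression of a missingness indicator on the standardized
    score: (log-odds slope per SD, Wald SE, two-sided P).

    Raises on an all-0/all-1 indicator; reports non-convergence (e.g.
    separable data) explicitly.
    """
    y = np.asarray(missing_indicator, dtype=float)
    x = np.asarray(pgs, dtype=float)
    if y.min() == y.max():
        raise ValueError("missingness indicator is constant")
    try:
        fit = sm.Logit(y, sm.add_constant(x)).fit(disp=0, maxiter=100)
    except Exception as err:  # perfect separation and friends
        raise RuntimeError(
            f"missingness_association: logistic fit failed ({err})") from err
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("missingness_association: logistic fit did not "
                           "converge (possibly separable data)")
    if np.abs(fit.params).max() > 30 or not np.isfinite(fit.bse).all():
        raise RuntimeError("missingness_association: logistic fit is "
                           "degenerate (perfectly separable data)")
    return float(fit.params[1]), float(fit.bse[1]), float(fit.pvalues[1])
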