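"""Multivariable regression (MVR) of effect-size vectors.

The core estimator: across an instrument set, per-variant outcome effect
estimates are regressed jointly on the exposure effect estimates (log odds
ratios) and the confounder effect estimates, by ordinary (unweighted) least
squares through the origin.  The exposure coefficient is the outcome change
per log-odds of exposure *conditional* on the confounder (the
confounder-independent component); the confounder coefficient captures the
exposure-outcome association shared with the confounder and is
sign-flipped for reporting so that, for an attainment-like confounder, it
reads as change per *missing* year of schooling.

No causal interpretation is attached: with genetically correlated exposure
and confounder the classical instrumental-variable assumptions do not
hold, and the decomposition is descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MvrResult", "mvr_fit", "standardize_for_mvr", "intercept_evidence",
    "reverse_mvr",
]

_COLLINEARITY_R = 0.999


@dataclass
class MvrResult:
    outcome: str
    instrument_label: str
    beta_exposure: float      # outcome units per log-odds of exposure
    se_exposure: float
    p_exposure: float
    beta_confounder: float    # sign-flipped: per missing confounder unit
    se_confounder: float
    p_confounder: float
    intercept_mode: str       # "constrained" | "free"
    n_instruments: int = 0
    standardized: bool = False
    intercept: float = float("nan")
    intercept_se: float = float("nan")
    intercept_p: float = float("nan")

    def to_row(self) -> dict:
        return {
            "outcome": self.outcome,
            "instruments": self.instrument_label,
            "beta_adhd_like": self.beta_exposure,
            "se_adhd_like": self.se_exposure,
            "p_adhd_like": self.p_exposure,
            "beta_confounder_flipped": self.beta_confounder,
            "se_confounder": self.se_confounder,
            "p_confounder": self.p_confounder,
            "n_instruments": self.n_instruments,
            "intercept_mode": self.intercept_mode,
            "standardized": self.standardized,
        }


def _check_effects(bx: np.ndarray, bc: np.ndarray, by: np.ndarray,
                   n_params: int) -> None:
    n = len(by)
    if len(bx) != n or len(bc) != n:
        raise ValueError("effect vectors must have equal length")
    if n < n_params + 1:
        raise ValueError(f"need at least {n_params + 1} instruments for "
                         f"{n_params} parameters, got {n}")
    sx, sc = np.std(bx), np.std(bc)
    if sx > 0 and sc > 0:
        r = float(np.corrcoef(bx, bc)[0, 1])
        if abs(r) > _COLLINEARITY_R:
            raise ValueError(
                f"exposure and confounder effect vectors are collinear "
                f"(|r| = {abs(r):.4f} > {_COLLINEARITY_R})")


def mvr_fit(beta_exposure: np.ndarray, beta_confounder: np.ndarray,
            beta_outcome: np.ndarray, intercept_mode: str = "constrained",
            outcome: str = "", instrument_label: str = "",
            standardized: bool = False,
            weights: np.ndarray | None = None) -> MvrResult:
    """Joint OLS of outcome effects on exposure and confounder effects.

    ``constrained`` (default) fits through the origin; ``free`` adds an
    intercept.  ``weights`` enables an optional inverse-variance-weighted
    fit (non-default).  The confounder slope is sign-flipped in the result.
    """
    bx = np.asarray(beta_exposure, dtype=float)
    bc = np.asarray(beta_confounder, dtype=float)
    by = np.asarray(beta_outcome, dtype=float)
    if intercept_mode not in ("constrained", "free"):
        raise ValueError("intercept_mode must be 'constrained' or 'free'")
    n_params = 2 + (intercept_mode == "free")
    _check_effects(bx, bc, by, n_params)

    X = np.column_stack([bx, bc])
    if intercept_mode == "free":
        X = sm.add_constant(X)
    model = sm.WLS(by, X, weights=weights) if weights is not None \
        else sm.OLS(by, X)
    fit = model.fit()
    k = 1 if intercept_mode == "free" else 0
    res = MvrResult(
        outcome=outcome, instrument_label=instrument_label,
        beta_exposure=float(fit.params[k]), se_exposure=float(fit.bse[k]),
        p_exposure=float(fit.pvalues[k]),
        beta_confounder=-float(fit.params[k + 1]),
        se_confounder=float(fit.bse[k + 1]),
        p_confounder=float(fit.pvalues[k + 1]),
        intercept_mode=intercept_mode, n_instruments=len(by),
        standardized=standardized,
    )
    if intercept_mode == "free":
        res.intercept = float(fit.params[0])
        res.intercept_se = float(fit.bse[0])
        res.intercept_p = float(fit.pvalues[0])
    return res


def standardize_for_mvr(beta_exposure: np.ndarray, beta_confounder: np.ndarray,
                        beta_outcome: np.ndarray, center: bool = False,
                        ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scale each effect vector to unit variance across the instrument set.

    The resulting ("fully standardised") slopes are unitless -- change in
    outcome Z-score per Z-score of exposure / confounder effects -- and
    mutually comparable in magnitude.  By default vectors are scaled
    without centering, preserving the origin for constrained fits;
    ``center=True`` additionally removes the mean (free-intercept use).
    Raises on a zero-variance vector.
    """
    out = []
    for name, v in (("exposure", beta_exposure),
                    ("confounder", beta_confounder),
                    ("outcome", beta_outcome)):
        v = np.asarray(v, dtype=float)
        s = v.std(ddof=1)
        scale = max(1.0, float(np.abs(v).max()))
        if s < 1e-12 * scale or not np.isfinite(s):
            raise ValueError(f"standardize_for_mvr: zero-variance "
                             f"{name} effect vector")
        out.append(((v - v.mean()) if center else v) / s)
    return tuple(out)  # type: ignore[return-value]


def intercept_evidence(beta_exposure: np.ndarray, beta_confounder: np.ndarray,
                       beta_outcome: np.ndarray) -> dict:
    """Compare free- vs constrained-intercept fits.

    Returns the free fit's intercept estimate/SE/P (two-sided test of
    intercept = 0), both slope pairs, and the change in unexplained
    variance when the intercept is freed.
    """
    con = mvr_fit(beta_exposure, beta_confounder, beta_outcome,
                  intercept_mode="constrained")
    fre = mvr_fit(beta_exposure, beta_confounder, beta_outcome,
                  intercept_mode="free")
    by = np.asarray(beta_outcome, dtype=float)
    bx = np.asarray(beta_exposure, dtype=float)
    bc = np.asarray(beta_confounder, dtype=float)
    rss_con = float(np.sum((by - bx * con.beta_exposure
                            + bc * con.beta_confounder) ** 2))
    rss_free = float(np.sum((by - fre.intercept - bx * fre.beta_exposure
                             + bc * fre.beta_confounder) ** 2))
    tss = float(np.sum(by ** 2))
    return {
        "constrained": con,
        "free": fre,
        "intercept": fre.intercept,
        "intercept_se": fre.intercept_se,
        "intercept_p": fre.intercept_p,
        "delta_unexplained": (rss_con - rss_free) / tss if tss > 0 else np.nan,
    }


def reverse_mvr(beta_confounder_as_exposure: np.ndarray,
                beta_exposure_as_confounder: np.ndarray,
                beta_outcome: np.ndarray, intercept_mode: str = "constrained",
                outcome: str = "", instrument_label: str = "",
                ) -> MvrResult:
    """Role-swapped sensitivity fit: instruments selected on the confounder,
    outcome effects regressed on (confounder, exposure) effects.

    The same estimator with swapped columns; the returned
    ``beta_exposure`` is the confounder-conditional-on-exposure slope and
    labels reflect the orientation.
    """
    res = mvr_fit(beta_confounder_as_exposure, beta_exposure_as_confounder,
                  beta_outcome, intercept_mode=intercept_mode,
                  outcome=outcome,
                  instrument_label=instrument_label or "reverse",
                  )
    return res
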