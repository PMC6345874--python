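"""Forward simulation of a three-sample summary-statistics study design.

The generator emulates the data constellation needed to decompose a
polygenic disorder--ability association into confounder-independent and
confounder-shared components:

* a case-control discovery GWAS for the exposure (a liability-threshold
  disorder, effects reported as log odds ratios),
* a continuous-trait discovery GWAS for the confounder (an
  educational-attainment-like "years of schooling" phenotype),
* an individual-level target cohort with several correlated quantitative
  outcome measures, covariates and genotype dosages.

Per-variant causal effects on exposure liability and confounder are drawn
from a bivariate normal with genetic correlation ``rg_exposure_confounder``,
so the cross-trait architecture matches the usual definition of r_g as the
correlation of per-variant effects.  Linkage disequilibrium is block
structured: within a block, haplotypes share a Gaussian latent factor
(a Gaussian copula over Bernoulli alleles), blocks are independent and
placed more than the clumping window apart.

Two discovery-GWAS modes are provided.  ``individual`` simulates genotypes
for every GWAS participant and runs per-variant logistic/linear regressions;
``summary`` (the default) draws the per-variant estimates directly from
their large-sample distribution around the exact marginal effects implied
by the generating model, which makes consortium-scale sample sizes
tractable.  The two modes are cross-validated against each other in the
test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SumstatTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "Genome",
    "Cohort",
    "StudyData",
    "build_genome",
    "draw_effects",
    "simulate_genotypes",
    "simulate_exposure_gwas",
    "simulate_confounder_gwas",
    "sample_exposure_sumstats",
    "sample_confounder_sumstats",
    "simulate_cohort",
    "simulate_study",
    "grouped_logistic_gwas",
    "linear_gwas",
]

_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
]


@dataclass
class SimConfig:
    """Generating parameters for one synthetic study.

    Sample sizes default to the consortium/cohort scale of the design this
    package targets: a combined clinical case-control exposure GWAS
    (20,183 cases / 35,191 controls), a 326,041-person confounder GWAS and
    a 5,919-child target cohort with 13 outcome measures.  ``h2`` values are
    the liability-scale SNP heritability of the exposure (0.26), the
    confounder heritability (0.11) and the total target outcome
    heritability; the exposure-confounder genetic correlation defaults to
    -0.53.  ``beta_direct`` is the outcome effect (in outcome SD) per SD of
    the exposure liability genetic score; ``beta_shared`` the effect per SD
    of the confounder genetic score.
    """

    n_variants: int = 3000
    n_blocks: int = 600
    within_block_r: float = 0.7
    eaf_range: tuple[float, float] = (0.05, 0.5)
    n_cases: int = 20183
    n_controls: int = 35191
    n_confounder: int = 326041
    n_cohort: int = 5919
    prevalence: float = 0.05
    h2_exposure_liability: float = 0.26
    h2_confounder: float = 0.11
    h2_outcome: float = 0.54
    rg_exposure_confounder: float = -0.53
    beta_direct: float = -0.3
    beta_shared: float = 0.5
    n_outcomes: int = 13
    outcome_residual_corr: np.ndarray | None = None
    missingness_slope: float = 0.2
    missingness_rate: float = 0.15
    low_info_fraction: float = 0.05
    gwas_mode: Literal["summary", "individual"] = "summary"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.prevalence < 1):
            raise ValueError("prevalence must lie in (0, 1)")
        for name in ("h2_exposure_liability", "h2_confounder", "h2_outcome"):
            v = getattr(self, name)
            if not (0 <= v < 1):
                raise ValueError(f"{name} must lie in [0, 1)")
        if not (-1 <= self.rg_exposure_confounder <= 1):
            raise ValueError("rg_exposure_confounder must lie in [-1, 1]")
        lo, hi = self.eaf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("eaf_range must lie within (0, 0.5]")
        if not (0 <= self.within_block_r < 1):
            raise ValueError("within_block_r must lie in [0, 1)")
        if self.n_blocks < 1 or self.n_variants < self.n_blocks:
            raise ValueError("need 1 <= n_blocks <= n_variants")
        if self.outcome_residual_corr is not None:
            m = np.asarray(self.outcome_residual_corr, dtype=float)
            if m.shape != (self.n_outcomes, self.n_outcomes):
                raise ValueError("outcome_residual_corr shape mismatch")
            if not np.allclose(m, m.T):
                raise ValueError("outcome_residual_corr must be symmetric")
            if not np.allclose(np.diag(m), 1.0):
                raise ValueError("outcome_residual_corr must have unit diagonal")
            if np.linalg.eigvalsh(m).min() <= 0:
                raise ValueError("outcome_residual_corr must be positive-definite")

    def residual_corr(self) -> np.ndarray:
        if self.outcome_residual_corr is not None:
            return np.asarray(self.outcome_residual_corr, dtype=float)
        m = np.full((self.n_outcomes, self.n_outcomes), 0.5)
        np.fill_diagonal(m, 1.0)
        return m


@dataclass
class Genome:
    """Fixed variant panel: frequencies, LD blocks, exact dosage covariance."""

    variants: pd.DataFrame          # variant_id, chr, pos, effect_allele, other_allele, eaf, block
    block_index: list[np.ndarray]   # variant indices per block
    dosage_cov_blocks: list[np.ndarray]  # exact dosage covariance per block
    within_block_r: float           # target dosage correlation within blocks
    latent_block_r: np.ndarray | None = None  # calibrated copula correlation

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def dosage_var(self) -> np.ndarray:
        p = self.variants["eaf"].to_numpy()
        return 2.0 * p * (1.0 - p)

    def matvec(self, v: np.ndarray) -> np.ndarray:
        """Exact dosage-covariance times an effect vector, blockwise."""
        out = np.zeros_like(v, dtype=float)
        for idx, cov in zip(self.block_index, self.dosage_cov_blocks):
            out[idx] = cov @ v[idx]
        return out


@dataclass
class SimTruth:
    """Ground truth carried alongside simulated data for recovery tests."""

    alpha: np.ndarray               # per-allele causal effects on exposure liability
    gamma: np.ndarray               # per-allele causal effects on confounder
    beta_direct: float
    beta_shared: float
    h2_exposure: float
    h2_confounder: float
    rg_realized: float
    rho_score: float                # exact LD-weighted genetic-score correlation
    path_variance: float            # outcome variance through the two score paths
    sd_score_exposure: float        # SD of the exposure liability genetic score
    sd_score_confounder: float
    lnor_per_liability_sd: float    # ascertained liability -> log-odds slope (lambda)
    slope_exposure_true: float      # MVR estimand: outcome SD per log-odds of exposure
    slope_confounder_true: float    # MVR estimand: outcome SD per confounder unit
    marginal_lnor: np.ndarray       # exact marginal log-OR per allele
    marginal_beta_confounder: np.ndarray
    background: np.ndarray | None = None  # outcome-specific effects (variants x outcomes)


@dataclass
class Cohort:
    """Individual-level target sample."""

    dosages: np.ndarray             # individuals x variants, uint8
    variants: pd.DataFrame
    phenotypes: pd.DataFrame        # raw outcome scores, NaN where missing
    covariates: pd.DataFrame        # sex, pc1, pc2
    missing: np.ndarray             # bool, data-missingness indicator
    diagnosed: np.ndarray           # bool, exposure-diagnosis flag (liability above threshold)
    domain_tags: list[str]
    truth: SimTruth | None = None   # absent for file-loaded cohorts


@dataclass
class StudyData:
    config: SimConfig
    genome: Genome
    exposure: SumstatTable
    confounder: SumstatTable
    cohort: Cohort
    ld_reference: np.ndarray        # reference-panel dosages for LD estimation
    truth: SimTruth | None = None   # absent for file-loaded studies


# ---------------------------------------------------------------------------
# genome and effects


def _equicorr_normal_cdf(t: np.ndarray, r: np.ndarray) -> np.ndarray:
    """P(Z1 < t, Z2 < t) under correlation r (equal thresholds), via
    Owen's T: Phi2(t, t; r) = Phi(t) - 2 T(t, sqrt((1-r)/(1+r)))."""
    from scipy.special import owens_t
    a = np.sqrt((1.0 - r) / (1.0 + r))
    return stats.norm.cdf(t) - 2.0 * owens_t(t, a)


def _latent_correlation_for(p: np.ndarray, rho_target: float) -> np.ndarray:
    """Latent Gaussian correlation giving Bernoulli(p) indicators the target
    correlation, solved by vectorized bisection (one value per block).

    Dichotomizing correlated Gaussians attenuates correlation, so the
    latent value is inflated above the target; with equal within-block
    allele frequencies any target in [0, 1) is attainable.
    """
    t = stats.norm.ppf(p)
    goal = rho_target * p * (1.0 - p) + p * p   # required joint probability
    lo = np.full_like(p, rho_target)            # latent >= indicator corr
    hi = np.full_like(p, 1.0 - 1e-9)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        too_low = _equicorr_normal_cdf(t, mid) < goal
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def build_genome(config: SimConfig, rng: np.random.Generator | None = None) -> Genome:
    """Draw allele frequencies, place LD blocks on a map, precompute dosage covariance.

    Variants within a block share their allele frequency (as variants in
    tight LD do), which makes the configured within-block dosage
    correlation attainable; the latent copula correlation is calibrated so
    the realized dosage correlation matches ``within_block_r``.  Blocks are
    laid out more than 500 kb apart (so clumping windows never straddle
    blocks) and each block spans well under 500 kb.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    m = config.n_variants
    blocks = np.array_split(np.arange(m), config.n_blocks)
    p_block = rng.uniform(config.eaf_range[0], config.eaf_range[1],
                          size=len(blocks))
    p = np.empty(m)
    for b, idx in enumerate(blocks):
        p[idx] = p_block[b]

    chrom = np.empty(m, dtype=int)
    pos = np.empty(m, dtype=int)
    per_chr_count: dict[int, int] = {}
    for b, idx in enumerate(blocks):
        c = (b % 22) + 1
        k = per_chr_count.get(c, 0)
        start = 1_000_000 + k * 2_000_000   # blocks 2 Mb apart on each chromosome
        per_chr_count[c] = k + 1
        chrom[idx] = c
        pos[idx] = start + 5_000 * np.arange(len(idx))

    pair_idx = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=m)
    ea = np.array([_NONPALINDROMIC_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_NONPALINDROMIC_PAIRS[i][1] for i in pair_idx])

    variants = pd.DataFrame({
        "variant_id": [f"snp_{i:06d}" for i in range(m)],
        "chr": chrom,
        "pos": pos,
        "effect_allele": ea,
        "other_allele": oa,
        "eaf": p,
        "block": np.concatenate([np.full(len(idx), b) for b, idx in enumerate(blocks)]),
    })

    # calibrate the latent copula correlation so dosage correlation matches
    rho = config.within_block_r
    if rho > 0:
        latent_r = _latent_correlation_for(p_block, rho)
    else:
        latent_r = np.zeros(len(blocks))

    # exact dosage covariance per block: equal frequencies within a block,
    # indicator correlation rho by construction
    cov_blocks: list[np.ndarray] = []
    for b, idx in enumerate(blocks):
        s = len(idx)
        pq = p_block[b] * (1.0 - p_block[b])
        cov = np.full((s, s), 2.0 * rho * pq)
        np.fill_diagonal(cov, 2.0 * pq)
        if s > 1 and np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError(
                f"block {b}: dosage covariance not positive-definite")
        cov_blocks.append(cov)

    return Genome(variants=variants, block_index=[np.asarray(i) for i in blocks],
                  dosage_cov_blocks=cov_blocks, within_block_r=rho,
                  latent_block_r=latent_r)


def _selection_lambda(prevalence: float) -> float:
    """Slope of case log-odds per liability unit in an ascertained case-control
    sample under the liability-threshold model (small-effect linearization):
    phi(t) * (1/K + 1/(1-K)) with t the liability threshold."""
    t = stats.norm.ppf(1.0 - prevalence)
    return stats.norm.pdf(t) * (1.0 / prevalence + 1.0 / (1.0 - prevalence))


def draw_effects(config: SimConfig, genome: Genome,
                 rng: np.random.Generator) -> SimTruth:
    """Draw bivariate-normal causal effects and derive all truth quantities.

    Effect sizes are frequency-independent; each vector is rescaled so the
    genetic-score variance equals the configured h2 exactly, hence
    sd(G) = sqrt(h2) by construction.
    """
    m = genome.n_variants
    rg = config.rg_exposure_confounder
    a_raw = rng.standard_normal(m)
    z = rng.standard_normal(m)
    c_raw = rg * a_raw + np.sqrt(max(1.0 - rg * rg, 0.0)) * z

    def _scale(v: np.ndarray, h2: float) -> np.ndarray:
        if h2 == 0:
            return np.zeros_like(v)
        var = float(v @ genome.matvec(v))
        return v * np.sqrt(h2 / var)

    alpha = _scale(a_raw, config.h2_exposure_liability)
    gamma = _scale(c_raw, config.h2_confounder)
    rg_real = float(np.corrcoef(a_raw, c_raw)[0, 1])
    # exact correlation of the two genetic scores (LD-weighted)
    if config.h2_exposure_liability > 0 and config.h2_confounder > 0:
        rho_score = float(alpha @ genome.matvec(gamma)
                          / np.sqrt(config.h2_exposure_liability
                                    * config.h2_confounder))
    else:
        rho_score = 0.0

    sd_ga = np.sqrt(config.h2_exposure_liability)
    sd_gc = np.sqrt(config.h2_confounder)
    lam = _selection_lambda(config.prevalence)
    dvar = genome.dosage_var
    marg_lnor = lam * genome.matvec(alpha) / dvar
    marg_gamma = genome.matvec(gamma) / dvar

    slope_exp = config.beta_direct / (sd_ga * lam) if sd_ga > 0 else np.nan
    slope_conf = config.beta_shared / sd_gc if sd_gc > 0 else np.nan

    # outcome-specific polygenic background topping total outcome h2 up to target
    path_var = _outcome_path_variance(config, rho_score)
    bg_var = max(0.0, config.h2_outcome - path_var)
    background = None
    if bg_var > 0:
        background = rng.standard_normal((m, config.n_outcomes))
        for k in range(config.n_outcomes):
            background[:, k] = _scale(background[:, k], bg_var)

    return SimTruth(
        alpha=alpha, gamma=gamma,
        beta_direct=config.beta_direct, beta_shared=config.beta_shared,
        h2_exposure=config.h2_exposure_liability,
        h2_confounder=config.h2_confounder,
        rg_realized=rg_real, rho_score=rho_score, path_variance=path_var,
        sd_score_exposure=sd_ga, sd_score_confounder=sd_gc,
        lnor_per_liability_sd=lam * sd_ga,
        slope_exposure_true=slope_exp, slope_confounder_true=slope_conf,
        marginal_lnor=marg_lnor, marginal_beta_confounder=marg_gamma,
        background=background,
    )


def _outcome_path_variance(config: SimConfig, rg_real: float) -> float:
    """Variance of beta_direct*S_A + beta_shared*S_C (standardized scores)."""
    bd, bs = config.beta_direct, config.beta_shared
    if config.h2_exposure_liability == 0 or config.h2_confounder == 0:
        r = 0.0
    else:
        r = rg_real
    return bd * bd + bs * bs + 2.0 * bd * bs * r


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(config: SimConfig, n_individuals: int,
                       genome: Genome | None = None,
                       rng: np.random.Generator | None = None,
                       ) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate dosage genotypes (0/1/2) for ``n_individuals``.

    Haplotype alleles are thresholded correlated Gaussians: within a block
    the latent variables share a factor whose loading is calibrated so the
    realized dosage correlation matches ``within_block_r``; across blocks
    it is zero.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    if genome is None:
        genome = build_genome(config, rng)
    m = genome.n_variants
    p = genome.variants["eaf"].to_numpy()
    t = stats.norm.ppf(p).astype(np.float32)
    r = genome.within_block_r
    block_of = genome.variants["block"].to_numpy()

    dos = np.zeros((n_individuals, m), dtype=np.uint8)
    n_blocks = int(block_of.max()) + 1
    sizes = np.bincount(block_of, minlength=n_blocks)
    uniform_blocks = sizes.min() == sizes.max()
    latent = genome.latent_block_r
    if latent is None:
        latent = np.full(n_blocks, r)
    sr_v = np.sqrt(latent)[block_of].astype(np.float32)
    sq_v = np.sqrt(1.0 - latent)[block_of].astype(np.float32)
    for _hap in range(2):
        z = rng.standard_normal((n_individuals, m), dtype=np.float32)
        z *= sq_v
        if r > 0:
            f = rng.standard_normal((n_individuals, n_blocks), dtype=np.float32)
            if uniform_blocks:
                f_full = np.repeat(f, sizes[0], axis=1)
            else:
                f_full = f[:, block_of]
            f_full *= sr_v
            z += f_full
        np.add(dos, z < t, out=dos, casting="unsafe")
    return dos, genome.variants.copy()


def _info_scores(m: int, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    info = rng.uniform(0.8, 1.0, size=m) + 1e-12
    n_low = int(round(config.low_info_fraction * m))
    if n_low:
        low_idx = rng.choice(m, size=n_low, replace=False)
        info[low_idx] = rng.uniform(0.5, 0.8, size=n_low)
    return np.minimum(info, 1.0)


# ---------------------------------------------------------------------------
# per-variant GWAS machinery


def grouped_logistic_gwas(dosages: np.ndarray, status: np.ndarray,
                          max_iter: int = 25, tol: float = 1e-10,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant logistic regression of case status on dosage, all variants
    at once.

    Because the single predictor takes only the values {0, 1, 2}, the exact
    MLE depends on the data only through six per-variant counts (cases and
    totals at each dosage level); Newton-Raphson on those sufficient
    statistics is run vectorized across variants.  Returns (lnOR, SE).
    """
    status = np.asarray(status, dtype=bool)
    m = dosages.shape[1]
    d_levels = np.array([0.0, 1.0, 2.0])
    n_d = np.stack([(dosages == d).sum(axis=0) for d in (0, 1, 2)], axis=1).astype(float)
    y_d = np.stack([(dosages[status] == d).sum(axis=0) for d in (0, 1, 2)], axis=1).astype(float)

    pbar = float(np.clip(status.mean(), 1e-6, 1 - 1e-6))
    b0 = np.full(m, np.log(pbar / (1.0 - pbar)))
    b1 = np.zeros(m)
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * d_levels[None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = n_d * mu * (1.0 - mu)
        g0 = (y_d - n_d * mu).sum(axis=1)
        g1 = ((y_d - n_d * mu) * d_levels).sum(axis=1)
        h00 = w.sum(axis=1)
        h01 = (w * d_levels).sum(axis=1)
        h11 = (w * d_levels ** 2).sum(axis=1)
        det = h00 * h11 - h01 ** 2
        det = np.where(det <= 0, np.nan, det)
        db0 = (h11 * g0 - h01 * g1) / det
        db1 = (h00 * g1 - h01 * g0) / det
        db0 = np.clip(np.nan_to_num(db0), -4, 4)
        db1 = np.clip(np.nan_to_num(db1), -4, 4)
        b0 += db0
        b1 += db1
        if max(np.abs(db0).max(), np.abs(db1).max()) < tol:
            break

    eta = b0[:, None] + b1[:, None] * d_levels[None, :]
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = n_d * mu * (1.0 - mu)
    h00 = w.sum(axis=1)
    h01 = (w * d_levels).sum(axis=1)
    h11 = (w * d_levels ** 2).sum(axis=1)
    det = h00 * h11 - h01 ** 2
    se = np.sqrt(np.where(det > 0, h00 / det, np.nan))
    return b1, se


def linear_gwas(dosages: np.ndarray, y: np.ndarray,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form per-variant simple linear regression of y on dosage."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    x = dosages.astype(np.float32)
    xm = x.mean(axis=0)
    ym = y.mean()
    sxy = (y - ym) @ x / n
    sxx = (x * x).mean(axis=0) - xm ** 2
    sxx = np.where(sxx <= 0, np.nan, sxx)
    beta = sxy / sxx
    syy = y.var()
    resid_var = np.maximum(syy - beta ** 2 * sxx, 1e-12) * n / (n - 2)
    se = np.sqrt(resid_var / (n * sxx))
    return beta, se


def _wald_table(genome_variants: pd.DataFrame, beta: np.ndarray, se: np.ndarray,
                eaf: np.ndarray, info: np.ndarray, n: int, trait: str,
                trait_type: str) -> SumstatTable:
    z = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    df = genome_variants[["variant_id", "chr", "pos", "effect_allele",
                          "other_allele"]].copy()
    df["beta"] = beta
    df["se"] = se
    df["pvalue"] = pval
    df["eaf"] = eaf
    df["info"] = info
    df["n"] = n
    return SumstatTable(trait=trait, trait_type=trait_type, data=df,
                        provenance="synthetic")


# ---------------------------------------------------------------------------
# discovery GWAS, individual mode


def simulate_exposure_gwas(config: SimConfig, genotypes: np.ndarray,
                           truth: SimTruth, genome: Genome,
                           rng: np.random.Generator) -> SumstatTable:
    """Case-control GWAS of the liability-threshold exposure.

    ``genotypes`` is a population sample; individuals whose liability
    (genetic value + normal residual) exceeds the (1 - prevalence) quantile
    are eligible cases.  n_cases cases and n_controls controls are drawn and
    per-variant log odds ratios estimated by logistic regression.
    """
    p = genome.variants["eaf"].to_numpy()
    g = (genotypes - 2.0 * p) @ truth.alpha
    resid_sd = np.sqrt(max(1.0 - config.h2_exposure_liability, 1e-12))
    liability = g + rng.normal(0.0, resid_sd, size=len(g))
    thr = stats.norm.ppf(1.0 - config.prevalence)
    is_case = liability > thr

    n_case_avail = int(is_case.sum())
    if n_case_avail < config.n_cases:
        raise ValueError(
            f"only {n_case_avail} eligible cases in the simulated population, "
            f"need {config.n_cases}; increase the population size"
        )
    if (~is_case).sum() < config.n_controls:
        raise ValueError("not enough controls in the simulated population")

    case_idx = rng.choice(np.flatnonzero(is_case), config.n_cases, replace=False)
    ctrl_idx = rng.choice(np.flatnonzero(~is_case), config.n_controls, replace=False)
    sel = np.concatenate([case_idx, ctrl_idx])
    status = np.zeros(len(sel), dtype=bool)
    status[: config.n_cases] = True
    dos = genotypes[sel]

    beta, se = grouped_logistic_gwas(dos, status)
    eaf = dos.mean(axis=0) / 2.0
    info = _info_scores(genome.n_variants, config, rng)
    return _wald_table(genome.variants, beta, se, eaf, info,
                       config.n_cases + config.n_controls,
                       trait="exposure", trait_type="binary")


def simulate_confounder_gwas(config: SimConfig, genotypes: np.ndarray,
                             truth: SimTruth, genome: Genome,
                             rng: np.random.Generator) -> SumstatTable:
    """Linear GWAS of the continuous confounder (years-of-schooling analogue)."""
    p = genome.variants["eaf"].to_numpy()
    g = (genotypes - 2.0 * p) @ truth.gamma
    resid_sd = np.sqrt(max(1.0 - config.h2_confounder, 1e-12))
    y = g + rng.normal(0.0, resid_sd, size=len(g))
    beta, se = linear_gwas(genotypes, y)
    eaf = genotypes.mean(axis=0) / 2.0
    info = _info_scores(genome.n_variants, config, rng)
    return _wald_table(genome.variants, beta, se, eaf, info, len(y),
                       trait="confounder", trait_type="quantitative")


# ---------------------------------------------------------------------------
# discovery GWAS, summary (asymptotic) mode


def sample_exposure_sumstats(config: SimConfig, truth: SimTruth, genome: Genome,
                             rng: np.random.Generator) -> SumstatTable:
    """Draw case-control lnOR estimates from their asymptotic distribution.

    True marginal lnORs follow the small-effect linearization of the
    ascertained liability-threshold model; the sampling SE is the inverse
    Fisher information of the per-variant logistic slope.
    """
    n = config.n_cases + config.n_controls
    phi = config.n_cases / n
    w = phi * (1.0 - phi)
    dvar = genome.dosage_var
    se = np.sqrt(1.0 / (n * w * dvar))
    beta = truth.marginal_lnor + rng.normal(0.0, se)
    p = genome.variants["eaf"].to_numpy()
    eaf = rng.binomial(2 * n, p) / (2.0 * n)
    info = _info_scores(genome.n_variants, config, rng)
    return _wald_table(genome.variants, beta, se, eaf, info, n,
                       trait="exposure", trait_type="binary")


def sample_confounder_sumstats(config: SimConfig, truth: SimTruth, genome: Genome,
                               rng: np.random.Generator) -> SumstatTable:
    """Draw linear-GWAS confounder estimates from their asymptotic distribution."""
    n = config.n_confounder
    dvar = genome.dosage_var
    # residual variance of the marginal regression is ~ 1 for small effects
    se = np.sqrt(1.0 / (n * dvar))
    beta = truth.marginal_beta_confounder + rng.normal(0.0, se)
    p = genome.variants["eaf"].to_numpy()
    eaf = rng.binomial(2 * n, p) / (2.0 * n)
    info = _info_scores(genome.n_variants, config, rng)
    return _wald_table(genome.variants, beta, se, eaf, info, n,
                       trait="confounder", trait_type="quantitative")


# ---------------------------------------------------------------------------
# target cohort

_DEFAULT_DOMAINS = ["reading"] * 7 + ["spelling"] * 2 + ["other"] * 3 + ["viq"]


def default_domain_tags(n_outcomes: int) -> list[str]:
    """Outcome domain labels mirroring a 13-measure literacy/language battery
    (7 reading, 2 spelling, 3 other language measures, 1 composite verbal IQ)."""
    if n_outcomes == 13:
        return list(_DEFAULT_DOMAINS)
    tags = ["reading", "spelling", "other"] * ((n_outcomes + 2) // 3)
    return tags[:n_outcomes]


def simulate_cohort(config: SimConfig, genotypes: np.ndarray,
                    truth: SimTruth, genome: Genome,
                    rng: np.random.Generator) -> Cohort:
    """Simulate target-cohort phenotypes, covariates and missingness.

    Each outcome loads on the standardized exposure-liability genetic score
    with ``beta_direct`` and on the standardized confounder genetic score
    with ``beta_shared``, plus an outcome-specific polygenic background and
    residuals correlated across outcomes.  Raw scores additionally carry
    small sex / principal-component effects, which downstream preparation
    is expected to adjust out.  Missingness is Bernoulli with log-odds
    linear in the standardized exposure genetic score.
    """
    n = genotypes.shape[0]
    p = genome.variants["eaf"].to_numpy()
    xc = genotypes.astype(np.float32)
    xc -= (2.0 * p).astype(np.float32)
    s_a = (xc @ truth.alpha.astype(np.float32)).astype(float) \
        / max(truth.sd_score_exposure, 1e-12) \
        if truth.sd_score_exposure > 0 else np.zeros(n)
    s_c = (xc @ truth.gamma.astype(np.float32)).astype(float) \
        / max(truth.sd_score_confounder, 1e-12) \
        if truth.sd_score_confounder > 0 else np.zeros(n)

    k = config.n_outcomes
    rc = config.residual_corr()
    path_var = truth.path_variance
    bg_var = max(0.0, config.h2_outcome - path_var)
    resid_var = max(1.0 - path_var - bg_var, 0.05)
    chol = np.linalg.cholesky(rc)
    resid = rng.standard_normal((n, k)) @ chol.T * np.sqrt(resid_var)

    y = (config.beta_direct * s_a[:, None]
         + config.beta_shared * s_c[:, None] + resid)
    if truth.background is not None:
        y = y + (xc @ truth.background.astype(np.float32)).astype(float)

    sex = rng.integers(0, 2, size=n)
    pc1 = rng.standard_normal(n)
    pc2 = rng.standard_normal(n)
    # covariate effects on the raw scores (to be adjusted out downstream)
    y = y + 0.2 * (sex - 0.5)[:, None] + 0.05 * pc1[:, None] - 0.05 * pc2[:, None]

    b0 = np.log(config.missingness_rate / (1.0 - config.missingness_rate))
    logit = b0 + config.missingness_slope * s_a
    missing = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    # exposure-diagnosis analogue: liability above the population threshold
    resid_sd = np.sqrt(max(1.0 - config.h2_exposure_liability, 1e-12))
    liability = truth.sd_score_exposure * s_a + rng.normal(0.0, resid_sd, size=n)
    diagnosed = liability > stats.norm.ppf(1.0 - config.prevalence)

    tags = default_domain_tags(k)
    pheno = pd.DataFrame(y, columns=[f"outcome_{i+1:02d}" for i in range(k)])
    pheno[missing] = np.nan
    covs = pd.DataFrame({"sex": sex, "pc1": pc1, "pc2": pc2})
    return Cohort(dosages=genotypes, variants=genome.variants.copy(),
                  phenotypes=pheno, covariates=covs, missing=missing,
                  diagnosed=diagnosed, domain_tags=tags, truth=truth)


# ---------------------------------------------------------------------------
# orchestration


def simulate_study(config: SimConfig, n_ld_reference: int = 2000,
                   genome: Genome | None = None,
                   ld_reference: np.ndarray | None = None) -> StudyData:
    """Simulate the complete three-sample study.

    Discovery GWAS use the mode set in ``config.gwas_mode``; the target
    cohort and the LD reference panel are always individual-level.  All
    randomness derives from ``config.seed``.  A prebuilt ``genome`` (and
    optionally an LD reference panel) may be reused across replicates --
    the variant panel is then treated as fixed and only effects and data
    are redrawn.
    """
    rng = np.random.default_rng(config.seed)
    if genome is None:
        genome = build_genome(config, rng)
    truth = draw_effects(config, genome, rng)

    if config.gwas_mode == "summary":
        exposure = sample_exposure_sumstats(config, truth, genome, rng)
        confounder = sample_confounder_sumstats(config, truth, genome, rng)
    else:
        n_pop = int(np.ceil(config.n_cases / config.prevalence * 1.25))
        n_pop = max(n_pop, config.n_cases + config.n_controls)
        pop, _ = simulate_genotypes(config, n_pop, genome=genome, rng=rng)
        exposure = simulate_exposure_gwas(config, pop, truth, genome, rng)
        del pop
        conf_geno, _ = simulate_genotypes(config, config.n_confounder,
                                          genome=genome, rng=rng)
        confounder = simulate_confounder_gwas(config, conf_geno, truth,
                                              genome, rng)
        del conf_geno

    cohort_geno, _ = simulate_genotypes(config, config.n_cohort,
                                        genome=genome, rng=rng)
    cohort = simulate_cohort(config, cohort_geno, truth, genome, rng)
    if ld_reference is None:
        ld_reference, _ = simulate_genotypes(config, n_ld_reference,
                                             genome=genome, rng=rng)
    return StudyData(config=config, genome=genome, truth=truth,
                     exposure=exposure, confounder=confounder,
                     cohort=cohort, ld_reference=ld_reference)


def recovery_config(seed: int = 0, **overrides) -> SimConfig:
    """Study conditions for estimator-calibration experiments: a paired-block
    genome yielding ~2000 independent subthreshold instruments after
    clumping, with discovery sample sizes large enough that instrument-level
    measurement error is negligible (the regime assumed by the unweighted
    MVR standard errors)."""
    base = dict(
        n_variants=4000, n_blocks=2000, within_block_r=0.7,
        n_cases=2_000_000, n_controls=2_000_000, n_confounder=20_000_000,
        n_cohort=5000, n_outcomes=1, beta_direct=-0.3, beta_shared=-0.5,
        missingness_slope=0.0, missingness_rate=0.15, gwas_mode="summary",
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)
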