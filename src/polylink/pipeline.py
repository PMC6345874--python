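"""End-to-end orchestration: simulate/ingest -> prepare -> select
instruments -> polygenic scoring -> MVR decomposition -> meta-regression ->
attrition, with a provenance manifest.

The report bundle mirrors the analysis layout of the study design this
package implements: a polygenic-scoring association table per discovery
threshold, an MVR table for conservative and subthreshold instrument sets
including pooled (meta-regression) rows, an attrition report, and a
manifest recording seed, thresholds and instrument counts at each stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .instruments import (CONSERVATIVE_P, SUBTHRESHOLD_P, InstrumentSet,
                          LdReference, instrument_strength, select_instruments)
from .metareg import build_sampling_cov, domain_contrast, remlfit
from .mvr import MvrResult, mvr_fit, standardize_for_mvr
from .pgs import compute_pgs, missingness_association, pgs_association
from .simulate import Cohort, SimConfig, StudyData, grouped_logistic_gwas, \
    linear_gwas, simulate_study
from .sumstats import SumstatTable, harmonize, orient_to_risk
from .transforms import adjust_and_rank, effective_tests, experimentwide_alpha

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineReport", "run_pipeline", "prepare_phenotypes",
           "outcome_gwas", "make_fixture", "FIXTURES"]

POOLED_SETS = {
    "pooled_reading": {"reading"},
    "pooled_spelling": {"spelling"},
    # the composite verbal-intelligence measure is excluded from the
    # all-outcomes pool
    "pooled_all": {"reading", "spelling", "other"},
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``sim`` (a :class:`SimConfig`) or ``paths`` (a mapping
    with keys exposure, confounder, cohort_dosages, cohort_phenotypes,
    cohort_covariates, ld) must be supplied.
    """

    sim: SimConfig | None = None
    paths: dict | None = None
    pgs_threshold: float = 0.1
    conservative_p: float = CONSERVATIVE_P
    subthreshold_p: float = SUBTHRESHOLD_P
    clump_r2: float = 0.25
    clump_window_kb: float = 500.0
    fwer: float = 0.05
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.paths is None):
            raise ValueError("supply exactly one of sim or paths")


@dataclass
class PipelineReport:
    pgs_table: pd.DataFrame
    mvr_table: pd.DataFrame
    attrition: dict
    manifest: dict
    meta_results: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.pgs_table.to_csv(outdir / "pgs_associations.tsv", sep="\t",
                              index=False, float_format="%.6g")
        self.mvr_table.to_csv(outdir / "mvr_table.tsv", sep="\t",
                              index=False, float_format="%.6g")
        with open(outdir / "attrition.json", "w") as fh:
            json.dump(self.attrition, fh, indent=2)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(self.manifest, fh, indent=2, default=str)


def prepare_phenotypes(cohort: Cohort) -> pd.DataFrame:
    """Covariate-adjust and rank-inverse-normalize every outcome."""
    covs = cohort.covariates[["sex", "pc1", "pc2"]]
    out = {}
    for col in cohort.phenotypes.columns:
        out[col] = adjust_and_rank(cohort.phenotypes[col].to_numpy(), covs)
    return pd.DataFrame(out)


def outcome_gwas(cohort: Cohort, prepared: pd.DataFrame) -> dict[str, SumstatTable]:
    """Per-outcome linear GWAS on complete cases, canonical sumstat tables."""
    from .simulate import _wald_table  # shared table builder
    tables = {}
    for col in prepared.columns:
        y = prepared[col].to_numpy()
        keep = ~np.isnan(y)
        beta, se = linear_gwas(cohort.dosages[keep], y[keep])
        eaf = cohort.dosages[keep].mean(axis=0) / 2.0
        tables[col] = _wald_table(cohort.variants, beta, se, eaf,
                                  np.ones(len(beta)), int(keep.sum()),
                                  trait=col, trait_type="quantitative")
    return tables


def _mvr_for_set(inst: InstrumentSet, effects: pd.DataFrame,
                 outcome_cols: list[str], label: str) -> list[MvrResult]:
    sub = effects.loc[effects.index.intersection(inst.variant_ids)]
    results = []
    for col in outcome_cols:
        res = mvr_fit(sub["beta_exposure"], sub["beta_confounder"],
                      sub[f"beta_{col}"], intercept_mode="constrained",
                      outcome=col, instrument_label=label)
        results.append(res)
        sx, sc, sy = standardize_for_mvr(sub["beta_exposure"],
                                         sub["beta_confounder"],
                                         sub[f"beta_{col}"])
        results.append(mvr_fit(sx, sc, sy, intercept_mode="constrained",
                               outcome=col, instrument_label=label,
                               standardized=True))
    return results


def _pool(results: list[MvrResult], tags: dict[str, str],
          pheno_corr: pd.DataFrame, label: str,
          standardized: bool) -> list[dict]:
    """Random-effects pooled rows + domain contrasts for one instrument set."""
    rows = []
    res = [r for r in results if r.standardized == standardized]
    outcomes = [r.outcome for r in res]
    for side in ("exposure", "confounder"):
        est = np.array([getattr(r, f"beta_{side}") for r in res])
        ses = np.array([getattr(r, f"se_{side}") for r in res])
        for pool_name, domains in POOLED_SETS.items():
            sel = [i for i, o in enumerate(outcomes) if tags[o] in domains]
            if len(sel) < 2:
                continue
            names = [outcomes[i] for i in sel]
            corr = pheno_corr.loc[names, names].to_numpy()
            v = build_sampling_cov(ses[sel], corr)
            fit = remlfit(est[sel], v, label=pool_name)
            rows.append({
                "outcome": pool_name, "instruments": label, "side": side,
                "standardized": standardized,
                "beta": fit.pooled_beta, "se": fit.pooled_se,
                "p": fit.pooled_p, "tau2": fit.tau2,
                "q": fit.q_stat, "p_het": fit.p_het,
                "n_estimates": fit.n_estimates,
            })
        # literacy (reading+spelling) vs other-domain moderator contrast
        lit_sel = [i for i, o in enumerate(outcomes)
                   if tags[o] in {"reading", "spelling", "other"}]
        lit_tags = [tags[outcomes[i]] for i in lit_sel]
        if len(set(t in {"reading", "spelling"} for t in lit_tags)) == 2:
            names = [outcomes[i] for i in lit_sel]
            corr = pheno_corr.loc[names, names].to_numpy()
            v = build_sampling_cov(ses[lit_sel], corr)
            contrast = domain_contrast(
                est[lit_sel], v,
                ["literacy" if t in {"reading", "spelling"} else "other"
                 for t in lit_tags],
                focal="literacy", label="literacy_vs_other")
            rows.append({
                "outcome": "contrast_literacy_vs_other", "instruments": label,
                "side": side, "standardized": standardized,
                "beta": contrast.moderator_beta, "se": contrast.moderator_se,
                "p": contrast.p_mod, "tau2": contrast.tau2,
                "q": contrast.q_stat, "p_het": contrast.p_het,
                "n_estimates": contrast.n_estimates,
            })
    return rows


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the full analysis and return the report bundle."""
    if config.paths is not None:
        study = load_study(config.paths)
    else:
        study = simulate_study(config.sim)
    return run_pipeline_on_study(study, config)


def load_study(paths: dict) -> StudyData:
    """Assemble a study from files (the bundle ``polylink simulate`` writes).

    Required keys: ``exposure`` and ``confounder`` (canonical sumstats
    TSV), ``cohort_dosages`` (individuals x variants TSV, header =
    variant ids) and ``cohort_phenotypes`` (outcome_* columns plus sex,
    pc1, pc2, missing and optionally diagnosed).  Optional ``ld`` points
    to reference-panel dosages in the same layout as ``cohort_dosages``;
    without it the cohort itself serves as the LD reference.
    """
    from .simulate import Cohort, Genome, SimConfig, default_domain_tags
    from .sumstats import read_sumstats

    required = {"exposure", "confounder", "cohort_dosages",
                "cohort_phenotypes"}
    missing_keys = required - set(paths)
    if missing_keys:
        raise ValueError(f"load_study: missing path(s): "
                         f"{', '.join(sorted(missing_keys))}")

    exposure = read_sumstats(paths["exposure"], trait="exposure",
                             trait_type="binary")
    confounder = read_sumstats(paths["confounder"], trait="confounder",
                               trait_type="quantitative")

    dos_df = pd.read_csv(paths["cohort_dosages"], sep="\t")
    pheno = pd.read_csv(paths["cohort_phenotypes"], sep="\t")
    outcome_cols = [c for c in pheno.columns if c.startswith("outcome")]
    covs = pheno[["sex", "pc1", "pc2"]].copy()
    missing = pheno["missing"].to_numpy(dtype=bool) if "missing" in pheno \
        else pheno[outcome_cols].isna().all(axis=1).to_numpy()
    diagnosed = pheno["diagnosed"].to_numpy(dtype=bool) \
        if "diagnosed" in pheno else np.zeros(len(pheno), dtype=bool)

    variants = exposure.data[["variant_id", "chr", "pos", "effect_allele",
                              "other_allele", "eaf"]].copy()
    variants = variants[variants["variant_id"].isin(dos_df.columns)]
    variants = variants.reset_index(drop=True)
    variants["block"] = np.arange(len(variants))
    if len(variants) == 0:
        raise ValueError("load_study: no exposure variants present in the "
                         "cohort dosage table")
    dosages = dos_df[variants["variant_id"]].to_numpy(dtype=np.float32)

    genome = Genome(variants=variants,
                    block_index=[np.array([i]) for i in range(len(variants))],
                    dosage_cov_blocks=[], within_block_r=0.0)
    cohort = Cohort(dosages=dosages, variants=variants,
                    phenotypes=pheno[outcome_cols], covariates=covs,
                    missing=missing, diagnosed=diagnosed,
                    domain_tags=default_domain_tags(len(outcome_cols)),
                    truth=None)
    if "ld" in paths and paths["ld"]:
        ld_df = pd.read_csv(paths["ld"], sep="\t")
        ld_ref = ld_df[variants["variant_id"]].to_numpy(dtype=np.float32)
    else:
        ld_ref = dosages
    cfg = SimConfig(n_variants=len(variants), n_blocks=len(variants),
                    n_cohort=len(pheno), n_outcomes=len(outcome_cols))
    return StudyData(config=cfg, genome=genome, exposure=exposure,
                     confounder=confounder, cohort=cohort,
                     ld_reference=ld_ref, truth=None)


def run_pipeline_on_study(study: StudyData, config: RunConfig,
                          ) -> PipelineReport:
    cohort = study.cohort
    prepared = prepare_phenotypes(cohort)
    pheno_corr = prepared.corr()
    m_eff, _ = effective_tests(pheno_corr.to_numpy())
    alpha_3sf, alpha_full = experimentwide_alpha(config.fwer, round(m_eff))

    ld = LdReference(study.ld_reference,
                     list(study.genome.variants["variant_id"]))

    # --- polygenic scoring -------------------------------------------------
    risk_oriented = orient_to_risk(study.exposure)
    scoring_set = select_instruments(
        risk_oriented, ld, p_max=config.pgs_threshold, label="pgs_scoring",
        r2_max=config.clump_r2, window_kb=config.clump_window_kb)
    scoring_table = SumstatTable(trait="scoring", trait_type="binary",
                                 data=scoring_set.variants)
    pgs = compute_pgs(cohort.dosages, cohort.variants, scoring_table,
                      p_threshold=config.pgs_threshold)
    tags = dict(zip(prepared.columns, cohort.domain_tags))
    pgs_rows = []
    for col in prepared.columns:
        for mask, variant in ((None, "all"),
                              (cohort.diagnosed, "excl_diagnosed")):
            r = pgs_association(prepared[col].to_numpy(), pgs,
                                exclusion_mask=mask, outcome_label=col,
                                p_threshold=config.pgs_threshold,
                                discovery=study.exposure.trait)
            pgs_rows.append({
                "outcome": col, "domain": tags[col], "sample": variant,
                "beta": r.beta, "se": r.se, "p": r.pvalue, "r2": r.r2,
                "n": r.n, "p_threshold": r.p_threshold,
                "pass_experimentwide": r.pvalue < alpha_full,
            })
    pgs_table = pd.DataFrame(pgs_rows)

    # --- MVR decomposition -------------------------------------------------
    out_tables = outcome_gwas(cohort, prepared)
    eff = harmonize([study.exposure, study.confounder] +
                    [out_tables[c] for c in prepared.columns])

    conservative = select_instruments(
        study.exposure, ld, p_max=config.conservative_p, label="conservative",
        r2_max=config.clump_r2, window_kb=config.clump_window_kb)
    subthreshold = select_instruments(
        study.exposure, ld, p_max=config.subthreshold_p, label="subthreshold",
        r2_max=config.clump_r2, window_kb=config.clump_window_kb)

    mvr_results: list[MvrResult] = []
    pooled_rows: list[dict] = []
    set_counts = {}
    for inst in (conservative, subthreshold):
        set_counts[inst.label] = len(inst)
        if len(inst) < 3:
            logger.warning("instrument set %s has %d variants; skipping MVR",
                           inst.label, len(inst))
            continue
        res = _mvr_for_set(inst, eff, list(prepared.columns), inst.label)
        mvr_results.extend(res)
        for std in (False, True):
            pooled_rows.extend(_pool(res, tags, pheno_corr, inst.label, std))

    per_outcome_rows = [r.to_row() for r in mvr_results]
    mvr_table = pd.concat([
        pd.DataFrame(per_outcome_rows),
        pd.DataFrame(pooled_rows),
    ], ignore_index=True) if pooled_rows or per_outcome_rows else pd.DataFrame()

    # --- attrition ---------------------------------------------------------
    slope, slope_se, slope_p = missingness_association(cohort.missing, pgs)
    miss_lnor, miss_se = grouped_logistic_gwas(cohort.dosages, cohort.missing)
    attrition: dict = {
        "pgs_logodds_per_sd": slope, "pgs_se": slope_se, "pgs_p": slope_p,
        "missing_fraction": float(cohort.missing.mean()),
    }
    if len(subthreshold) >= 3:
        from .simulate import _wald_table
        miss_table = _wald_table(cohort.variants, miss_lnor, miss_se,
                                 cohort.dosages.mean(axis=0) / 2.0,
                                 np.ones(len(miss_lnor)),
                                 len(cohort.missing),
                                 trait="missingness", trait_type="binary")
        miss_eff = harmonize([study.exposure, study.confounder, miss_table])
        sub_eff = miss_eff.loc[miss_eff.index.intersection(
            subthreshold.variant_ids)]
        mres = mvr_fit(sub_eff["beta_exposure"], sub_eff["beta_confounder"],
                       sub_eff["beta_missingness"], outcome="missingness",
                       instrument_label="subthreshold")
        attrition["mvr_beta_exposure"] = mres.beta_exposure
        attrition["mvr_se_exposure"] = mres.se_exposure
        attrition["mvr_p_exposure"] = mres.p_exposure

    manifest = {
        "polylink_version": __version__,
        "seed": study.config.seed,
        "sim_config": {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                       for k, v in vars(study.config).items()},
        "pgs_threshold": config.pgs_threshold,
        "conservative_p": config.conservative_p,
        "subthreshold_p": config.subthreshold_p,
        "clump": {"r2": config.clump_r2, "window_kb": config.clump_window_kb},
        "m_eff": m_eff,
        "experimentwide_alpha": alpha_3sf,
        "experimentwide_alpha_full": alpha_full,
        "instrument_counts": set_counts,
        "scoring_variants": len(scoring_set),
        "mean_f": {
            "conservative": instrument_strength(conservative).attrs["mean_f"],
            "subthreshold": instrument_strength(subthreshold).attrs["mean_f"],
        },
        "harmonized_variants": len(eff),
    }

    report = PipelineReport(pgs_table=pgs_table, mvr_table=mvr_table,
                            attrition=attrition, manifest=manifest)
    if config.outdir:
        report.write(config.outdir)
    return report


# ---------------------------------------------------------------------------
# fixture registry (tiny deterministic datasets for tests and examples)


def _fixture_mvr15() -> pd.DataFrame:
    rng = np.random.default_rng(7)
    bx = rng.normal(0.0, 0.05, 15)
    bc = -0.5 * bx + rng.normal(0.0, 0.02, 15)
    by = -0.3 * bx + 0.8 * bc + rng.normal(0.0, 0.01, 15)
    return pd.DataFrame({"variant_id": [f"fx_{i:02d}" for i in range(15)],
                         "beta_exposure": bx, "beta_confounder": bc,
                         "beta_outcome": by})


def _fixture_clump12() -> tuple[pd.DataFrame, dict]:
    """12 variants in 3 LD blocks on one chromosome."""
    rng = np.random.default_rng(11)
    pos = np.concatenate([[1_000_000 + i * 50_000 for i in range(4)],
                          [3_000_000 + i * 50_000 for i in range(4)],
                          [5_000_000 + i * 50_000 for i in range(4)]])
    df = pd.DataFrame({
        "variant_id": [f"cl_{i:02d}" for i in range(12)],
        "chr": "1", "pos": pos,
        "effect_allele": "A", "other_allele": "G",
        "beta": rng.normal(0, 0.1, 12), "se": 0.02,
        "pvalue": rng.uniform(1e-9, 0.01, 12),
        "eaf": rng.uniform(0.1, 0.5, 12), "info": 0.95, "n": 10_000,
    })
    pairs = {}
    ids = list(df["variant_id"])
    for b in range(3):
        for i in range(4):
            for j in range(i + 1, 4):
                pairs[(ids[4 * b + i], ids[4 * b + j])] = 0.6 if j == i + 1 else 0.3
    return df, pairs


def _fixture_null_cohort() -> SimConfig:
    return SimConfig(n_variants=200, n_blocks=40, n_cases=150, n_controls=150,
                     n_confounder=400, n_cohort=400, n_outcomes=3,
                     beta_direct=0.0, beta_shared=0.0,
                     h2_exposure_liability=0.0, h2_confounder=0.0,
                     h2_outcome=0.0, gwas_mode="individual", seed=13)


FIXTURES = {
    "mvr-15": _fixture_mvr15,
    "clump-12": _fixture_clump12,
    "null-cohort": _fixture_null_cohort,
}


def make_fixture(name: str):
    """Deterministic tiny datasets used by the test suite and examples."""
    if name not in FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: "
                       f"{sorted(FIXTURES)}")
    return FIXTURES[name]()
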