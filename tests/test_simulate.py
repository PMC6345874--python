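"""Synthetic three-sample study generator: genotypes, GWAS, cohort, truth."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats

from polylink.simulate import (SimConfig, build_genome, draw_effects,
                               grouped_logistic_gwas, linear_gwas,
                               sample_confounder_sumstats,
                               sample_exposure_sumstats, simulate_cohort,
                               simulate_confounder_gwas,
                               simulate_exposure_gwas, simulate_genotypes,
                               simulate_study)


class TestConfigValidation:
    def test_invalid_prevalence(self):
        with pytest.raises(ValueError, match="prevalence"):
            SimConfig(prevalence=1.5)

    def test_invalid_rg(self):
        with pytest.raises(ValueError, match="rg"):
            SimConfig(rg_exposure_confounder=1.2)

    def test_invalid_eaf_range(self):
        with pytest.raises(ValueError, match="eaf_range"):
            SimConfig(eaf_range=(0.0, 0.6))

    def test_non_pd_residual_corr_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99],
                        [0.99, 1.0, 0.99],
                        [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="positive-definite"):
            SimConfig(n_outcomes=3, outcome_residual_corr=bad)


class TestGenotypes:
    def test_independent_variants_when_no_ld(self):
        cfg = SimConfig(n_variants=20, n_blocks=20, within_block_r=0.0, seed=1)
        dos, _ = simulate_genotypes(cfg, 5000)
        corr = np.corrcoef(dos.astype(float), rowvar=False)
        off = corr[~np.eye(20, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_half_frequency_gives_mean_dosage_one(self):
        cfg = SimConfig(n_variants=10, n_blocks=10, eaf_range=(0.5, 0.5),
                        within_block_r=0.0, seed=2)
        dos, _ = simulate_genotypes(cfg, 20_000)
        np.testing.assert_allclose(dos.mean(axis=0), 1.0, atol=0.03)

    def test_within_block_dosage_correlation_near_target(self):
        # two blocks of three at r = 0.6, n = 10000
        cfg = SimConfig(n_variants=6, n_blocks=2, within_block_r=0.6, seed=3)
        dos, var = simulate_genotypes(cfg, 10_000)
        x = dos.astype(float)
        for block in (0, 1):
            idx = np.flatnonzero(var["block"] == block)
            for i in range(len(idx)):
                for j in range(i + 1, len(idx)):
                    r = np.corrcoef(x[:, idx[i]], x[:, idx[j]])[0, 1]
                    assert 0.45 <= r <= 0.75
        # across blocks: independent
        r_cross = np.corrcoef(x[:, 0], x[:, 3])[0, 1]
        assert abs(r_cross) < 0.05

    def test_sample_frequencies_match_eaf(self):
        cfg = SimConfig(n_variants=30, n_blocks=10, seed=4)
        dos, var = simulate_genotypes(cfg, 8000)
        emp = dos.mean(axis=0) / 2
        # binomial tolerance at n = 8000 haplotype pairs
        se = np.sqrt(var["eaf"] * (1 - var["eaf"]) / (2 * 8000))
        assert (np.abs(emp - var["eaf"]) < 6 * se + 0.01).all()

    def test_block_layout_respects_clump_window(self):
        cfg = SimConfig(n_variants=50, n_blocks=10, seed=5)
        g = build_genome(cfg)
        v = g.variants
        for _, sub in v.groupby(["chr", "block"]):
            assert sub["pos"].max() - sub["pos"].min() < 500_000
        for c, sub in v.groupby("chr"):
            starts = sub.groupby("block")["pos"].min().sort_values()
            ends = sub.groupby("block")["pos"].max().sort_values()
            gaps = starts.to_numpy()[1:] - ends.to_numpy()[:-1]
            assert (gaps > 500_000).all()

    def test_seed_reproducibility(self):
        cfg = SimConfig(n_variants=40, n_blocks=8, seed=6)
        a, _ = simulate_genotypes(cfg, 200)
        b, _ = simulate_genotypes(cfg, 200)
        np.testing.assert_array_equal(a, b)


class TestGroupedLogistic:
    def test_matches_statsmodels_mle(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(7)
        n = 2000
        dos = rng.binomial(2, 0.3, size=(n, 3)).astype(np.uint8)
        eta = -0.5 + 0.4 * dos[:, 0] - 0.2 * dos[:, 1]
        y = rng.random(n) < 1 / (1 + np.exp(-eta))
        beta, se = grouped_logistic_gwas(dos, y)
        for j in range(3):
            fit = sm.Logit(y.astype(float),
                           sm.add_constant(dos[:, j].astype(float))).fit(disp=0)
            assert beta[j] == pytest.approx(fit.params[1], abs=1e-6)
            assert se[j] == pytest.approx(fit.bse[1], abs=1e-6)


class TestExposureGwas:
    @pytest.fixture(scope="class")
    def cfg(self):
        return SimConfig(n_variants=60, n_blocks=60, within_block_r=0.0,
                         n_cases=250, n_controls=250, prevalence=0.1,
                         h2_exposure_liability=0.3, gwas_mode="individual",
                         seed=8)

    def test_null_variants_type_one_error(self):
        cfg = SimConfig(n_variants=2000, n_blocks=2000, within_block_r=0.0,
                        n_cases=250, n_controls=250, prevalence=0.1,
                        h2_exposure_liability=0.0, h2_confounder=0.0,
                        seed=9, gwas_mode="individual")
        rng = np.random.default_rng(9)
        genome = build_genome(cfg, rng)
        truth = draw_effects(cfg, genome, rng)
        pop, _ = simulate_genotypes(cfg, 4000, genome=genome, rng=rng)
        ss = simulate_exposure_gwas(cfg, pop, truth, genome, rng)
        frac = (ss.data["pvalue"] < 0.05).mean()
        assert 0.03 < frac < 0.07

    def test_polygenic_inflation_with_heritable_liability(self, cfg):
        rng = np.random.default_rng(10)
        genome = build_genome(cfg, rng)
        truth = draw_effects(cfg, genome, rng)
        pop, _ = simulate_genotypes(cfg, 4000, genome=genome, rng=rng)
        ss = simulate_exposure_gwas(cfg, pop, truth, genome, rng)
        chi2 = (ss.data["beta"] / ss.data["se"]) ** 2
        assert chi2.mean() > 1.0

    def test_insufficient_cases_explicit_failure(self, cfg):
        rng = np.random.default_rng(11)
        genome = build_genome(cfg, rng)
        truth = draw_effects(cfg, genome, rng)
        pop, _ = simulate_genotypes(cfg, 500, genome=genome, rng=rng)
        with pytest.raises(ValueError, match="eligible cases"):
            simulate_exposure_gwas(cfg, pop, truth, genome, rng)

    def test_info_scores_in_range_with_low_fraction(self, cfg):
        rng = np.random.default_rng(12)
        genome = build_genome(cfg, rng)
        truth = draw_effects(cfg, genome, rng)
        pop, _ = simulate_genotypes(cfg, 4000, genome=genome, rng=rng)
        ss = simulate_exposure_gwas(cfg, pop, truth, genome, rng)
        info = ss.data["info"]
        assert ((info > 0) & (info <= 1)).all()
        assert (info < 0.8).sum() == round(cfg.low_info_fraction * cfg.n_variants)


class TestConfounderGwas:
    def _effects(self, rg, seed=13, m=2000):
        cfg = SimConfig(n_variants=m, n_blocks=m, within_block_r=0.0,
                        rg_exposure_confounder=rg, seed=seed)
        genome = build_genome(cfg, np.random.default_rng(seed))
        truth = draw_effects(cfg, genome, np.random.default_rng(seed + 1))
        return truth

    def test_null_rg_gives_uncorrelated_effects(self):
        truth = self._effects(0.0)
        assert abs(np.corrcoef(truth.alpha, truth.gamma)[0, 1]) < 0.05

    def test_target_rg_recovered(self):
        truth = self._effects(-0.53)
        r = np.corrcoef(truth.alpha, truth.gamma)[0, 1]
        assert -0.60 <= r <= -0.46

    def test_perfect_rg_gives_proportional_effects(self):
        truth = self._effects(1.0)
        ratio = truth.gamma / truth.alpha
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-8)

    def test_linear_gwas_matches_closed_form(self):
        rng = np.random.default_rng(14)
        dos = rng.binomial(2, 0.4, size=(800, 4)).astype(np.uint8)
        y = rng.standard_normal(800)
        beta, se = linear_gwas(dos, y)
        for j in range(4):
            sl, icpt, *_ = stats.linregress(dos[:, j].astype(float), y)
            assert beta[j] == pytest.approx(sl, abs=1e-5)


class TestSummaryMode:
    """Asymptotic summary sampling agrees with individual-level GWAS."""

    def test_exposure_estimates_center_on_marginal_lnor(self):
        cfg = SimConfig(n_variants=150, n_blocks=50, n_cases=1500,
                        n_controls=1500, prevalence=0.1,
                        gwas_mode="individual", seed=15)
        rng = np.random.default_rng(15)
        genome = build_genome(cfg, rng)
        truth = draw_effects(cfg, genome, rng)
        pop, _ = simulate_genotypes(cfg, 22_000, genome=genome, rng=rng)
        ss = simulate_exposure_gwas(cfg, pop, truth, genome, rng)
        # regression of individual-mode estimates on the analytic marginals
        # should have slope ~1 (the linearized truth the summary mode uses)
        slope = np.polyfit(truth.marginal_lnor, ss.data["beta"], 1)[0]
        assert 0.85 < slope < 1.15
        # and the summary-mode SEs should match the logistic SEs
        ss2 = sample_exposure_sumstats(
            replace(cfg, n_cases=1500, n_controls=1500), truth, genome,
            np.random.default_rng(16))
        ratio = ss2.data["se"] / ss.data["se"]
        assert 0.8 < ratio.median() < 1.2

    def test_confounder_estimates_center_on_marginal_beta(self):
        cfg = SimConfig(n_variants=150, n_blocks=50, n_confounder=8000,
                        gwas_mode="individual", seed=17)
        rng = np.random.default_rng(17)
        genome = build_genome(cfg, rng)
        truth = draw_effects(cfg, genome, rng)
        geno, _ = simulate_genotypes(cfg, 8000, genome=genome, rng=rng)
        ss = simulate_confounder_gwas(cfg, geno, truth, genome, rng)
        slope = np.polyfit(truth.marginal_beta_confounder, ss.data["beta"], 1)[0]
        assert 0.9 < slope < 1.1


class TestCohort:
    def _cohort(self, cfg, seed=18):
        rng = np.random.default_rng(seed)
        genome = build_genome(cfg, rng)
        truth = draw_effects(cfg, genome, rng)
        geno, _ = simulate_genotypes(cfg, cfg.n_cohort, genome=genome, rng=rng)
        return simulate_cohort(cfg, geno, truth, genome, rng), truth, genome

    def test_null_effects_give_null_score_correlations(self):
        cfg = SimConfig(n_variants=100, n_blocks=50, n_cohort=2000,
                        n_outcomes=3, beta_direct=0.0, beta_shared=0.0,
                        h2_outcome=0.0, seed=19)
        cohort, truth, genome = self._cohort(cfg)
        p = genome.variants["eaf"].to_numpy()
        s_a = (cohort.dosages - 2 * p) @ truth.alpha
        for col in cohort.phenotypes.columns:
            y = cohort.phenotypes[col].to_numpy()
            keep = ~np.isnan(y)
            r = np.corrcoef(y[keep], s_a[keep])[0, 1]
            assert abs(r) < 0.06

    def test_outcome_heritability_matches_target(self):
        cfg = SimConfig(n_variants=200, n_blocks=100, n_cohort=4000,
                        n_outcomes=2, h2_outcome=0.6, missingness_rate=0.01,
                        seed=20)
        cohort, truth, genome = self._cohort(cfg)
        p = genome.variants["eaf"].to_numpy()
        xc = cohort.dosages - 2 * p
        total_g = (truth.beta_direct * (xc @ truth.alpha) / truth.sd_score_exposure
                   + truth.beta_shared * (xc @ truth.gamma) / truth.sd_score_confounder
                   + xc @ truth.background[:, 0])
        y = cohort.phenotypes["outcome_01"].to_numpy()
        keep = ~np.isnan(y)
        r2 = np.corrcoef(y[keep], total_g[keep])[0, 1] ** 2
        assert abs(r2 - cfg.h2_outcome) < 0.08

    def test_missingness_null_slope_ci_coverage(self):
        import statsmodels.api as sm
        cfg = SimConfig(n_variants=60, n_blocks=30, n_cohort=900,
                        n_outcomes=2, missingness_slope=0.0, seed=21)
        rng = np.random.default_rng(21)
        genome = build_genome(cfg, rng)
        covered = 0
        n_reps = 60
        for _ in range(n_reps):
            truth = draw_effects(cfg, genome, rng)
            geno, _ = simulate_genotypes(cfg, cfg.n_cohort, genome=genome,
                                         rng=rng)
            cohort = simulate_cohort(cfg, geno, truth, genome, rng)
            p = genome.variants["eaf"].to_numpy()
            s = (geno - 2 * p) @ truth.alpha / truth.sd_score_exposure
            fit = sm.Logit(cohort.missing.astype(float),
                           sm.add_constant(s)).fit(disp=0)
            lo, hi = fit.conf_int()[1]
            covered += lo <= 0.0 <= hi
        assert covered / n_reps >= 0.90

    def test_missingness_rate_near_target(self):
        cfg = SimConfig(n_variants=60, n_blocks=30, n_cohort=4000,
                        n_outcomes=2, missingness_rate=0.15, seed=22)
        cohort, *_ = self._cohort(cfg)
        assert abs(cohort.missing.mean() - 0.15) < 0.03


class TestStudyDeterminism:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig(n_variants=80, n_blocks=20, n_cases=150,
                        n_controls=150, n_confounder=400, n_cohort=300,
                        n_outcomes=2, gwas_mode="individual", seed=23)
        a = simulate_study(cfg, n_ld_reference=200)
        b = simulate_study(cfg, n_ld_reference=200)
        pd.testing.assert_frame_equal(a.exposure.data, b.exposure.data)
        pd.testing.assert_frame_equal(a.confounder.data, b.confounder.data)
        pd.testing.assert_frame_equal(a.cohort.phenotypes, b.cohort.phenotypes)
        np.testing.assert_array_equal(a.cohort.dosages, b.cohort.dosages)
        np.testing.assert_array_equal(a.ld_reference, b.ld_reference)
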