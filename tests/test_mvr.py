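"""Multivariable effect-decomposition regression vs closed-form oracles."""

import numpy as np
import pytest
from scipy import stats

from polylink.mvr import (intercept_evidence, mvr_fit, reverse_mvr,
                          standardize_for_mvr)
from polylink.pipeline import make_fixture


def normal_equations_oracle(X: np.ndarray, y: np.ndarray):
    """Brute-force (X'X)^-1 X'y with textbook coefficient SEs."""
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ y
    resid = y - X @ coef
    dof = len(y) - X.shape[1]
    s2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(s2 * xtx_inv))
    t = coef / se
    p = 2 * stats.t.sf(np.abs(t), dof)
    return coef, se, p


class TestMvrFit:
    def test_constrained_matches_normal_equations_oracle(self, mvr15):
        fit = mvr_fit(mvr15["beta_exposure"], mvr15["beta_confounder"],
                      mvr15["beta_outcome"], intercept_mode="constrained")
        X = mvr15[["beta_exposure", "beta_confounder"]].to_numpy()
        coef, se, p = normal_equations_oracle(X, mvr15["beta_outcome"].to_numpy())
        assert fit.beta_exposure == pytest.approx(coef[0], abs=1e-10)
        assert -fit.beta_confounder == pytest.approx(coef[1], abs=1e-10)
        assert fit.se_exposure == pytest.approx(se[0], abs=1e-10)
        assert fit.se_confounder == pytest.approx(se[1], abs=1e-10)
        assert fit.p_exposure == pytest.approx(p[0], rel=1e-8)

    def test_free_intercept_matches_oracle(self, mvr15):
        fit = mvr_fit(mvr15["beta_exposure"], mvr15["beta_confounder"],
                      mvr15["beta_outcome"], intercept_mode="free")
        X = np.column_stack([np.ones(len(mvr15)),
                             mvr15[["beta_exposure", "beta_confounder"]]])
        coef, se, _ = normal_equations_oracle(X, mvr15["beta_outcome"].to_numpy())
        assert fit.intercept == pytest.approx(coef[0], abs=1e-10)
        assert fit.beta_exposure == pytest.approx(coef[1], abs=1e-10)
        assert -fit.beta_confounder == pytest.approx(coef[2], abs=1e-10)
        assert fit.intercept_se == pytest.approx(se[0], abs=1e-10)

    def test_oracle_agreement_on_random_fixtures(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            n = rng.integers(5, 60)
            bx = rng.normal(0, 0.1, n)
            bc = rng.normal(0, 0.2, n)
            by = rng.normal(0, 0.05, n)
            fit = mvr_fit(bx, bc, by)
            coef, se, _ = normal_equations_oracle(np.column_stack([bx, bc]), by)
            np.testing.assert_allclose(
                [fit.beta_exposure, -fit.beta_confounder], coef, atol=1e-10)
            np.testing.assert_allclose(
                [fit.se_exposure, fit.se_confounder], se, atol=1e-10)

    def test_null_outcome_gives_zero_slopes_positive_ses(self):
        rng = np.random.default_rng(22)
        bx, bc = rng.normal(0, 1, 20), rng.normal(0, 1, 20)
        fit = mvr_fit(bx, bc, np.zeros(20))
        assert fit.beta_exposure == pytest.approx(0.0, abs=1e-12)
        assert fit.beta_confounder == pytest.approx(0.0, abs=1e-12)
        # a perfectly null outcome has zero residual variance, so the OLS
        # standard errors collapse to exactly zero
        assert fit.se_exposure == 0.0 and fit.se_confounder == 0.0
        fit2 = mvr_fit(bx, bc, np.zeros(20) + rng.normal(0, 1e-3, 20))
        assert fit2.se_exposure > 0 and fit2.se_confounder > 0

    def test_exact_recovery_when_outcome_proportional_to_exposure(self):
        rng = np.random.default_rng(23)
        bx = rng.normal(0, 1, 30)
        bc = rng.normal(0, 1, 30)
        bc -= bx * (bc @ bx) / (bx @ bx)   # orthogonalize
        fit = mvr_fit(bx, bc, 0.7 * bx)
        assert fit.beta_exposure == pytest.approx(0.7, abs=1e-10)
        assert fit.beta_confounder == pytest.approx(0.0, abs=1e-10)

    def test_sign_convention_flip(self):
        """Flipping all confounder effect signs flips reported beta exactly."""
        rng = np.random.default_rng(24)
        bx, bc = rng.normal(0, 1, 25), rng.normal(0, 1, 25)
        by = rng.normal(0, 1, 25)
        a = mvr_fit(bx, bc, by)
        b = mvr_fit(bx, -bc, by)
        assert b.beta_confounder == pytest.approx(-a.beta_confounder, abs=1e-12)
        assert b.beta_exposure == pytest.approx(a.beta_exposure, abs=1e-12)

    def test_collinear_predictors_rejected(self):
        rng = np.random.default_rng(25)
        bx = rng.normal(0, 1, 20)
        with pytest.raises(ValueError, match="collinear"):
            mvr_fit(bx, bx * 2.0 + 1e-9 * rng.normal(size=20),
                    rng.normal(0, 1, 20))

    def test_too_few_instruments_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            mvr_fit([0.1, 0.2], [0.3, 0.1], [0.0, 0.1])


class TestStandardize:
    def test_single_predictor_scaling_identity(self):
        """Raw slope c with predictor SD s_x and outcome SD s_y implies a
        standardized slope of c * s_x / s_y."""
        rng = np.random.default_rng(26)
        x = rng.normal(0, 0.3, 40)
        ortho = rng.normal(0, 1e-6, 40)  # near-degenerate second predictor
        y = 0.5 * x + rng.normal(0, 0.1, 40)
        sx, sy = x.std(ddof=1), y.std(ddof=1)
        raw = np.linalg.lstsq(x[:, None], y, rcond=None)[0][0]
        xs, _, ys = standardize_for_mvr(x, ortho + 1.0, y)
        std_slope = np.linalg.lstsq(xs[:, None], ys, rcond=None)[0][0]
        assert std_slope == pytest.approx(raw * sx / sy, rel=1e-6)

    def test_unit_variance_vectors_unchanged(self):
        rng = np.random.default_rng(27)
        vecs = [rng.standard_normal(50) for _ in range(3)]
        vecs = [v / v.std(ddof=1) for v in vecs]
        out = standardize_for_mvr(*vecs)
        for got, orig in zip(out, vecs):
            np.testing.assert_allclose(got, orig, atol=1e-12)

    def test_constant_vector_rejected(self):
        rng = np.random.default_rng(28)
        with pytest.raises(ValueError, match="zero-variance"):
            standardize_for_mvr(rng.normal(size=10), np.full(10, 0.3),
                                rng.normal(size=10))

    def test_scaling_preserves_origin_by_default(self):
        rng = np.random.default_rng(29)
        v = rng.normal(2.0, 1.0, 30)   # nonzero mean
        out, *_ = standardize_for_mvr(v, v + rng.normal(size=30),
                                      rng.normal(size=30))
        assert out.mean() != pytest.approx(0.0, abs=0.1)


class TestInterceptEvidence:
    def test_null_intercept_p_uniform(self):
        """Data generated through the origin: intercept P is ~Uniform(0,1)
        (Kolmogorov-Smirnov over 200 simulations)."""
        rng = np.random.default_rng(30)
        pvals = []
        for _ in range(200):
            bx = rng.normal(0, 0.1, 40)
            bc = rng.normal(0, 0.1, 40)
            by = 0.5 * bx - 0.2 * bc + rng.normal(0, 0.05, 40)
            pvals.append(intercept_evidence(bx, bc, by)["intercept_p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_injected_intercept_detected_with_power(self):
        """An intercept of half the effect-noise scale is detected with
        >80% power at ~2700 instruments."""
        rng = np.random.default_rng(31)
        hits = 0
        n_sims = 50
        for _ in range(n_sims):
            n = 2700
            bx = rng.normal(0, 0.1, n)
            bc = rng.normal(0, 0.1, n)
            noise_sd = 0.05
            by = 0.5 * noise_sd + 0.3 * bx + rng.normal(0, noise_sd, n)
            ev = intercept_evidence(bx, bc, by)
            hits += ev["intercept_p"] < 0.05
        assert hits / n_sims > 0.8

    def test_constrained_and_free_agree_on_origin_true_data(self):
        rng = np.random.default_rng(32)
        bx = rng.normal(0, 0.2, 100)
        bc = rng.normal(0, 0.2, 100)
        by = -0.4 * bx + 0.6 * bc + rng.normal(0, 0.02, 100)
        ev = intercept_evidence(bx, bc, by)
        con, fre = ev["constrained"], ev["free"]
        assert abs(con.beta_exposure - fre.beta_exposure) < 2 * fre.se_exposure
        assert abs(con.beta_confounder - fre.beta_confounder) < 2 * fre.se_confounder


class TestReverseMvr:
    def test_roles_swap_consistently(self):
        rng = np.random.default_rng(33)
        bx, bc = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        by = rng.normal(0, 1, 30)
        fwd = mvr_fit(bx, bc, by)
        rev = reverse_mvr(bc, bx, by)
        # swapped roles: reverse exposure slope equals forward's unflipped
        # confounder slope
        assert rev.beta_exposure == pytest.approx(-fwd.beta_confounder,
                                                  abs=1e-12)
        assert -rev.beta_confounder == pytest.approx(fwd.beta_exposure,
                                                     abs=1e-12)

    def test_null_confounder_gives_null_conditional_slope(self):
        rng = np.random.default_rng(34)
        bx = rng.normal(0, 0.3, 500)
        bc = rng.normal(0, 0.3, 500)     # confounder unrelated to outcome
        by = 0.5 * bx + rng.normal(0, 0.02, 500)
        rev = reverse_mvr(bc, bx, by)
        assert abs(rev.beta_exposure) < 3 * rev.se_exposure
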