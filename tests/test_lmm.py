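import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

import cnvjoint as cj
from cnvjoint.exceptions import FitError
from conftest import dense_reml_loglik


def _sim_fixture(rng, sizes, p_cov=2, s2f=2.0, s2e=1.0):
    fams = np.repeat([f"F{i}" for i in range(len(sizes))], sizes)
    n = len(fams)
    X = np.column_stack([np.ones(n)] + [rng.normal(size=n) for _ in range(p_cov)])
    codes = pd.factorize(fams)[0]
    gamma = rng.normal(0, np.sqrt(s2f), len(sizes))
    y = X @ rng.normal(size=X.shape[1]) + gamma[codes] + rng.normal(0, np.sqrt(s2e), n)
    return y, X, fams


class TestRemlLoglik:
    @pytest.mark.parametrize("sizes,s2f,s2e", [
        ((3, 3), 0.5, 1.0),
        ((1, 2, 3, 4, 5), 2.0, 0.3),
        ((4,) * 10, 0.01, 1.7),
        ((1,) * 20, 1.0, 1.0),
    ])
    def test_blockwise_matches_dense_oracle(self, sizes, s2f, s2e):
        rng = np.random.default_rng(101)
        y, X, fams = _sim_fixture(rng, sizes)
        got = cj.reml_loglik(y, X, fams, s2f, s2e)
        want = dense_reml_loglik(y, X, fams, s2f, s2e)
        assert got == pytest.approx(want, abs=1e-10)

    def test_zero_family_variance_collapses_to_ols(self):
        rng = np.random.default_rng(7)
        y, X, fams = _sim_fixture(rng, (3, 3, 3), s2f=0.0)
        s2e = 0.8
        got = cj.reml_loglik(y, X, fams, 0.0, s2e)
        # OLS restricted log-likelihood at the same residual variance
        n, p = X.shape
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        rss = float(((y - X @ beta) ** 2).sum())
        _, ld_a = np.linalg.slogdet(X.T @ X / s2e)
        want = -0.5 * ((n - p) * np.log(2 * np.pi) + n * np.log(s2e) + ld_a + rss / s2e)
        assert got == pytest.approx(want, abs=1e-10)

    def test_singletons_identify_only_the_total_variance(self):
        rng = np.random.default_rng(8)
        y, X, fams = _sim_fixture(rng, (1,) * 15)
        assert cj.reml_loglik(y, X, fams, 0.3, 0.7) == pytest.approx(
            cj.reml_loglik(y, X, fams, 0.0, 1.0), abs=1e-10
        )

    def test_bad_domain(self):
        rng = np.random.default_rng(9)
        y, X, fams = _sim_fixture(rng, (2, 2))
        with pytest.raises(FitError):
            cj.reml_loglik(y, X, fams, 0.1, 0.0)


def _grid_refine_oracle(y, X, fams):
    """Brute-force 2-D grid + local refinement of the dense restricted
    likelihood, independent of the profiled blockwise path."""
    best = (-np.inf, None)
    for s2f in np.concatenate(([0.0], np.geomspace(1e-3, 20, 40))):
        for s2e in np.geomspace(1e-3, 20, 40):
            ll = dense_reml_loglik(y, X, fams, s2f, s2e)
            if ll > best[0]:
                best = (ll, (s2f, s2e))
    x0 = np.array(best[1])
    res = optimize.minimize(
        lambda v: -dense_reml_loglik(y, X, fams, max(v[0], 0.0), max(v[1], 1e-8)),
        x0, method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000},
    )
    s2f, s2e = max(res.x[0], 0.0), res.x[1]
    return -res.fun, s2f, s2e


class TestFitReml:
    def test_balanced_grand_mean(self):
        y = np.array([1.0, 1.0, 2.0, 2.0])
        X = np.ones((4, 1))
        fit = cj.fit_lmm_reml(y, X, ["F1", "F1", "F2", "F2"], feature_names=["intercept"])
        assert fit.beta_[0] == pytest.approx(1.5, abs=1e-10)

    def test_matches_grid_refinement_oracle(self):
        rng = np.random.default_rng(202)
        y, X, fams = _sim_fixture(rng, (4,) * 10, s2f=2.0, s2e=1.0)
        fit = cj.fit_lmm_reml(y, X, fams)
        ll, s2f, s2e = _grid_refine_oracle(y, X, fams)
        assert fit.sigma2_family_ == pytest.approx(s2f, rel=1e-4)
        assert fit.sigma2_resid_ == pytest.approx(s2e, rel=1e-4)
        assert fit.reml_loglik_ >= ll - 1e-6
        # optimum dominates every oracle grid point
        grid_best = max(
            dense_reml_loglik(y, X, fams, a, b)
            for a in np.concatenate(([0.0], np.geomspace(1e-3, 20, 15)))
            for b in np.geomspace(1e-2, 20, 15)
        )
        assert fit.reml_loglik_ >= grid_best - 1e-8

    def test_boundary_mass_under_null(self):
        # with sigma2_family = 0 truth, the REML estimate sits on the zero
        # boundary in roughly half of replicates
        rng = np.random.default_rng(303)
        hits = 0
        for _ in range(100):
            y, X, fams = _sim_fixture(rng, (4,) * 10, p_cov=1, s2f=0.0, s2e=1.0)
            fit = cj.fit_lmm_reml(y, X, fams)
            hits += fit.sigma2_family_ < 1e-8
        assert hits >= 50

    def test_invariant_to_reordering_and_relabeling(self):
        rng = np.random.default_rng(404)
        y, X, fams = _sim_fixture(rng, (2, 3, 4, 1))
        fit1 = cj.fit_lmm_reml(y, X, fams)
        perm = rng.permutation(len(y))
        relabel = np.array(["G" + f for f in fams])
        fit2 = cj.fit_lmm_reml(y[perm], X[perm], relabel[perm])
        np.testing.assert_allclose(fit1.beta_, fit2.beta_, atol=1e-7)
        assert fit1.sigma2_family_ == pytest.approx(fit2.sigma2_family_, rel=1e-5)
        assert fit1.reml_loglik_ == pytest.approx(fit2.reml_loglik_, abs=1e-9)

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(5)
        y, X, fams = _sim_fixture(rng, (3, 3, 3, 3))
        X2 = np.column_stack([X, X[:, 1]])
        with pytest.raises(FitError, match="aliased"):
            cj.fit_lmm_reml(y, X2, fams, feature_names=["i", "x1", "x2", "x1copy"])


class TestConditionalResiduals:
    def test_zero_family_variance_gives_ols_residuals(self):
        rng = np.random.default_rng(11)
        # singletons force the family variance to the boundary
        y, X, fams = _sim_fixture(rng, (1,) * 30, s2f=0.0)
        fit = cj.fit_lmm_reml(y, X, fams)
        assert fit.sigma2_family_ == 0.0
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(
            fit.conditional_residuals_, y - X @ beta, atol=1e-8
        )

    def test_exact_orthogonality_to_null_design(self):
        rng = np.random.default_rng(12)
        y, X, fams = _sim_fixture(rng, (3,) * 12, s2f=1.0, s2e=0.5)
        fit = cj.fit_lmm_reml(y, X, fams)
        ystar = fit.conditional_residuals_
        # Y* = sigma2_resid * V^-1 r, hence X' Y* = 0 exactly
        np.testing.assert_allclose(X.T @ ystar, 0.0, atol=1e-8)
        assert abs(ystar.mean()) < 1e-8

    def test_blup_shrinkage_algebra_on_two_families(self):
        rng = np.random.default_rng(13)
        y, X, fams = _sim_fixture(rng, (4, 6), p_cov=1, s2f=1.0, s2e=1.0)
        fit = cj.fit_lmm_reml(y, X, fams)
        raw = y - (X @ fit.beta_)
        s2f, s2e = fit.sigma2_family_, fit.sigma2_resid_
        for fam, size in (("F0", 4), ("F1", 6)):
            idx = np.asarray(fams) == fam
            shrink = size * s2f / (s2e + size * s2f)
            assert fit.family_effects_[fam] == pytest.approx(
                shrink * raw[idx].mean(), abs=1e-10
            )
        np.testing.assert_allclose(
            fit.conditional_residuals_,
            raw - fit.family_effects_.reindex(fams).to_numpy(),
            atol=1e-12,
        )

    def test_module_function_matches_training_residuals(self):
        rng = np.random.default_rng(14)
        y, X, fams = _sim_fixture(rng, (3,) * 8)
        fit = cj.FamilyLMM(fit_intercept=True).fit(X[:, 1:], y, groups=fams)
        got = cj.conditional_residuals(fit, y, X[:, 1:], fams)
        np.testing.assert_allclose(got, fit.conditional_residuals_, atol=1e-12)


class TestWaldJointTest:
    def _manual_fit(self, names, beta, cov):
        fit = cj.FamilyLMM()
        fit.converged_ = True
        fit.fixed_names_ = names
        fit.beta_ = np.asarray(beta, float)
        fit.cov_beta_ = np.asarray(cov, float)
        return fit

    def test_zero_estimates_give_p_one(self):
        fit = self._manual_fit(
            ["intercept", cj.ALLELE_CONTRAST, cj.COPY_TOTAL],
            [1.0, 0.0, 0.0], np.eye(3) * 0.1,
        )
        res = cj.wald_joint_test(fit)
        assert res.statistic == 0.0
        assert res.p_value == 1.0
        assert res.df == 2

    def test_single_term_chi_square_tail(self):
        # estimate / se = 2 -> statistic 4, p = 0.0455 on 1 df
        fit = self._manual_fit(["intercept", cj.ALLELE_CONTRAST], [0.3, 0.10], np.diag([1.0, 0.0025]))
        res = cj.wald_joint_test(fit)
        assert res.df == 1
        assert res.statistic == pytest.approx(4.0, abs=1e-12)
        assert res.p_value == pytest.approx(stats.chi2.sf(4.0, 1), abs=1e-12)
        assert res.p_value == pytest.approx(0.0455, abs=1e-4)

    def test_copy_total_absent_defaults_to_single_df(self):
        fit = self._manual_fit(["intercept", cj.ALLELE_CONTRAST], [0.3, 0.10], np.diag([1.0, 0.0025]))
        res = cj.wald_joint_test(fit, (cj.ALLELE_CONTRAST, cj.COPY_TOTAL))
        assert res.tested_terms == (cj.ALLELE_CONTRAST,)
        assert res.df == 1


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
class TestAgainstLme4:
    def test_variance_components_and_fixed_effects(self, tmp_path):
        rng = np.random.default_rng(909)
        y, X, fams = _sim_fixture(rng, (3,) * 10, p_cov=2, s2f=1.5, s2e=0.8)
        df = pd.DataFrame({"y": y, "x1": X[:, 1], "x2": X[:, 2], "fam": fams})
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rscript = (
            f'd <- read.csv("{csv}"); library(lme4);'
            "m <- lmer(y ~ x1 + x2 + (1|fam), data=d, REML=TRUE);"
            "vc <- as.data.frame(VarCorr(m));"
            'cat(vc$vcov[1], vc$vcov[2], fixef(m), sqrt(diag(vcov(m))), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", rscript], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        s2f_r, s2e_r = vals[0], vals[1]
        beta_r = vals[2:5]
        se_r = vals[5:8]
        fit = cj.fit_lmm_reml(y, X, fams, feature_names=["intercept", "x1", "x2"])
        assert fit.sigma2_family_ == pytest.approx(s2f_r, rel=1e-3)
        assert fit.sigma2_resid_ == pytest.approx(s2e_r, rel=1e-3)
        np.testing.assert_allclose(fit.beta_, beta_r, rtol=1e-4)
        np.testing.assert_allclose(np.sqrt(np.diag(fit.cov_beta_)), se_r, rtol=1e-3)
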