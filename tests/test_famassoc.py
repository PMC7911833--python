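"""Logistic family-association models: IRLS, the random-intercept AGQ
integrator, and the univariate/multivariate member scans."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from twinstats import famassoc
from twinstats.errors import SeparationError, ValidationError
from twinstats.famassoc import (
    RegressionFit,
    RegressionSpec,
    fit_logistic,
    multivariate_model,
    univariate_scan,
    zygosity_prevalence_or,
)
from twinstats.simulate import ACEParams, SimConfig, simulate_cohort


def _frame(y, **cols):
    df = pd.DataFrame({"y": np.asarray(y, int), **cols})
    return df


def _two_by_two(n11, n10, n01, n00):
    """Outcome-by-exposure table as unit rows (exposure x, outcome y)."""
    y = [1] * n11 + [1] * n10 + [0] * n01 + [0] * n00
    x = [1] * n11 + [0] * n10 + [1] * n01 + [0] * n00
    return _frame(y, x=x)


class TestIRLS:
    def test_constant_predictor_is_rejected_as_collinear(self):
        df = _frame([1] * 13 + [0] * 37, x=[0.0] * 50)
        with pytest.raises(ValidationError):
            fit_logistic(df, RegressionSpec("y", ("x",)))

    def test_saturated_fit_reproduces_cell_logits(self):
        # closed form: with one binary predictor the MLE hits the observed
        # cell rates, so intercept = logit(rate | x=0)
        y = [1] * 5 + [0] * 20 + [1] * 12 + [0] * 13
        x = [0.0] * 25 + [1.0] * 25
        fit = fit_logistic(_frame(y, x=x), RegressionSpec("y", ("x",)))
        assert fit.term("intercept").coef == pytest.approx(logit(5 / 25), abs=1e-8)
        assert fit.term("x").coef == pytest.approx(
            logit(12 / 25) - logit(5 / 25), abs=1e-8
        )

    def test_two_by_two_matches_cross_product_oracle(self):
        df = _two_by_two(10, 20, 20, 10)
        fit = fit_logistic(df, RegressionSpec("y", ("x",)))
        assert fit.term("x").odds_ratio == pytest.approx(0.25, abs=1e-8)

    def test_score_equations_hold_at_convergence(self):
        rng = np.random.default_rng(11)
        n = 500
        x1 = rng.normal(size=n)
        x2 = rng.binomial(1, 0.4, size=n)
        y = rng.binomial(1, expit(-0.5 + 0.8 * x1 - 0.3 * x2))
        df = _frame(y, x1=x1, x2=x2)
        fit = fit_logistic(df, RegressionSpec("y", ("x1", "x2")))
        X = np.column_stack([np.ones(n), x1, x2])
        p = expit(X @ np.array([fit.coef["intercept"], fit.coef["x1"],
                                fit.coef["x2"]]))
        assert np.max(np.abs(X.T @ (y - p))) < 1e-8

    def test_null_predictor_within_three_se(self):
        rng = np.random.default_rng(21)
        n = 600
        x = rng.binomial(1, 0.5, n)
        y = rng.binomial(1, 0.3, n)
        fit = fit_logistic(_frame(y, x=x), RegressionSpec("y", ("x",)))
        t = fit.term("x")
        assert abs(t.coef) < 3 * t.se

    def test_complete_separation_flagged(self):
        df = _two_by_two(25, 0, 0, 25)
        with pytest.raises(SeparationError):
            fit_logistic(df, RegressionSpec("y", ("x",)))

    def test_rank_deficiency_names_problem(self):
        rng = np.random.default_rng(2)
        x = rng.binomial(1, 0.5, 100)
        df = _frame(rng.binomial(1, 0.4, 100), x=x, x2=x)
        with pytest.raises(ValidationError, match="rank"):
            fit_logistic(df, RegressionSpec("y", ("x", "x2")))


class TestRandomIntercept:
    @staticmethod
    def _clustered(n_fam=300, sigma=1.5, beta=(-1.5, 0.6), seed=13):
        rng = np.random.default_rng(seed)
        u = rng.normal(0, sigma, n_fam)
        rows = []
        for g in range(n_fam):
            x = rng.binomial(1, 0.5, 2)
            p = expit(beta[0] + beta[1] * x + u[g])
            y = rng.binomial(1, p)
            for j in range(2):
                rows.append(dict(family_id=f"F{g}", y=y[j], x=float(x[j])))
        return pd.DataFrame(rows)

    def test_vanishing_variance_matches_plain_logistic(self):
        from numpy.polynomial.hermite import hermgauss
        from twinstats.famassoc import _agq_loglik, _bernoulli_loglik, _irls

        df = self._clustered(sigma=0.0, seed=3)
        X = np.column_stack([np.ones(len(df)), df["x"]])
        y = df["y"].to_numpy(float)
        beta, _, ll_plain, _ = _irls(X, y)
        codes, _ = pd.factorize(df["family_id"])
        nodes, weights = hermgauss(21)
        ll_glmm = _agq_loglik(beta, 1e-8, X, y, codes, codes.max() + 1,
                              nodes, np.log(weights))
        assert ll_glmm == pytest.approx(ll_plain, abs=1e-4)

    def test_agrees_with_lme4_glmer_oracle(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        df = self._clustered(n_fam=200, sigma=1.2, seed=7)
        fit = fit_logistic(
            df, RegressionSpec("y", ("x",), random_intercept=True),
            groups="family_id",
        )
        csv = tmp_path / "clustered.csv"
        df.to_csv(csv, index=False)
        script = (
            'suppressMessages(library(lme4));'
            f'd <- read.csv("{csv}");'
            'm <- glmer(y ~ x + (1|family_id), data=d, family=binomial, nAGQ=21);'
            'cat(fixef(m), sqrt(unlist(VarCorr(m))), as.numeric(logLik(m)), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        b0, b1, sigma, ll = map(float, out.stdout.strip().split("\n"))
        assert fit.term("intercept").coef == pytest.approx(b0, abs=2e-3)
        assert fit.term("x").coef == pytest.approx(b1, abs=2e-3)
        assert fit.random_intercept_sd == pytest.approx(sigma, abs=5e-3)
        assert fit.loglik == pytest.approx(ll, abs=1e-3)

    def test_ignoring_clustering_matches_on_independent_pairs(self):
        rng = np.random.default_rng(3)
        nf = 1500
        zyg = np.where(rng.random(nf) < 0.5, "MZ", "DZ")
        df = pd.DataFrame({
            "family_id": np.repeat([f"F{i}" for i in range(nf)], 2),
            "role": ["twin1", "twin2"] * nf,
            "zygosity": np.repeat(zyg, 2),
            "sex": rng.choice(["female", "male"], 2 * nf),
            "age": rng.uniform(3, 18, 2 * nf).round(1),
        })
        k = np.where(np.repeat(zyg, 2) == "MZ", 0.18, 0.12)
        df["gp"] = pd.Series((rng.random(2 * nf) < k).astype(int)).astype("Int8")
        with_ri = zygosity_prevalence_or(df, "gp", covariate_policy="never")
        without = zygosity_prevalence_or(df, "gp", covariate_policy="never",
                                         random_intercept=False)
        assert with_ri.term("mz").coef == pytest.approx(
            without.term("mz").coef, abs=1e-3
        )


def _index_rows(n=900, seed=0, cotwin_beta=2.2, member_betas=(0.0, 0.0, 0.0)):
    """Index-twin rows where only chosen member statuses drive the outcome."""
    rng = np.random.default_rng(seed)
    cot = rng.binomial(1, 0.25, n)
    sib = rng.binomial(1, 0.2, n)
    mot = rng.binomial(1, 0.25, n)
    fat = rng.binomial(1, 0.15, n)
    eta = -2.0 + cotwin_beta * cot + member_betas[0] * sib \
        + member_betas[1] * mot + member_betas[2] * fat
    return pd.DataFrame({
        "family_id": [f"F{i}" for i in range(n)],
        "index_status": rng.binomial(1, expit(eta)),
        "cotwin_status": cot, "sibling_status": sib,
        "mother_status": mot, "father_status": fat,
        "index_sex": rng.binomial(1, 0.5, n),
        "index_age": rng.uniform(3, 18, n).round(1),
    })


class TestScans:
    def test_cotwin_only_signal_detected(self):
        rows = _index_rows(seed=4)
        scan = univariate_scan(rows)
        assert scan["cotwin"].term("cotwin_status").p_value < 0.001
        for member in ("sibling", "mother", "father"):
            t = scan[member].term(f"{member}_status")
            assert abs(t.coef) < 3 * t.se

    def test_parent_effects_recovered_multivariately(self):
        rows = _index_rows(n=1000, seed=9, cotwin_beta=1.5,
                           member_betas=(0.0, np.log(2), np.log(2.5)))
        fit = multivariate_model(rows)
        for member, true_or in (("mother", 2.0), ("father", 2.5)):
            t = fit.term(f"{member}_status")
            assert abs(t.coef - np.log(true_or)) < 3 * t.se
        t_sib = fit.term("sibling_status")
        assert abs(t_sib.coef) < 3 * t_sib.se

    def test_attenuation_with_correlated_predictors(self):
        rng = np.random.default_rng(30)
        n = 2000
        shared = rng.binomial(1, 0.5, n)
        cot = np.where(rng.random(n) < 0.7, shared, rng.binomial(1, 0.5, n))
        sib = np.where(rng.random(n) < 0.7, shared, rng.binomial(1, 0.5, n))
        eta = -2.0 + 1.2 * cot + 1.2 * sib
        rows = _index_rows(n=n, seed=31)
        rows["cotwin_status"] = cot
        rows["sibling_status"] = sib
        rows["index_status"] = rng.binomial(1, expit(eta))
        uni = univariate_scan(rows, covariate_policy="never")
        mult = multivariate_model(rows, covariate_policy="never")
        for m in ("cotwin", "sibling"):
            assert mult.term(f"{m}_status").coef < uni[m].term(f"{m}_status").coef

    def test_orthogonal_design_univariate_equals_multivariate(self):
        # balanced 2x2 cells with identical outcome rates across the second
        # factor: its MLE is exactly zero, so the first factor's coefficient
        # must coincide with its univariate fit
        cells = []
        for x1 in (0, 1):
            for x2 in (0, 1):
                k = 10 if x1 == 0 else 30
                for i in range(50):
                    cells.append((x1, x2, 1 if i < k else 0))
        df = pd.DataFrame(cells, columns=["x1", "x2", "y"])
        uni = fit_logistic(df, RegressionSpec("y", ("x1",)))
        mult = fit_logistic(df, RegressionSpec("y", ("x1", "x2")))
        assert mult.term("x2").coef == pytest.approx(0.0, abs=1e-8)
        assert mult.term("x1").coef == pytest.approx(
            uni.term("x1").coef, abs=1e-6
        )

    def test_too_few_families_errors(self):
        rows = _index_rows(n=10)
        with pytest.raises(ValidationError, match="too few"):
            univariate_scan(rows)

    def test_scan_survives_one_member_separating(self):
        rows = _index_rows(n=200, seed=12)
        rows["father_status"] = rows["index_status"]  # forces separation
        scan = univariate_scan(rows, covariate_policy="never")
        assert isinstance(scan["father"], SeparationError)
        assert isinstance(scan["cotwin"], RegressionFit)


class TestZygosityPrevalence:
    def test_null_difference_within_three_se(self):
        params = ACEParams(a2=0.5, c2=0.1, prevalence=0.15)
        df = simulate_cohort({"gp": params}, SimConfig(n_families=1200, seed=6))
        fit = zygosity_prevalence_or(df, "gp", covariate_policy="never")
        t = fit.term("mz")
        assert abs(t.coef) < 3 * t.se

    def test_doubled_mz_prevalence_detected(self):
        rng = np.random.default_rng(8)
        nf = 1500
        zyg = np.where(np.arange(nf) % 2 == 0, "MZ", "DZ")
        df = pd.DataFrame({
            "family_id": np.repeat([f"F{i}" for i in range(nf)], 2),
            "role": ["twin1", "twin2"] * nf,
            "zygosity": np.repeat(zyg, 2),
            "sex": rng.choice(["female", "male"], 2 * nf),
            "age": rng.uniform(3, 18, 2 * nf).round(1),
        })
        k = np.where(np.repeat(zyg, 2) == "MZ", 0.12, 0.06)
        df["gp"] = pd.Series((rng.random(2 * nf) < k).astype(int)).astype("Int8")
        fit = zygosity_prevalence_or(df, "gp", covariate_policy="never")
        t = fit.term("mz")
        assert t.coef > 0
        assert t.p_value < 0.01
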