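import json
import math
import shutil
import subprocess
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import calfnet as cn


def simulate_glmm_cohort(n, n_mothers, coefs, mother_sd=0.0, seed=0):
    """Bernoulli outcomes from a logistic model with a mother random intercept.

    ``coefs`` maps design terms (intercept, eigenvector, strength, sex,
    eigenvector:sex) to logit-scale values.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "eigenvector": rng.normal(size=n),
        "strength": rng.normal(size=n),
        "sex": np.where(rng.random(n) < 0.5, "M", "F"),
        "mother_id": rng.integers(0, n_mothers, size=n).astype(str),
        "weaning_group": rng.integers(0, 4, size=n).astype(str),
    })
    male = (df["sex"] == "M").astype(float)
    eta = (coefs.get("intercept", 0.0)
           + coefs.get("eigenvector", 0.0) * df["eigenvector"]
           + coefs.get("strength", 0.0) * df["strength"]
           + coefs.get("sex", 0.0) * male
           + coefs.get("eigenvector:sex", 0.0) * df["eigenvector"] * male)
    if mother_sd > 0:
        u = rng.normal(0, mother_sd, size=n_mothers)
        eta = eta + u[df["mother_id"].astype(int)]
    df["survived"] = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return df


TRUE_COEFS = {"intercept": 0.5, "eigenvector": -0.4, "strength": 0.6,
              "sex": -1.0, "eigenvector:sex": 1.2}


class TestGLMM:
    def test_zero_variance_reduces_to_plain_logistic(self):
        """On zero-variance data whose variance MLE lands on the boundary,
        the mixed fit must agree with ordinary logistic regression.  (When
        sampling noise supports a positive variance estimate the fits differ
        legitimately; lme4 behaves the same way.)"""
        df = simulate_glmm_cohort(2000, 300, TRUE_COEFS, mother_sd=0.0, seed=0)
        fit = cn.fit_glmm(df)
        assert max(fit.random_sd.values()) < 0.05  # boundary fit on this draw
        X, y, names = cn.build_design(df, cn.ModelSpec())
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.allclose(fit.table["estimate"], ref.params, atol=1e-3)

    def test_aic_identity(self):
        df = simulate_glmm_cohort(200, 40, TRUE_COEFS, seed=2)
        fit = cn.fit_glmm(df)
        k = len(fit.table) + len(fit.random_sd)
        assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * k)

    def test_subject_random_intercept_dropped(self):
        df = simulate_glmm_cohort(120, 30, TRUE_COEFS, seed=3)
        df["subject_id"] = [f"S{i}" for i in range(len(df))]
        spec = cn.ModelSpec(random=("subject_id", "mother_id"))
        fit = cn.fit_glmm(df, cn.ModelSpec(random=("mother_id",)))
        fit2 = cn.fit_glmm(df, spec)
        assert "subject_id" not in fit2.random_sd
        assert fit2.table["estimate"].to_numpy() == pytest.approx(
            fit.table["estimate"].to_numpy(), abs=1e-6)

    def test_separation_flagged(self):
        df = pd.DataFrame({
            "eigenvector": np.r_[np.ones(20), -np.ones(20)],
            "strength": np.zeros(40) + np.r_[np.linspace(-1, 1, 40)],
            "sex": ["M", "F"] * 20,
            "mother_id": [str(i % 10) for i in range(40)],
            "weaning_group": ["a"] * 40,
            "survived": np.r_[np.ones(20), np.zeros(20)].astype(int),
        })
        fit = cn.fit_glmm(df, cn.ModelSpec(fixed=("eigenvector",)))
        assert fit.separation

    def test_interaction_requires_mains(self):
        with pytest.raises(ValueError):
            cn.ModelSpec(fixed=("eigenvector", "eigenvector:sex"))

    def test_parameter_recovery_with_random_effects(self):
        """Planted coefficients recovered within 2 SE on a large cohort."""
        df = simulate_glmm_cohort(2000, 300, TRUE_COEFS, mother_sd=0.8, seed=4)
        fit = cn.fit_glmm(df)
        t = fit.table.set_index("term")
        for term, true_val in TRUE_COEFS.items():
            est, se = t.loc[term, "estimate"], t.loc[term, "se"]
            assert abs(est - true_val) < 2.5 * se, term
        assert 0.3 < fit.random_sd["mother_id"] < 1.5

    def test_matches_lme4_glmer(self, tmp_path):
        """Laplace fit agrees with lme4::glmer (same approximation) on a
        moderate cohort with a real mother effect."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript expected on PATH for the glmer cross-check")
        df = simulate_glmm_cohort(500, 60, TRUE_COEFS, mother_sd=1.0, seed=5)
        fit = cn.fit_glmm(df, cn.ModelSpec(random=("mother_id",)))
        csv = tmp_path / "d.csv"
        df.assign(male=(df["sex"] == "M").astype(int)).to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(f"""
suppressMessages(library(lme4))
d <- read.csv("{csv}")
m <- glmer(survived ~ eigenvector + strength + male + eigenvector:male
           + (1 | mother_id), data = d, family = binomial)
cat(fixef(m), sigma <- sqrt(unlist(VarCorr(m))), logLik(m), sep = "\\n")
""")
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        vals = [float(v) for v in out.stdout.strip().split("\n")]
        ref_fixef, ref_sd, ref_ll = vals[:5], vals[5], vals[6]
        assert np.allclose(fit.table["estimate"], ref_fixef, atol=0.02)
        assert fit.random_sd["mother_id"] == pytest.approx(ref_sd, abs=0.05)
        assert fit.loglik == pytest.approx(ref_ll, abs=0.5)


class TestModelSelection:
    def test_equal_specs_tie_break_first(self):
        df = simulate_glmm_cohort(150, 30, TRUE_COEFS, seed=6)
        s1 = cn.ModelSpec(fixed=("eigenvector", "sex"))
        s2 = cn.ModelSpec(fixed=("eigenvector", "sex"))
        best, table, _ = cn.select_model_aic(df, [s1, s2])
        assert best is s1
        assert table["aic"].iloc[0] == pytest.approx(table["aic"].iloc[1])

    def test_lrt_against_nested(self):
        df = simulate_glmm_cohort(300, 60, TRUE_COEFS, seed=7)
        full = cn.ModelSpec()
        sub = cn.ModelSpec(fixed=("eigenvector", "sex"))
        best, table, fits = cn.select_model_aic(df, [full, sub])
        assert best.label() == full.label()
        p = table.loc[~table["selected"], "lrt_p_vs_best"].iloc[0]
        assert 0 <= p <= 1
        assert fits[0].loglik >= fits[1].loglik  # nesting sanity

    def test_true_null_prefers_simpler_model(self):
        """With no real effects the intercept-only model usually wins on AIC."""
        wins = 0
        for seed in range(8):
            df = simulate_glmm_cohort(120, 25, {"intercept": 0.3}, seed=100 + seed)
            best, _, _ = cn.select_model_aic(
                df, [cn.ModelSpec(fixed=()),
                     cn.ModelSpec(fixed=("eigenvector", "strength", "sex"))])
            wins += best.fixed == ()
        assert wins >= 5


class TestVIF:
    def test_orthogonal_predictors_unit_vif(self):
        n = 24
        t = 2 * np.pi * np.arange(n) / n
        X = pd.DataFrame({"a": np.sin(t), "b": np.cos(t), "c": np.sin(2 * t)})
        vif = cn.compute_vif(X)
        assert np.allclose(vif, 1.0, atol=1e-8)

    def test_duplicated_predictor_infinite(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": x, "c": rng.normal(size=50)})
        vif = cn.compute_vif(X)
        assert np.isinf(vif["a"]) and np.isinf(vif["b"])

    def test_known_r_squared(self):
        """x2 = sqrt(.75) v1 + .5 v2 with orthonormal centered v1, v2 has
        R^2 = 0.75 on v1, hence VIF = 4."""
        n = 40
        v1 = np.sin(2 * np.pi * np.arange(n) / n)
        v2 = np.cos(2 * np.pi * np.arange(n) / n)
        v1, v2 = v1 / np.linalg.norm(v1), v2 / np.linalg.norm(v2)
        X = pd.DataFrame({"x1": v1, "x2": math.sqrt(0.75) * v1 + 0.5 * v2})
        vif = cn.compute_vif(X)
        assert vif["x2"] == pytest.approx(4.0, abs=1e-8)


class TestPermutation:
    def test_exact_worked_example(self):
        res = cn.permutation_test_two_sample([1, 2], [10, 11])
        assert res.exact
        assert res.n_permutations == 6
        assert res.p_value == pytest.approx(2 / 6)

    def test_identical_samples(self):
        res = cn.permutation_test_two_sample([3.0, 4.0, 5.0], [3.0, 4.0, 5.0])
        assert res.observed_statistic == 0.0
        assert res.p_value == 1.0

    def test_monte_carlo_near_exact(self):
        """Seeded Monte Carlo p within 3 binomial SE of the enumerated p."""
        rng = np.random.default_rng(12)
        for trial in range(10):
            x = rng.normal(0, 1, 6)
            y = rng.normal(0.8, 1, 7)
            exact = cn.permutation_test_two_sample(x, y)
            assert exact.exact
            mc = cn.permutation_test_two_sample(x, y, n_perm=10000,
                                                seed=trial, exact_limit=1)
            se = math.sqrt(exact.p_value * (1 - exact.p_value) / 10000)
            assert abs(mc.p_value - exact.p_value) <= 3 * se + 2 / 10001

    def test_add_one_floor(self):
        x = np.arange(20.0)
        y = np.arange(20.0) + 100
        res = cn.permutation_test_two_sample(x, y, n_perm=999, seed=1)
        assert not res.exact
        assert res.p_value == pytest.approx(1 / 1000)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            cn.permutation_test_two_sample([], [1.0])

    def test_null_calibration(self):
        """Under a true null the rejection rate at 0.05 stays near 0.05."""
        rng = np.random.default_rng(99)
        rejections = 0
        n_tests = 300
        for i in range(n_tests):
            x = rng.normal(size=7)
            y = rng.normal(size=7)
            res = cn.permutation_test_two_sample(x, y)
            rejections += res.p_value < 0.05
        assert 0.02 <= rejections / n_tests <= 0.08


class TestChiSquared:
    def test_uniform_table(self):
        stat, p = cn.sex_survival_chisq([[10, 10], [10, 10]])
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_maximal_association(self):
        stat, _ = cn.sex_survival_chisq([[20, 0], [0, 20]])
        assert stat == pytest.approx(40.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            t = rng.integers(1, 40, size=(2, 2)).astype(float)
            stat, p = cn.sex_survival_chisq(t)
            row, col, n = t.sum(1), t.sum(0), t.sum()
            expected = np.outer(row, col) / n
            ref = ((t - expected) ** 2 / expected).sum()
            assert stat == pytest.approx(ref)
            assert p == pytest.approx(stats.chi2.sf(ref, 1))

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            cn.sex_survival_chisq([[0, 0], [5, 5]])
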