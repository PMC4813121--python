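import json
import math
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from weevilmove import (
    DegenerateDataError,
    FINAL_SPEC,
    GLOBAL_SPEC,
    ModelSpec,
    build_model_matrix,
    compute_vif,
    dispersion,
    fit_glmm,
    fit_windows,
    lrt,
    mcmc_fit,
    random_effect_lrt,
)
from weevilmove.glmm_inference import FitResult


def simulate_glmm_rows(n_ind=80, n_rep=8, n_per=15, sigma_ind=0.0,
                       sigma_rep=0.0, beta=(-1.0, 0.8, -0.5), seed=0):
    """Plain synthetic logistic-mixed data (exogenous covariates)."""
    rng = np.random.default_rng(seed)
    ind = np.repeat(np.arange(n_ind), n_per)
    rep = ind % n_rep
    X = np.column_stack([np.ones(len(ind)),
                         rng.normal(0, 1, len(ind)),
                         rng.integers(0, 2, len(ind)).astype(float)])
    ui = rng.normal(0, sigma_ind, n_ind)
    ur = rng.normal(0, sigma_rep, n_rep)
    eta = X @ np.asarray(beta) + ui[ind] + ur[rep]
    y = (rng.random(len(ind)) < expit(eta)).astype(float)
    return y, X, {"individual": ind, "replicate": rep}


class TestModelMatrix:
    def test_global_spec_has_sixteen_columns(self, small_chain):
        y, X, names, groups = build_model_matrix(small_chain["windows"],
                                                 GLOBAL_SPEC)
        assert X.shape[1] == 16 and names[0] == "intercept"
        assert set(groups) == {"individual", "replicate"}

    def test_intercept_only_spec(self, small_chain):
        spec = ModelSpec(fixed=(), random=("individual",))
        _, X, names, _ = build_model_matrix(small_chain["windows"], spec)
        assert X.shape[1] == 1 and (X == 1.0).all()

    def test_duplicate_term_rejected(self):
        with pytest.raises(ValueError, match="duplicated"):
            ModelSpec(fixed=("time", "time"))

    def test_marginality_enforced_in_spec(self):
        with pytest.raises(ValueError, match="marginality"):
            ModelSpec(fixed=("local_density", "sex:local_sex_ratio", "sex"))

    def test_missing_column_named(self, small_chain):
        broken = small_chain["windows"].drop(columns=["local_density"])
        with pytest.raises(KeyError, match="local_density"):
            build_model_matrix(broken, FINAL_SPEC)

    def test_sex_coded_female_zero_male_one(self, small_chain):
        _, X, names, _ = build_model_matrix(small_chain["windows"],
                                            ModelSpec(fixed=("sex",)))
        male = small_chain["windows"]["sex"] == "M"
        assert np.array_equal(X[:, 1], male.to_numpy(dtype=float))


class TestVIF:
    def test_orthogonal_columns_give_one(self):
        rng = np.random.default_rng(1)
        q, _ = np.linalg.qr(rng.normal(size=(500, 4)))
        X = np.column_stack([np.ones(500), q])
        vif = compute_vif(X, ["intercept", "a", "b", "c", "d"])
        assert all(abs(v - 1.0) < 0.02 for v in vif.values())

    def test_duplicated_column_flagged_infinite(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=300)
        X = np.column_stack([np.ones(300), x, x])
        with pytest.warns(UserWarning, match="collinear"):
            vif = compute_vif(X, ["intercept", "a", "a_copy"])
        assert math.isinf(vif["a"])

    def test_known_correlation_closed_form(self):
        rng = np.random.default_rng(3)
        n = 200_000
        x1 = rng.normal(size=n)
        x2 = 0.8 * x1 + math.sqrt(1 - 0.64) * rng.normal(size=n)
        X = np.column_stack([np.ones(n), x1, x2])
        vif = compute_vif(X, ["intercept", "x1", "x2"])
        assert vif["x1"] == pytest.approx(1 / (1 - 0.64), rel=0.02)


class TestFit:
    def test_matches_plain_logistic_when_variances_vanish(self):
        y, X, groups = simulate_glmm_rows(seed=5)
        import statsmodels.api as sm
        oracle = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        pinned = fit_glmm(y, X, groups,
                          fix_sigma={"individual": 0.0, "replicate": 0.0})
        plain = fit_glmm(y, X, {})
        assert np.abs(plain.beta - oracle.params).max() < 1e-6
        assert np.abs(pinned.beta - oracle.params).max() < 1e-6
        free = fit_glmm(y, X, groups)
        assert np.abs(free.beta - oracle.params).max() < 0.05
        assert all(v < 0.1 for v in free.sigma2.values())

    def test_recovers_variance_components(self):
        y, X, groups = simulate_glmm_rows(n_ind=300, n_per=30, sigma_ind=0.9,
                                          sigma_rep=0.4, seed=6)
        fit = fit_glmm(y, X, groups)
        assert fit.converged
        assert fit.sigma2["individual"] == pytest.approx(0.81, abs=0.25)
        assert (fit.ci_low <= fit.beta).all() and (fit.beta <= fit.ci_high).all()

    def test_agrees_with_reference_glmer(self, tmp_path):
        y, X, groups = simulate_glmm_rows(n_ind=120, n_rep=12, n_per=18,
                                          sigma_ind=0.9, sigma_rep=0.5,
                                          beta=(-1.0, 0.6, 0.8), seed=42)
        fit = fit_glmm(y, X, groups, terms=["intercept", "x1", "x3"])
        df = pd.DataFrame({"y": y, "x1": X[:, 1], "x3": X[:, 2],
                           "ind": groups["individual"],
                           "rep": groups["replicate"]})
        df.to_csv(tmp_path / "dat.csv", index=False)
        rscript = tmp_path / "fit.R"
        rscript.write_text(
            'suppressMessages(library(lme4))\n'
            f'd <- read.csv("{tmp_path / "dat.csv"}")\n'
            'm <- glmer(y ~ x1 + x3 + (1|ind) + (1|rep), data=d,\n'
            '           family=binomial, control=glmerControl(optimizer="bobyqa"))\n'
            'vc <- as.data.frame(VarCorr(m))\n'
            'cat(jsonlite::toJSON(list(beta=as.numeric(fixef(m)),\n'
            '    sigma2=vc$vcov[match(c("ind","rep"), vc$grp)],\n'
            '    loglik=as.numeric(logLik(m))), digits=10))\n')
        out = subprocess.run(["Rscript", str(rscript)], capture_output=True,
                             text=True, check=True)
        ref = json.loads(out.stdout)
        assert np.abs(fit.beta - np.asarray(ref["beta"])).max() < 0.02
        assert abs(fit.sigma2["individual"] - ref["sigma2"][0]) < 0.02
        assert abs(fit.sigma2["replicate"] - ref["sigma2"][1]) < 0.02
        assert abs(fit.loglik - ref["loglik"][0]) < 0.1

    def test_constant_response_is_degenerate(self):
        y, X, groups = simulate_glmm_rows(seed=7)
        with pytest.raises(DegenerateDataError):
            fit_glmm(np.zeros_like(y), X, groups)

    def test_sex_recoding_flips_sign_and_keeps_probabilities(self, small_chain):
        win = small_chain["windows"]
        spec = ModelSpec(fixed=("time", "sex"))
        fit = fit_windows(win, spec)
        flipped = win.copy()
        flipped["sex"] = flipped["sex"].map({"M": "F", "F": "M"})
        fit2 = fit_windows(flipped, spec)
        b, b2 = fit.beta_dict, fit2.beta_dict
        assert b2["sex"] == pytest.approx(-b["sex"], abs=5e-3)
        assert b2["intercept"] == pytest.approx(b["intercept"] + b["sex"],
                                                abs=5e-3)

    def test_adding_a_term_never_lowers_loglik(self, small_chain):
        win = small_chain["windows"]
        base = fit_windows(win, ModelSpec(fixed=("time",)))
        bigger = fit_windows(win, ModelSpec(fixed=("time", "local_density")))
        assert bigger.loglik >= base.loglik - 1e-6

    def test_anchored_term_becomes_offset(self, small_chain):
        win = small_chain["windows"]
        spec = ModelSpec(fixed=("time", "local_density"))
        fit = fit_windows(win, spec, anchors={"local_density": 0.0})
        assert "local_density" not in fit.terms
        free = fit_windows(win, ModelSpec(fixed=("time",)))
        assert fit.loglik == pytest.approx(free.loglik, abs=1e-6)


class TestLRT:
    @staticmethod
    def _stub(terms, loglik, sigma2=None):
        k = len(terms)
        z = np.zeros(k)
        return FitResult(terms=list(terms), beta=z, se=z, ci_low=z,
                         ci_high=z, sigma2=sigma2 or {}, loglik=loglik,
                         converged=True, n_obs=10, n_groups={},
                         mu=np.full(10, 0.5), u_modes={},
                         response=np.zeros(10))

    def test_identical_models_give_zero(self):
        full = self._stub(["intercept", "x"], -100.0)
        red = self._stub(["intercept"], -100.0)
        chi2, df, p = lrt(full, red)
        assert chi2 == 0.0 and df == 1 and p == 1.0

    def test_hand_set_difference(self):
        chi2, df, p = lrt(self._stub(["intercept", "a", "b"], -97.0),
                          self._stub(["intercept"], -100.0))
        assert chi2 == pytest.approx(6.0) and df == 2

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            lrt(self._stub(["intercept", "a"], -1.0),
                self._stub(["intercept", "b"], -2.0))

    def test_random_effect_lrt_detects_real_heterogeneity(self):
        y, X, groups = simulate_glmm_rows(n_ind=150, n_per=20, sigma_ind=0.9,
                                          sigma_rep=0.3, seed=8)
        win = pd.DataFrame({
            "y": y.astype(int), "time_min": X[:, 1] * 0,
            "local_density": X[:, 1], "neighboring_density": 0.0,
            "sex": np.where(X[:, 2] > 0, "M", "F"),
            "local_sex_ratio": 0.5, "neighboring_sex_ratio": 0.5,
            "bulb_age": 0,
            "tag_id": [f"w{i}" for i in groups["individual"]],
            "replicate_id": [f"r{i}" for i in groups["replicate"]],
        })
        spec = ModelSpec(fixed=("local_density", "sex"))
        res = random_effect_lrt(win, spec, refine_beta=False)
        chi2_ind, p_ind = res["individual"]
        assert chi2_ind > 3.84 and p_ind < 0.05

    def test_random_effect_lrt_requires_random_terms(self, small_chain):
        with pytest.raises(ValueError):
            random_effect_lrt(small_chain["windows"],
                              ModelSpec(fixed=("time",), random=()))


class TestDispersion:
    def test_perfect_fit_is_zero(self):
        y = np.array([0.0, 1.0, 0.0, 1.0])
        fit = TestLRT._stub(["intercept"], -1.0)
        fit.response = y
        fit.mu = np.where(y > 0, 1 - 1e-12, 1e-12)
        fit.n_obs = 4
        assert dispersion(fit) == pytest.approx(0.0, abs=1e-5)

    def test_hand_built_unit_residuals(self):
        fit = TestLRT._stub(["intercept"], -1.0)
        fit.response = np.array([1.0, 0.0, 1.0, 0.0])
        fit.mu = np.full(4, 0.5)  # Pearson residuals +-1
        fit.n_obs = 4
        assert dispersion(fit) == pytest.approx(1.0)

    def test_well_specified_model_near_one(self):
        y, X, groups = simulate_glmm_rows(n_ind=200, n_per=20, sigma_ind=0.6,
                                          sigma_rep=0.3, seed=9)
        fit = fit_glmm(y, X, groups)
        assert 0.8 < dispersion(fit) < 1.2


class TestMCMC:
    def test_balanced_intercept_posterior_matches_sample_logit(self):
        rng = np.random.default_rng(3)
        n_ind, n_per = 30, 10
        y = rng.random(n_ind * n_per) < 0.35
        win = pd.DataFrame({
            "y": y.astype(int), "time_min": 0.0, "local_density": 0.0,
            "neighboring_density": 0.0, "sex": "F", "local_sex_ratio": 0.5,
            "neighboring_sex_ratio": 0.5, "bulb_age": 0,
            "tag_id": [f"w{i // n_per}" for i in range(n_ind * n_per)],
            "replicate_id": [f"r{i % 3}" for i in range(n_ind * n_per)],
        })
        spec = ModelSpec(fixed=())
        post = mcmc_fit(win, spec, n_draws=800, n_burn=300, chains=2, seed=4)
        sample_logit = logit(y.mean())
        assert post["mean"]["intercept"] == pytest.approx(sample_logit,
                                                          abs=0.15)
        lap = fit_windows(win, spec)
        assert post["mean"]["intercept"] == pytest.approx(
            lap.beta_dict["intercept"], abs=0.15)
        # convergence diagnostics are reported for every parameter
        assert set(post["rhat"]) >= {"intercept"}
        assert post["n_draws"] == 1600
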