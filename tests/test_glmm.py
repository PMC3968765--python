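import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import special

from ravensim.glmm import (
    GlmmFit,
    GlmmSpec,
    MODEL_TERMS,
    box_tidwell,
    compare_bic,
    fit_glmm,
    make_profiles,
    simulate_from_model,
    white_nonlinearity_test,
)
from ravensim.glmm import _build_design

MODEL1_COEF = {
    "intercept": 2.93,
    "wmc": 0.53,
    "position^lambda": -0.01,
    "wmc:position^lambda": 0.001,
}


@pytest.fixture(scope="module")
def profiles():
    return make_profiles()


@pytest.fixture(scope="module")
def small_profiles():
    return make_profiles(n_items=12, novelty_items=(2, 5, 9))


class TestWhiteTest:
    def test_strong_curvature_detected(self, rng):
        x = np.tile(np.arange(1, 37.0), 126)
        eta = 1.5 - 0.05 * x + 0.4 * ((x - 18) / 10) ** 2
        y = (rng.random(x.size) < special.expit(eta)).astype(float)
        chi2, df, p = white_nonlinearity_test(x, y)
        assert df == 2
        assert p < 1e-6

    def test_constant_predictor_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            white_nonlinearity_test(np.ones(100), rng.integers(0, 2, 100))

    def test_nonbinary_response_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            white_nonlinearity_test(np.arange(100.0), np.arange(100.0))


class TestBoxTidwell:
    def test_identity_exponent_recovered(self):
        lams = []
        for s in range(6):
            rng = np.random.default_rng(1000 + s)
            x = np.tile(np.arange(1, 37.0), 200)
            y = (rng.random(x.size) < special.expit(2.0 - 0.09 * x)).astype(float)
            lam, _ = box_tidwell(x, y)
            lams.append(lam)
        assert np.mean(lams) == pytest.approx(1.0, abs=0.15)

    def test_quadratic_exponent_recovered(self):
        lams = []
        for s in range(6):
            rng = np.random.default_rng(2000 + s)
            x = np.tile(np.arange(1, 37.0), 300)
            y = (rng.random(x.size) < special.expit(2.5 - 0.004 * x**2)).astype(float)
            lam, conv = box_tidwell(x, y)
            lams.append(lam)
        assert np.mean(lams) == pytest.approx(2.0, abs=0.15)

    def test_nonpositive_predictor_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            box_tidwell(np.arange(0.0, 10.0), rng.integers(0, 2, 10))


class TestFitGlmm:
    def test_glm_reduction_oracle(self, rng, small_profiles):
        """With the random-effect SD pinned at zero the marginal fit must
        equal plain logistic ML (statsmodels oracle) within 1e-3."""
        z = rng.standard_normal(80)
        spec = GlmmSpec()
        resp = simulate_from_model(spec, MODEL1_COEF, {"intercept": 0.0}, z,
                                   small_profiles, rng)
        fit = fit_glmm(resp, small_profiles, z, spec, fix_random_sd=0.0)
        y, X, _, labels, _ = _build_design(resp, small_profiles, z, spec)
        glm = sm.Logit(y.reshape(-1), X.reshape(-1, X.shape[2])).fit(disp=0)
        ours = np.array([fit.coefficients[l] for l in labels])
        assert np.max(np.abs(ours - glm.params)) < 1e-3
        assert fit.loglik == pytest.approx(glm.llf, abs=1e-6)

    def test_free_variance_shrinks_on_null_data(self, rng, small_profiles):
        z = rng.standard_normal(80)
        resp = simulate_from_model(GlmmSpec(), MODEL1_COEF, {"intercept": 0.0}, z,
                                   small_profiles, rng)
        fit = fit_glmm(resp, small_profiles, z, GlmmSpec())
        assert fit.random_sd["intercept"] < 0.35

    def test_intercept_only_closed_form(self, rng, small_profiles):
        """No covariate effects and no random variance: the ML intercept is
        exactly the logit of the overall accuracy."""
        n = 100
        resp = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(1, n + 1), 12),
                "item": np.tile(np.arange(1, 13), n),
                "y": (np.random.default_rng(5).random(12 * n) < 0.75).astype(int),
            }
        )
        spec = GlmmSpec(fixed_terms=("intercept",), random_terms=("intercept",))
        fit = fit_glmm(resp, small_profiles, np.zeros(n), spec, fix_random_sd=0.0)
        assert fit.coefficients["intercept"] == pytest.approx(
            special.logit(resp["y"].mean()), abs=1e-6
        )

    def test_bic_arithmetic_identity(self, rng, small_profiles):
        z = rng.standard_normal(60)
        resp = simulate_from_model(GlmmSpec(), MODEL1_COEF, {"intercept": 0.4}, z,
                                   small_profiles, rng)
        fit = fit_glmm(resp, small_profiles, z, GlmmSpec())
        assert fit.bic == pytest.approx(
            -2 * fit.loglik + fit.df * np.log(fit.n_obs), abs=1e-9
        )
        assert fit.df == 5  # 4 fixed effects + 1 variance component

    def test_novelty_coefficient_round_trip(self, rng, profiles):
        """Simulate from the novelty model (beta_kappa = 0.08) and refit."""
        spec = GlmmSpec(fixed_terms=MODEL_TERMS["4"][0],
                        random_terms=MODEL_TERMS["4"][1])
        coef = dict(MODEL1_COEF, novelty=0.08)
        est = []
        for s in range(8):
            r = np.random.default_rng(3000 + s)
            z = r.standard_normal(126)
            resp = simulate_from_model(spec, coef, {"intercept": 0.25}, z, profiles, r)
            est.append(fit_glmm(resp, profiles, z, spec).coefficients["novelty"])
        assert np.mean(est) == pytest.approx(0.08, abs=0.12)

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ValueError, match="main effects"):
            GlmmSpec(fixed_terms=("intercept", "wmc:position"))


class TestCompareBic:
    def _fake(self, loglik, df, n_obs=4536):
        bic = -2 * loglik + df * np.log(n_obs)
        return GlmmFit({}, {}, {}, loglik, bic, df, n_obs, True)

    def test_printed_arithmetic_example(self):
        fit = self._fake(-2039.5, 5)
        assert fit.bic == pytest.approx(2 * 2039.5 + 5 * np.log(4536), abs=1e-9)
        assert fit.bic == pytest.approx(4121.1, abs=0.05)

    def test_tie_breaks_toward_fewer_parameters(self):
        a = self._fake(-2000.0, 5)
        b = self._fake(-2000.0 - 2.5 * np.log(4536) / 2, 10)  # larger BIC
        c = self._fake(-2000.0, 5)
        c.df = 4
        c.bic = a.bic  # forced tie
        best, ranking = compare_bic([a, b, c])
        assert best is c
        assert ranking[-1] is b

    def test_mismatched_data_rejected(self):
        with pytest.raises(ValueError, match="identical data"):
            compare_bic([self._fake(-1, 2, 100), self._fake(-1, 2, 200)])

    def test_random_intercept_structure_recovered(self, profiles):
        """Data from a random-intercept model prefer Model 1 over Model 2 by BIC."""
        wins = 0
        spec1 = GlmmSpec()
        spec2 = GlmmSpec(fixed_terms=MODEL_TERMS["2"][0],
                         random_terms=MODEL_TERMS["2"][1])
        n_sims = 6
        for s in range(n_sims):
            rng = np.random.default_rng(4000 + s)
            z = rng.standard_normal(126)
            resp = simulate_from_model(spec1, MODEL1_COEF, {"intercept": 0.5}, z,
                                       make_profiles(), rng)
            f1 = fit_glmm(resp, make_profiles(), z, spec1)
            f2 = fit_glmm(resp, make_profiles(), z, spec2)
            wins += compare_bic([f1, f2])[0].df == f1.df
        assert wins >= n_sims - 1


class TestSimulateFromModel:
    def test_null_model_gives_half_accuracy(self, rng, profiles):
        spec = GlmmSpec()
        coef = {k: 0.0 for k in MODEL1_COEF}
        resp = simulate_from_model(spec, coef, {"intercept": 0.0},
                                   rng.standard_normal(126), profiles, rng)
        assert resp["y"].mean() == pytest.approx(0.5, abs=0.02)

    def test_intercept_only_mean_accuracy(self, rng, profiles):
        coef = dict.fromkeys(MODEL1_COEF, 0.0)
        coef["intercept"] = 2.93
        resp = simulate_from_model(GlmmSpec(), coef, {"intercept": 0.0},
                                   rng.standard_normal(126), profiles, rng)
        assert resp["y"].mean() == pytest.approx(special.expit(2.93), abs=0.015)

    def test_missing_coefficient_rejected(self, rng, profiles):
        with pytest.raises(ValueError, match="missing"):
            simulate_from_model(GlmmSpec(), {"intercept": 1.0}, {},
                                rng.standard_normal(10), profiles, rng)


class TestAgainstLme4:
    def test_fixed_effects_match_glmer(self, rng, small_profiles, tmp_path):
        """Independent oracle: lme4::glmer with nAGQ=15 on one dataset."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; lme4 oracle cannot run")
        z = rng.standard_normal(90)
        spec = GlmmSpec()
        resp = simulate_from_model(spec, MODEL1_COEF, {"intercept": 0.6}, z,
                                   small_profiles, rng)
        fit = fit_glmm(resp, small_profiles, z, spec)

        df = resp.merge(small_profiles, on="item")
        df["zwmc"] = z[df["subject"].to_numpy() - 1]
        df["psi"] = df["position"].astype(float) ** spec.lambda_
        csv = tmp_path / "d.csv"
        df.to_csv(csv, index=False)
        rcode = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- glmer(y ~ zwmc + psi + zwmc:psi + (1 | subject), data = d,
                       family = binomial, nAGQ = 15)
            cat(fixef(m), sqrt(unlist(VarCorr(m))), logLik(m), sep = "\\n")
        """)
        out = subprocess.run(["Rscript", "-e", rcode], capture_output=True,
                             text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        vals = [float(v) for v in out.stdout.split()]
        b0, bz, bp, bint, sd_r, ll = vals
        ours = fit.coefficients
        assert ours["intercept"] == pytest.approx(b0, abs=0.02)
        assert ours["wmc"] == pytest.approx(bz, abs=0.02)
        assert ours["position^lambda"] == pytest.approx(bp, abs=0.002)
        assert ours["wmc:position^lambda"] == pytest.approx(bint, abs=0.002)
        assert fit.random_sd["intercept"] == pytest.approx(sd_r, abs=0.05)
        assert fit.loglik == pytest.approx(ll, abs=0.5)
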