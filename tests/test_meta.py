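"""Multilevel random-effects meta-analysis: oracles, recovery, diagnostics."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import antcomp.meta as mt


def sim_effects(rng, k=40, n_studies=15, mu=0.25, s2=0.04, dom_types=("behavioral",)):
    """Effects from the study-level random-intercept model with Fisher v."""
    studies = rng.integers(0, n_studies, k)
    u = rng.normal(0, np.sqrt(s2), n_studies)
    n = rng.integers(4, 21, k)
    v = 1.0 / (n - 3)
    z = mu + u[studies] + rng.normal(0, np.sqrt(v))
    return pd.DataFrame(
        {"study": [f"S{s}" for s in studies], "response": [f"r{i}" for i in range(k)],
         "dom_type": [dom_types[i % len(dom_types)] for i in range(k)],
         "n_species": n, "r_s": np.tanh(z), "z": z, "v": v}
    )


class TestMakeEffect:
    def test_fisher_z_and_variance(self):
        e = mt.make_effect("s", "r", "behavioral", 0.5, 20)
        assert e.z == pytest.approx(np.arctanh(0.5), abs=1e-12)
        assert e.z == pytest.approx(0.5493, abs=1e-4)
        assert e.v == pytest.approx(1 / 17)

    def test_spearman_adjusted_variance(self):
        e = mt.make_effect("s", "r", "behavioral", 0.5, 20, "spearman_adjusted")
        assert e.v == pytest.approx(1.06 / 17)

    def test_zero_correlation(self):
        assert mt.make_effect("s", "r", "numerical", 0.0, 8).z == 0.0

    def test_too_few_species_excluded(self):
        with pytest.raises(ValueError, match="fewer than four"):
            mt.make_effect("s", "r", "ecological", 0.5, 3)

    def test_perfect_correlation_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            mt.make_effect("s", "r", "behavioral", 1.0, 10)

    @given(st.floats(-0.999, 0.999))
    @settings(max_examples=200, deadline=None)
    def test_tanh_atanh_round_trip(self, r):
        assert np.tanh(np.arctanh(r)) == pytest.approx(r, abs=1e-12)


class TestFitMultilevel:
    def test_identical_effects_give_mu_and_zero_sigma2(self):
        effects = [mt.make_effect("s1", f"r{i}", "behavioral", 0.4, 10) for i in range(4)]
        fit = mt.fit_multilevel(effects)
        assert fit.mu == pytest.approx(np.arctanh(0.4), abs=1e-8)
        assert fit.sigma2_study == 0.0

    def test_fixed_effect_limit_matches_inverse_variance_mean(self):
        """Spread far below sampling error: REML puts sigma2 at 0 and the
        pooled mean is the closed-form inverse-variance weighted mean."""
        z = np.array([0.10, 0.12, 0.11, 0.09, 0.105])
        v = np.array([1.0, 2.0, 0.5, 1.5, 1.0])
        df = pd.DataFrame(
            {"study": [f"S{i}" for i in range(5)], "response": range(5),
             "dom_type": "behavioral", "n_species": 10, "r_s": np.tanh(z),
             "z": z, "v": v}
        )
        fit = mt.fit_multilevel(df)
        assert fit.sigma2_study == 0.0
        assert fit.mu == pytest.approx(np.sum(z / v) / np.sum(1 / v), abs=1e-8)
        assert fit.se_mu == pytest.approx(1 / np.sqrt(np.sum(1 / v)), abs=1e-8)

    def test_single_effect(self):
        fit = mt.fit_multilevel([mt.make_effect("s", "r", "behavioral", 0.3, 12)])
        assert fit.mu == pytest.approx(np.arctanh(0.3))
        assert fit.sigma2_study == 0.0
        assert fit.ci_r[0] < 0.3 < fit.ci_r[1]

    def test_single_study_sigma2_not_identifiable(self):
        effects = [mt.make_effect("only", f"r{i}", "behavioral", r, 10)
                   for i, r in enumerate([0.1, 0.5, -0.2, 0.7])]
        fit = mt.fit_multilevel(effects)
        # mean and study intercept are confounded; sigma2 stays at the boundary
        assert fit.sigma2_study == pytest.approx(0.0, abs=1e-6)

    def test_back_transformed_ci_in_unit_interval(self, rng):
        fit = mt.fit_multilevel(sim_effects(rng))
        assert -1 < fit.ci_r[0] < fit.ci_r[1] < 1

    def test_ci_coverage_and_sigma2_recovery(self):
        """Over 200 replicates of k = 40 effects from 15 studies with
        mu_z = 0.25 and sigma2 = 0.04: 95% CI coverage lands in [0.90, 0.99]
        and the mean sigma2 estimate is within 30% of truth."""
        rng = np.random.default_rng(123)
        cover, s2s = 0, []
        for _ in range(200):
            fit = mt.fit_multilevel(sim_effects(rng))
            cover += fit.ci_z[0] <= 0.25 <= fit.ci_z[1]
            s2s.append(fit.sigma2_study)
        assert 0.90 <= cover / 200 <= 0.99
        assert abs(np.mean(s2s) - 0.04) <= 0.3 * 0.04

    def test_moderator_model_recovers_equal_type_means(self):
        """Identical truth per dominance type: the three no-intercept type
        coefficients agree within Monte-Carlo error."""
        rng = np.random.default_rng(7)
        ests = []
        for _ in range(50):
            df = sim_effects(rng, k=45, mu=0.3,
                             dom_types=("behavioral", "numerical", "ecological"))
            fit = mt.fit_multilevel(df, moderators="dom_type")
            ests.append(fit.coefficients["estimate"].to_numpy()[:3])
        mean_est = np.mean(ests, axis=0)
        assert np.ptp(mean_est) < 0.06

    def test_missing_type_level_rejected(self, rng):
        df = sim_effects(rng, dom_types=("behavioral", "numerical"))
        with pytest.raises(ValueError, match="ecological"):
            mt.fit_multilevel(df, moderators="dom_type")


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not available")
class TestMetaforOracle:
    """Independent cross-check against metafor::rma.mv on a fixed table."""

    @staticmethod
    @pytest.fixture(scope="class")
    def fixture_fit(tmp_path_factory):
        rng = np.random.default_rng(3)
        types = ["behavioral", "numerical", "ecological"]
        effects = []
        for i in range(12):
            n = int(rng.integers(4, 21))
            r = float(np.round(rng.uniform(-0.8, 0.9), 2))
            effects.append(mt.make_effect(f"St{i//3}", f"resp{i}", types[i % 3], r, n))
        path = tmp_path_factory.mktemp("meta") / "eff.csv"
        mt.effects_frame(effects).to_csv(path, index=False)
        script = f"""
        suppressMessages(library(metafor))
        d <- read.csv("{path}")
        f <- rma.mv(z, v, random = ~1|study, data=d, method="REML")
        cat(coef(f), f$sigma2, f$se, "\\n")
        fm <- rma.mv(z, v, mods = ~ dom_type + n_species - 1, random = ~1|study,
                     data=d, method="REML")
        cat(coef(fm)[c("dom_typebehavioral","dom_typenumerical","dom_typeecological",
                       "n_species")], fm$sigma2, "\\n")
        b3 <- anova(fm, btt=1:3); b1 <- anova(fm, btt=4)
        cat(b3$QM, b1$QM, "\\n")
        """
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True,
                             check=True)
        lines = [np.array(l.split(), dtype=float) for l in out.stdout.strip().splitlines()]
        return effects, lines

    def test_pooled_model_matches(self, fixture_fit):
        effects, (overall, _, _) = fixture_fit
        fit = mt.fit_multilevel(effects)
        assert fit.mu == pytest.approx(overall[0], abs=1e-5)
        assert fit.sigma2_study == pytest.approx(overall[1], abs=1e-5)
        assert fit.se_mu == pytest.approx(overall[2], abs=1e-5)

    def test_moderator_model_matches(self, fixture_fit):
        effects, (_, mod, qm) = fixture_fit
        fit = mt.fit_multilevel(effects, moderators="dom_type")
        np.testing.assert_allclose(fit.coefficients["estimate"], mod[:4], atol=1e-5)
        assert fit.sigma2_study == pytest.approx(mod[4], abs=1e-5)
        assert fit.QM["dom_type"]["stat"] == pytest.approx(qm[0], abs=1e-4)
        assert fit.QM["n_species"]["stat"] == pytest.approx(qm[1], abs=1e-4)


class TestEgger:
    def test_orthogonal_residuals_give_zero_intercept(self):
        """Residuals built orthogonal to both 1 and sqrt(v)."""
        v = np.array([0.1, 0.2, 0.3, 0.4])
        se = np.sqrt(v)
        resid = np.array([1.0, -1.0, 0.3, 0.2])
        X = np.column_stack([np.ones(4), se])
        resid -= X @ np.linalg.lstsq(X, resid, rcond=None)[0]
        z = 0.3 + resid
        df = pd.DataFrame({"study": [f"S{i}" for i in range(4)], "response": range(4),
                           "dom_type": "behavioral", "n_species": 10,
                           "r_s": np.tanh(z), "z": z, "v": v})
        fit = mt.fit_multilevel(df)
        fit.coefficients.loc[0, "estimate"] = 0.3  # evaluate at the known mean
        intercept, _, _ = mt.egger_test(fit)
        assert intercept == pytest.approx(0.0, abs=1e-10)

    def test_symmetric_funnel_rarely_flags_bias(self):
        """k = 50 unbiased effects: Egger p > 0.05 in >= 90% of 200 reps."""
        rng = np.random.default_rng(5)
        ok = 0
        for _ in range(200):
            k = 50
            n = rng.integers(5, 30, k)
            v = 1.0 / (n - 3)
            z = 0.3 + rng.normal(0, 0.1, k) + rng.normal(0, np.sqrt(v))
            df = pd.DataFrame(
                {"study": [f"S{i//2}" for i in range(k)], "response": range(k),
                 "dom_type": "behavioral", "n_species": n, "r_s": np.tanh(z),
                 "z": z, "v": v}
            )
            _, _, p = mt.egger_test(mt.fit_multilevel(df))
            ok += p > 0.05
        assert ok / 200 >= 0.90

    def test_two_effects_rejected(self):
        effects = [mt.make_effect("a", "1", "behavioral", 0.2, 10),
                   mt.make_effect("b", "2", "behavioral", 0.3, 15)]
        with pytest.raises(ValueError, match=">= 3"):
            mt.egger_test(mt.fit_multilevel(effects))

    def test_constant_se_rejected(self):
        effects = [mt.make_effect(f"s{i}", str(i), "behavioral", r, 10)
                   for i, r in enumerate([0.1, 0.3, 0.5])]
        with pytest.raises(ValueError, match="degenerate"):
            mt.egger_test(mt.fit_multilevel(effects))


class TestI2:
    def _fit(self, z, v, s2):
        df = pd.DataFrame({"study": [f"S{i}" for i in range(len(z))],
                           "response": range(len(z)), "dom_type": "behavioral",
                           "n_species": 10, "r_s": np.tanh(z), "z": z, "v": v})
        fit = mt.fit_multilevel(df)
        fit.sigma2_study = s2
        return fit

    def test_zero_heterogeneity(self):
        fit = self._fit(np.r_[0.1, 0.2, 0.3], np.r_[0.2, 0.3, 0.4], 0.0)
        assert mt.i2_multilevel(fit) == 0.0

    def test_equal_variance_half(self):
        """With all v_i = v, the typical within-study variance reduces to v,
        so sigma2 = v gives exactly 50%."""
        v = 0.25
        fit = self._fit(np.r_[0.1, 0.2, 0.3, 0.15], np.full(4, v), v)
        assert mt.i2_multilevel(fit) == pytest.approx(50.0, abs=1e-10)

    def test_vanishing_sampling_variance_approaches_100(self):
        fit = self._fit(np.r_[0.1, 0.2, 0.3], np.full(3, 1e-8), 0.04)
        assert mt.i2_multilevel(fit) > 99.9
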