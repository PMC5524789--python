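import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, special, stats

from multistress import (
    ConfigurationError,
    DataError,
    ExperimentDesign,
    ModelError,
    ModelSpec,
    default_params,
    fit_glm,
    generate_design,
    lrt,
    prune_interactions,
    simulate_survival,
    wald_test,
)
from multistress.simulate import with_seed

from conftest import flat_design, two_arm_survival_frame

logit = special.logit


def _small_sim(seed, n_plates=100, beta_b=0.0, beta_density=0.3):
    """Two-arm exogenous simulation used by the test-statistic checks."""
    design = flat_design(n_plates, treatments=("a", "b"))
    base = default_params(design, seed=seed, panel_effect_sd=0.0)
    params = replace(
        base,
        beta_intercept=0.2,
        beta_treatment={"a": 0.0, "b": beta_b},
        beta_density=beta_density,
        beta_panel={p: 0.0 for p in design.panel_labels()},
    )
    return simulate_survival(generate_design(design), params)


class TestModelSpec:
    def test_family_follows_outcome(self):
        assert ModelSpec("survival").family == "binomial-logit"
        assert ModelSpec("size").family == "poisson-log"
        assert ModelSpec("log_fecundity").family == "gaussian-identity"

    def test_unknown_outcome_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("happiness")

    def test_interaction_requires_main_effects(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("survival", terms=("treatment",),
                      interactions=(("treatment", "density"),))


class TestSaturatedClosedForms:
    def test_binomial_empirical_logits(self):
        records = two_arm_survival_frame(8, 10, 5, 10)
        fit = fit_glm(records, ModelSpec("survival", terms=("treatment",)))
        assert fit.coefficients["intercept"] == pytest.approx(logit(0.8), abs=1e-6)
        assert fit.coefficients["treatment[b]"] == pytest.approx(
            logit(0.5) - logit(0.8), abs=1e-6
        )
        assert fit.n == 20
        assert fit.converged

    def test_poisson_log_arm_means(self):
        records = two_arm_survival_frame(10, 10, 10, 10)
        records["size"] = pd.array(
            [2] * 10 + [8] * 10, dtype="Int64"
        )
        fit = fit_glm(records, ModelSpec("size", terms=("treatment",)))
        assert fit.coefficients["intercept"] == pytest.approx(math.log(2), abs=1e-6)
        assert fit.coefficients["treatment[b]"] == pytest.approx(math.log(4), abs=1e-6)

    def test_gaussian_arm_means_with_ols_variance(self):
        rng = np.random.default_rng(0)
        records = two_arm_survival_frame(10, 10, 10, 10)
        records["block"] = 1
        log_fec = np.concatenate([rng.normal(3, 0.5, 10), rng.normal(4, 0.5, 10)])
        records["fecundity"] = np.exp(log_fec)
        fit = fit_glm(records, ModelSpec("log_fecundity", terms=("treatment",)))
        mean_a = log_fec[:10].mean()
        mean_b = log_fec[10:].mean()
        assert fit.coefficients["intercept"] == pytest.approx(mean_a, abs=1e-8)
        assert fit.coefficients["treatment[b]"] == pytest.approx(
            mean_b - mean_a, abs=1e-8
        )
        ssr = ((log_fec[:10] - mean_a) ** 2).sum() + ((log_fec[10:] - mean_b) ** 2).sum()
        s2 = ssr / (20 - 2)
        assert fit.std_errors["intercept"] == pytest.approx(math.sqrt(s2 / 10), rel=1e-6)

    def test_separation_flagged_not_raised(self):
        records = two_arm_survival_frame(10, 10, 10, 10)  # everyone survives
        with pytest.warns(UserWarning, match="converge|separation"):
            fit = fit_glm(records, ModelSpec("survival", terms=("treatment",)))
        assert not fit.converged


class TestBruteForceOracle:
    """fit_glm vs direct numerical likelihood optimisation (<= 3 coefficients)."""

    @staticmethod
    def _binomial_nll(records):
        y = records["survived"].to_numpy(float)
        x_b = (records["treatment"] == "b").to_numpy(float)
        d = records["density"].to_numpy(float)

        def nll(theta):
            eta = theta[0] + theta[1] * x_b + theta[2] * d
            return -np.sum(y * eta - np.log1p(np.exp(eta)))

        return nll

    def test_binomial_three_coefficient_instance(self):
        records = _small_sim(seed=3, n_plates=60)
        fit = fit_glm(records, ModelSpec("survival", terms=("treatment", "density")))
        nll = self._binomial_nll(records)
        res = optimize.minimize(nll, np.zeros(3), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12,
                                         "maxiter": 20_000})
        assert fit.log_likelihood == pytest.approx(-res.fun, abs=1e-6)
        assert fit.coefficients["intercept"] == pytest.approx(res.x[0], abs=1e-4)

    def test_poisson_two_coefficient_instance(self):
        rng = np.random.default_rng(7)
        records = two_arm_survival_frame(15, 15, 15, 15)
        records["size"] = pd.array(rng.poisson([3] * 15 + [6] * 15), dtype="Int64")
        fit = fit_glm(records, ModelSpec("size", terms=("treatment",)))
        y = records["size"].to_numpy(float)
        x_b = (records["treatment"] == "b").to_numpy(float)

        def nll(theta):
            eta = theta[0] + theta[1] * x_b
            return -np.sum(y * eta - np.exp(eta) - special.gammaln(y + 1))

        res = optimize.minimize(nll, np.zeros(2), method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12})
        assert fit.log_likelihood == pytest.approx(-res.fun, abs=1e-6)


class TestWald:
    def test_zero_estimate_gives_zero_chi2(self):
        records = two_arm_survival_frame(5, 10, 5, 10)
        fit = fit_glm(records, ModelSpec("survival", terms=("treatment",)))
        assert fit.coefficients["treatment[b]"] == pytest.approx(0.0, abs=1e-10)
        test = wald_test(fit, "treatment")
        assert test.chi2 == pytest.approx(0.0, abs=1e-12)
        assert test.p == pytest.approx(1.0)
        assert test.df == 1

    def test_single_coefficient_equals_squared_z(self):
        records = _small_sim(seed=5)
        fit = fit_glm(records, ModelSpec("survival", terms=("treatment", "density")))
        test = wald_test(fit, "density")
        z = fit.coefficients["density"] / fit.std_errors["density"]
        assert test.chi2 == pytest.approx(z**2, rel=1e-10)
        assert test.p == pytest.approx(2 * stats.norm.sf(abs(z)), rel=1e-9)

    def test_block_df_is_levels_minus_one(self, sim_records):
        fit = fit_glm(sim_records, ModelSpec("survival"))
        assert wald_test(fit, "treatment").df == 5
        assert wald_test(fit, "panel").df == 15
        assert wald_test(fit, "density").df == 1

    def test_unknown_term_rejected(self):
        records = _small_sim(seed=6)
        fit = fit_glm(records, ModelSpec("survival", terms=("treatment", "density")))
        with pytest.raises(ModelError, match="panel"):
            wald_test(fit, "panel")

    def test_moderate_calibration_under_null(self):
        # Light version of the full calibration run (acceptance covers 1000).
        rejections = 0
        n_reps = 120
        for rep in range(n_reps):
            records = _small_sim(seed=10_000 + rep, n_plates=80)
            fit = fit_glm(records, ModelSpec("survival", terms=("treatment", "density")))
            if wald_test(fit, "treatment").p < 0.05:
                rejections += 1
        assert 0.05 * n_reps - 3 * math.sqrt(n_reps * 0.05 * 0.95) <= rejections
        assert rejections <= 0.05 * n_reps + 3 * math.sqrt(n_reps * 0.05 * 0.95)


class TestLRT:
    def test_identical_models_rejected(self):
        records = _small_sim(seed=8)
        fit = fit_glm(records, ModelSpec("survival", terms=("treatment", "density")))
        with pytest.raises(ModelError):
            lrt(fit, fit)

    def test_non_nested_rejected(self):
        records = _small_sim(seed=8)
        fit_t = fit_glm(records, ModelSpec("survival", terms=("treatment",)))
        fit_d = fit_glm(records, ModelSpec("survival", terms=("density",)))
        with pytest.raises(ModelError):
            lrt(fit_t, fit_d)

    def test_different_outcomes_rejected(self, sim_records):
        fit_s = fit_glm(sim_records, ModelSpec("survival", terms=("treatment",)))
        fit_z = fit_glm(sim_records, ModelSpec("size", terms=("treatment",)))
        with pytest.raises(ModelError):
            lrt(fit_s, fit_z)

    def test_noise_covariate_chi2_distribution(self):
        # Wilks: adding a no-effect covariate gives chi2 ~ chi2_1 (mean ~ 1).
        chi2s = []
        for rep in range(200):
            records = _small_sim(seed=20_000 + rep, n_plates=60, beta_density=0.0)
            full = fit_glm(records, ModelSpec("survival", terms=("treatment", "density")))
            reduced = fit_glm(records, ModelSpec("survival", terms=("treatment",)))
            chi2s.append(lrt(full, reduced).chi2)
        mean = float(np.mean(chi2s))
        assert 0.75 <= mean <= 1.25  # SE(mean) = sqrt(2/200) ~ 0.1

    def test_power_against_strong_effect(self, default_design):
        significant = 0
        for rep in range(10):
            params = replace(
                default_params(default_design, seed=0, panel_effect_sd=0.0),
                beta_treatment={t: (0.0 if t == "control" else -1.0)
                                for t in default_design.treatments},
                beta_panel={p: 0.0 for p in default_design.panel_labels()},
                seed=30_000 + rep,
            )
            records = simulate_survival(generate_design(default_design), params)
            full = fit_glm(records, ModelSpec("survival", terms=("treatment", "density")))
            reduced = fit_glm(records, ModelSpec("survival", terms=("density",)))
            if lrt(full, reduced).p < 0.001:
                significant += 1
        assert significant >= 9


class TestPruneInteractions:
    SPEC = ModelSpec(
        "survival", ("treatment", "panel", "density"),
        (("treatment", "panel"), ("treatment", "density")),
    )

    def test_no_interactions_is_noop(self, sim_records):
        spec = ModelSpec("survival")
        fit, audit = prune_interactions(sim_records, spec)
        assert audit == []
        assert fit.spec == spec

    def test_null_interactions_usually_dropped(self):
        design = ExperimentDesign(n_blocks=2, panels_per_block=2)
        main_only = 0
        n_runs = 10
        for rep in range(n_runs):
            params = with_seed(default_params(design, seed=1), 40_000 + rep)
            records = simulate_survival(generate_design(design), params)
            fit, audit = prune_interactions(records, self.SPEC)
            assert len(audit) == 2
            if not fit.spec.interactions:
                main_only += 1
        assert main_only >= 7  # ~5% false retention per test

    def test_strong_interaction_retained(self):
        # Hand-rolled generator with a real treatment-x-density interaction.
        rng = np.random.default_rng(42)
        design = flat_design(400, treatments=("a", "b"))
        skeleton = generate_design(design)
        d = rng.poisson(3, size=len(skeleton)).clip(max=5)
        x_b = (skeleton["treatment"] == "b").to_numpy(float)
        eta = 0.2 - 0.3 * x_b + 0.1 * d + 0.8 * x_b * d
        records = skeleton.copy()
        records["survived"] = (rng.random(len(skeleton)) < special.expit(eta)).astype(int)
        records["density"] = d
        spec = ModelSpec("survival", ("treatment", "density"),
                         (("treatment", "density"),))
        fit, audit = prune_interactions(records, spec)
        assert audit[0].p < 0.001
        assert not audit[0].dropped
        assert ("treatment", "density") in fit.spec.interactions


class TestInvariances:
    def test_row_order_invariance(self, sim_records):
        spec = ModelSpec("survival")
        fit_a = fit_glm(sim_records, spec)
        shuffled = sim_records.sample(frac=1.0, random_state=9).reset_index(drop=True)
        fit_b = fit_glm(shuffled, spec)
        for name, value in fit_a.coefficients.items():
            assert fit_b.coefficients[name] == pytest.approx(value, abs=1e-8)

    def test_relabeling_non_reference_level(self, sim_records):
        spec = ModelSpec("survival", terms=("treatment", "density"))
        fit_a = fit_glm(sim_records, spec)
        renamed = sim_records.replace({"treatment": {"heat": "zzz_heat"}})
        fit_b = fit_glm(renamed, spec)
        assert fit_b.coefficients["treatment[zzz_heat]"] == pytest.approx(
            fit_a.coefficients["treatment[heat]"], abs=1e-8
        )
        assert fit_b.coefficients["intercept"] == pytest.approx(
            fit_a.coefficients["intercept"], abs=1e-8
        )


class TestMissingOutcomes:
    def test_size_model_uses_survivors_only(self, sim_records):
        fit = fit_glm(sim_records, ModelSpec("size", terms=("treatment", "density")))
        assert fit.n == int((sim_records["survived"] == 1).sum())

    def test_fecundity_model_uses_fecund_block_only(self, sim_records):
        fit = fit_glm(
            sim_records, ModelSpec("log_fecundity", terms=("treatment", "density"))
        )
        expected = int(sim_records["fecundity"].notna().sum())
        assert fit.n == expected

    def test_empty_level_error_names_level(self, sim_records):
        records = sim_records.copy()
        records.loc[records["treatment"] == "copper", "size"] = pd.NA
        with pytest.raises(DataError, match="copper"):
            fit_glm(records, ModelSpec("size", terms=("treatment",)))

    def test_zero_fecundity_warns_and_is_excluded(self, sim_records):
        records = sim_records.copy()
        idx = records.index[records["fecundity"].notna()][0]
        records.loc[idx, "fecundity"] = 0.0
        with pytest.warns(UserWarning, match="zero-fecundity"):
            fit = fit_glm(records, ModelSpec("log_fecundity", terms=("treatment",)))
        assert fit.n == int(records["fecundity"].notna().sum()) - 1
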