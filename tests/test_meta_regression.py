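"""Tests of the weighted random-intercept REML fitter and named analyses.

The fitter is checked against two independent routes: a dense-matrix
numerical maximisation of the restricted likelihood written here from
first principles, and lme4's `lmer` via Rscript.
"""

import json
import math
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from varmeta.meta_regression import (
    MetaDataset,
    ModelError,
    ModelSpec,
    backtransform_sd,
    fit_base_model,
    fit_drugclass_model,
    fit_interaction_model,
    fit_subgroup,
    fit_weighted_lmm,
    subgroup_dataset,
    variance_of_means,
)
from varmeta.synthetic_data import ArmLevelSimConfig, simulate_meta_dataset

from conftest import make_dataset


# ---------------------------------------------------------------------------
# Oracle A: dense-matrix REML, written independently of the fitter
# ---------------------------------------------------------------------------

def dense_reml_fit(dataset: MetaDataset):
    """Numerically maximise the restricted likelihood with dense linear
    algebra over (log tau2, log sigma2); GLS beta at the optimum."""
    df = dataset.frame
    X = np.column_stack(
        [
            np.ones(len(df)),
            (df["treatment"].astype(str) == "verum").to_numpy(float),
            df["log_mean"].to_numpy(float),
        ]
    )
    y = df["lnsd_bc"].to_numpy(float)
    w = df["weight"].to_numpy(float)
    trial = pd.factorize(df["trial_id"])[0]
    Z = np.equal.outer(trial, np.arange(trial.max() + 1)).astype(float)
    N, p = X.shape

    def neg_restricted_loglik(params):
        tau2, sigma2 = np.exp(params)
        V = tau2 * Z @ Z.T + sigma2 * np.diag(1.0 / w)
        Vinv = np.linalg.inv(V)
        XtVX = X.T @ Vinv @ X
        beta = np.linalg.solve(XtVX, X.T @ Vinv @ y)
        r = y - X @ beta
        _, ld_V = np.linalg.slogdet(V)
        _, ld_I = np.linalg.slogdet(XtVX)
        return 0.5 * (ld_V + ld_I + r @ Vinv @ r + (N - p) * math.log(2 * math.pi))

    best = None
    for start in ([-2.0, 0.0], [0.0, 0.0], [-5.0, 1.0]):
        res = optimize.minimize(
            neg_restricted_loglik, start, method="Nelder-Mead",
            options={"xatol": 1e-13, "fatol": 1e-13, "maxiter": 20_000},
        )
        if best is None or res.fun < best.fun:
            best = res
    tau2, sigma2 = np.exp(best.x)
    V = tau2 * Z @ Z.T + sigma2 * np.diag(1.0 / w)
    Vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vinv @ X, X.T @ Vinv @ y)
    return beta, tau2, sigma2, -best.fun


def assert_sig_digits(a, b, digits):
    scale = max(abs(a), abs(b), 1e-12)
    assert abs(a - b) / scale < 10.0 ** (-digits)


class TestDualOracleEquivalence:
    def test_matches_dense_numerical_reml(self, small_dataset, medium_dataset):
        for data in (small_dataset, medium_dataset):
            fit = fit_base_model(data, tau2_ci=False)
            beta, tau2, sigma2, loglik = dense_reml_fit(data)
            for est, oracle in zip(
                [fit.coefficients["intercept"],
                 fit.coefficients["treatment[verum]"],
                 fit.coefficients["log_mean"]],
                beta,
            ):
                assert_sig_digits(est, oracle, 6)
            assert_sig_digits(fit.tau2, tau2, 5)
            assert_sig_digits(fit.sigma2, sigma2, 6)
            assert fit.loglik == pytest.approx(loglik, abs=1e-6)

    @pytest.mark.skipif(shutil.which("Rscript") is None, reason="R not on PATH")
    def test_matches_lme4(self, medium_dataset, tmp_path):
        csv = tmp_path / "d.csv"
        medium_dataset.frame.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            'suppressMessages(library(lme4))\n'
            f'd <- read.csv("{csv}")\n'
            'd$T <- as.numeric(d$treatment == "verum")\n'
            'm <- lmer(lnsd_bc ~ T + log_mean + (1 | trial_id), data = d,\n'
            '          weights = weight, REML = TRUE)\n'
            'vc <- as.data.frame(VarCorr(m))\n'
            'cat(jsonlite::toJSON(list(beta = unname(fixef(m)),\n'
            '    tau2 = vc$vcov[1], sigma2 = vc$vcov[2]), digits = 12))\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        ref = json.loads(out.stdout)
        fit = fit_base_model(medium_dataset, tau2_ci=False)
        assert_sig_digits(fit.coefficients["intercept"], ref["beta"][0], 6)
        assert_sig_digits(fit.coefficients["treatment[verum]"], ref["beta"][1], 6)
        assert_sig_digits(fit.coefficients["log_mean"], ref["beta"][2], 6)
        assert_sig_digits(fit.tau2, ref["tau2"][0], 5)
        assert_sig_digits(fit.sigma2, ref["sigma2"][0], 5)


class TestFitterContracts:
    def test_reduces_to_wls_when_lambda_fixed_at_zero(self, medium_dataset):
        fit = fit_base_model(medium_dataset, tau2_ci=False, fix_lambda=0.0)
        df = medium_dataset.frame
        X = np.column_stack(
            [np.ones(len(df)),
             (df["treatment"].astype(str) == "verum").to_numpy(float),
             df["log_mean"].to_numpy(float)]
        )
        y = df["lnsd_bc"].to_numpy(float)
        sw = np.sqrt(df["weight"].to_numpy(float))
        beta_wls, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        est = [fit.coefficients["intercept"],
               fit.coefficients["treatment[verum]"],
               fit.coefficients["log_mean"]]
        np.testing.assert_allclose(est, beta_wls, rtol=1e-10)
        assert fit.tau2 == 0.0

    def test_weight_rescaling_leaves_beta_invariant(self, medium_dataset):
        fit1 = fit_base_model(medium_dataset, tau2_ci=False)
        scaled = MetaDataset(frame=medium_dataset.frame.assign(
            weight=medium_dataset.frame["weight"] * 7.0))
        fit2 = fit_base_model(scaled, tau2_ci=False)
        for term in fit1.terms:
            assert fit2.coefficients[term] == pytest.approx(
                fit1.coefficients[term], rel=1e-6)
        assert fit2.sigma2 == pytest.approx(7.0 * fit1.sigma2, rel=1e-6)

    def test_verum_sd_inflation_shifts_treatment_coefficient_exactly(
        self, medium_dataset
    ):
        delta = 0.25
        df = medium_dataset.frame.copy()
        verum = df["treatment"].astype(str) == "verum"
        df.loc[verum, "lnsd_bc"] += delta
        fit0 = fit_base_model(medium_dataset, tau2_ci=False)
        fit1 = fit_base_model(MetaDataset(frame=df), tau2_ci=False)
        assert fit1.coefficients["treatment[verum]"] - fit0.coefficients[
            "treatment[verum]"
        ] == pytest.approx(delta, abs=1e-8)
        assert fit1.coefficients["log_mean"] == pytest.approx(
            fit0.coefficients["log_mean"], abs=1e-8)
        assert fit1.tau2 == pytest.approx(fit0.tau2, rel=1e-6)

    def test_null_model_estimates_near_zero(self):
        config = ArmLevelSimConfig(
            n_trials=400, beta0=0.0, beta_t=0.0, beta_m=0.0, tau2=0.0,
            sigma2=1.0, seed=11,
        )
        fit = fit_base_model(simulate_meta_dataset(config), tau2_ci=False)
        for term in ("treatment[verum]", "log_mean"):
            lo, hi = fit.ci[term]
            assert lo < 0.0 < hi
        assert fit.tau2 < 0.01

    def test_tau2_profile_interval_brackets_estimate(self, paper_scale_dataset):
        fit = fit_base_model(paper_scale_dataset)
        lo, hi = fit.tau2_ci
        assert 0.0 <= lo <= fit.tau2 <= hi < math.inf

    def test_ml_switch_gives_smaller_variance_estimates(self, medium_dataset):
        reml = fit_base_model(medium_dataset, tau2_ci=False)
        ml = fit_base_model(
            medium_dataset, ModelSpec(estimation="ML"), tau2_ci=False)
        assert ml.sigma2 < reml.sigma2

    def test_rank_deficiency_names_offending_term(self, medium_dataset):
        df = medium_dataset.frame.assign(bmi=1.0)  # aliased with intercept
        spec = ModelSpec(
            fixed_terms=("intercept", "treatment", "log_mean", "bmi"))
        with pytest.raises(ModelError, match="rank deficient"):
            fit_weighted_lmm(MetaDataset(frame=df), spec)

    def test_requires_two_trials(self):
        data = make_dataset([
            dict(trial_id="A", treatment="placebo", n=40, mean_pct=8.0, sd_pct=1.1),
            dict(trial_id="A", treatment="verum", n=40, mean_pct=7.4, sd_pct=1.2),
        ])
        with pytest.raises(ModelError, match="2 trials"):
            fit_base_model(data)

    def test_mandatory_terms_enforced(self):
        with pytest.raises(ModelError):
            ModelSpec(fixed_terms=("intercept", "treatment"))
        with pytest.raises(ModelError):
            ModelSpec(fixed_terms=("treatment", "log_mean"))


class TestInteractionModel:
    def test_slope_difference_is_verum_minus_placebo(self, paper_scale_dataset):
        res = fit_interaction_model(
            paper_scale_dataset, "baseline_hba1c_pct", tau2_ci=False)
        assert res.slope_difference == pytest.approx(
            res.slope_verum - res.slope_placebo, abs=1e-12)

    def test_recovers_generating_interaction(self):
        config = ArmLevelSimConfig(
            n_trials=600, interaction_betas={"disease_duration_years": 0.02},
            seed=13,
        )
        res = fit_interaction_model(
            simulate_meta_dataset(config), "disease_duration_years",
            tau2_ci=False,
        )
        lo, hi = res.slope_difference_ci
        assert lo < 0.02 < hi
        assert res.slope_difference == pytest.approx(0.02, abs=0.01)

    def test_missing_predictor_arms_counted(self, paper_scale_dataset):
        df = paper_scale_dataset.frame.copy()
        df.loc[df.index[:30], "bmi"] = np.nan
        res = fit_interaction_model(MetaDataset(frame=df), "bmi", tau2_ci=False)
        assert res.n_missing_arms == 30
        assert res.fit.n_arms_used == len(df) - 30

    def test_all_missing_predictor_rejected(self, paper_scale_dataset):
        df = paper_scale_dataset.frame.assign(bmi=np.nan)
        with pytest.raises(ModelError, match="missing on every arm"):
            fit_interaction_model(MetaDataset(frame=df), "bmi")


class TestDrugClassModel:
    def test_single_class_collapses_to_base_treatment_contrast(
        self, medium_dataset
    ):
        df = medium_dataset.frame.copy()
        df["drug_class"] = np.where(
            df["treatment"].astype(str) == "verum", "metformin", "placebo")
        data = MetaDataset(frame=df)
        base = fit_base_model(data, tau2_ci=False)
        classes = fit_drugclass_model(data, tau2_ci=False)
        assert classes["metformin"]["contrast"] == pytest.approx(
            base.coefficients["treatment[verum]"], abs=1e-10)

    def test_inflated_class_is_elevated(self):
        config = ArmLevelSimConfig(
            n_trials=500, beta_t=0.0,
            class_effects={"GLP-1 receptor agonists": 0.3}, seed=17,
        )
        classes = fit_drugclass_model(
            simulate_meta_dataset(config), tau2_ci=False)
        target = classes["GLP-1 receptor agonists"]["contrast"]
        others = [v["contrast"] for k, v in classes.items()
                  if not k.startswith("_") and k != "GLP-1 receptor agonists"]
        assert target == pytest.approx(0.3, abs=0.1)
        assert all(abs(o) < 0.15 for o in others)

    def test_sparse_class_flagged_unstable(self, medium_dataset):
        df = medium_dataset.frame.copy()
        df["drug_class"] = np.where(
            df["treatment"].astype(str) == "verum", "metformin", "placebo")
        first_verum = df.index[df["treatment"].astype(str) == "verum"][0]
        df.loc[first_verum, "drug_class"] = "sulfonylureas"
        classes = fit_drugclass_model(MetaDataset(frame=df), tau2_ci=False)
        assert classes["sulfonylureas"]["unstable"]
        assert not classes["metformin"]["unstable"]


class TestSubgroup:
    def test_subgroup_selects_class_and_concurrent_placebo_arms(self):
        rows = []
        for trial, cls in [("A", "GLP-1 receptor agonists"), ("B", "metformin")]:
            rows.append(dict(trial_id=trial, treatment="placebo",
                             n=40, mean_pct=8.0, sd_pct=1.1, drug_class="placebo"))
            rows.append(dict(trial_id=trial, treatment="verum",
                             n=40, mean_pct=7.4, sd_pct=1.2, drug_class=cls))
        data = make_dataset(rows)
        sub = subgroup_dataset(data, "GLP-1 receptor agonists")
        assert set(sub.frame["trial_id"]) == {"A"}
        assert len(sub.frame) == 2

    def test_single_class_subgroup_is_full_dataset(self, medium_dataset):
        df = medium_dataset.frame.copy()
        df["drug_class"] = np.where(
            df["treatment"].astype(str) == "verum", "metformin", "placebo")
        data = MetaDataset(frame=df)
        sub = subgroup_dataset(data, "metformin")
        assert len(sub.frame) == len(df)

    def test_empty_subgroup_rejected(self):
        rows = [
            dict(trial_id="A", treatment="placebo", n=40, mean_pct=8.0,
                 sd_pct=1.1, drug_class="placebo"),
            dict(trial_id="A", treatment="verum", n=40, mean_pct=7.4,
                 sd_pct=1.2, drug_class="metformin"),
        ]
        with pytest.raises(ModelError, match="no trials"):
            subgroup_dataset(make_dataset(rows), "sulfonylureas")

    def test_recovers_subgroup_interaction(self):
        config = ArmLevelSimConfig(
            n_trials=500,
            class_mix={"GLP-1 receptor agonists": 1.0},
            interaction_betas={"baseline_hba1c_pct": 0.05},
            seed=19,
        )
        res = fit_subgroup(
            simulate_meta_dataset(config), "GLP-1 receptor agonists",
            "baseline_hba1c_pct", tau2_ci=False,
        )
        assert res.slope_verum > res.slope_placebo
        lo, hi = res.slope_difference_ci
        assert lo < 0.05 < hi


class TestVarianceOfMeans:
    def test_matches_two_pass_variance(self):
        rng = np.random.default_rng(23)
        rows = [
            dict(trial_id=f"t{i}", treatment=t, n=30,
                 mean_pct=float(rng.uniform(6.5, 9.5)), sd_pct=1.0)
            for i in range(40) for t in ("placebo", "verum")
        ]
        data = make_dataset(rows)
        out = variance_of_means(data)
        for grp in ("placebo", "verum"):
            vals = data.frame.loc[
                data.frame["treatment"] == grp, "mean_pct"].to_numpy()
            mean = sum(vals) / len(vals)
            two_pass = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
            assert out[grp]["variance"] == pytest.approx(two_pass, rel=1e-12)
            lo, hi = out[grp]["ci"]
            assert lo < two_pass < hi

    def test_equal_means_give_zero_variance(self):
        rows = [
            dict(trial_id=f"t{i}", treatment=t, n=30, mean_pct=8.0, sd_pct=1.0)
            for i in range(5) for t in ("placebo", "verum")
        ]
        out = variance_of_means(make_dataset(rows))
        assert out["placebo"]["variance"] == 0.0

    def test_single_arm_group_rejected(self):
        rows = [
            dict(trial_id="A", treatment="placebo", n=30, mean_pct=8.0, sd_pct=1.0),
            dict(trial_id="A", treatment="verum", n=30, mean_pct=7.4, sd_pct=1.0),
            dict(trial_id="B", treatment="verum", n=30, mean_pct=7.2, sd_pct=1.0),
        ]
        with pytest.raises(ModelError, match="fewer than 2"):
            variance_of_means(make_dataset(rows))


class TestBacktransform:
    def test_published_style_values(self):
        assert backtransform_sd(0.10) == pytest.approx(1.105, abs=5e-4)
        assert backtransform_sd(0.10, 0.037) == pytest.approx(1.147, abs=5e-4)

    def test_zero_delta_is_plain_exp(self):
        assert backtransform_sd(0.5) == math.exp(0.5)
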