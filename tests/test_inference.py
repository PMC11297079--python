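import itertools

import numpy as np
import pandas as pd
import pytest

from gazescene.inference import (
    LMMFit,
    build_contrasts,
    cfb_covariates,
    fit_lmm,
    significance_report,
)


def exp1_table(n_rep=1):
    rows = [
        {"task_level": t, "posture_level": p}
        for t, p in itertools.product(("Free_Viewing", "Guess_Time"),
                                      ("Chin_Rest", "Standing"))
    ] * n_rep
    return pd.DataFrame(rows)


def exp2_table(n_rep=1):
    rows = [{"posture_level": p}
            for p in ("Chin_Rest", "Sitting", "Standing", "Balancing")] * n_rep
    return pd.DataFrame(rows)


class TestContrasts:
    def test_exp1_columns_orthogonal_on_balanced_design(self):
        X = build_contrasts(1, exp1_table())
        C = X[["Task", "Body", "Task:Body"]].to_numpy()
        gram = C.T @ C
        np.testing.assert_allclose(gram, np.diag(np.diag(gram)), atol=1e-12)

    def test_exp2_coding_values(self):
        X = build_contrasts(2, exp2_table())
        np.testing.assert_allclose(X["C1"], [-0.5, -0.5, 0.5, 0.5])
        np.testing.assert_allclose(X["C2"], [-0.5, 0.5, 0.0, 0.0])
        np.testing.assert_allclose(X["C3"], [0.0, 0.0, -0.5, 0.5])

    def test_columns_sum_to_zero(self):
        for exp, tab in ((1, exp1_table()), (2, exp2_table())):
            X = build_contrasts(exp, tab).drop(columns="Intercept")
            np.testing.assert_allclose(X.sum(axis=0), 0.0, atol=1e-12)

    def test_unknown_level_lists_valid_levels(self):
        tab = exp1_table()
        tab.loc[0, "task_level"] = "Memorize"
        with pytest.raises(ValueError, match="Free_Viewing"):
            build_contrasts(1, tab)

    def test_unknown_experiment(self):
        with pytest.raises(ValueError, match="experiment"):
            build_contrasts(3, exp1_table())


class TestContrastSemantics:
    """On balanced noiseless designs each coefficient equals its named
    condition-mean difference exactly."""

    def test_exp1_estimates_are_mean_differences(self):
        tab = exp1_table(n_rep=5)
        means = {("Free_Viewing", "Chin_Rest"): 5.50,
                 ("Free_Viewing", "Standing"): 5.58,
                 ("Guess_Time", "Chin_Rest"): 5.41,
                 ("Guess_Time", "Standing"): 5.63}
        y = np.array([means[(t, p)] for t, p in
                      zip(tab["task_level"], tab["posture_level"])])
        X = build_contrasts(1, tab)
        fit = fit_lmm(y, X)
        est = dict(zip(fit.terms, fit.estimates))
        gt = (means[("Guess_Time", "Chin_Rest")]
              + means[("Guess_Time", "Standing")]) / 2
        fv = (means[("Free_Viewing", "Chin_Rest")]
              + means[("Free_Viewing", "Standing")]) / 2
        assert est["Task"] == pytest.approx(gt - fv, abs=1e-10)
        st = (means[("Free_Viewing", "Standing")]
              + means[("Guess_Time", "Standing")]) / 2
        cr = (means[("Free_Viewing", "Chin_Rest")]
              + means[("Guess_Time", "Chin_Rest")]) / 2
        assert est["Body"] == pytest.approx(st - cr, abs=1e-10)
        dod = (means[("Guess_Time", "Standing")]
               - means[("Guess_Time", "Chin_Rest")]) \
            - (means[("Free_Viewing", "Standing")]
               - means[("Free_Viewing", "Chin_Rest")])
        assert est["Task:Body"] == pytest.approx(dod, abs=1e-10)
        assert est["Intercept"] == pytest.approx(np.mean(list(means.values())),
                                                 abs=1e-10)

    def test_exp2_estimates_are_mean_differences(self):
        tab = exp2_table(n_rep=3)
        means = {"Chin_Rest": 10.0, "Sitting": 10.4, "Standing": 9.7,
                 "Balancing": 9.1}
        y = np.array([means[p] for p in tab["posture_level"]])
        fit = fit_lmm(y, build_contrasts(2, tab))
        est = dict(zip(fit.terms, fit.estimates))
        assert est["C1"] == pytest.approx(
            (means["Standing"] + means["Balancing"]) / 2
            - (means["Chin_Rest"] + means["Sitting"]) / 2, abs=1e-10)
        assert est["C2"] == pytest.approx(means["Sitting"] - means["Chin_Rest"],
                                          abs=1e-10)
        assert est["C3"] == pytest.approx(
            means["Balancing"] - means["Standing"], abs=1e-10)


def simulate_crossed(rng, n_subj=12, n_img=12, beta=-0.03, subj_sd=0.1,
                     img_sd=0.1, resid_sd=0.3):
    subj, img = np.meshgrid(np.arange(n_subj), np.arange(n_img),
                            indexing="ij")
    subj, img = subj.ravel(), img.ravel()
    task = np.where((subj + img) % 2 == 0, -0.5, 0.5)
    u = rng.normal(0, subj_sd, n_subj)
    v = rng.normal(0, img_sd, n_img)
    y = 5.5 + beta * task + u[subj] + v[img] + rng.normal(0, resid_sd,
                                                          len(subj))
    X = pd.DataFrame({"Intercept": np.ones(len(subj)), "Task": task})
    return y, X, subj, img


class TestFitLmm:
    def test_zero_variance_data_matches_ols(self):
        rng = np.random.default_rng(0)
        y, X, subj, img = simulate_crossed(rng, subj_sd=0.0, img_sd=0.0)
        mixed = fit_lmm(y, X, subject_ids=subj, image_ids=img)
        ols = fit_lmm(y, X)   # no grouping: ordinary least squares
        np.testing.assert_allclose(mixed.estimates, ols.estimates, atol=1e-6)
        assert mixed.vc_sd["subject"] < 0.05
        assert mixed.vc_sd["image"] < 0.05

    def test_ml_likelihood_dominates_ols(self):
        rng = np.random.default_rng(1)
        y, X, subj, img = simulate_crossed(rng)
        mixed = fit_lmm(y, X, subject_ids=subj, image_ids=img)
        ols = fit_lmm(y, X)
        assert mixed.loglik >= ols.loglik - 1e-6

    def test_single_subject_boundary_equals_image_only_model(self):
        rng = np.random.default_rng(2)
        y, X, subj, img = simulate_crossed(rng, n_subj=1, n_img=10)
        fit = fit_lmm(y, X, subject_ids=subj, image_ids=img)
        assert "subject" in fit.boundary
        img_only = fit_lmm(y, X, subject_ids=None, image_ids=img)
        np.testing.assert_allclose(fit.estimates, img_only.estimates,
                                   atol=1e-8)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(3)
        y, X, subj, img = simulate_crossed(rng)
        a = fit_lmm(y, X, subject_ids=subj, image_ids=img)
        b = fit_lmm(y, X, subject_ids=subj + 1000,
                    image_ids=np.array([f"img{i}" for i in img]))
        np.testing.assert_allclose(a.estimates, b.estimates, atol=1e-8)
        np.testing.assert_allclose(a.loglik, b.loglik, atol=1e-6)

    def test_variance_components_recovered(self):
        rng = np.random.default_rng(4)
        y, X, subj, img = simulate_crossed(rng, n_subj=40, n_img=40,
                                           subj_sd=0.2, img_sd=0.1)
        fit = fit_lmm(y, X, subject_ids=subj, image_ids=img)
        assert fit.vc_sd["subject"] == pytest.approx(0.2, abs=0.07)
        assert fit.vc_sd["image"] == pytest.approx(0.1, abs=0.05)
        assert fit.residual_sd == pytest.approx(0.3, abs=0.03)

    def test_uncorrelated_image_slope_component(self):
        rng = np.random.default_rng(5)
        n_img, n_rep = 30, 8
        img = np.repeat(np.arange(n_img), n_rep)
        task = np.tile(np.array([-0.5, 0.5]), n_img * n_rep // 2)
        slopes = rng.normal(0, 0.4, n_img)
        y = 2.0 + 0.1 * task + slopes[img] * task \
            + rng.normal(0, 0.2, len(img))
        X = pd.DataFrame({"Intercept": np.ones(len(img)), "Task": task})
        fit = fit_lmm(y, X, image_ids=img, image_slope="Task")
        assert "image_slope" in fit.vc_sd
        assert fit.vc_sd["image_slope"] == pytest.approx(0.4, abs=0.15)

    def test_missing_values_rejected(self):
        y = np.array([1.0, np.nan])
        X = pd.DataFrame({"Intercept": [1.0, 1.0]})
        with pytest.raises(ValueError, match="missing"):
            fit_lmm(y, X)


class TestSignificanceReport:
    def _fit(self, est, se):
        return LMMFit(terms=["a"], estimates=np.array([est]),
                      se=np.array([se]), vc_sd={}, residual_sd=1.0,
                      loglik=0.0, converged=True)

    def test_t_of_exactly_two_not_flagged(self):
        rep = significance_report(self._fit(2.0, 1.0))
        assert not rep["significant"].iloc[0]

    def test_large_negative_t_flagged(self):
        rep = significance_report(self._fit(-3.34, 1.0))
        assert rep["significant"].iloc[0]

    def test_zero_se_degenerate(self):
        rep = significance_report(self._fit(1.0, 0.0))
        assert rep["degenerate"].iloc[0]
        assert not rep["significant"].iloc[0]

    def test_criterion_labelled_as_convention(self):
        rep = significance_report(self._fit(1.0, 1.0))
        assert "convention" in rep.attrs["criterion"]


def test_cfb_covariates_standardized():
    rng = np.random.default_rng(6)
    tab = pd.DataFrame({
        "start_distance_deg": rng.uniform(0, 15, 200),
        "sample": rng.integers(1, 30, 200),
    })
    cov = cfb_covariates(tab)
    for col in ("start_distance", "log_sample"):
        assert cov[col].mean() == pytest.approx(0.0, abs=1e-12)
        assert cov[col].std(ddof=1) == pytest.approx(1.0, abs=1e-12)
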