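import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

from histomarkers import survival as sv
from histomarkers import synthetic
from histomarkers.features import normalize_table
from oracles import partial_loglik_bruteforce


def _small_cohort(seed=0, n=30, p=2, beta=(0.8,), censor=0.25):
    df = synthetic.synth_survival_cohort(
        synthetic.SyntheticSurvivalSpec(n=n, p=p, true_beta=beta,
                                        censor_rate=censor, rng_seed=seed))
    return sv.cohort_arrays(df)


class TestPartialLikelihood:
    def test_null_beta_closed_form(self):
        # no ties, beta=0: ll = -sum over events of log |risk set|
        time = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        event = np.array([1, 1, 0, 1, 1])
        X = np.zeros((5, 1))
        expected = -(np.log(5) + np.log(4) + np.log(3) + np.log(1))
        ll = sv.cox_partial_loglik(np.zeros(1), X, time, event)
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_hand_expanded_three_subjects(self):
        """n=3, times (1,2,3) all events, x=(1,0,0), beta=1: the partial
        likelihood expands to three explicit terms."""
        X = np.array([[1.0], [0.0], [0.0]])
        time = np.array([1.0, 2.0, 3.0])
        event = np.array([1, 1, 1])
        e = np.e
        expected = (1 - np.log(e + 2)) + (0 - np.log(2)) + (0 - np.log(1))
        ll = sv.cox_partial_loglik(np.array([1.0]), X, time, event)
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariance(self):
        X, t, d = _small_cohort(1)
        beta = np.full(X.shape[1], 0.3)
        base = sv.cox_partial_loglik(beta, X.to_numpy(), t, d)
        rng = np.random.default_rng(0)
        for _ in range(3):
            perm = rng.permutation(len(t))
            ll = sv.cox_partial_loglik(beta, X.to_numpy()[perm], t[perm],
                                       d[perm])
            assert ll == pytest.approx(base, abs=1e-10)

    def test_matches_bruteforce_risk_sets(self):
        X, t, d = _small_cohort(2, n=25)
        beta = np.array([0.5, -0.3])
        mine = sv.cox_partial_loglik(beta, X.to_numpy(), t, d)
        ref = partial_loglik_bruteforce(beta, X.to_numpy(), t, d)
        assert mine == pytest.approx(ref, abs=1e-12)

    def test_matches_lifelines(self):
        X, t, d = _small_cohort(3, n=40)
        df = X.copy()
        df["time"], df["event"] = t, d
        cph = CoxPHFitter().fit(df, "time", "event")
        mine = sv.cox_partial_loglik(cph.params_.to_numpy(), X.to_numpy(),
                                     t, d)
        assert mine == pytest.approx(cph.log_likelihood_, abs=1e-8)


class TestUnivariateScreen:
    def test_null_features_retained_at_threshold_rate(self):
        """p-values of pure-noise covariates are uniform, so a 0.25
        threshold retains about a quarter of 200 noise features."""
        rng = np.random.default_rng(0)
        df = synthetic.synth_survival_cohort(
            synthetic.SyntheticSurvivalSpec(n=300, p=1, censor_rate=0.2,
                                            rng_seed=4))
        noise = pd.DataFrame(rng.standard_normal((300, 200)),
                             columns=[f"n{j}" for j in range(200)])
        screen = sv.univariate_screen(noise, df["time"].to_numpy(),
                                      df["event"].to_numpy(int), 0.25)
        frac = screen["retained"].mean()
        assert abs(frac - 0.25) <= 0.08

    def test_true_predictor_retained(self):
        X, t, d = _small_cohort(5, n=150, beta=(1.0,))
        screen = sv.univariate_screen(X[["x1"]], t, d, 0.25)
        assert bool(screen.loc["x1", "retained"])

    def test_threshold_one_retains_everything(self):
        X, t, d = _small_cohort(6, n=60, p=4)
        screen = sv.univariate_screen(X, t, d, p_threshold=1.0)
        assert screen["retained"].all()


class TestCoxBoost:
    def test_converges_to_mle_single_covariate(self):
        X, t, d = _small_cohort(1, n=150, p=1, beta=(0.8,))
        model = sv.coxboost_fit(X, t, d, M=300, penalty=0.0)
        df = X.copy()
        df["time"], df["event"] = t, d
        cph = CoxPHFitter().fit(df, "time", "event")
        assert abs(model.beta["x1"] - cph.params_["x1"]) < 1e-4

    def test_infinite_penalty_freezes_coefficients(self):
        X, t, d = _small_cohort(2, n=100, p=5, beta=(1.0,))
        model = sv.coxboost_fit(X, t, d, M=50, penalty=1e12)
        assert model.beta.abs().max() < 1e-6

    def test_path_shape_and_sparsity(self):
        X, t, d = _small_cohort(3, n=100, p=20, beta=(0.7, -0.7))
        M = 15
        model = sv.coxboost_fit(X, t, d, M=M, penalty=50.0)
        assert model.path.shape == (M + 1, 20)
        assert not model.path[0].any()
        # componentwise: consecutive path entries differ in one coordinate
        for a, b in zip(model.path, model.path[1:]):
            assert (a != b).sum() <= 1
        assert len(model.selected) <= M

    def test_training_likelihood_monotone_along_path(self):
        X, t, d = _small_cohort(4, n=120, p=10, beta=(0.8, -0.8))
        model = sv.coxboost_fit(X, t, d, M=25, penalty=30.0)
        lls = [sv.cox_partial_loglik(b, X.to_numpy(), t, d)
               for b in model.path]
        assert all(b >= a - 1e-10 for a, b in zip(lls, lls[1:]))

    def test_scaling_equivariance(self):
        X, t, d = _small_cohort(5, n=150, p=1, beta=(0.8,))
        model1 = sv.coxboost_fit(X, t, d, M=150, penalty=0.0)
        Xc = X * 2.0
        model2 = sv.coxboost_fit(Xc, t, d, M=150, penalty=0.0)
        assert model2.beta["x1"] == pytest.approx(model1.beta["x1"] / 2,
                                                  abs=1e-3)

    def test_mandatory_covariate_unpenalized(self):
        X, t, d = _small_cohort(6, n=150, p=5, beta=(1.0,))
        model = sv.coxboost_fit(X, t, d, M=5, penalty=1e12,
                                mandatory=["x1"])
        # candidates frozen by the huge penalty, mandatory still fitted
        assert abs(model.beta["x1"]) > 0.3
        assert model.beta.drop("x1").abs().max() < 1e-6


class TestCrossValidation:
    def test_null_data_prefers_no_boosting(self):
        votes = 0
        for seed in range(5):
            df = synthetic.synth_survival_cohort(
                synthetic.SyntheticSurvivalSpec(n=150, p=20,
                                                censor_rate=0.3,
                                                rng_seed=seed))
            X, t, d = sv.cohort_arrays(df)
            m_opt, _ = sv.cv_choose_steps(X, t, d, 9.0 * d.sum(),
                                          range(0, 31, 10), rng_seed=seed)
            votes += m_opt == 0
        assert votes >= 3

    def test_signal_improves_heldout_likelihood(self,
                                                strong_survival_cohort):
        X, t, d = sv.cohort_arrays(strong_survival_cohort)
        m_opt, curve = sv.cv_choose_steps(X, t, d, 5.0 * d.sum(),
                                          range(0, 51, 10), rng_seed=1)
        lls = curve["mean_heldout_loglik"]
        assert m_opt > 0
        assert lls.max() > lls.iloc[0]

    def test_deterministic(self, strong_survival_cohort):
        X, t, d = sv.cohort_arrays(strong_survival_cohort)
        out1 = sv.cv_choose_steps(X, t, d, 500.0, [0, 10, 20], rng_seed=7)
        out2 = sv.cv_choose_steps(X, t, d, 500.0, [0, 10, 20], rng_seed=7)
        assert out1[0] == out2[0]
        pd.testing.assert_frame_equal(out1[1], out2[1])


class TestTimeDependentROC:
    def test_perfect_anticoncordant_score(self):
        rng = np.random.default_rng(0)
        t = rng.uniform(1, 100, 40)
        d = np.ones(40, dtype=int)
        scores = -t
        for q in (0.25, 0.5, 0.75):
            auc = sv.time_dependent_auc(scores, t, d, np.quantile(t, q))
            assert auc == pytest.approx(1.0)

    def test_matches_pairwise_concordance(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(1, 50, 20)
        d = np.ones(20, dtype=int)
        scores = rng.standard_normal(20)
        t_eval = float(np.median(t))
        auc = sv.time_dependent_auc(scores, t, d, t_eval)
        cases = t <= t_eval
        num = den = 0.0
        for sc in scores[cases]:
            for sn in scores[~cases]:
                num += 1.0 if sc > sn else (0.5 if sc == sn else 0.0)
                den += 1
        assert auc == pytest.approx(num / den, abs=1e-12)

    def test_identical_scores_single_group(self, strong_survival_cohort):
        X, t, d = sv.cohort_arrays(strong_survival_cohort)
        model = sv.coxboost_fit(X.iloc[:, :3] * 0.0, t, d, M=1,
                                penalty=1e9)
        with pytest.warns(UserWarning):
            report = sv.risk_scores_and_threshold(model, X.iloc[:, :3] * 0.0,
                                                  t, d)
        assert report.auc == 0.5
        assert set(report.groups) == {"low"}


class TestKaplanMeierLogrank:
    def test_hand_product_limit(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        d = np.ones(4, dtype=int)
        curve = sv.km_curve(t, d)
        assert np.allclose(curve["survival"], [0.75, 0.5, 0.25, 0.0])

    def test_identical_groups_null_statistic(self):
        X, t, d = _small_cohort(7, n=20)
        t2 = np.concatenate([t, t])
        d2 = np.concatenate([d, d])
        groups = np.array(["a"] * 20 + ["b"] * 20)
        _, chi2, p = sv.km_logrank(t2, d2, groups)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0, abs=1e-10)

    def test_agrees_with_lifelines(self):
        X, t, d = _small_cohort(8, n=30)
        groups = np.where(np.arange(30) % 2 == 0, "a", "b")
        curves, chi2, p = sv.km_logrank(t, d, groups)
        res = logrank_test(t[groups == "a"], t[groups == "b"],
                           d[groups == "a"], d[groups == "b"])
        assert chi2 == pytest.approx(res.test_statistic, abs=1e-6)
        assert p == pytest.approx(res.p_value, abs=1e-6)
        kmf = KaplanMeierFitter().fit(t[groups == "a"], d[groups == "a"])
        mine = curves["a"]
        for _, row in mine.iterrows():
            assert row["survival"] == pytest.approx(
                kmf.predict(row["time"]), abs=1e-6)


class TestBootstrap:
    def test_single_replicate_binary_frequencies(self):
        X, t, d = _small_cohort(9, n=60, p=5, beta=(1.0,))
        freq = sv.bootstrap_selection(X, t, d, B=1, penalty=100.0, M=5,
                                      rng_seed=0)
        assert set(freq.unique()) <= {0.0, 1.0}

    def test_deterministic(self, strong_survival_cohort):
        X, t, d = sv.cohort_arrays(strong_survival_cohort)
        f1 = sv.bootstrap_selection(X, t, d, B=5, penalty=5 * d.sum(),
                                    M=10, rng_seed=3)
        f2 = sv.bootstrap_selection(X, t, d, B=5, penalty=5 * d.sum(),
                                    M=10, rng_seed=3)
        pd.testing.assert_series_equal(f1, f2)


class TestMultivariateCox:
    def test_hazard_ratio_identity_and_recovery(self):
        df = synthetic.synth_survival_cohort(
            synthetic.SyntheticSurvivalSpec(n=500, p=3,
                                            true_beta=(0.8, -0.5),
                                            censor_rate=0.2, rng_seed=12))
        X, t, d = sv.cohort_arrays(df)
        rep = sv.multivariate_cox_report(X, t, d)
        assert np.allclose(rep.table["hazard_ratio"],
                           np.exp(rep.table["coef"]))
        assert abs(rep.table.loc["x1", "coef"] - 0.8) <= 0.2
        assert abs(rep.table.loc["x2", "coef"] + 0.5) <= 0.2

    def test_informative_risk_score_lowers_aic(self, strong_survival_cohort):
        X, t, d = sv.cohort_arrays(strong_survival_cohort)
        rng = np.random.default_rng(0)
        clinical = pd.DataFrame({
            "age": rng.uniform(40, 80, len(t)),
            "gender": rng.integers(0, 2, len(t)).astype(float),
        })
        base = sv.multivariate_cox_report(clinical, t, d)
        model = sv.coxboost_fit(X, t, d, M=30, penalty=5.0 * d.sum())
        withscore = sv.multivariate_cox_report(
            clinical, t, d, risk_score=model.linear_predictor(X))
        assert withscore.aic < base.aic
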