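import numpy as np
import pandas as pd
import pytest
from scipy import stats

from becorr.classify import (
    LofGaussianMixture,
    evaluate,
    fit_gmm,
    lof_posterior_and_call,
    model_selection_report,
    wald_bh,
)
from oracles import bh_stepup, fisher_exact_p, grid_cutoff


def make_mixture(weights, means, variances, threshold=0.8):
    """Construct a LofGaussianMixture with prescribed parameters."""
    from sklearn.mixture import GaussianMixture

    k = len(weights)
    gm = GaussianMixture(n_components=k, covariance_type="full")
    gm.weights_ = np.asarray(weights, dtype=float)
    gm.means_ = np.asarray(means, dtype=float).reshape(-1, 1)
    gm.covariances_ = np.asarray(variances, dtype=float).reshape(-1, 1, 1)
    gm.precisions_cholesky_ = 1.0 / np.sqrt(gm.covariances_)
    m = LofGaussianMixture(n_components=k, threshold=threshold)
    m.gmm_ = gm
    m.weights_ = gm.weights_.copy()
    m.means_ = gm.means_.ravel().copy()
    m.variances_ = gm.covariances_.reshape(-1).copy()
    neg = np.flatnonzero(m.means_ < 0)
    if neg.size != 2:
        neg = np.argsort(m.means_)[:2]
    m.negative_components_ = np.sort(neg)
    m.converged_ = True
    m.beta_cutoff_ = m._find_cutoff()
    return m


class TestFit:
    def test_recovers_separated_components(self):
        rng = np.random.default_rng(123)
        true_means = np.array([-3.0, -1.5, 0.0, 1.5])
        x = np.concatenate([rng.normal(mu, 0.2, 1000) for mu in true_means])
        fit = fit_gmm(x, seed=123)
        assert np.allclose(np.sort(fit.means_), true_means, atol=0.05)
        assert fit.converged_
        # structure: two negative-mean components are the two lowest
        assert set(fit.negative_components_) == set(np.argsort(fit.means_)[:2])

    def test_degenerate_input_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gmm(np.zeros(100))

    def test_too_few_scores_raises(self):
        with pytest.raises(ValueError, match="finite scores"):
            fit_gmm(np.arange(10.0))

    def test_posteriors_sum_to_one(self):
        rng = np.random.default_rng(5)
        x = np.concatenate([rng.normal(m, 0.3, 500) for m in (-2, -1, 0, 1)])
        fit = fit_gmm(x, seed=5)
        resp = fit.gmm_.predict_proba(np.linspace(-4, 3, 200)[:, None])
        assert np.allclose(resp.sum(axis=1), 1.0, atol=1e-12)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        x = np.concatenate([rng.normal(m, 0.3, 300) for m in (-2, -0.8, 0, 1)])
        f1 = fit_gmm(x, seed=7)
        f2 = fit_gmm(x, seed=7)
        assert np.array_equal(f1.means_, f2.means_)


class TestPosteriorAndCutoff:
    MIX = dict(weights=[0.50, 0.44, 0.03, 0.03],
               means=[0.0, -1.0, 1.5, -2.0],
               variances=[0.04, 0.04, 0.25, 0.09])

    def test_far_negative_score_called(self):
        m = make_mixture(**self.MIX)
        assert m.posterior([-2.5])[0] > 0.99
        assert m.predict([-2.5])[0]

    def test_null_mean_score_not_called(self):
        m = make_mixture(**self.MIX)
        assert m.posterior([0.0])[0] < 0.2
        assert not m.predict([0.0])[0]

    def test_cutoff_between_negative_and_null_means(self):
        m = make_mixture(**self.MIX)
        assert -1.0 < m.beta_cutoff_ < 0.0

    def test_bisection_matches_grid_oracle(self):
        m = make_mixture(**self.MIX)

        def oracle_posterior(x):
            x = np.asarray(x, dtype=float)
            dens = np.array([w * stats.norm.pdf(x, mu, np.sqrt(v))
                             for w, mu, v in zip(self.MIX["weights"],
                                                 self.MIX["means"],
                                                 self.MIX["variances"])])
            return (dens[1] + dens[3]) / dens.sum(axis=0)

        oracle = grid_cutoff(oracle_posterior, -2.5, 0.5, 0.8)
        assert m.beta_cutoff_ == pytest.approx(oracle, abs=1e-4)

    def test_monotone_check_passes_for_separated_fit(self):
        m = make_mixture(**self.MIX)
        assert m.check_monotone()

    def test_functional_wrapper(self):
        m = make_mixture(**self.MIX)
        out = lof_posterior_and_call([-2.5, 0.0], m)
        assert out["lof_call"].tolist() == [True, False]
        assert np.allclose(out["beta_cutoff"], m.beta_cutoff_)


class TestWaldBH:
    def test_hand_wald_example(self):
        # mean -1.0, SE 0.5 -> z = -2, two-sided p ~ 0.0455
        beta = pd.DataFrame({"r1": [-1.5], "r2": [-0.5]})
        # sd = 0.7071, se = 0.5
        out = wald_bh(beta)
        assert out["wald_z"].iloc[0] == pytest.approx(-2.0)
        assert out["wald_p"].iloc[0] == pytest.approx(0.0455, abs=2e-4)

    def test_all_zero_replicates(self):
        out = wald_bh(pd.DataFrame({"r1": [0.0], "r2": [0.0]}))
        assert out["wald_p"].iloc[0] == 1.0
        assert bool(out["se_zero"].iloc[0])

    def test_se_zero_nonzero_mean(self):
        out = wald_bh(pd.DataFrame({"r1": [-1.0], "r2": [-1.0]}))
        assert out["wald_p"].iloc[0] == 0.0
        assert bool(out["se_zero"].iloc[0])

    def test_bh_hand_example(self):
        # p = (.01,.02,.03,.04): the step-up makes every adjusted p 0.04
        assert np.allclose(bh_stepup([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        z = stats.norm.isf(np.array([0.01, 0.02, 0.03, 0.04]) / 2)
        # build replicate pairs with mean/SE reproducing those z values
        beta = pd.DataFrame({"r1": z + 1, "r2": z - 1})  # se = 1/sqrt(2)*sqrt(2)=1
        out = wald_bh(beta)
        assert np.allclose(out["wald_p"], [0.01, 0.02, 0.03, 0.04], atol=1e-12)
        assert np.allclose(out["bh_p"], 0.04)

    def test_bh_matches_oracle_on_random_pvectors(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(3)
        for _ in range(20):
            ps = rng.uniform(0, 1, rng.integers(2, 40))
            got = multipletests(ps, method="fdr_bh")[1]
            assert np.allclose(got, bh_stepup(list(ps)), atol=1e-12)


class TestEvaluate:
    def _calls(self, betas, lof, types=None):
        df = pd.DataFrame({"mean_beta": betas, "lof_call": lof})
        if types is not None:
            df["mutational_type"] = types
        df.index = [f"v{i}" for i in range(len(df))]
        return df

    def test_perfect_separation_auc_one(self):
        calls = self._calls([-2, -1.5, 0.1, 0.2], [True, True, False, False])
        labels = pd.Series(["P/LP", "P/LP", "B/LB", "B/LB"], index=calls.index)
        rep = evaluate(calls, labels)
        assert rep["auc"] == 1.0
        assert rep["call_sensitivity"] == 1.0
        assert rep["call_specificity"] == 1.0

    def test_permuted_labels_auc_near_half(self):
        rng = np.random.default_rng(11)
        n = 2000
        calls = self._calls(rng.normal(0, 1, n), [False] * n)
        labels = pd.Series(rng.permutation(["P/LP"] * (n // 2) + ["B/LB"] * (n // 2)),
                           index=calls.index)
        rep = evaluate(calls, labels)
        assert abs(rep["auc"] - 0.5) < 0.04

    def test_fisher_matches_hypergeometric_oracle(self):
        _, p = stats.fisher_exact([[10, 90], [50, 50]], alternative="two-sided")
        assert p == pytest.approx(fisher_exact_p(10, 90, 50, 50), rel=1e-9)

    def test_enrichment_table(self):
        calls = self._calls([-2, -1.5, 0.0, 0.1], [True, True, False, False],
                            types=["stop_gain", "stop_gain", "synonymous", "synonymous"])
        rep = evaluate(calls)
        enr = rep["enrichment"].set_index("mutational_type")
        assert enr.loc["stop_gain", "lof_fraction"] == 1.0
        assert enr.loc["synonymous", "lof_fraction"] == 0.0


def test_model_selection_reports_candidate_ks():
    rng = np.random.default_rng(2)
    x = np.concatenate([rng.normal(m, 0.3, 400) for m in (-1.5, 0.0)])
    rep = model_selection_report(x, ks=[2, 3, 4], seed=2)
    assert rep["n_components"].tolist() == [2, 3, 4]
    assert rep["bic"].idxmin() == 0  # two true components
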