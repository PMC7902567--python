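import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

import tripletaft as ta
from tripletaft.aft import (
    AftData,
    BayesianAFT,
    PosteriorDraws,
    log_likelihood,
    log_posterior,
    pool_imputations,
    rhat,
    sample_posterior,
)
from tripletaft.priors import NormalPrior, PriorSpec


def intercept_data(times, events=None):
    times = np.asarray(times, dtype=float)
    events = np.ones_like(times) if events is None else np.asarray(events, float)
    return AftData(X=np.ones((len(times), 1)), time=times, event=events,
                   labels=["intercept"])


def simple_priors(intercept=NormalPrior(0, 1), log_sigma=NormalPrior(0, 1)):
    return PriorSpec(priors={"intercept": intercept, "log_sigma": log_sigma},
                     classes={"intercept": "intercept", "log_sigma": "log-scale"})


class TestLogLikelihood:
    def test_single_uncensored_at_location(self):
        # t = 1 month, x'beta = 0, sigma = 1: lognormal logpdf = -0.5 ln(2 pi)
        data = intercept_data([1.0])
        assert log_likelihood(np.zeros(1), 0.0, data) == pytest.approx(-0.9189385, abs=1e-6)

    def test_censored_at_median_is_log_half(self):
        data = intercept_data([np.exp(1.3)], events=[0])
        assert log_likelihood(np.array([1.3]), 0.0, data) == pytest.approx(np.log(0.5))

    def test_additivity_over_records(self):
        d1 = intercept_data([2.0], events=[1])
        d2 = intercept_data([5.0], events=[0])
        both = AftData(X=np.ones((2, 1)), time=np.array([2.0, 5.0]),
                       event=np.array([1.0, 0.0]), labels=["intercept"])
        beta = np.array([0.4])
        assert log_likelihood(beta, -0.2, both) == pytest.approx(
            log_likelihood(beta, -0.2, d1) + log_likelihood(beta, -0.2, d2)
        )

    def test_matches_scipy_lognormal_density(self, rng):
        t = rng.lognormal(1.0, 0.7, size=50)
        data = intercept_data(t)
        ours = log_likelihood(np.array([1.2]), np.log(0.7), data)
        ref = stats.lognorm.logpdf(t, s=0.7, scale=np.exp(1.2)).sum()
        assert ours == pytest.approx(ref)

    def test_nonfinite_parameters_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(np.array([np.nan]), 0.0, intercept_data([1.0]))

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError, match="strictly positive"):
            intercept_data([0.0])


class TestLogPosterior:
    def test_flat_prior_shifts_likelihood_by_constant(self):
        data = intercept_data([1.0, 3.0, 8.0], events=[1, 1, 0])
        priors = simple_priors(NormalPrior(0, 100), NormalPrior(0, 100))
        b1, b2 = np.array([0.3]), np.array([1.1])
        d_post = log_posterior(b1, 0.1, data, priors) - log_posterior(b2, 0.1, data, priors)
        d_lik = log_likelihood(b1, 0.1, data) - log_likelihood(b2, 0.1, data)
        assert d_post == pytest.approx(d_lik, abs=1e-4)

    def test_conjugate_density_ratio(self, rng):
        # known sigma=1: posterior for the location is normal with closed form
        t = rng.lognormal(0.5, 1.0, size=30)
        data = intercept_data(t)
        priors = simple_priors(NormalPrior(0, 1), NormalPrior(0, 1))
        n = len(t)
        post_var = 1 / (n + 1)
        post_mean = post_var * np.log(t).sum()
        b1, b2 = np.array([0.2]), np.array([0.8])
        ours = log_posterior(b1, 0.0, data, priors) - log_posterior(b2, 0.0, data, priors)
        ref = stats.norm.logpdf(b1[0], post_mean, np.sqrt(post_var)) - \
            stats.norm.logpdf(b2[0], post_mean, np.sqrt(post_var))
        assert ours == pytest.approx(ref)

    def test_missing_prior_label_reported(self):
        data = AftData(X=np.ones((2, 2)), time=np.array([1.0, 2.0]),
                       event=np.array([1.0, 1.0]), labels=["intercept", "slope"])
        with pytest.raises(ValueError, match="slope"):
            log_posterior(np.zeros(2), 0.0, data, simple_priors())


class TestSampler:
    def test_conjugate_posterior_recovered(self, rng):
        t = rng.lognormal(0.4, 1.0, size=25)
        data = intercept_data(t)
        # near-point-mass prior pins sigma at its known value of 1
        priors = simple_priors(NormalPrior(0, 1), NormalPrior(0, 1e-4))
        d = sample_posterior(data, priors, n_chains=4, n_warmup=500, n_iter=1500, seed=5)
        n = len(t)
        post_var = 1 / (n + 1)
        post_mean = post_var * np.log(t).sum()
        mu = d.extract("intercept")
        mcse = np.sqrt(post_var) / np.sqrt(d.convergence.ess["intercept"])
        assert abs(mu.mean() - post_mean) < 3 * mcse + 1e-3
        assert mu.std(ddof=1) == pytest.approx(np.sqrt(post_var), rel=0.1)

    def test_deterministic_under_seed(self):
        data = intercept_data([1.0, 2.0, 4.0, 9.0], events=[1, 1, 1, 0])
        priors = simple_priors()
        a = sample_posterior(data, priors, n_chains=2, n_warmup=100, n_iter=200, seed=3)
        b = sample_posterior(data, priors, n_chains=2, n_warmup=100, n_iter=200, seed=3)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_flat_prior_median_tracks_mle(self, rng):
        # one binary covariate: closed-form MLE by per-group means of log time
        n = 300
        x = (rng.uniform(size=n) < 0.5).astype(float)
        t = np.exp(1.0 + 0.6 * x + 0.8 * rng.standard_normal(n))
        data = AftData(X=np.column_stack([np.ones(n), x]), time=t,
                       event=np.ones(n), labels=["intercept", "x"])
        priors = PriorSpec(
            priors={"intercept": NormalPrior(0, 100), "x": NormalPrior(0, 100),
                    "log_sigma": NormalPrior(0, 2)},
            classes={"intercept": "intercept", "x": "nuisance", "log_sigma": "log-scale"},
        )
        d = sample_posterior(data, priors, n_chains=2, n_warmup=500, n_iter=2000, seed=8)
        logt = np.log(t)
        mle_slope = logt[x == 1].mean() - logt[x == 0].mean()
        assert np.median(d.extract("x")) == pytest.approx(mle_slope, abs=0.01)

    def test_single_chain_rejected(self):
        data = intercept_data([1.0, 2.0])
        with pytest.raises(ValueError, match="chains"):
            sample_posterior(data, simple_priors(), n_chains=1)


class TestDiagnostics:
    def test_identical_distribution_chains_near_one(self, rng):
        draws = PosteriorDraws(draws=rng.standard_normal((2, 4000, 1)), labels=["b"])
        report = rhat(draws)
        assert report.rhat["b"] == pytest.approx(1.0, abs=0.01)
        assert report.passed

    def test_separated_chains_flagged(self, rng):
        sep = np.stack([rng.standard_normal((500, 1)), 10 + rng.standard_normal((500, 1))])
        report = rhat(PosteriorDraws(draws=sep, labels=["b"]))
        assert report.rhat["b"] > 1.1
        assert not report.passed

    def test_pass_flag_is_conjunction_over_parameters(self, rng):
        good = rng.standard_normal((2, 500, 1))
        bad = np.stack([rng.standard_normal((500, 1)), 8 + rng.standard_normal((500, 1))])
        draws = PosteriorDraws(draws=np.concatenate([good, bad], axis=2), labels=["a", "b"])
        report = rhat(draws)
        assert report.rhat["a"] < 1.1 < report.rhat["b"]
        assert not report.passed

    def test_iid_ess_near_sample_size(self, rng):
        draws = PosteriorDraws(draws=rng.standard_normal((4, 1000, 1)), labels=["b"])
        ess = rhat(draws).ess["b"]
        assert 2000 < ess  # 4000 iid draws; estimator noise allowed

    def test_matches_arviz_rhat(self, rng):
        arviz = pytest.importorskip("arviz")
        raw = rng.standard_normal((4, 800, 2)).cumsum(axis=1) * 0.01 + \
            rng.standard_normal((4, 800, 2))
        draws = PosteriorDraws(draws=raw, labels=["a", "b"])
        ours = rhat(draws).rhat
        ref = arviz.rhat(arviz.convert_to_dataset(raw))
        for j, lab in enumerate(["a", "b"]):
            assert ours[lab] == pytest.approx(float(ref["x"][j]), abs=0.01)


class TestPooling:
    def test_mixture_of_degenerate_posteriors(self):
        a = PosteriorDraws(draws=np.zeros((2, 50, 1)), labels=["b"])
        b = PosteriorDraws(draws=np.full((2, 50, 1), 0.2), labels=["b"])
        pooled = pool_imputations([a, b])
        assert pooled.extract("b").mean() == pytest.approx(0.1)

    def test_pooling_copies_preserves_summaries(self, rng):
        d = PosteriorDraws(draws=rng.standard_normal((2, 200, 1)), labels=["b"])
        pooled = pool_imputations([d, d, d])
        assert pooled.extract("b").mean() == pytest.approx(d.extract("b").mean())
        assert pooled.extract("b").std() == pytest.approx(d.extract("b").std(), rel=1e-6)

    def test_pooled_variance_dominates_mean_within_variance(self, rng):
        sets = [PosteriorDraws(draws=rng.standard_normal((2, 300, 1)) + mu, labels=["b"])
                for mu in (-0.3, 0.0, 0.4)]
        pooled = pool_imputations(sets)
        within = np.mean([d.extract("b").var() for d in sets])
        assert pooled.extract("b").var() >= within

    def test_label_mismatch_rejected(self, rng):
        a = PosteriorDraws(draws=rng.standard_normal((2, 10, 1)), labels=["b"])
        b = PosteriorDraws(draws=rng.standard_normal((2, 10, 1)), labels=["c"])
        with pytest.raises(ValueError, match="labels"):
            pool_imputations([a, b])


class TestGroundTruthRecovery:
    def test_uncensored_flat_prior_fit_recovers_generator_truth(self):
        """Fitting the PFS model with flat priors to a large uncensored
        cohort recovers every true coefficient within 3 posterior sd."""
        cfg = ta.default_config(n=20_000, seed=77)
        cfg.missingness = {}
        cfg.censoring = None
        cohort = ta.generate_cohort(cfg)
        coef = cfg.truth["pfs"]["coef"]
        feats = ta.registry.truth_features(cohort, arm=cohort["arm"])
        cols = [np.ones(len(cohort))]
        labels = ["intercept"]
        for name in coef:
            if ":" in name:
                a, b = name.split(":", 1)
                cols.append(feats[a].to_numpy() * feats[b].to_numpy())
            else:
                cols.append(feats[name].to_numpy())
            labels.append(name)
        data = AftData(X=np.column_stack(cols), time=cohort["pfs_time"].to_numpy(),
                       event=cohort["pfs_event"].to_numpy(), labels=labels)
        priors = PriorSpec(
            priors={**{l: NormalPrior(0, 100) for l in labels},
                    "log_sigma": NormalPrior(0, 2)},
            classes={**{l: "nuisance" for l in labels}, "intercept": "intercept",
                     "log_sigma": "log-scale"},
        )
        draws = sample_posterior(data, priors, n_chains=2, n_warmup=400,
                                 n_iter=1000, seed=13)
        truth = {"intercept": cfg.truth["pfs"]["intercept"], **coef}
        for lab in labels:
            sample = draws.extract(lab)
            err = abs(np.median(sample) - truth[lab])
            assert err < 3 * sample.std(ddof=1), (lab, np.median(sample), truth[lab])
        sigma = np.exp(draws.extract("log_sigma"))
        assert np.median(sigma) == pytest.approx(cfg.truth["pfs"]["sigma"], rel=0.03)


class TestEstimator:
    def test_fitted_attributes_and_convergence(self, small_fit):
        assert small_fit.convergence_.passed
        assert small_fit.coef_.index.tolist() == small_fit.spec_.labels()
        assert small_fit.scale_ > 0
        assert small_fit.draws_.n_chains == 2

    def test_sklearn_params_protocol(self):
        model = BayesianAFT(endpoint="pfs", n_draws=123)
        cloned = clone(model)
        assert cloned.get_params()["n_draws"] == 123
        cloned.set_params(endpoint="os")
        assert cloned.endpoint == "os"

    def test_predict_median_survival_scale(self, small_fit, complete_cohort):
        preds = small_fit.predict(complete_cohort.head(20))
        assert preds.shape == (20,)
        assert np.all(preds > 0)
        # predictions should live on the months scale of the cohort
        assert 1 < np.median(preds) < 40

    def test_fit_imputed_pools_draws(self, default_cohort):
        sets = ta.impute_cohort(default_cohort.head(250), m=2, n_iter=2, seed=4)
        model = BayesianAFT(endpoint="os", prior_mode="weak", interactions=(),
                            n_chains=2, n_warmup=200, n_draws=300, seed=1)
        model.fit_imputed(sets)
        assert model.draws_.n_chains == 2 * 2
        assert len(model.per_imputation_convergence_) == 2

    def test_missing_outcome_column_rejected(self, complete_cohort):
        model = BayesianAFT(endpoint="os")
        with pytest.raises(ValueError, match="os_time"):
            model.fit(complete_cohort.drop(columns=["os_time"]))


def test_draws_csv_roundtrip(tmp_path, small_fit):
    path = tmp_path / "draws.csv"
    small_fit.draws_.save(path)
    back = PosteriorDraws.load(path)
    assert back.labels == small_fit.draws_.labels
    np.testing.assert_allclose(back.draws, small_fit.draws_.draws)
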