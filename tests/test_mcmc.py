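import math

import numpy as np
import pytest
from scipy.special import logit

from mrocc.data_model import Region, Site, StudyDataset, augment
from mrocc.mcmc import PosteriorSamples, SamplerConfig, ess, fit, rhat, run, summarize
from mrocc.model_core import Design, ModelParams

from _oracles import enumerate_richness_posterior


def _fixed_params(Omega, psi, p, R=1, M=3):
    beta = np.zeros(10)
    beta[0] = logit(Omega)
    theta = np.zeros(5)
    theta[0] = logit(psi)
    alpha = np.zeros(3)
    alpha[0] = logit(p)
    return ModelParams(
        beta=beta, theta=theta, alpha=alpha,
        sigma_psi=np.ones(R), sigma_p=np.ones(R),
        eps_psi=np.zeros((R, M)), eps_p=np.zeros((R, M)),
    )


def _design(R=1, J=2, K=2):
    X = np.zeros((R, 10))
    X[:, 0] = 1.0
    return Design(
        X_rich=X, X_occ=np.zeros((R, 4)), cam=np.zeros((R, J)),
        settl_site=np.zeros((R, J)), site_mask=np.ones((R, J), bool),
        K=np.full((R, J), float(K)), region_ids=[f"R{r+1:02d}" for r in range(R)],
    )


def _tiny_aug(y_obs, M=3, K=2):
    J = y_obs.shape[1]
    sites = [Site(f"s{j}", K, 1000.0, "fast") for j in range(J)]
    species = [f"sp{i}" for i in range(y_obs.shape[0])]
    data = StudyDataset([Region("R01", "Afrotropics", sites, species, y_obs)])
    return augment(data, M)


class TestSamplerCore:
    def test_same_seed_identical_draws(self):
        aug = _tiny_aug(np.array([[1, 0]]))
        cfg = SamplerConfig(n_chains=2, n_iter=300, n_burnin=100, seed=3,
                            record_lp=True)
        fx = _fixed_params(0.6, 0.5, 0.4)
        s1 = run(aug, _design(), config=cfg, fixed_params=fx)
        s2 = run(aug, _design(), config=cfg, fixed_params=fx)
        for k in s1.draws:
            np.testing.assert_array_equal(s1.draws[k], s2.draws[k])

    def test_richness_draws_within_support(self):
        aug = _tiny_aug(np.array([[1, 0], [0, 2]]), M=4)
        s = run(aug, _design(), config=SamplerConfig(
            n_chains=1, n_iter=500, n_burnin=100, seed=1),
        )
        N = s.draws["N"]
        assert N.min() >= 2 and N.max() <= 4

    def test_matches_enumeration_small_instance(self):
        # fixed continuous parameters; richness posterior vs brute force
        Omega, psi, p = 0.45, 0.6, 0.35
        y_obs = np.array([[2, 0], [0, 1]])
        aug = _tiny_aug(y_obs, M=3)
        y_aug = np.zeros((3, 2), dtype=int)
        y_aug[:2] = y_obs
        exact = enumerate_richness_posterior(y_aug, 2, Omega, psi, p)
        s = run(
            aug, _design(), fixed_params=_fixed_params(Omega, psi, p),
            config=SamplerConfig(n_chains=1, n_iter=42_000, n_burnin=2_000,
                                 seed=2, record_lp=False),
        )
        N = s.draws["N"].ravel()
        mc = np.bincount(N, minlength=4) / N.size
        assert 0.5 * np.abs(mc - exact).sum() < 0.02

    def test_region_order_invariance_of_marginals(self):
        # two regions with different data; per-region richness posterior is
        # unchanged (up to MC error) when the regions are swapped
        Omega, psi, p = 0.5, 0.5, 0.4
        yA, yB = np.array([[2, 1]]), np.array([[1, 0], [0, 1]])
        cfg = SamplerConfig(n_chains=1, n_iter=30_000, n_burnin=2_000, seed=9,
                            record_lp=False)

        def posterior(y_list):
            sites = lambda: [Site(f"s{j}", 2, 1000.0, "fast") for j in range(2)]
            regions = [
                Region(f"R{i+1:02d}", "Afrotropics", sites(),
                       [f"sp{i}{k}" for k in range(y.shape[0])], y)
                for i, y in enumerate(y_list)
            ]
            aug = augment(StudyDataset(regions), 3)
            s = run(aug, _design(R=2), config=cfg,
                    fixed_params=_fixed_params(Omega, psi, p, R=2))
            out = {}
            for r, rid in enumerate(s.region_ids):
                N = s.draws["N"][:, :, r].ravel()
                out[tuple(np.sort(y_list[r].ravel()))] = (
                    np.bincount(N, minlength=4) / N.size
                )
            return out

        a = posterior([yA, yB])
        b = posterior([yB, yA])
        for key in a:
            assert 0.5 * np.abs(a[key] - b[key]).sum() < 0.02

    def test_acceptance_rates_in_healthy_window(self, small_fit):
        for block, rate in small_fit.acceptance.items():
            assert 0.15 <= rate <= 0.6, (block, rate)

    def test_retained_count_matches_config(self, small_fit):
        cfg = small_fit.config
        assert small_fit.draws["beta"].shape[:2] == (
            cfg.n_chains, cfg.n_retained
        )

    def test_richness_support_on_real_fit(self, small_fit):
        N = small_fit.draws["N"]
        for r in range(len(small_fit.region_ids)):
            assert N[:, :, r].min() >= small_fit.n_obs[r]
            assert N[:, :, r].max() <= small_fit.M

    def test_impossible_initialization_recovers_via_fallback(self):
        # psi = p = 1 numerically: random z init is impossible, fallback works
        aug = _tiny_aug(np.array([[2, 2]]))
        fx = _fixed_params(0.5, 0.5, 0.5)
        fx.theta[0] = 500.0
        fx.alpha[0] = 500.0
        s = run(aug, _design(), fixed_params=fx,
                config=SamplerConfig(n_chains=1, n_iter=200, n_burnin=50,
                                     seed=0, record_lp=False))
        assert (s.draws["N"] == 1).all()

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            SamplerConfig(n_iter=100, n_burnin=100)
        with pytest.raises(ValueError):
            SamplerConfig(thin=0)


class TestRhat:
    def test_unsplit_two_chain_hand_value(self):
        chains = np.array([[1.0, 2, 3, 4], [1.0, 2, 3, 4]])
        np.testing.assert_allclose(
            rhat(chains, split=False), math.sqrt(0.75), rtol=1e-12
        )

    def test_disjoint_chains_flagged(self):
        chains = np.vstack([np.zeros(50), np.ones(50)]) + \
            0.01 * np.random.default_rng(0).standard_normal((2, 50))
        assert rhat(chains, split=False) > 1.1
        assert rhat(chains, split=True) > 1.1

    def test_stationary_chains_near_one(self):
        rng = np.random.default_rng(1)
        chains = rng.standard_normal((3, 2_000))
        assert abs(rhat(chains) - 1.0) < 0.05

    def test_constant_chains_undefined(self):
        assert math.isnan(rhat(np.ones((2, 10)), split=False))

    def test_split_detects_within_chain_drift(self):
        # a strong trend inside a single chain only shows after splitting
        trend = np.linspace(0, 5, 400)[None, :].repeat(2, axis=0)
        assert rhat(trend, split=True) > 1.1


class TestEss:
    def test_iid_draws_near_nominal(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2, 3_000))
        assert 0.6 * x.size < ess(x) < 1.4 * x.size

    def test_autocorrelated_chain_shrinks(self):
        rng = np.random.default_rng(4)
        n = 4_000
        x = np.empty(n)
        x[0] = 0.0
        for t in range(1, n):
            x[t] = 0.95 * x[t - 1] + rng.standard_normal()
        assert ess(x[None, :]) < 0.2 * n


class TestSummarize:
    def _toy_samples(self, draws_1d):
        x = np.asarray(draws_1d, dtype=float)[None, :]
        draws = {
            "beta": np.tile(x[:, :, None], (1, 1, 10)),
            "theta": np.tile(x[:, :, None], (1, 1, 5)),
            "alpha": np.tile(x[:, :, None], (1, 1, 3)),
            "sigma_psi": np.abs(x[:, :, None]) + 0.5,
            "sigma_p": np.abs(x[:, :, None]) + 0.5,
            "N": np.clip(x[:, :, None], 1, 50).astype(int),
        }
        return PosteriorSamples(
            draws=draws, region_ids=["R01"], n_obs=np.array([1]), M=50,
            config=SamplerConfig(n_iter=len(draws_1d), n_burnin=0, n_chains=1),
        )

    def test_equal_tailed_interval_rule(self):
        s = self._toy_samples(np.arange(1, 101))
        table = summarize(s, levels=(0.9,))
        row = table.loc["beta_intercept"]
        np.testing.assert_allclose([row["lo90"], row["hi90"]], [5.95, 95.05])

    def test_constant_draws(self):
        s = self._toy_samples(np.full(20, 7.0))
        row = summarize(s).loc["beta_hden"]
        assert row["mean"] == row["median"] == 7.0
        assert row["sd"] == 0.0

    def test_bad_level_rejected(self, small_fit):
        with pytest.raises(ValueError):
            summarize(small_fit, levels=(1.2,))

    def test_richness_median_within_support(self, small_fit):
        table = summarize(small_fit)
        for r, rid in enumerate(small_fit.region_ids):
            med = table.loc[f"N_{rid}", "median"]
            assert small_fit.n_obs[r] <= med <= small_fit.M

    def test_long_format_export(self, small_fit, tmp_path):
        import pandas as pd

        small_fit.to_csv(tmp_path / "draws.csv")
        df = pd.read_csv(tmp_path / "draws.csv")
        assert set(df.columns) == {"chain", "iter", "parameter", "value"}
        assert df["chain"].nunique() == small_fit.config.n_chains
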