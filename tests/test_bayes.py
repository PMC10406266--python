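"""Bayesian inference layer: gradients, samplers, model recovery, summaries."""

import numpy as np
import pytest
from scipy import stats

from mreeg.bayes import (ModelSpec, PriorConfig, compute_diagnostics,
                         fit_effect_size_model, fit_single_level_model,
                         fit_two_level_model, posterior_probability,
                         robust_correlation, simulate_two_level_dataset,
                         summarize_posterior)
from mreeg.bayes.models import (PosteriorSamples, _two_level_logp_autodiff,
                                _two_level_logp_factory, _two_level_logp_manual)
from mreeg.bayes import autodiff as ad


# ---------------------------------------------------------------------------
# autodiff
# ---------------------------------------------------------------------------

class TestAutodiff:
    def _check_grad(self, build, x0):
        x = ad.Var(x0.copy())
        out = build(x)
        ad.backward(out)
        g = x.grad.copy()
        eps = 1e-6
        for i in np.ndindex(x0.shape):
            xp, xm = x0.copy(), x0.copy()
            xp[i] += eps
            xm[i] -= eps
            fd = (build(ad.Var(xp)).value - build(ad.Var(xm)).value) / (2 * eps)
            assert g[i] == pytest.approx(float(np.sum(fd)), rel=1e-4, abs=1e-7)

    def test_elementwise_chain(self, rng):
        x0 = 0.5 * rng.standard_normal(5)
        self._check_grad(lambda x: ad.vsum(ad.tanh(ad.exp(x) / 3.0) ** 2.0), x0)

    def test_matmul_and_gather(self, rng):
        A = rng.standard_normal((4, 3))
        idx = np.array([0, 2, 1, 2])
        x0 = rng.standard_normal(3)
        self._check_grad(
            lambda x: ad.vsum(ad.square(ad.gather(A @ x, idx))), x0)

    def test_solve_lower(self, rng):
        b = rng.standard_normal(3)
        x0 = np.tril(rng.standard_normal((3, 3))) + 3 * np.eye(3)

        def build(L):
            return ad.vsum(ad.square(ad.solve_lower(L, b)))

        L = ad.Var(x0.copy())
        out = build(L)
        ad.backward(out)
        g = L.grad
        eps = 1e-6
        for i in range(3):
            for j in range(i + 1):
                xp, xm = x0.copy(), x0.copy()
                xp[i, j] += eps
                xm[i, j] -= eps
                fd = (build(ad.Var(xp)).value - build(ad.Var(xm)).value) / (2 * eps)
                assert g[i, j] == pytest.approx(float(fd), rel=1e-5, abs=1e-8)

    def test_gammaln_gradient(self, rng):
        x0 = 1.0 + rng.random(4)
        self._check_grad(lambda x: ad.vsum(ad.gammaln(x * 2.0)), x0)


# ---------------------------------------------------------------------------
# log-posterior implementations agree (dual route)
# ---------------------------------------------------------------------------

class TestLogPosteriorAgreement:
    @pytest.mark.parametrize("pooled", [False, True])
    def test_manual_gradient_matches_autodiff(self, pooled, rng):
        spec, _ = simulate_two_level_dataset(4, 8, 3, seed=2)
        if pooled:
            spec = ModelSpec(spec.y, spec.X, spec.participant_idx,
                             spec.method_idx, "per_method_per_participant_pooled")
        pk1, lg_man = _two_level_logp_manual(spec, PriorConfig(), pooled_sd=pooled)
        pk2, lg_ad = _two_level_logp_autodiff(spec, PriorConfig(), False, pooled)
        assert pk1.dim == pk2.dim
        for _ in range(5):
            th = 0.5 * rng.standard_normal(pk1.dim)
            l1, g1 = lg_man(th)
            l2, g2 = lg_ad(th)
            assert l1 == pytest.approx(l2, rel=1e-10)
            np.testing.assert_allclose(g1, g2, rtol=1e-8, atol=1e-10)

    def test_robust_correlation_manual_matches_autodiff(self, rng):
        from mreeg.bayes.models import (_Packer, _robust_logp_autodiff,
                                        _robust_logp_manual)
        data = np.column_stack([rng.standard_normal(40), rng.standard_normal(40)])
        packer = _Packer([("mu", (2,)), ("log_s", (2,)), ("u_rho", ()),
                          ("log_nu", ())])
        lg_m = _robust_logp_manual(data, PriorConfig(), packer)
        lg_a = _robust_logp_autodiff(data, PriorConfig(), packer)
        for _ in range(6):
            th = 0.6 * rng.standard_normal(packer.dim)
            l1, g1 = lg_m(th)
            l2, g2 = lg_a(th)
            assert l1 == pytest.approx(l2, rel=1e-10)
            np.testing.assert_allclose(g1, g2, rtol=1e-8, atol=1e-9)

    def test_gradient_matches_finite_differences(self, rng):
        spec, _ = simulate_two_level_dataset(3, 6, 2, seed=3)
        pk, lg = _two_level_logp_factory(spec, PriorConfig(), False, False)
        th = 0.4 * rng.standard_normal(pk.dim)
        lp, g = lg(th)
        eps = 1e-6
        for i in range(0, pk.dim, 3):
            tp, tm = th.copy(), th.copy()
            tp[i] += eps
            tm[i] -= eps
            fd = (lg(tp)[0] - lg(tm)[0]) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)


# ---------------------------------------------------------------------------
# two-level model
# ---------------------------------------------------------------------------

class TestTwoLevelModel:
    def test_null_effects_concentrate_contrasts_at_zero(self):
        spec, _ = simulate_two_level_dataset(6, 24, 3, seed=4,
                                             beta=np.array([1.0, 1.0, 1.0]),
                                             tau=0.2, sigma=0.5)
        samples, _ = fit_two_level_model(spec, chains=2, warmup=300, draws=300,
                                         seed=0, compute_diag=False)
        beta = samples.flat("beta")
        contrast = beta[:, 1] - beta[:, 0]
        lo, hi = np.quantile(contrast, [0.025, 0.975])
        assert lo < 0 < hi
        assert abs(np.median(contrast)) < 0.3

    def test_conjugate_limit_matches_closed_form(self):
        """With a single shared sigma and weak hierarchy, the group mean
        posterior approaches the analytic normal posterior of cell means."""
        rng = np.random.default_rng(8)
        J, reps = 6, 30
        y, X, pidx, midx = [], [], [], []
        true = 1.3
        for j in range(J):
            for _ in range(reps):
                y.append(true + 0.5 * rng.standard_normal())
                X.append([1.0])
                pidx.append(j)
                midx.append(0)
        spec = ModelSpec(np.array(y), np.array(X), np.array(pidx), np.array(midx))
        samples, _ = fit_two_level_model(spec, chains=2, warmup=300, draws=300,
                                         seed=1, compute_diag=False)
        post_mean = samples.flat("beta")[:, 0].mean()
        assert post_mean == pytest.approx(np.mean(y), abs=0.1)

    def test_centered_and_noncentered_agree(self):
        """The two parameterizations target the same posterior."""
        spec, _ = simulate_two_level_dataset(6, 20, 2, seed=5, tau=0.8, sigma=0.5)
        a, _ = fit_two_level_model(spec, chains=2, warmup=300, draws=300, seed=2,
                                   centered=False, compute_diag=False)
        b, _ = fit_two_level_model(spec, chains=2, warmup=300, draws=300, seed=3,
                                   centered=True, compute_diag=False)
        for m in range(2):
            ks = stats.ks_2samp(a.flat("beta")[:, m], b.flat("beta")[:, m])
            assert ks.pvalue > 0.01

    def test_quick_parameter_recovery(self):
        hits, total = 0, 0
        for seed in range(3):
            spec, truth = simulate_two_level_dataset(4, 10, 2, seed=50 + seed,
                                                     tau=0.5, sigma=1.0)
            samples, _ = fit_two_level_model(spec, chains=2, warmup=200,
                                             draws=200, seed=seed,
                                             compute_diag=False)
            beta = samples.flat("beta")
            for m in range(2):
                lo, hi = np.quantile(beta[:, m], [0.025, 0.975])
                hits += lo <= truth["beta"][m] <= hi
                total += 1
        assert hits >= total - 1

    def test_prior_scales_produce_finite_prior_predictive(self, rng):
        pr = PriorConfig()
        beta = pr.beta_sd * rng.standard_normal(200)
        sd = np.abs(stats.cauchy.rvs(scale=pr.sd_scale, size=200,
                                     random_state=np.random.RandomState(0)))
        y = beta + sd * rng.standard_normal(200)
        assert np.all(np.isfinite(y))

    def test_insufficient_participants_rejected(self):
        spec, _ = simulate_two_level_dataset(2, 4, 2, seed=0)
        spec = ModelSpec(spec.y[:8], spec.X[:8], np.zeros(8, dtype=int),
                         spec.method_idx[:8])
        with pytest.raises(ValueError, match="participants"):
            fit_two_level_model(spec)


class TestEffectSizeModel:
    @staticmethod
    def _vep_like_dataset(delta=0.5, seed=0, J=4, trials=12, M=2):
        rng = np.random.default_rng(seed)
        y, X, pidx, midx = [], [], [], []
        for j in range(J):
            for m in range(M):
                for t in range(trials):
                    for side in (0, 1):
                        x = np.zeros(2 * M)
                        x[m] = 1.0
                        x[M + m] = side
                        y.append(x[m] * 0.2 + side * delta + rng.standard_normal())
                        X.append(x)
                        pidx.append(j)
                        midx.append(m)
        return ModelSpec(np.array(y), np.array(X), np.array(pidx),
                         np.array(midx),
                         "per_method_per_participant_pooled"), M

    def test_standardized_difference_recovered(self):
        spec, M = self._vep_like_dataset(delta=0.5, seed=1)
        samples, _ = fit_effect_size_model(spec, effect_cols=np.arange(M, 2 * M),
                                           chains=2, warmup=250, draws=250, seed=0)
        es = samples.flat("effect_size")
        for m in range(M):
            lo, hi = np.quantile(es[:, m], [0.025, 0.975])
            assert lo <= 0.5 <= hi

    def test_null_difference_centred_at_zero(self):
        spec, M = self._vep_like_dataset(delta=0.0, seed=2)
        samples, _ = fit_effect_size_model(spec, effect_cols=np.arange(M, 2 * M),
                                           chains=2, warmup=250, draws=250, seed=1)
        es = samples.flat("effect_size")
        assert abs(np.median(es)) < 0.2

    def test_participant_sds_shrink_toward_method_sd(self):
        """Homogeneous truth: the posterior spread of participant-level SDs
        stays well below the prior spread (partial pooling)."""
        spec, M = self._vep_like_dataset(delta=0.3, seed=3)
        samples, _ = fit_effect_size_model(spec, effect_cols=np.arange(M, 2 * M),
                                           chains=2, warmup=250, draws=250, seed=2)
        sig_jm = samples.flat("sigma_participant_method")
        spread = np.log(sig_jm).std(axis=(1, 2)).mean()
        assert spread < 0.5  # prior spread (half-Cauchy 2.5 on kappa) is far larger


class TestSingleLevelModel:
    def test_matches_ols_with_weak_priors(self, rng):
        X = np.column_stack([np.ones(60), rng.standard_normal(60)])
        y = X @ np.array([1.0, -2.0]) + 0.5 * rng.standard_normal(60)
        samples, _ = fit_single_level_model(y, X, chains=2, warmup=300,
                                            draws=300, seed=0)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(samples.flat("beta").mean(axis=0), ols,
                                   atol=0.1)

    def test_intercept_only_posterior_mean_is_sample_mean(self, rng):
        y = 3.0 + rng.standard_normal(50)
        samples, _ = fit_single_level_model(y, np.ones((50, 1)), chains=2,
                                            warmup=300, draws=300, seed=0)
        assert samples.flat("beta")[:, 0].mean() == pytest.approx(np.mean(y),
                                                                  abs=0.1)

    def test_underdetermined_design_rejected(self, rng):
        with pytest.raises(ValueError, match="observations"):
            fit_single_level_model(rng.standard_normal(3),
                                   rng.standard_normal((3, 3)))


class TestRobustCorrelation:
    def test_near_perfect_correlation_recovered(self, rng):
        x = rng.standard_normal(60)
        samples, _ = robust_correlation(x, x + 0.1 * rng.standard_normal(60),
                                        chains=2, warmup=200, draws=200, seed=0)
        assert np.median(samples.flat("rho")) > 0.99

    def test_matches_pearson_on_clean_gaussian(self, rng):
        n = 400
        x = rng.standard_normal(n)
        y = 0.7 * x + np.sqrt(1 - 0.49) * rng.standard_normal(n)
        samples, _ = robust_correlation(x, y, chains=2, warmup=400, draws=400,
                                        seed=1)
        pearson = np.corrcoef(x, y)[0, 1]
        assert np.median(samples.flat("rho")) == pytest.approx(pearson, abs=0.05)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            robust_correlation(np.ones(20), np.arange(20.0))


class TestPosteriorUtilities:
    @staticmethod
    def _samples(draws_dict):
        return PosteriorSamples({k: np.asarray(v)[None, :] if np.asarray(v).ndim == 1
                                 else np.asarray(v) for k, v in draws_dict.items()})

    def test_counting_example(self):
        s = self._samples({"d": np.array([[-1.0, 2.0, 3.0, 4.0]])})
        assert posterior_probability(s, "d") == 0.75

    def test_symmetric_posterior_near_half(self, rng):
        s = self._samples({"d": rng.standard_normal((2, 2000))})
        assert posterior_probability(s, "d") == pytest.approx(0.5, abs=0.05)

    def test_unknown_parameter_raises(self):
        s = self._samples({"d": np.zeros((1, 10))})
        with pytest.raises(KeyError, match="nope"):
            posterior_probability(s, "nope + 1")

    def test_invariant_under_monotone_transform(self, rng):
        d = rng.standard_normal((1, 500)) + 0.3
        s = self._samples({"d": d})
        p1 = posterior_probability(s, "d")
        p2 = posterior_probability(s, "np.expm1(d)")  # monotone, sign-preserving
        assert p1 == p2

    def test_quantile_convention(self):
        s = self._samples({"x": np.arange(1.0, 101.0)[None, :]})
        out = summarize_posterior(s, "x")
        assert out["median"] == pytest.approx(50.5)
        assert out["interval_95"][0] == pytest.approx(3.475)
        assert out["interval_95"][1] == pytest.approx(97.525)

    def test_degenerate_draws_give_degenerate_intervals(self):
        s = self._samples({"x": np.full((1, 50), 2.0)})
        out = summarize_posterior(s, "x")
        assert out["interval_95"] == (2.0, 2.0)


class TestDiagnostics:
    def test_iid_draws_look_converged(self, rng):
        draws = {"x": rng.standard_normal((4, 500))}
        d = compute_diagnostics(PosteriorSamples(draws))
        assert d.max_rhat < 1.01
        assert d.min_ess_bulk > 1000

    def test_shifted_chains_flagged(self, rng):
        draws = rng.standard_normal((4, 500))
        draws[0] += 5.0
        d = compute_diagnostics(PosteriorSamples({"x": draws}))
        assert d.max_rhat > 1.2

    def test_constant_parameter_reported_as_nan(self, rng):
        draws = {"c": np.ones((2, 200)), "x": rng.standard_normal((2, 200))}
        d = compute_diagnostics(PosteriorSamples(draws))
        assert np.isnan(float(d.rhat["c"]))
        assert np.isfinite(d.max_rhat)

    def test_single_chain_rejected(self, rng):
        with pytest.raises(ValueError, match="chains"):
            compute_diagnostics(PosteriorSamples({"x": rng.standard_normal((1, 500))}))
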