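import math

import numpy as np
import pytest

from lipsss.network import ModelParameters, PARAM_ORDER
from lipsss.mcmc import (
    EnsembleResult,
    adaptive_metropolis,
    integrated_autocorr_time,
    quality_filter,
    sample_posterior,
    summarize_ensemble,
)


class TestAutocorrTime:
    def test_white_noise_is_about_one(self):
        x = np.random.default_rng(0).standard_normal(10_000)
        tau = integrated_autocorr_time(x)
        assert tau == pytest.approx(1.0, rel=0.2)

    def test_ar1_matches_closed_form(self):
        """AR(1) with phi = 0.9 has tau = (1+phi)/(1-phi) = 19."""
        phi = 0.9
        rng = np.random.default_rng(1)
        n = 50_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        tau = integrated_autocorr_time(x)
        assert tau == pytest.approx(19.0, rel=0.25)

    def test_constant_chain_returns_sentinel(self):
        assert integrated_autocorr_time(np.ones(500)) == math.inf

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            integrated_autocorr_time(np.arange(50))


class TestAdaptiveMetropolis:
    def test_quadratic_posterior_variance(self):
        """Detailed-balance smoke test: on a 1-D quadratic cost the sampled
        variance matches the analytic posterior variance within 5%."""
        s2 = 2.37

        def logdens(z):
            return -0.5 * z[0] ** 2 / s2, 0.0

        out = adaptive_metropolis(logdens, np.array([0.5]), 50_000, seed=4)
        var = out["chain"][:, 0].var(ddof=1)
        assert var == pytest.approx(s2, rel=0.05)

    def test_determinism(self):
        def logdens(z):
            return -0.5 * float(z @ z), float(z @ z)

        a = adaptive_metropolis(logdens, np.zeros(3), 500, seed=11)
        b = adaptive_metropolis(logdens, np.zeros(3), 500, seed=11)
        np.testing.assert_array_equal(a["chain"], b["chain"])

    def test_mask_freezes_coordinates(self):
        def logdens(z):
            return -0.5 * float(z @ z), 0.0

        out = adaptive_metropolis(logdens, np.array([1.0, 2.0]), 300, seed=2,
                                  sample_mask=[True, False])
        assert np.all(out["chain"][:, 1] == 2.0)
        assert out["chain"][:, 0].std() > 0


class TestSamplePosterior:
    def test_same_seed_identical_chains(self):
        def cost(p):
            return (p.j_tca - 7.0) ** 2

        start = ModelParameters(7, 7, 0.202, 0.3, 0.1)
        r1 = sample_posterior(cost, start, n_draws=300, seed=9)
        r2 = sample_posterior(cost, start, n_draws=300, seed=9)
        np.testing.assert_array_equal(r1.chain, r2.chain)

    def test_tight_likelihood_shrinks_ensemble(self):
        """Delta-function limit: an overwhelmingly tight cost pins every
        parameter, so ensemble SDs fall below 1% of the parameter values."""
        truth = ModelParameters(7.0, 6.0, 0.202, 0.3, 0.2)
        z_truth = np.log([truth.j_tca, truth.j_exch, truth.t_trans,
                          truth.p_dil / (1 - truth.p_dil), truth.p_anap])

        def cost(p):
            z = np.log([p.j_tca, p.j_exch, p.t_trans,
                        p.p_dil / (1 - p.p_dil), p.p_anap])
            d = z - z_truth
            return 1e7 * float(d @ d)

        res = sample_posterior(cost, truth, n_draws=2000, seed=1)
        for name in PARAM_ORDER:
            col = res.column(name)
            assert np.std(col, ddof=1) < 0.01 * abs(col.mean())

    def test_best_fit_never_worse_than_chain(self):
        def cost(p):
            return (p.j_tca - 7.0) ** 2 + (p.p_dil - 0.3) ** 2

        res = sample_posterior(cost, ModelParameters(6, 7, 0.2, 0.4, 0.1),
                               n_draws=500, seed=3)
        assert res.best_cost <= res.costs.min() + 1e-12


def _fake_result(chain, best=None):
    n = chain.shape[0]
    return EnsembleResult(
        param_names=PARAM_ORDER, chain=chain, costs=np.zeros(n),
        best_params=best or ModelParameters(7, 7, 0.202, 0.3, 0.1),
        best_cost=0.0, acceptance_rate=0.3,
        tau={k: 5.0 for k in PARAM_ORDER}, n_burn=0, seed=0)


class TestSummaries:
    def test_identical_rows_collapse(self):
        row = np.array([7.0, 7.0, 0.202, 0.3, 0.1])
        res = _fake_result(np.tile(row, (200, 1)))
        s = summarize_ensemble(res)
        for i, name in enumerate(PARAM_ORDER):
            for stat in ("mean", "median", "mode"):
                assert s.loc[name, stat] == pytest.approx(row[i], rel=1e-12)
            assert s.loc[name, "sd"] == pytest.approx(0.0, abs=1e-15)

    def test_symmetric_chain_mean_equals_median(self):
        rng = np.random.default_rng(5)
        base = rng.normal(7.0, 0.5, size=(20_000, 5)).clip(0.01)
        base[:, 3] = rng.uniform(0.2, 0.4, size=20_000)
        res = _fake_result(base)
        s = summarize_ensemble(res)
        assert s.loc["j_tca", "mean"] == pytest.approx(
            s.loc["j_tca", "median"], rel=0.01)

    def test_summaries_match_brute_force(self):
        rng = np.random.default_rng(6)
        chain = np.abs(rng.normal(5.0, 1.0, size=(5000, 5))) + 0.01
        chain[:, 3] = rng.uniform(0.1, 0.9, 5000)
        res = _fake_result(chain)
        s = summarize_ensemble(res)
        for i, name in enumerate(PARAM_ORDER):
            assert s.loc[name, "mean"] == pytest.approx(chain[:, i].mean())
            assert s.loc[name, "sd"] == pytest.approx(chain[:, i].std(ddof=1))
            assert s.loc[name, "median"] == pytest.approx(np.median(chain[:, i]))

    def test_empty_chain_rejected(self):
        res = _fake_result(np.zeros((0, 5)))
        with pytest.raises(ValueError):
            summarize_ensemble(res)


class TestQualityFilter:
    def _result_with_jtca_sd(self, sd):
        rng = np.random.default_rng(0)
        n = 4001
        chain = np.tile([7.0, 7.0, 0.202, 0.3, 0.1], (n, 1))
        col = rng.standard_normal(n)
        col = (col - col.mean()) / col.std(ddof=1)
        chain[:, 0] = 20.0 + sd * col
        return _fake_result(chain)

    def test_excluded_above_threshold(self):
        q = quality_filter(self._result_with_jtca_sd(12.0))
        assert not q.passed and "exceeds" in q.reason

    def test_passes_below_threshold(self):
        assert quality_filter(self._result_with_jtca_sd(5.0)).passed

    def test_boundary_value_passes(self):
        # the rule is strictly "exceeded"
        assert quality_filter(self._result_with_jtca_sd(10.0)).passed

    def test_high_autocorrelation_flagged_not_rejected(self):
        res = self._result_with_jtca_sd(5.0)
        res.tau = dict(res.tau, j_tca=900.0)
        q = quality_filter(res)
        assert q.passed and "high_autocorrelation" in q.flags
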