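import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from lipsss.network import ConfigError, ModelParameters, default_config
from lipsss.nmr import MultipletMeasurement, NMRSample, multiplet_intensities
from lipsss.inference import (
    CostEvaluator,
    default_grid,
    default_priors,
    grid_optimize,
    lognormal_prior_cost,
    panap_constants,
    panap_prior_cost,
    params_to_z,
    sigma_from_factor,
    simplex_refine,
    total_cost,
    z_to_params,
)
from lipsss.synthetic import NoiseModel, generate_sample

from _oracles import eq1_cost


class TestSigmaFromFactor:
    def test_95pct_factor_gives_printed_value(self):
        # (ln(1.96 theta) - ln(theta/1.96))/4 = ln(1.96)/2 = 0.336 (3 dp)
        assert round(sigma_from_factor(1.96), 3) == 0.336

    def test_factor_15(self):
        # ln(15)/2; see docs/methods.md for the historically printed 1.345
        assert sigma_from_factor(15.0) == pytest.approx(1.35403, abs=5e-6)

    def test_limit_at_one(self):
        assert sigma_from_factor(1.0 + 1e-12) == pytest.approx(0.0, abs=1e-9)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            sigma_from_factor(1.0)


class TestLognormalPrior:
    def test_zero_at_reference(self):
        assert lognormal_prior_cost(0.202, 0.202, 0.336) == 0.0

    def test_one_sd_deviation_costs_half(self):
        s = 0.336
        assert lognormal_prior_cost(0.202 * math.exp(s), 0.202, s) == \
            pytest.approx(0.5)

    def test_spec_example_value(self):
        # 1/2 (ln 1.96 / 0.336)^2
        expected = 0.5 * (math.log(1.96) / 0.336) ** 2
        assert lognormal_prior_cost(0.202 * 1.96, 0.202, 0.336) == \
            pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(2.0056, abs=2e-4)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            lognormal_prior_cost(0.0, 1.0, 0.3)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.floats(min_value=0.01, max_value=100.0))
    def test_symmetric_in_log_space(self, x):
        ref = 0.7
        a = lognormal_prior_cost(ref * x, ref, 0.5)
        b = lognormal_prior_cost(ref / x, ref, 0.5)
        assert a == pytest.approx(b, rel=1e-9, abs=1e-12)


class TestPanapPrior:
    def test_constant_on_unit_interval(self):
        assert panap_prior_cost(0.3) == panap_prior_cost(0.9)
        assert panap_prior_cost(0.0) == panap_prior_cost(1.0)

    def test_density_continuous_at_one(self):
        eps = 1e-9
        assert panap_prior_cost(1.0 - eps) == pytest.approx(
            panap_prior_cost(1.0 + eps), abs=1e-6)

    def test_unit_integral_by_quadrature(self):
        total, _ = quad(lambda p: math.exp(-panap_prior_cost(p)), 0.0, 1.0)
        tail, _ = quad(lambda p: math.exp(-panap_prior_cost(p)), 1.0, 10.0)
        assert total + tail == pytest.approx(1.0, abs=1e-6)

    def test_constants_consistent(self):
        c1, c2 = panap_constants(0.3)
        assert c1 == pytest.approx(c2 / (0.3 * math.sqrt(2 * math.pi)))

    def test_domain_error(self):
        with pytest.raises(ValueError):
            panap_prior_cost(-0.1)


def _perfect_sample(params, cfg, sigma=0.01):
    from lipsss.model import build_system, simulate
    system = build_system(cfg.pools, cfg.transitions,
                          concentration_overrides={"glutamate": 20.0})
    vec = simulate(params, system, cfg.schedule, 5.5)
    m = multiplet_intensities(vec["glutamate"])
    meas = {k: MultipletMeasurement(v, sigma) for k, v in m.items()}
    return NMRSample("perfect", "H", "g", 0.1, 20.0, meas)


class TestTotalCost:
    def test_perfect_fit_leaves_only_prior_constant(self, cfg):
        p = ModelParameters(7.0, 7.0, 0.202, 0.3, 0.5)  # auxiliaries at refs
        sample = _perfect_sample(p, cfg)
        bd = total_cost(p, sample)
        c1, _ = panap_constants()
        assert bd.data_total == pytest.approx(0.0, abs=1e-6)
        assert bd.prior_terms["t_trans"] == pytest.approx(0.0)
        assert bd.prior_terms["jexch_jtca_ratio"] == pytest.approx(0.0)
        assert bd.total == pytest.approx(-math.log(c1), abs=1e-6)

    def test_breakdown_sums_to_total(self, cfg):
        p = ModelParameters(5.0, 9.0, 0.15, 0.4, 0.3)
        sample = _perfect_sample(ModelParameters(7, 7, 0.202, 0.3, 0.1), cfg)
        bd = total_cost(p, sample)
        assert bd.total == pytest.approx(
            sum(bd.data_terms.values()) + sum(bd.prior_terms.values()),
            abs=1e-12)

    def test_one_sigma_residual_costs_half(self, cfg):
        p = ModelParameters(7.0, 7.0, 0.202, 0.3, 0.5)
        sample = _perfect_sample(p, cfg, sigma=0.01)
        meas = dict(sample.multiplets)
        m0 = meas["C4S"]
        meas["C4S"] = MultipletMeasurement(m0.intensity + 0.01, 0.01)
        shifted = NMRSample("s", "H", "g", 0.1, 20.0, meas)
        bd = total_cost(p, shifted)
        assert bd.data_total == pytest.approx(0.5, abs=1e-3)

    def test_matches_duplicate_formula_oracle(self, cfg):
        rng = np.random.default_rng(7)
        truth = ModelParameters(7.0, 7.0, 0.202, 0.3, 0.1)
        sample = generate_sample(truth, cfg, NoiseModel(seed=5))
        ev = CostEvaluator(sample, cfg)
        p = ModelParameters(float(rng.uniform(3, 12)), float(rng.uniform(2, 20)),
                            float(rng.uniform(0.1, 0.4)), float(rng.uniform(0.1, 0.9)),
                            float(rng.uniform(0.05, 1.5)))
        ref = eq1_cost(ev.m_sim(p), sample.intensity_array(),
                       sample.sigma_array(), p)
        assert ev(p) == pytest.approx(ref, abs=1e-10)

    def test_doubled_prior_sds_quarter_lognormal_terms(self, cfg):
        """The doubled-prior sensitivity analysis: each lognormal prior term
        falls by exactly 4x at fixed parameters."""
        p = ModelParameters(4.0, 12.0, 0.3, 0.4, 0.5)
        sample = _perfect_sample(ModelParameters(7, 7, 0.202, 0.3, 0.1), cfg)
        b1 = total_cost(p, sample, priors=default_priors(1.0))
        b2 = total_cost(p, sample, priors=default_priors(2.0))
        for key in ("t_trans", "jexch_jtca_ratio"):
            assert b2.prior_terms[key] == pytest.approx(
                b1.prior_terms[key] / 4.0, rel=1e-9)

    def test_zero_sigma_rejected_at_construction(self):
        with pytest.raises(ValueError, match="sigma"):
            MultipletMeasurement(0.1, -1.0)


class TestTransforms:
    def test_round_trip(self):
        p = ModelParameters(3.3, 8.1, 0.4, 0.27, 0.8)
        q = z_to_params(params_to_z(p))
        np.testing.assert_allclose(q.as_array(), p.as_array(), rtol=1e-12)

    def test_negative_p_anap_coordinate_rejected(self):
        with pytest.raises(ValueError):
            z_to_params(np.array([1.0, 1.0, -1.5, 0.0, -0.2]))


class TestGridOptimize:
    def test_single_point_grid(self, cfg):
        sample = _perfect_sample(ModelParameters(7, 7, 0.202, 0.3, 0.1), cfg)
        ev = CostEvaluator(sample, cfg)
        grid = {"j_tca": [7.0], "j_exch": [7.0], "t_trans": [0.202],
                "p_dil": [0.3], "p_anap": [0.1]}
        p, c = grid_optimize(ev, grid)
        assert p == ModelParameters(7, 7, 0.202, 0.3, 0.1)

    def test_grid_containing_truth_wins_on_noiseless_data(self, cfg):
        truth = ModelParameters(7.0, 7.0, 0.202, 0.3, 0.1)
        sample = _perfect_sample(truth, cfg, sigma=0.005)
        ev = CostEvaluator(sample, cfg)
        grid = {"j_tca": [3.0, 7.0, 15.0], "j_exch": [7.0],
                "t_trans": [0.202], "p_dil": [0.1, 0.3, 0.7],
                "p_anap": [0.1]}
        p, c = grid_optimize(ev, grid)
        assert (p.j_tca, p.p_dil) == (7.0, 0.3)

    def test_returned_point_beats_all_others(self, cfg):
        sample = _perfect_sample(ModelParameters(7, 7, 0.202, 0.3, 0.1), cfg)
        ev = CostEvaluator(sample, cfg)
        grid = {"j_tca": [4.0, 8.0], "j_exch": [5.0, 10.0],
                "t_trans": [0.15, 0.25], "p_dil": [0.2, 0.5],
                "p_anap": [0.1, 0.6]}
        p, c = grid_optimize(ev, grid)
        import itertools
        for combo in itertools.product(*grid.values()):
            assert c <= ev(ModelParameters(*combo)) + 1e-12

    def test_empty_grid_rejected(self, cfg):
        sample = _perfect_sample(ModelParameters(7, 7, 0.202, 0.3, 0.1), cfg)
        ev = CostEvaluator(sample, cfg)
        with pytest.raises(ConfigError, match="empty"):
            grid_optimize(ev, {"j_tca": []})

    def test_default_grid_shape(self):
        g = default_grid()
        assert len(g["j_tca"]) == 7 and len(g["p_dil"]) == 5
        assert g["j_tca"][-1] / g["j_tca"][0] == pytest.approx(30.0)


class TestSimplexRefine:
    def test_never_worse_than_start(self, cfg):
        truth = ModelParameters(7.0, 7.0, 0.202, 0.3, 0.1)
        sample = _perfect_sample(truth, cfg, sigma=0.005)
        ev = CostEvaluator(sample, cfg)
        c_start = ev(truth)
        p, c = simplex_refine(ev, truth, max_evaluations=200)
        assert c <= c_start + 1e-12

    def test_recovers_truth_from_nearby_start_noiseless(self, cfg):
        truth = ModelParameters(7.0, 7.0, 0.202, 0.3, 0.5)
        sample = _perfect_sample(truth, cfg, sigma=0.002)
        ev = CostEvaluator(sample, cfg)
        start = ModelParameters(9.0, 5.0, 0.25, 0.45, 0.5)
        p, c = simplex_refine(ev, start)
        assert p.j_tca == pytest.approx(truth.j_tca, rel=0.01)
        assert p.p_dil == pytest.approx(truth.p_dil, rel=0.01)
        # noiseless best fit drives the data term to (nearly) zero
        assert CostEvaluator(sample, cfg).breakdown(p).data_total < 1e-4

    def test_nonfinite_start_rejected(self, cfg):
        sample = _perfect_sample(ModelParameters(7, 7, 0.202, 0.3, 0.1), cfg)
        with pytest.raises(ValueError, match="non-finite"):
            simplex_refine(lambda p: math.nan, ModelParameters(7, 7, 0.202, 0.3, 0.1))
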