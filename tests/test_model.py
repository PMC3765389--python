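import numpy as np
import pytest

from lipsss.network import LabelSchedule, ModelParameters, Phase
from lipsss.model import (
    acetyl_coa_target,
    build_system,
    rhs,
    simulate,
    simulate_fast,
)
from lipsss.nmr import positional_enrichment

from _oracles import brute_force_rhs
from conftest import random_normalized_state


def test_state_counts_match_enumeration(cfg, system):
    # a 5-carbon pool contributes 2^5 states, a 2-carbon pool 2^2
    glu = system.pool_slice("glutamate")
    assert glu.stop - glu.start == 32
    ac = system.pool_slice("acetyl_coa")
    assert ac.stop - ac.start == 4
    expected = sum(2 ** p.n_carbons for p in cfg.pools if p.dynamic)
    assert system.n_states == expected


class TestAcetylTarget:
    def test_before_schedule_is_unlabeled(self, cfg):
        t = acetyl_coa_target(-1.0, cfg.schedule, 0.3)
        assert t[0] == pytest.approx(1.0)

    def test_2c13_phase_no_dilution(self, cfg):
        t = acetyl_coa_target(2.0, cfg.schedule, 0.0)
        # methyl carbon (C2, bit 1) labeled
        assert t[0b10] == pytest.approx(1.0)

    def test_double_label_phase(self, cfg):
        t = acetyl_coa_target(4.5, cfg.schedule, 0.2)
        assert t[0b11] == pytest.approx(0.8)
        assert t[0] == pytest.approx(0.2)

    def test_full_dilution_is_unlabeled(self, cfg):
        t = acetyl_coa_target(2.0, cfg.schedule, 1.0)
        assert t[0] == pytest.approx(1.0)

    def test_sums_to_one(self, cfg):
        for tv, pd_ in [(0.5, 0.3), (4.2, 0.9), (-2, 0.1)]:
            assert acetyl_coa_target(tv, cfg.schedule, pd_).sum() == pytest.approx(1.0)


class TestRHS:
    def test_per_pool_derivative_sums_vanish(self, cfg, system, params):
        rng = np.random.default_rng(1)
        for _ in range(5):
            y = random_normalized_state(system, rng)
            d = rhs(y, 1.7, params, system, cfg.schedule)
            for pool in system.pools:
                assert abs(d[system.pool_slice(pool.name)].sum()) < 1e-12

    def test_zero_flux_means_no_change_in_tca_pools(self, cfg, system):
        # only the acetyl-CoA relaxation remains active at zero flux
        p = ModelParameters(0.0, 0.0, 0.202, 0.0, 0.0)
        rng = np.random.default_rng(2)
        y = random_normalized_state(system, rng)
        d = rhs(y, 0.5, p, system, cfg.schedule)
        for pool in system.pools:
            if pool.name == "acetyl_coa":
                continue
            assert np.max(np.abs(d[system.pool_slice(pool.name)])) < 1e-14

    def test_matches_brute_force_enumeration(self, cfg, system):
        """Flux-by-flux recomputation over all transitions (independent
        oracle) agrees with the compiled right-hand side."""
        rng = np.random.default_rng(3)
        p = ModelParameters(5.3, 11.0, 0.25, 0.4, 0.35)
        for t in (0.5, 4.7):
            y = random_normalized_state(system, rng)
            d = rhs(y, t, p, system, cfg.schedule)
            state = {pl.name: y[system.pool_slice(pl.name)] for pl in system.pools}
            ref = brute_force_rhs(state, t, p, cfg)
            for pl in system.pools:
                np.testing.assert_allclose(
                    d[system.pool_slice(pl.name)], ref[pl.name], atol=1e-9)

    def test_rejects_wrong_state_shape(self, cfg, system, params):
        with pytest.raises(ValueError, match="shape"):
            rhs(np.zeros(3), 0.0, params, system, cfg.schedule)


class TestSimulate:
    def test_t_zero_is_unlabeled(self, cfg, system, params):
        vec = simulate(params, system, cfg.schedule, 0.0)
        for pool in system.pools:
            assert vec[pool.name][0] == pytest.approx(1.0)

    def test_fractions_sum_to_one_along_trajectory(self, cfg, system, params):
        t, traj = simulate(params, system, cfg.schedule, 5.5,
                           t_eval=np.linspace(0.0, 5.5, 23))
        assert t.shape[0] == 23
        for pool in system.pools:
            sums = traj[:, system.pool_slice(pool.name)].sum(axis=1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)
            assert traj[:, system.pool_slice(pool.name)].min() > -1e-9

    def test_full_dilution_stays_unlabeled(self, cfg, system):
        p = ModelParameters(7.0, 7.0, 0.202, 1.0, 0.1)
        vec = simulate(p, system, cfg.schedule, 5.5)
        for pool in system.pools:
            assert vec[pool.name][0] == pytest.approx(1.0, abs=1e-7)

    def test_monotone_label_entry(self, cfg, system, constant_2c13_schedule):
        """With constant labeled input and p_dil < 1, glutamate's total
        labeled fraction is non-decreasing in time."""
        p = ModelParameters(7.0, 7.0, 0.202, 0.3, 0.1)
        grid = np.linspace(0.0, 20.0, 41)
        _, traj = simulate(p, system, constant_2c13_schedule, 20.0, t_eval=grid)
        labeled = 1.0 - traj[:, system.pool_slice("glutamate")][:, 0]
        assert np.all(np.diff(labeled) > -1e-9)

    def test_transport_limit_tracks_target(self, cfg, system):
        """As t_trans -> 0 the acetyl-CoA composition follows its target."""
        p = ModelParameters(7.0, 7.0, 1e-3, 0.2, 0.1)
        vec = simulate(p, system, cfg.schedule, 2.0)
        tgt = acetyl_coa_target(2.0, cfg.schedule, 0.2)
        np.testing.assert_allclose(vec["acetyl_coa"], tgt, atol=5e-3)

    def test_fast_path_matches_reference(self, cfg, system, params):
        vec = simulate(params, system, cfg.schedule, 5.5)
        y = simulate_fast(params, system, cfg.schedule, 5.5)
        ref = np.concatenate([vec[pl.name] for pl in system.pools])
        np.testing.assert_allclose(y, ref, atol=1e-7)

    def test_glutamate_c4_labels_first_from_methyl_acetate(
            self, system, constant_2c13_schedule):
        """[2-13C]acetate feeds glutamate C4 before any other carbon."""
        p = ModelParameters(7.0, 7.0, 0.202, 0.0, 0.0)
        vec = simulate(p, system, constant_2c13_schedule, 1.0)
        enr = [positional_enrichment(vec["glutamate"], c) for c in range(1, 6)]
        assert enr[3] > 3 * max(enr[0], enr[1], enr[2], enr[4])
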