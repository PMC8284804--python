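"""The stochastic constriction process: calibration, steps, trajectories."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from agf.constriction import (DisruptionSpec, FeedbackConfig,
                              NeighborTriggerConfig, apply_disruption,
                              calibrate_sigma_ref, constriction_step,
                              run_simulation)


@pytest.fixture(scope="module")
def strong_feedback(small_system, model):
    fb = FeedbackConfig(beta=250.0, f_c=0.6)
    sref = calibrate_sigma_ref(small_system, fb, n_trials=20, seed=2,
                               model=model)
    return dataclasses.replace(fb, sigma_ref=sref)


class TestCalibration:
    def test_noop_constriction_rejected(self, small_system, model):
        with pytest.raises(ValueError):
            calibrate_sigma_ref(small_system, FeedbackConfig(f_c=1.0),
                                n_trials=5, seed=0, model=model)

    def test_strong_constriction_yields_larger_reference(self, small_system,
                                                         model):
        strong = calibrate_sigma_ref(small_system, FeedbackConfig(f_c=0.6),
                                     n_trials=15, seed=4, model=model)
        weak = calibrate_sigma_ref(small_system, FeedbackConfig(f_c=0.85),
                                   n_trials=15, seed=4, model=model)
        assert strong > weak > 0

    def test_deterministic_from_seed(self, small_system, model):
        a = calibrate_sigma_ref(small_system, FeedbackConfig(), n_trials=8,
                                seed=9, model=model)
        b = calibrate_sigma_ref(small_system, FeedbackConfig(), n_trials=8,
                                seed=9, model=model)
        assert a == b

    def test_calibration_leaves_system_untouched(self, small_system, model):
        pos = small_system.positions.copy()
        diam = small_system.diameters.copy()
        calibrate_sigma_ref(small_system, FeedbackConfig(), n_trials=5,
                            seed=1, model=model)
        np.testing.assert_array_equal(small_system.positions, pos)
        np.testing.assert_array_equal(small_system.diameters, diam)


class TestConstrictionStep:
    def test_zero_alpha_never_constricts(self, small_system, model):
        work = small_system.copy()
        cfg = FeedbackConfig(beta=0.0, alpha=0.0)
        rng = np.random.default_rng(0)
        for _ in range(50):
            _, new = constriction_step(work, cfg, model, rng)
            assert new == []

    def test_random_step_count_is_binomial_with_unit_mean(self, small_system,
                                                          model):
        """With beta=0 each of the N_a candidates succeeds w.p. 1/N_a, so
        the per-step count is Binomial(N_a, 1/N_a) with mean 1."""
        cfg = FeedbackConfig(beta=0.0, f_c=0.6)
        rng = np.random.default_rng(42)
        counts = []
        for _ in range(3000):
            work = small_system.copy()     # fresh system: no depletion
            _, new = constriction_step(work, cfg, model, rng)
            counts.append(len(new))
        assert np.mean(counts) == pytest.approx(1.0, abs=0.1)

    def test_constriction_is_permanent_and_exact(self, small_system, model,
                                                 strong_feedback):
        traj = run_simulation(small_system,
                              dataclasses.replace(strong_feedback,
                                                  target_fraction=0.2),
                              model, seed=5)
        order = traj.constricted_order
        assert len(set(order.tolist())) == len(order)
        expected = small_system.diameters.copy()
        expected[order] *= strong_feedback.f_c
        np.testing.assert_allclose(traj.final.diameters, expected)
        assert traj.final.constricted[order].all()


class TestRunSimulation:
    def test_zero_target_returns_no_events(self, small_system, model):
        cfg = FeedbackConfig(beta=0.0, target_fraction=0.0)
        traj = run_simulation(small_system, cfg, model, seed=1)
        assert traj.events == []
        np.testing.assert_array_equal(traj.final.diameters,
                                      small_system.diameters)

    def test_identical_seeds_give_identical_event_logs(self, small_system,
                                                       model, strong_feedback):
        cfg = dataclasses.replace(strong_feedback, target_fraction=0.15)
        a = run_simulation(small_system, cfg, model, seed=77)
        b = run_simulation(small_system, cfg, model, seed=77)
        assert a.events == b.events

    def test_pct_nc_monotone_and_reaches_target(self, small_system, model):
        cfg = FeedbackConfig(beta=0.0, target_fraction=0.4)
        traj = run_simulation(small_system, cfg, model, seed=3,
                              mechanics=False)
        assert traj.pct_nc_final() >= 0.4
        ids = traj.constricted_order
        assert len(np.unique(ids)) == len(ids)
        assert small_system.active[ids].all()

    def test_all_alpha_zero_aborts(self, small_system, model):
        cfg = FeedbackConfig(beta=0.0, alpha=0.0)
        with pytest.raises(RuntimeError):
            run_simulation(small_system, cfg, model, seed=0, mechanics=False)

    def test_beta_requires_sigma_ref(self, small_system, model):
        with pytest.raises(ValueError):
            run_simulation(small_system, FeedbackConfig(beta=250.0), model,
                           seed=0)

    def test_beta0_events_uniform_over_active_cells(self, small_system):
        """Null model: constriction events are uniform over unconstricted
        active cells (chi-square goodness of fit, alpha = 0.01)."""
        cfg = FeedbackConfig(beta=0.0, f_c=0.6, target_fraction=0.4)
        active_ids = np.flatnonzero(small_system.active)
        counts = np.zeros(small_system.n)
        n_events = 0
        seed = 0
        while n_events < 10_000:
            traj = run_simulation(small_system, cfg, seed=seed,
                                  mechanics=False)
            ids = traj.constricted_order
            counts[ids] += 1
            n_events += len(ids)
            seed += 1
        observed = counts[active_ids]
        # each run constricts a fixed fraction without replacement, so per
        # run each active cell is included with equal probability
        _, pvalue = stats.chisquare(observed)
        assert pvalue > 0.01

    def test_snapshot_levels_recorded(self, small_system, model):
        cfg = FeedbackConfig(beta=0.0, target_fraction=0.4)
        traj = run_simulation(small_system, cfg, model, seed=8,
                              mechanics=False, snapshot_levels=(0.1, 0.3))
        assert set(traj.snapshots) == {0.1, 0.3}
        n10 = traj.snapshots[0.1].constricted.sum()
        assert n10 >= 0.1 * traj.n_active0
        assert n10 <= len(traj.constricted_at_level(0.1))

    def test_constricted_at_level_prefix_semantics(self, small_system, model):
        cfg = FeedbackConfig(beta=0.0, target_fraction=0.4)
        traj = run_simulation(small_system, cfg, model, seed=8,
                              mechanics=False)
        lo = traj.constricted_at_level(0.1)
        hi = traj.constricted_at_level(0.4)
        assert set(lo) <= set(hi)
        with pytest.raises(ValueError):
            traj.constricted_at_level(0.9)


class TestDisruption:
    def test_identity_when_alpha_r_is_one(self, small_system):
        cfg = FeedbackConfig(beta=0.0)
        lx = small_system.box[0]
        spec = DisruptionSpec(shape="band", x_interval=(lx / 3, 2 * lx / 3),
                              alpha_r=1.0)
        out = apply_disruption(cfg, spec, small_system)
        assert np.all(out.alpha_array(small_system.n) == 1.0)

    def test_band_fraction_q(self, medium_system):
        cfg = FeedbackConfig(beta=0.0)
        lx = medium_system.box[0]
        spec = DisruptionSpec(shape="band",
                              x_interval=(lx / 2 - lx / 8, lx / 2 + lx / 8),
                              alpha_r=0.5)
        apply_disruption(cfg, spec, medium_system)
        assert spec.q == pytest.approx(0.25, abs=0.07)

    def test_ellipse_leaves_bypass_cells(self, medium_system):
        cfg = FeedbackConfig(beta=0.0)
        lx, ly = medium_system.box
        stripe_width = 8.0
        spec = DisruptionSpec(shape="ellipse", center=(lx / 2, ly / 2),
                              semi_axes=(4.0, 0.375 * stripe_width),
                              alpha_r=0.3)
        apply_disruption(cfg, spec, medium_system)
        strip = spec.strip_mask(medium_system) & medium_system.active
        ellipse = spec.region_mask(medium_system) & medium_system.active
        assert 0 < spec.b_frac < 1
        assert (strip & ~ellipse).sum() > 0   # unaffected cells above/below

    def test_empty_region_rejected(self, small_system):
        cfg = FeedbackConfig(beta=0.0)
        spec = DisruptionSpec(shape="band", x_interval=(-5.0, -4.0),
                              alpha_r=0.5)
        with pytest.raises(ValueError):
            apply_disruption(cfg, spec, small_system)

    def test_invalid_alpha_r_rejected(self):
        with pytest.raises(ValueError):
            DisruptionSpec(shape="band", x_interval=(0, 1), alpha_r=1.5)


class TestNeighborTriggerRun:
    def test_trigger_concentrates_constrictions(self, small_system, model):
        """Neighbor-triggered enhancement produces clumpier patterns than
        the uniform random process (fewer clusters at equal %N_c)."""
        from agf.clusters import trajectory_cluster_report

        cfg = FeedbackConfig(beta=0.0, f_c=0.6, target_fraction=0.4)
        trig = NeighborTriggerConfig(slope=3.33)
        n_random, n_trig = [], []
        for seed in range(30):
            a = run_simulation(small_system, cfg, model, seed=seed,
                               mechanics=False)
            b = run_simulation(small_system, cfg, model, seed=seed,
                               mechanics=False, neighbor_trigger=trig)
            n_random.append(trajectory_cluster_report(a, 0.4).n_clusters)
            n_trig.append(trajectory_cluster_report(b, 0.4).n_clusters)
        assert np.mean(n_trig) < np.mean(n_random)
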