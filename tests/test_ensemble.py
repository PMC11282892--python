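"""Ensemble encoders: observation channel, posteriors, point estimates,
whole-report simulation."""

import numpy as np
import pytest
from scipy import special

from wholereport.circular import KAPPA_CAP, StimulusGrid, circ_dist, circ_mean
from wholereport.ensemble import (
    BFMMSpec,
    HBMSpec,
    HierarchicalEnsembleModel,
    MCMCSettings,
    VonMisesMixtureModel,
    component_mean_for_stimulus,
    hbm_infer,
    observe,
    occupied_components,
    posterior_point_estimate,
    simulate_whole_report_trial,
    simulate_whole_report_trials,
)

GRID360 = StimulusGrid(360)


class TestObserve:
    def test_cap_gives_exact_observation(self):
        theta = np.array([0.1, -2.0, 3.0])
        np.testing.assert_array_equal(observe(theta, KAPPA_CAP, 0), theta)

    def test_seeded_reproducibility(self):
        theta = np.linspace(-3, 3, 10)
        np.testing.assert_array_equal(observe(theta, 8.0, 4), observe(theta, 8.0, 4))

    def test_circular_sd_matches_closed_form(self):
        kappa = 10.0
        theta = np.zeros(10_000)
        x = observe(theta, kappa, 1)
        r_emp = np.abs(np.exp(1j * x).mean())
        r_theory = special.i1e(kappa) / special.i0e(kappa)
        sd_emp = np.sqrt(-2 * np.log(r_emp))
        sd_theory = np.sqrt(-2 * np.log(r_theory))
        assert sd_emp == pytest.approx(sd_theory, rel=0.05)

    def test_invalid_kappa(self):
        with pytest.raises(ValueError):
            observe([0.0], 0.0, 1)


class TestHBM:
    def test_shrinkage_toward_ensemble_mean(self):
        x = np.array([0.9, 1.0, 1.25])  # clustered within 0.3 rad
        res = HierarchicalEnsembleModel(x, kappa_obs=5.0).fit(draws=8000, tune=1000, seed=0)
        post_means = np.angle(np.exp(1j * res.theta).mean(axis=0))
        m = circ_mean(x)
        for xi, pm in zip(x, post_means):
            toward = circ_dist(m, xi)
            moved = circ_dist(pm, xi)
            if abs(toward) > 0.03:  # outside MC tolerance
                assert np.sign(moved) == np.sign(toward)
                # between x_i and the mean (tight clusters shrink almost fully,
                # so allow Monte Carlo slack at the boundary)
                assert abs(moved) < abs(toward) + 0.01

    def test_ensemble_mean_tracks_observations(self):
        x = np.array([0.9, 1.0, 1.25])
        res = hbm_infer(x, HBMSpec(kappa_obs=5.0, mcmc=MCMCSettings(draws=3000, tune=500)),
                        seed=1)
        mu_e_hat = circ_mean(res.ensemble_mean)
        assert abs(circ_dist(mu_e_hat, circ_mean(x))) < 0.2

    def test_single_stimulus_posterior_centered_on_observation(self):
        x = np.array([1.3])
        res = HierarchicalEnsembleModel(x, kappa_obs=10.0).fit(draws=4000, tune=500, seed=2)
        pm = circ_mean(res.theta[:, 0])
        assert abs(circ_dist(pm, 1.3)) < 0.05

    def test_summary_and_diagnostics(self):
        res = HierarchicalEnsembleModel([0.1, 0.5, -0.2], 5.0).fit(draws=500, tune=200, seed=3)
        summ = res.summary()
        assert {"theta[0]", "mu_e", "kappa_e"} <= set(summ.index)
        diag = res.diagnostics()
        assert diag["ess_theta_min"] > 10


class TestBFMM:
    def test_two_clusters_recovered(self):
        x = np.array([1.5, 1.6, 1.55, -1.5, -1.6, -1.55])
        # near-exact observations: the posterior mode of the occupancy is 2
        res = VonMisesMixtureModel(x, kappa_obs=100.0, n_components=6).fit(
            draws=2000, tune=500, seed=4)
        occ = occupied_components(res)
        assert np.argmax(occ) + 1 == 2
        cm0 = component_mean_for_stimulus(res, 0)
        assert abs(circ_dist(cm0, circ_mean(x[:3]))) < 0.2

    def test_cluster_coassignment_structure_under_observation_noise(self):
        x = np.array([1.5, 1.6, 1.55, -1.5, -1.6, -1.55])
        res = VonMisesMixtureModel(x, kappa_obs=20.0, n_components=6).fit(
            draws=2000, tune=500, seed=4)
        z = res.assignments
        within = (z[:, 0] == z[:, 1]).mean()
        across = (z[:, 0] == z[:, 3]).mean()
        assert within > 0.5
        assert across < 0.2

    def test_single_component_shrinks_like_hbm(self):
        x = np.array([0.9, 1.0, 1.25])
        res = VonMisesMixtureModel(x, kappa_obs=5.0, n_components=1).fit(
            draws=2000, tune=500, seed=5)
        post_means = np.angle(np.exp(1j * res.theta).mean(axis=0))
        m = circ_mean(x)
        for xi, pm in zip(x, post_means):
            if abs(circ_dist(m, xi)) > 0.05:
                assert np.sign(circ_dist(pm, xi)) == np.sign(circ_dist(m, xi))
        # single component: per-stimulus component mean equals posterior mean of mu_1
        cm = component_mean_for_stimulus(res, 0)
        assert abs(circ_dist(cm, circ_mean(res.component_means[:, 0]))) < 1e-9

    def test_weights_sum_to_one_every_draw(self):
        res = VonMisesMixtureModel([0.1, 2.0, -2.0], 5.0).fit(draws=300, tune=100, seed=6)
        np.testing.assert_allclose(res.weights.sum(axis=1), 1.0, atol=1e-6)
        assert res.assignments.min() >= 0
        assert res.assignments.max() < res.model.n_components

    def test_hbm_posterior_rejected_by_mixture_accessors(self):
        res = HierarchicalEnsembleModel([0.1, 0.2], 5.0).fit(draws=200, tune=100, seed=7)
        with pytest.raises(TypeError):
            occupied_components(res)
        with pytest.raises(TypeError):
            component_mean_for_stimulus(res, 0)


class TestPointEstimate:
    def test_identical_draws(self):
        assert posterior_point_estimate(np.full(500, 0.7)) == pytest.approx(0.7, abs=np.pi / 360)

    def test_unimodal_von_mises_draws(self):
        draws = np.random.default_rng(0).vonmises(1.0, 10.0, 5000)
        est = posterior_point_estimate(draws)
        assert abs(est - 1.0) < 2 * np.pi / 360 + 0.05

    def test_bimodal_picks_heavier_mode(self):
        rng = np.random.default_rng(1)
        draws = np.concatenate([rng.vonmises(np.pi / 2, 30, 700),
                                rng.vonmises(-np.pi / 2, 30, 300)])
        est = posterior_point_estimate(draws)
        assert abs(circ_dist(est, np.pi / 2)) < 0.2

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            posterior_point_estimate(np.zeros(50))


class TestSimulation:
    def test_outputs_on_grid_with_right_shape(self):
        theta = GRID360.values[[10, 200, 300]]
        spec = HBMSpec(kappa_obs=10.0, mcmc=MCMCSettings(draws=400, tune=200))
        rep = simulate_whole_report_trial(theta, GRID360, spec, seed=8)
        assert rep.shape == (3,)
        for v in rep:
            assert GRID360.contains(v)

    def test_noise_monotonicity(self):
        rng = np.random.default_rng(9)
        theta = GRID360.values[rng.integers(0, 360, size=(50, 3))]
        errs = {}
        for kobs in (5.0, 20.0):
            spec = HBMSpec(kappa_obs=kobs, mcmc=MCMCSettings(draws=500, tune=200))
            sim = simulate_whole_report_trials(theta, GRID360, spec, seed=10)
            errs[kobs] = np.abs(circ_dist(sim.reported, theta)).mean()
        assert errs[20.0] < errs[5.0]

    def test_mixture_simulation_carries_component_means(self):
        rng = np.random.default_rng(11)
        theta = GRID360.values[rng.integers(0, 360, size=(10, 4))]
        spec = BFMMSpec(kappa_obs=10.0, mcmc=MCMCSettings(draws=400, tune=200))
        sim = simulate_whole_report_trials(theta, GRID360, spec, seed=12)
        assert sim.component_means.shape == (10, 4)
        assert sim.occupied_hist.shape == (10, 4)
        np.testing.assert_allclose(sim.occupied_hist.sum(axis=1), 1.0)
        assert np.all(np.abs(sim.component_means) <= np.pi)

    def test_seeded_reproducibility(self):
        theta = GRID360.values[[5, 100]]
        spec = HBMSpec(kappa_obs=10.0, mcmc=MCMCSettings(draws=300, tune=100))
        a = simulate_whole_report_trial(theta, GRID360, spec, seed=13)
        b = simulate_whole_report_trial(theta, GRID360, spec, seed=13)
        np.testing.assert_array_equal(a, b)


class TestSpecs:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            HBMSpec(kappa_obs=0.0)
        with pytest.raises(ValueError):
            BFMMSpec(kappa_obs=5.0, alpha=0.0)
        with pytest.raises(ValueError):
            MCMCSettings(draws=0)
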