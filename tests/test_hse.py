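"""Excited-state reaction-diffusion solver and its Monte-Carlo oracle."""

import numpy as np
import pytest

from trfret import (
    ContractError,
    DistanceDistribution,
    ProbePair,
    RadialGrid,
    SubPopulation,
    TimeGrid,
    donor_survival,
    mc_survival_oracle,
    photon_budget,
    solve_hse,
    transfer_sink,
)
from trfret.hse import transfer_rate

TINY_R0 = 1e-6  # effectively no transfer


class TestTimeGrid:
    def test_times_are_k_dt(self):
        tg = TimeGrid(dt=0.0122, n_steps=3000)
        assert tg.times[0] == 0.0
        assert tg.times[2999] == pytest.approx(2999 * 0.0122, abs=1e-12)

    def test_invalid(self):
        from trfret import RangeError

        with pytest.raises(RangeError):
            TimeGrid(dt=0.0, n_steps=10)
        with pytest.raises(RangeError):
            TimeGrid(dt=0.01, n_steps=0)


class TestSolver:
    def test_reaction_only_matches_analytic_pointwise(self, probes):
        """With D = 0 the equation decouples: Nbar = exp(-k(r) t) exactly."""
        g = RadialGrid(2.0, 80.0, 200)
        dist = DistanceDistribution.from_moments(19.3, 8.0, g)
        pop = SubPopulation(dist, 0.0)
        tg = TimeGrid(0.1, 200)
        sol = solve_hse(pop, probes, tg)
        k = transfer_rate(g.nodes, probes)
        expected = np.exp(-np.outer(k, tg.times))
        mask = expected > 1e-250
        rel = np.abs(sol.n_bar[mask] - expected[mask]) / expected[mask]
        assert rel.max() < 1e-6

    def test_no_transfer_preserves_uniform_decay(self):
        """R0 -> 0 with D > 0: the conservative diffusion operator leaves the
        spatially uniform initial condition uniform; only spontaneous decay."""
        probes = ProbePair(r0=TINY_R0, tau_d0=10.0, tau_a0=4.0)
        g = RadialGrid(2.0, 80.0, 200)
        dist = DistanceDistribution.from_moments(39.0, 39.0, g)
        pop = SubPopulation(dist, 20.0)
        tg = TimeGrid(0.0122, 3000)
        sol = solve_hse(pop, probes, tg)
        expected = np.exp(-tg.times / 10.0)
        assert np.abs(sol.n_bar - expected[None, :]).max() < 1e-6

    def test_equilibrium_preserved_with_sink_off(self):
        """No transfer and (numerically) no spontaneous decay: diffusion in
        the equilibrium potential must leave Nbar = 1 unchanged."""
        probes = ProbePair(r0=TINY_R0, tau_d0=1e12, tau_a0=4.0)
        g = RadialGrid(2.0, 80.0, 150)
        dist = DistanceDistribution.from_moments(30.0, 15.0, g)
        pop = SubPopulation(dist, 25.0)
        n_steps = 100
        sol = solve_hse(pop, probes, TimeGrid(0.05, n_steps))
        # drift bounded by 1e-10 per step
        assert np.abs(sol.n_bar[:, 1] - 1.0).max() < 1e-10
        assert np.abs(sol.n_bar - 1.0).max() < 1e-10 * n_steps

    def test_solution_invariants(self, flexible, probes):
        sol = solve_hse(flexible, probes, TimeGrid(0.05, 400))
        nb = sol.n_bar
        assert np.allclose(nb[:, 0], 1.0, atol=1e-9)
        assert nb.min() >= 0.0 and nb.max() <= 1.0

    def test_monotone_decay_at_every_node_when_frozen(self, rigid, probes):
        sol = solve_hse(rigid, probes, TimeGrid(0.1, 100))
        assert np.all(np.diff(sol.n_bar, axis=1) <= 1e-15)


class TestDonorSurvival:
    def test_basic_properties(self, flexible, probes):
        sol = solve_hse(flexible, probes, TimeGrid(0.05, 500))
        s = donor_survival(sol, flexible.distribution)
        assert s[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all(s >= 0) and np.all(s <= 1.0 + 1e-12)
        assert np.all(np.diff(s) <= 1e-12)

    def test_no_transfer_is_pure_exponential(self):
        probes = ProbePair(r0=TINY_R0, tau_d0=10.0, tau_a0=4.0)
        g = RadialGrid(2.0, 80.0, 200)
        pop = SubPopulation(DistanceDistribution.from_moments(30.0, 15.0, g), 10.0)
        tg = TimeGrid(0.05, 500)
        s = donor_survival(solve_hse(pop, probes, tg), pop.distribution)
        assert np.abs(s - np.exp(-tg.times / 10.0)).max() < 1e-6

    def test_frozen_matches_independent_fine_quadrature(self, probes):
        """D = 0 closed form integrated on a much finer grid (independent
        oracle for the shared-grid quadrature)."""
        g = RadialGrid(2.0, 80.0, 2000)
        dist = DistanceDistribution.from_moments(19.3, 8.0, g)
        pop = SubPopulation(dist, 0.0)
        tg = TimeGrid(0.5, 40)
        s = donor_survival(solve_hse(pop, probes, tg), dist)
        rf = np.linspace(2.0, 80.0, 8001)
        dens = dist.density(rf)
        dens /= np.trapezoid(dens, rf)
        k = transfer_rate(rf, probes)
        ref = np.array([np.trapezoid(dens * np.exp(-k * t), rf) for t in tg.times])
        assert np.abs(s - ref).max() < 1e-6

    def test_delta_at_forster_radius_doubles_decay_rate(self, probes):
        g = RadialGrid(16.0, 48.0, 3000)
        dist = DistanceDistribution.from_moments(32.0, 0.5, g)
        pop = SubPopulation(dist, 0.0)
        tg = TimeGrid(0.5, 40)  # out to 2*tau_d0
        sol = solve_hse(pop, probes, tg)
        s = donor_survival(sol, dist)
        assert np.abs(s - np.exp(-2.0 * tg.times / 10.0)).max() < 1e-3
        flux = transfer_sink(sol, dist, probes)
        assert np.abs(flux - 0.1 * np.exp(-2.0 * tg.times / 10.0)).max() < 1e-3

    def test_grid_mismatch_rejected(self, rigid, flexible, probes):
        sol = solve_hse(rigid, probes, TimeGrid(0.1, 50))
        other = DistanceDistribution.from_moments(
            25.0, 10.0, rigid.distribution.grid
        )
        with pytest.raises(ContractError):
            donor_survival(sol, other)


class TestTransferSink:
    def test_no_transfer_flux_is_zero(self):
        probes = ProbePair(r0=TINY_R0, tau_d0=10.0, tau_a0=4.0)
        g = RadialGrid(2.0, 80.0, 150)
        pop = SubPopulation(DistanceDistribution.from_moments(30.0, 15.0, g), 5.0)
        sol = solve_hse(pop, probes, TimeGrid(0.1, 100))
        flux = transfer_sink(sol, pop.distribution, probes)
        assert flux.max() < 1e-12

    def test_flux_nonnegative_and_decaying(self, flexible, probes):
        sol = solve_hse(flexible, probes, TimeGrid(0.05, 1000))
        flux = transfer_sink(sol, flexible.distribution, probes)
        assert np.all(flux >= 0)
        assert flux[-1] < 1e-3 * flux[0]

    @pytest.mark.parametrize("which", ["rigid", "flexible"])
    def test_photon_budget_conservation(self, which, rigid, flexible, probes):
        """Every excitation ends in spontaneous emission or transfer."""
        pop = {"rigid": rigid, "flexible": flexible}[which]
        sol = solve_hse(pop, probes, TimeGrid(0.1, 2))
        assert photon_budget(sol, pop.distribution, probes) == pytest.approx(
            1.0, abs=1e-4
        )


class TestDynamicRegimes:
    def test_fast_diffusion_averages_to_single_exponential(self):
        """D -> large: S(t) -> exp(-<k> t) with the density-weighted rate."""
        probes = ProbePair(r0=32.0, tau_d0=10.0, tau_a0=4.0)
        g = RadialGrid(10.0, 70.0, 300)
        dist = DistanceDistribution.from_moments(35.0, 10.0, g)
        pop = SubPopulation(dist, 1e4)
        tg = TimeGrid(0.1, 101)  # [0, tau_d0]
        s = donor_survival(solve_hse(pop, probes, tg), dist)
        k_mean = float(
            np.dot(g.trapezoid_weights, dist.on_grid * transfer_rate(g.nodes, probes))
        )
        ref = np.exp(-k_mean * tg.times)
        assert np.abs(s / ref - 1.0).max() < 0.01

    def test_transfer_efficiency_nondecreasing_in_d(self, probes):
        """Diffusion feeds population into the high-rate region when the
        distribution sits mostly beyond R0."""
        g = RadialGrid(2.0, 80.0, 200)
        dist = DistanceDistribution.from_moments(39.0, 25.0, g)
        effs = []
        for d in (0.0, 1.0, 5.0, 20.0, 100.0):
            pop = SubPopulation(dist, d)
            sol = solve_hse(pop, probes, TimeGrid(1.0, 2))
            e = 1.0 - sol.modal_integral(np.ones(g.n_points)) / probes.tau_d0
            effs.append(e)
        assert np.all(np.diff(effs) >= -1e-12)


class TestMCOracle:
    def test_frozen_agrees_with_closed_form(self, rigid, probes):
        tg = TimeGrid(2.0, 6)
        mc = mc_survival_oracle(rigid, probes, tg, n_traj=200_000, dt_mc=0.01, seed=0)
        s = donor_survival(solve_hse(rigid, probes, tg), rigid.distribution)
        dev = np.abs(mc.survival - s) / np.maximum(mc.stderr, 1e-12)
        assert dev.max() <= 3.0

    def test_no_transfer_is_exponential(self):
        probes = ProbePair(r0=TINY_R0, tau_d0=10.0, tau_a0=4.0)
        g = RadialGrid(2.0, 80.0, 200)
        pop = SubPopulation(DistanceDistribution.from_moments(30.0, 15.0, g), 10.0)
        tg = TimeGrid(2.0, 6)
        mc = mc_survival_oracle(pop, probes, tg, n_traj=100_000, dt_mc=0.01, seed=1)
        ref = np.exp(-tg.times / 10.0)
        dev = np.abs(mc.survival - ref) / np.maximum(mc.stderr, 1e-12)
        assert dev.max() <= 3.0

    @pytest.mark.parametrize("d_coef", [2.0, 10.0, 30.0])
    @pytest.mark.parametrize("mean", [25.0, 32.0, 40.0])
    def test_pde_mc_agreement_grid(self, d_coef, mean, probes):
        """3x3 (D, mean) cross-check of the PDE against Brownian dynamics."""
        g = RadialGrid(2.0, 80.0, 300)
        dist = DistanceDistribution.from_moments(mean, 12.0, g)
        pop = SubPopulation(dist, d_coef)
        tg = TimeGrid(2.5, 5)
        s = donor_survival(solve_hse(pop, probes, tg), dist)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mc = mc_survival_oracle(
                pop, probes, tg, n_traj=30_000, dt_mc=0.008, seed=7
            )
        dev = np.abs(mc.survival - s) / np.maximum(mc.stderr, 1e-12)
        # 36 comparisons across the parametrization: Bonferroni-adjusted
        # white-noise band (3.5 sigma ~ two-sided 0.05/36)
        assert dev.max() <= 3.5

    def test_contract_errors(self, rigid, probes):
        tg = TimeGrid(1.0, 5)
        with pytest.raises(ContractError):
            mc_survival_oracle(rigid, probes, tg, n_traj=100, dt_mc=-0.1, seed=0)
        with pytest.raises(ContractError):
            mc_survival_oracle(rigid, probes, tg, n_traj=100, dt_mc=0.01, seed=-3)
        with pytest.raises(ContractError):
            mc_survival_oracle(rigid, probes, tg, n_traj=0, dt_mc=0.01, seed=0)

    def test_determinism(self, rigid, probes):
        tg = TimeGrid(2.0, 4)
        a = mc_survival_oracle(rigid, probes, tg, n_traj=10_000, dt_mc=0.01, seed=5)
        b = mc_survival_oracle(rigid, probes, tg, n_traj=10_000, dt_mc=0.01, seed=5)
        assert np.array_equal(a.survival, b.survival)
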