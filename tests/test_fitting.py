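"""Global analysis: chi-square, fitting, scans, diagnostics."""

import copy

import numpy as np
import pytest

from trfret import (
    AcquisitionSettings,
    ContractError,
    FitSpec,
    ParamSpec,
    benchmark_grid,
    benchmark_mixture,
    chi_squared,
    estimate_lifetime,
    fit_global,
    model_curveset,
    model_dimension_test,
    residual_autocorrelation,
    rigorous_interval,
    simulate_curveset,
)
from trfret.fitting import _GlobalObjective
from trfret.simulate import BENCHMARK_PROBES


@pytest.fixture(scope="module")
def rigid_set_fast(fast_acq):
    return simulate_curveset(benchmark_mixture(1.0), fast_acq, seed=31)


@pytest.fixture(scope="module")
def mixed_set_fast(fast_acq):
    return simulate_curveset(benchmark_mixture(0.5), fast_acq, seed=32)


def _fast_spec(dimension, n_datasets=1, n_restarts=2):
    return FitSpec.default(
        dimension,
        BENCHMARK_PROBES,
        benchmark_grid(),
        n_datasets=n_datasets,
        n_restarts=n_restarts,
    )


class TestChiSquared:
    def test_zero_when_model_equals_data(self, rigid_set_fast):
        model = {r: c.counts.copy() for r, c in rigid_set_fast.curves().items()}
        total, per_curve = chi_squared(model, list(rigid_set_fast.curves().values()))
        assert total == 0.0
        assert all(v == 0.0 for v in per_curve)

    def test_noiseless_self_consistency(self, fast_acq):
        st = AcquisitionSettings(
            **{**fast_acq.__dict__, "noise_model": "none"}
        )
        mix = benchmark_mixture(0.5)
        cs = simulate_curveset(mix, st, seed=0)
        ideal = model_curveset(mix, st.time_grid, irf=cs.irf)
        model = {}
        for role in ("DO", "AO", "DA", "DAA"):
            shape = ideal.by_role(role)
            model[role] = shape * (st.peak_counts / shape.max())
        total, _ = chi_squared(model, list(cs.curves().values()))
        assert total < 1e-6

    def test_noisy_data_vs_generating_model(self, fast_acq):
        """Counting-statistics expectation: reduced chi2 near 1."""
        mix = benchmark_mixture(0.5)
        st0 = AcquisitionSettings(**{**fast_acq.__dict__, "noise_model": "none"})
        clean = simulate_curveset(mix, st0, seed=0)
        model = {r: c.counts.copy() for r, c in clean.curves().items()}
        noisy = simulate_curveset(mix, fast_acq, seed=8)
        total, _ = chi_squared(model, list(noisy.curves().values()))
        assert total == pytest.approx(1.0, abs=0.05)

    def test_shape_mismatch_rejected(self, rigid_set_fast):
        model = {r: c.counts[:-1] for r, c in rigid_set_fast.curves().items()}
        with pytest.raises(ContractError):
            chi_squared(model, list(rigid_set_fast.curves().values()))


class TestEstimateLifetime:
    @pytest.mark.parametrize("role,tau", [("do", 10.0), ("ao", 4.0)])
    def test_reference_curves(self, mixed_set_fast, role, tau):
        est = estimate_lifetime(getattr(mixed_set_fast, role))
        assert est == pytest.approx(tau, rel=0.03)


class TestResidualAutocorrelation:
    def test_white_noise_stays_in_band(self):
        rng = np.random.default_rng(4)
        r = rng.standard_normal(3000)
        ac = residual_autocorrelation(r)
        assert ac.values[0] == pytest.approx(1.0)
        assert ac.band_violation_fraction() < 0.01
        assert not ac.degenerate

    def test_structured_residuals_violate_band(self):
        t = np.arange(3000)
        r = np.sin(2 * np.pi * t / 400)  # slow systematic wave
        ac = residual_autocorrelation(r)
        assert ac.band_violation_fraction() > 0.2

    def test_constant_residuals_flagged_degenerate(self):
        ac = residual_autocorrelation(np.full(100, 3.7))
        assert ac.degenerate

    def test_too_short_rejected(self):
        with pytest.raises(ContractError):
            residual_autocorrelation(np.ones(16))


class TestFitGlobal:
    def test_noiseless_one_population_identifiability(self, fast_acq):
        """With no noise and D frozen at its true value, the moments come
        back to within 0.05 A."""
        st = AcquisitionSettings(**{**fast_acq.__dict__, "noise_model": "none"})
        cs = simulate_curveset(benchmark_mixture(1.0), st, seed=0)
        spec = _fast_spec("one_population", n_restarts=1)
        spec.params["d1"] = ParamSpec(0.0, vary=False, min=0.0, max=200.0)
        fit = fit_global(cs, spec, seed=0)
        assert fit.params["mean1"] == pytest.approx(19.3, abs=0.05)
        assert fit.params["fwhm1"] == pytest.approx(8.0, abs=0.05)
        assert fit.chi2_reduced < 1e-6

    def test_seeded_runs_are_bitwise_identical(self, mixed_set_fast):
        spec = _fast_spec("one_population", n_restarts=2)
        f1 = fit_global(mixed_set_fast, spec, seed=9)
        f2 = fit_global(mixed_set_fast, spec, seed=9)
        assert f1.params == f2.params
        assert f1.chi2_total == f2.chi2_total

    def test_swap_symmetry_of_objective(self, mixed_set_fast):
        """Relabeling the two sub-populations and replacing FRX by 1-FRX
        leaves the stacked residual vector unchanged."""
        spec = _fast_spec("two_population")
        obj = _GlobalObjective([mixed_set_fast], spec)
        p = {
            "mean1": 20.0, "fwhm1": 9.0, "d1": 1.0,
            "mean2": 38.0, "fwhm2": 30.0, "d2": 15.0,
            "frx_0": 0.3, "tau_d": 10.0, "tau_a": 4.0, "background": 0.0,
        }
        swapped = {
            "mean1": 38.0, "fwhm1": 30.0, "d1": 15.0,
            "mean2": 20.0, "fwhm2": 9.0, "d2": 1.0,
            "frx_0": 0.7, "tau_d": 10.0, "tau_a": 4.0, "background": 0.0,
        }
        r1 = obj.residual_vector(p)
        r2 = obj.residual_vector(swapped)
        assert np.abs(np.sum(r1**2) - np.sum(r2**2)) < 1e-9

    def test_canonical_order_mean1_below_mean2(self, fast_acq):
        sets = [
            simulate_curveset(benchmark_mixture(f), fast_acq, seed=40 + i)
            for i, f in enumerate([0.2, 0.8])
        ]
        spec = _fast_spec("two_population", n_datasets=2, n_restarts=2)
        fit = fit_global(sets, spec, seed=3)
        assert fit.params["mean1"] < fit.params["mean2"]

    def test_pure_rigid_pins_frx_at_bound(self, rigid_set_fast):
        """Two-population fit of one-population data: the mole fraction runs
        to its boundary and the fit flags it."""
        spec = _fast_spec("two_population", n_restarts=2)
        fit = fit_global(rigid_set_fast, spec, seed=2)
        frx = fit.params["frx_0"]
        assert min(frx, 1.0 - frx) < 0.02
        assert any("unidentifiable" in w for w in fit.warnings)

    def test_missing_frx_params_rejected(self, mixed_set_fast):
        spec = _fast_spec("two_population", n_datasets=2)
        with pytest.raises(ContractError):
            fit_global([mixed_set_fast], spec, seed=0)


@pytest.fixture(scope="module")
def rigid_fit(rigid_set_fast):
    spec = _fast_spec("one_population", n_restarts=2)
    return spec, fit_global(rigid_set_fast, spec, seed=1)


class TestRigorousInterval:
    def test_interval_contains_best_fit(self, rigid_set_fast, rigid_fit):
        spec, fit = rigid_fit
        v0 = fit.params["mean1"]
        ci = rigorous_interval(
            rigid_set_fast, spec, fit, "mean1",
            scan_values=np.linspace(v0 - 0.5, v0 + 0.5, 5), seed=0,
        )
        assert ci.lower <= v0 <= ci.upper
        assert ci.level == 0.95

    def test_default_level_for_diffusion_is_one_sd(self, rigid_set_fast, rigid_fit):
        spec, fit = rigid_fit
        ci = rigorous_interval(
            rigid_set_fast, spec, fit, "d1",
            scan_values=[0.0, 0.2, 0.5, 1.0, 2.0], seed=0,
        )
        assert ci.level == 0.66
        assert ci.lower <= fit.params["d1"] <= ci.upper

    def test_non_bracketing_scan_rejected(self, rigid_set_fast, rigid_fit):
        spec, fit = rigid_fit
        with pytest.raises(ContractError):
            rigorous_interval(
                rigid_set_fast, spec, fit, "mean1",
                scan_values=[30.0, 35.0, 40.0], seed=0,
            )

    def test_unknown_parameter_rejected(self, rigid_set_fast, rigid_fit):
        spec, fit = rigid_fit
        with pytest.raises(ContractError):
            rigorous_interval(rigid_set_fast, spec, fit, "bogus", seed=0)


class TestModelDimension:
    def test_two_population_data_demands_two_populations(self, fast_acq):
        sets = [
            simulate_curveset(benchmark_mixture(f), fast_acq, seed=50 + i)
            for i, f in enumerate([0.3, 0.7])
        ]
        cmp_ = model_dimension_test(
            sets,
            _fast_spec("one_population", n_datasets=2, n_restarts=2),
            _fast_spec("two_population", n_datasets=2, n_restarts=2),
            seed=4,
        )
        assert cmp_.p_value < 0.01
        assert cmp_.fit_two.chi2_reduced < cmp_.fit_one.chi2_reduced

    def test_one_population_data_needs_no_second(self, rigid_set_fast):
        cmp_ = model_dimension_test(
            rigid_set_fast,
            _fast_spec("one_population", n_restarts=2),
            _fast_spec("two_population", n_restarts=2),
            seed=5,
        )
        # chi2 gain from the extra sub-population is statistically empty
        assert cmp_.delta_chi2 < cmp_.fit_one.chi2_total * 0.01
        assert cmp_.p_value > 0.001

    def test_identical_specs_flagged_degenerate(self, rigid_set_fast):
        spec = _fast_spec("one_population", n_restarts=1)
        cmp_ = model_dimension_test(rigid_set_fast, spec, copy.deepcopy(spec), seed=6)
        assert cmp_.degenerate
        assert cmp_.fit_one.chi2_total == pytest.approx(cmp_.fit_two.chi2_total)
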