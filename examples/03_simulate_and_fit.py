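"""Simulate one TCSPC experiment set and recover its parameters blind.

Generates the four decay curves of the pure flexible sample at realistic
acquisition settings (10,000 peak counts, 3000 channels of 0.0122 ns, 50 ps
IRF, counting noise) and runs the one-population global fit from generic
initial guesses.  Takes a few seconds.
"""

from trfret import (
    AcquisitionSettings,
    FitSpec,
    benchmark_grid,
    benchmark_mixture,
    fit_global,
    simulate_curveset,
)
from trfret.simulate import BENCHMARK_PROBES

settings = AcquisitionSettings()
truth = {"mean": 39.0, "fwhm": 39.0, "D": 20.0}
cs = simulate_curveset(benchmark_mixture(0.0), settings, seed=202)
print("simulated DO/AO/DA/DAA, peak counts:",
      [int(c.counts.max()) for c in cs.curves().values()])

spec = FitSpec.default("one_population", BENCHMARK_PROBES, benchmark_grid())
fit = fit_global(cs, spec, seed=1)

print(f"\nreduced chi2 = {fit.chi2_reduced:.3f}")
print(f"{'parameter':10s} {'true':>8s} {'recovered':>10s}")
print(f"{'mean (A)':10s} {truth['mean']:8.1f} {fit.params['mean1']:10.2f}")
print(f"{'FWHM (A)':10s} {truth['fwhm']:8.1f} {fit.params['fwhm1']:10.2f}")
print(f"{'D (A^2/ns)':10s} {truth['D']:8.1f} {fit.params['d1']:10.2f}")
print(f"{'tau_d (ns)':10s} {10.0:8.1f} {fit.params['tau_d']:10.3f}")
print(f"{'tau_a (ns)':10s} {4.0:8.1f} {fit.params['tau_a']:10.3f}")
# The recovered moments land within ~1 A and D within ~1 A^2/ns of the
# inputs: the joint DO/AO/DA/DAA information is what breaks the strong
# width-diffusion correlation a donor-only analysis suffers from.
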