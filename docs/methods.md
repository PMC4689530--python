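# Methods

## Physical model

An ensemble of doubly labeled chain molecules is described as a mixture of
two conformer sub-populations.  Sub-population *i* has

- a radial end-to-end (inter-probe) distance density
  `N0_i(r) = 4πr² exp(−b_i (r − a_i)²) / Z_i` on `[R_min, R_max]`, reported
  by its mean and FWHM.  The r² prefactor (the "skewed Gaussian") captures
  the non-Gaussian statistics of short chain segments; a plain Gaussian in
  r is the b→large limit and needs no separate implementation;
- an intramolecular diffusion coefficient `D_i` (Å²/ns) for the relative
  motion of the two labeled segments, taken independent of r.

After pulsed excitation, the reduced donor excited population
`N̄(r,t) = N*(r,t)/N0(r)` of each sub-population evolves under

    ∂N̄/∂t = −(1/τ_d⁰)[1 + (R₀/r)⁶] N̄ + (D/N0) ∂/∂r [ N0 ∂N̄/∂r ],

`N̄(r,0) = 1`, zero-flux boundaries.  The donor (DA) curve is the
FRX-weighted sum of `∫N̄_i N0_i dr`; the acceptor (DAA) curve is the
transfer sink `(1/τ_d⁰)∫(R₀/r)⁶ N̄_i N0_i dr` convolved with
`exp(−t/τ_a⁰)`, plus a direct-excitation term
`der · exp(−t/τ_a⁰)` (der = acceptor/donor absorbance ratio at the donor
excitation wavelength; default 0 in simulations).  DO and AO are pure
exponentials and serve as internal lifetime references.  All four model
curves are convolved with the IRF and scaled per curve.

Assumptions: mono-exponential probe decays; r-independent D (a deliberate
simplification — only an average fluctuation rate per sub-population is
recoverable); quasi-static orientation factor absorbed into R₀; constant
background (subtracted upstream or fit as a parameter).

## Numerics

**Spatial discretization.** One uniform radial grid (default 200 nodes,
`R_min = max(2 Å, 0.1·R₀)`, `R_max = 2·R₀` with override — the benchmark
uses 80 Å to hold the broad flexible distribution) is shared by the
normalization, the moments, and the solver, so forward model and reported
moments see the same quadrature (composite trapezoid throughout).  Grid
convergence: refining 200 → 1600 nodes moves benchmark survival values by
~1e−5 (relative), far below counting noise.

**Time propagation.** The diffusion operator is discretized in conservative
flux form with geometric-mean face densities.  Under the similarity
transform `y = √N0 · N̄` the operator is a symmetric tridiagonal matrix
with constant off-diagonal `D/Δr²`; the drift enters only the diagonal
through the log-density differences (capped at e^±12 per face to bound the
matrix norm for near-singular potentials).  The semi-discrete system is
propagated **exactly** through `eigh_tridiagonal`:
`y(t) = V e^{−Λt} Vᵀ y(0)`.  Rationale over a time-stepping scheme: the
transfer rate at contact, `(R₀/R_min)⁶/τ_d⁰ ≈ 1e5–1e6 ns⁻¹`, makes any
channel-width step (0.0122 ns) enormously stiff — a Crank–Nicolson step has
amplification ≈ −1 there and oscillates — while the exponential is
unconditionally stable, positivity-preserving, and leaves the equilibrium
state invariant to ~1e−11 per step.  It also renders every survival/sink
curve an exact n-term multi-exponential, which the fitter exploits: one
eigendecomposition per sub-population per objective evaluation (~10 ms).

**Sub-channel transients.** Conformers near contact transfer within
femto–picoseconds, producing a flux spike far below the channel bandwidth.
Time integrals therefore use the closed-form modal sums (`Σ A_k/λ_k`), and
the acceptor-lifetime convolution is evaluated mode-by-mode analytically
(`(e^{−λt} − e^{−t/τ_a})/(1/τ_a − λ)`, with the `t·e^{−t/τ_a}` limit at
degeneracy).  A channel-sampled discrete convolution
(`convolve_lifetime`, trapezoid weights) is provided for arbitrary sampled
fluxes and agrees with the modal route to <0.5% when all rates are
channel-resolved.  `n_bar` back-transforms `y/√N0` only at nodes carrying
>1e−6 of the peak density; emptier nodes report their local reaction-only
decay (they hold no population, and the division would amplify eigensolver
roundoff).

**Monte-Carlo oracle.** An independent Brownian-dynamics walker:
Euler–Maruyama in the potential `U = −ln N0`, reflecting boundaries,
initial positions by inverse-CDF sampling.  De-excitation uses the
exponential-clock construction — one Exp(1) threshold per trajectory
against the path-accumulated hazard `∫k(r)dt` (trapezoid along the path) —
which is distribution-identical to per-step Bernoulli killing with
`p = 1 − e^{−kΔt}` but needs one draw per trajectory, and is stable for
arbitrarily large k.  Agreement with the PDE is verified at 10⁶
trajectories (3 SE) and across a 3×3 (D, mean) grid.

## Simulator

Emulates the benchmark acquisition: 3000 channels × 0.0122 ns, Gaussian IRF
of 50 ps FWHM (centered at channel 30 by default), each of the four curves
scaled to 10,000 counts at its maximum, optional constant background, and
counting noise — Gaussian with variance equal to the expected counts
(negative draws clamped to 0) by default, Poisson as an option; the two
agree in mean and variance within 5% above 100 counts.  What it does *not*
emulate: timing jitter/IRF drift between curves, pile-up, dark noise,
after-pulsing, scattered-light contamination, and multi-exponential probe
photophysics.  Passing recovery tests therefore demonstrate the estimator's
correctness and statistical efficiency under the stated noise model, not
robustness to instrument systematics.

## Global fit

- **Parameters.** Sub-populations are optimized in their reported
  coordinates (mean, FWHM) — converted internally to (a, b) by a warm-started
  2-D root find — so scans and intervals act directly on the quantities of
  interest; D is optimized as √D to keep the D ≥ 0 boundary smooth.  τ_d⁰
  and τ_a⁰ are shared free parameters initialized from mono-exponential
  tail fits of DO/AO (optionally fixed).  FRX is free per dataset; the
  per-curve scale c is projected out in closed form each evaluation.
- **Weights.** Counting noise has variance equal to the *expected* counts,
  so residuals are weighted `1/max(model, 1)`.  Data-based weights would
  bias the reduced χ² upward by ≈3/m per channel (≈+0.05 globally,
  dominated by the low-count tail of the short-lived AO curve) and bias
  parameter estimates; model-based weights give E[χ²_red] ≈ 0.99 and the
  Pearson-optimal scale has the closed form `c* = √(Σd²/s / Σs)`.
- **Optimizer.** Bounded trust-region least squares (lmfit/`least_squares`)
  on the stacked weighted residual vector, with seeded multi-start
  (default 8 starts: the supplied initials plus ±25% perturbations).
  Default initials bracket R₀ (0.7·R₀ and 1.3·R₀ for two populations)
  since the informative window is ≈(0.5–1.5)·R₀.  The sub-population swap
  degeneracy is resolved by canonicalizing mean₁ < mean₂ (FRX → 1−FRX).
  (mean, FWHM) requests no skewed Gaussian on the grid can realize return a
  flat penalty residual, which the trust region treats as a rejected step.
  Identical seeds and inputs reproduce results bitwise.
- **Diagnostics.** Global and per-curve χ², residual traces, normalized
  residual autocorrelations with a 3/√n white-noise band, an F-test
  comparing one- vs two-population fits, and an identifiability warning
  when a recovered mole fraction leaves one sub-population below 2% weight.
- **Rigorous intervals.** Exhaustive scan: fix the parameter, re-minimize
  all others (warm-started, 2 starts), accept values with
  `χ² ≤ χ²_best · (1 + p/(n−p)·F(p, n−p; level))`; edges interpolated
  linearly in χ² between scan points and clamped to the scan boundary when
  no crossing occurs inside it.  Levels default to 0.95, and 0.66 ("1 SD")
  for diffusion coefficients.

## Benchmark conditions and problem sizes

The canonical study conditions are frozen in `trfret.simulate`: rigid
(mean 19.3 Å, FWHM 8.0 Å, D = 0 — a stably folded state) vs flexible
(mean 39 Å, FWHM 39 Å, D = 20 Å²/ns — a disordered chain near the upper
end of observed reconfiguration rates), R₀ = 32 Å, τ_d⁰ = 10 ns,
τ_a⁰ = 4 ns, der = 0, 10,000 peak counts.  `scripts/acceptance.py` runs the
three benchmark fits at full scale (3000 channels × 4 curves; two datasets
jointly for the mixture case).  Unit tests exercising fit machinery use a
reduced 750-channel × 0.05 ns grid, chosen so the whole suite stays
interactive; the scan grids for D use 8–10 points spanning the benchmark
brackets.

## Known limitations

- Only two sub-populations; the method yields a *minimal* number of
  components, and more cannot be excluded from the fit quality alone.
- One average D per sub-population; r-dependent friction is not modeled.
- The distance dependence of the transfer probability is weak at both ends
  of the distribution, so tail shapes (and hence FWHM of broad, fast
  sub-populations) carry large uncertainties — visible in the scan traces.
- Measured-IRF input assumes a noise-free response; IRF counting noise is
  not propagated into the intervals.
- The confidence thresholds use the F statistic on the full free-parameter
  count, the conventional exhaustive-search calibration; it is approximate
  for parameters pinned at bounds (e.g. D = 0).
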