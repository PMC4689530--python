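# trfret

Ensemble-level time-resolved FRET (trFRET) analysis: resolve **two conformer
sub-populations** in a mixture of flexible biopolymers — their intramolecular
distance distributions, their nanosecond distance-fluctuation rates, and their
mole fraction — from time-correlated single-photon-counting (TCSPC) decay
curves measured on the bulk ensemble.

Who this is for: spectroscopists and structural biophysicists analyzing
four-curve trFRET experiments (donor-only DO, acceptor-only AO, donor with
acceptor DA, acceptor under donor excitation DAA), e.g. folded/unfolded
mixtures during protein folding transitions, using small natural probes that
single-molecule FRET cannot easily use.

## The model

Each sub-population *i* carries a skewed-Gaussian end-to-end distance
distribution on a radial grid [R_min, R_max],

    N0(r) = 4 π r² exp(−b (r − a)²) / Z ,

reported by its mean and FWHM, and an intramolecular diffusion coefficient
D (Å²/ns) for the relative Brownian motion of the labeled segments.  The
reduced donor excited-state population N̄(r,t) obeys the reaction–diffusion
equation

    ∂N̄/∂t = −(1/τ_d⁰)[1 + (R₀/r)⁶] N̄ + (D/N0(r)) ∂/∂r [ N0(r) ∂N̄/∂r ] ,

with reflecting boundaries: Förster transfer (critical distance R₀) plus
spontaneous decay, and diffusion in the potential of the equilibrium
distribution.  The donor decay of a two-population mixture is

    I_d(t) = c { FRX ∫ N̄₁ N0,1 dr + (1−FRX) ∫ N̄₂ N0,2 dr } ,

and the acceptor grow-in is the transfer sink ∫ (R₀/r)⁶ N̄ N0 dr / τ_d⁰
convolved with the acceptor lifetime τ_a⁰, plus direct acceptor excitation.
All model curves are convolved with the measured instrument response (IRF)
and compared with the four measured histograms through a global weighted
χ²; one or more mixture compositions are fit **jointly**, sharing
(a₁,b₁,D₁,a₂,b₂,D₂) with per-dataset FRX and per-curve scale.  Confidence
intervals come from the rigorous scan: fix one parameter, re-minimize all
others, threshold the χ² surface with an F statistic (95% for distribution
parameters and FRX, 66% — "1 SD" — for diffusion coefficients).

The PDE is solved by exact time-exponentiation of the symmetrized
conservative finite-volume operator (eigendecomposition of a symmetric
tridiagonal matrix), which is unconditionally stable against the stiff
transfer rates near contact and makes every model curve an exact
multi-exponential; a Brownian-dynamics Monte-Carlo walker provides an
independent cross-check.  See `docs/methods.md` for the numerical details.

## Worked example

Simulate the four decay curves of a disordered chain (mean 39 Å, FWHM 39 Å,
D = 20 Å²/ns; R₀ = 32 Å, τ_d⁰ = 10 ns, τ_a⁰ = 4 ns; 10,000 peak counts,
3000 channels × 0.0122 ns, 50 ps IRF, counting noise) and recover its
parameters blind:

```sh
python examples/03_simulate_and_fit.py
```

prints

```
simulated DO/AO/DA/DAA, peak counts: [10256, 10020, 10035, 10200]

reduced chi2 = 1.009
parameter      true  recovered
mean (A)       39.0      38.92
FWHM (A)       39.0      38.80
D (A^2/ns)     20.0      19.59
tau_d (ns)     10.0     10.002
tau_a (ns)      4.0      4.009
```

A reduced χ² of ≈1 says the fit sits at the counting-noise floor; the
recovered moments land within ~1 Å and D within ~1 Å²/ns of the generating
inputs because the joint donor+acceptor analysis breaks the strong
width–diffusion correlation that a donor-only analysis suffers from.  The
other examples build distributions (`01`), inspect survival curves and the
transfer-efficiency gap between sub-populations (`02`), and run a rigorous
confidence scan on a diffusion coefficient (`04`).

The same workflows are available from the shell:

```sh
trfret benchmark --frx 0.1,0.9 --seed 1 --out data/   # canonical datasets
trfret simulate --config config.json --seed 7         # custom simulations
trfret fit      --config config.json --out out/       # global fit -> report
trfret scan     --config config.json --param d1       # confidence interval
trfret moments  --mean 19.3 --fwhm 8.0                # moments <-> (a, b)
```

Curves are two-column TSV (`time_ns<TAB>counts`, `#` metadata headers);
configurations and fit reports are JSON.

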