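"""Joint global analysis of DO/AO/DA/DAA curve sets.

One or more simultaneously measured four-curve sets (different mixture
compositions of the same two conformer sub-populations) are fit together:
the sub-population parameters (mean, FWHM, D) are shared across all
datasets, while the mole fraction FRX and the per-curve scale c are local.
The DO and AO curves act as internal references that pin the FRET-free
lifetimes tau_d0 and tau_a0 (free by default, initialized from
mono-exponential tail fits).

Weighting and chi-square
------------------------
Counting noise has variance equal to the expected counts, so residuals are
weighted by the model estimate of that variance:

    chi2_curve = sum_channels (data - model)^2 / max(model, 1)
    chi2_reduced = sum_curves chi2_curve / (N_channels_total - n_free)

Per-curve scales are not iterated numerically: for Pearson weights the
optimal scale has the closed form c* = sqrt(sum(d^2/s) / sum(s)) and is
projected out at every objective evaluation.

Parameterization
----------------
Distributions are parameterized by their reported moments (mean, FWHM),
converted internally to (a, b); D is optimized as sqrt(D) so the physical
D >= 0 boundary is smooth.  The sub-population swap degeneracy is resolved
by canonicalizing to mean1 < mean2 (with FRX -> 1-FRX).

Confidence intervals use the rigorous-scan procedure: one parameter is
stepped over a grid and held fixed while all others are re-minimized; the
interval holds the values whose minimized global chi-square stays below the
F-statistic threshold chi2_best * (1 + p/(n-p) * F(p, n-p; level)).
Default levels: 0.95 for distribution parameters and FRX, 0.66 ("1 SD")
for diffusion coefficients.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import lmfit
import numpy as np
from scipy import stats

from .exceptions import ContractError, ConvergenceError
from .forward import ModelCurveSet, growin_from_modes
from .hse import solve_hse
from .model import (
    DistanceDistribution,
    ProbePair,
    RadialGrid,
    SubPopulation,
    params_from_moments,
)
from .simulate import CurveSet, DecayCurve

__all__ = [
    "ParamSpec",
    "FitSpec",
    "FitResult",
    "ConfidenceInterval",
    "AutocorrelationResult",
    "ModelComparison",
    "chi_squared",
    "fit_global",
    "residual_autocorrelation",
    "rigorous_interval",
    "model_dimension_test",
    "estimate_lifetime",
]

ROLE_ORDER = ("DO", "AO", "DA", "DAA")
DIMENSIONS = ("one_population", "two_population")


@dataclass
class ParamSpec:
    """Status of a single fit parameter (natural scale)."""

    value: float | None
    vary: bool = True
    min: float = -np.inf
    max: float = np.inf


@dataclass
class FitSpec:
    """Complete specification of a global fit.

    ``params`` maps natural parameter names — mean1, fwhm1, d1 (plus mean2,
    fwhm2, d2 and frx_0..frx_{K-1} for two-population fits), tau_d, tau_a,
    background — to :class:`ParamSpec`.  ``r0`` and the direct-excitation
    ratio are fixed probe constants.  tau values of ``None`` are initialized
    from mono-exponential fits of the DO/AO curves at fit time.
    """

    dimension: str
    grid: RadialGrid
    r0: float
    params: dict[str, ParamSpec]
    direct_excitation_ratio: float = 0.0
    n_restarts: int = 8
    restart_scale: float = 0.25

    def __post_init__(self):
        if self.dimension not in DIMENSIONS:
            raise ContractError(f"dimension must be one of {DIMENSIONS}")
        for name, p in self.params.items():
            if p.value is not None and not (p.min <= p.value <= p.max):
                raise ContractError(
                    f"initial value of {name} ({p.value}) outside its bounds"
                )
            if name in ("d1", "d2") and p.min < 0:
                p.min = 0.0
            if name.startswith("frx"):
                p.min = max(p.min, 0.0)
                p.max = min(p.max, 1.0)

    @property
    def n_populations(self) -> int:
        return 1 if self.dimension == "one_population" else 2

    @property
    def frx_names(self) -> list[str]:
        return sorted(
            (n for n in self.params if n.startswith("frx_")),
            key=lambda s: int(s.split("_")[1]),
        )

    @classmethod
    def default(
        cls,
        dimension: str,
        probes: ProbePair,
        grid: RadialGrid,
        n_datasets: int = 1,
        fix_lifetimes: bool = False,
        n_restarts: int = 8,
    ) -> "FitSpec":
        """Generic initial guesses bracketing the Forster radius.

        The efficient-transfer window is roughly (0.5-1.5)*R0, so the
        one-population guess starts at R0 and the two-population guesses at
        0.7*R0 and 1.3*R0; widths start at 0.4*R0 and the diffusion guesses
        at a slow / moderately fast pair.
        """
        span = grid.r_max - grid.r_min
        lo = grid.r_min + 0.02 * span
        hi = grid.r_max - 0.02 * span
        fw_lo, fw_hi = 0.5, 0.75 * span
        d_hi = 200.0
        p: dict[str, ParamSpec] = {}
        if dimension == "one_population":
            p["mean1"] = ParamSpec(np.clip(probes.r0, lo, hi), True, lo, hi)
            p["fwhm1"] = ParamSpec(0.4 * probes.r0, True, fw_lo, fw_hi)
            p["d1"] = ParamSpec(5.0, True, 0.0, d_hi)
        else:
            p["mean1"] = ParamSpec(np.clip(0.7 * probes.r0, lo, hi), True, lo, hi)
            p["fwhm1"] = ParamSpec(0.3 * probes.r0, True, fw_lo, fw_hi)
            p["d1"] = ParamSpec(2.0, True, 0.0, d_hi)
            p["mean2"] = ParamSpec(np.clip(1.3 * probes.r0, lo, hi), True, lo, hi)
            p["fwhm2"] = ParamSpec(0.5 * probes.r0, True, fw_lo, fw_hi)
            p["d2"] = ParamSpec(10.0, True, 0.0, d_hi)
            for k in range(n_datasets):
                p[f"frx_{k}"] = ParamSpec(0.5, True, 0.0, 1.0)
        p["tau_d"] = ParamSpec(
            probes.tau_d0 if fix_lifetimes else None, not fix_lifetimes, 0.05, 500.0
        )
        p["tau_a"] = ParamSpec(
            probes.tau_a0 if fix_lifetimes else None, not fix_lifetimes, 0.05, 500.0
        )
        p["background"] = ParamSpec(0.0, False, 0.0, np.inf)
        return cls(
            dimension=dimension,
            grid=grid,
            r0=probes.r0,
            params=p,
            direct_excitation_ratio=probes.direct_excitation_ratio,
            n_restarts=n_restarts,
        )


def estimate_lifetime(curve: DecayCurve) -> float:
    """Mono-exponential lifetime from a weighted log-linear tail fit."""
    c = np.asarray(curve.counts, dtype=float)
    t = np.asarray(curve.times, dtype=float)
    ipk = int(np.argmax(c))
    peak = c[ipk]
    after = np.arange(ipk, len(c))
    below = after[c[after] <= 0.7 * peak]
    start = int(below[0]) if len(below) else ipk + 1
    sel = np.arange(start, len(c))
    sel = sel[c[sel] >= max(10.0, 1e-4 * peak)]
    if len(sel) < 10:
        raise ConvergenceError("too few counts for a lifetime estimate")
    w = c[sel]
    coef = np.polyfit(t[sel], np.log(c[sel]), 1, w=np.sqrt(w))
    slope = coef[0]
    if slope >= 0:
        raise ConvergenceError("non-decaying curve: lifetime estimate failed")
    return float(-1.0 / slope)


def chi_squared(
    model_curves: ModelCurveSet | dict,
    data: list[DecayCurve] | dict,
    n_free: int = 0,
):
    """Global and per-curve chi-square of model curves against data.

    per-curve: sum over channels of (data-model)^2 / max(model, 1), divided
    by the curve's channel count; global: total sum over all curves divided
    by (total channels - n_free).
    """
    if isinstance(data, dict):
        data_map = data
    else:
        data_map = {c.role: c for c in data}
    per_curve = []
    total = 0.0
    n_total = 0
    for role in ROLE_ORDER:
        if role not in data_map:
            continue
        d = np.asarray(data_map[role].counts, dtype=float)
        if isinstance(model_curves, ModelCurveSet):
            m = model_curves.by_role(role)
        else:
            if role not in model_curves:
                raise ContractError(f"model curves missing role {role}")
            m = np.asarray(model_curves[role], dtype=float)
        if m.shape != d.shape:
            raise ContractError(f"{role}: model and data lengths differ")
        s = float(np.sum((d - m) ** 2 / np.maximum(m, 1.0)))
        per_curve.append(s / len(d))
        total += s
        n_total += len(d)
    if n_total == 0:
        raise ContractError("no overlapping curve roles between model and data")
    dof = max(n_total - n_free, 1)
    return total / dof, per_curve


@dataclass(frozen=True)
class ConfidenceInterval:
    """Rigorous-scan confidence interval for one fit parameter."""

    parameter: str
    lower: float
    upper: float
    level: float
    scan_values: np.ndarray
    scan_chi2: np.ndarray
    threshold: float


@dataclass(frozen=True)
class AutocorrelationResult:
    """Normalized residual autocorrelation at lags 0..n/2 (values[0] = 1)."""

    values: np.ndarray
    degenerate: bool = False

    def band_violation_fraction(self) -> float:
        """Fraction of lags >= 1 outside the white-noise band 3/sqrt(n)."""
        n = 2 * (len(self.values) - 1)
        band = 3.0 / np.sqrt(n)
        return float(np.mean(np.abs(self.values[1:]) > band))


def residual_autocorrelation(residuals) -> AutocorrelationResult:
    """Normalized autocorrelation of a residual trace at lags 0..n/2."""
    r = np.asarray(residuals, dtype=float)
    n = len(r)
    if n < 32:
        raise ContractError("need at least 32 channels for autocorrelation")
    r = r - r.mean()
    var = float(np.dot(r, r))
    n_lags = n // 2
    if var <= 1e-300 * n:
        return AutocorrelationResult(np.ones(n_lags + 1), degenerate=True)
    full = np.correlate(r, r, mode="full")[n - 1 : n - 1 + n_lags + 1]
    return AutocorrelationResult(full / var, degenerate=False)


@dataclass
class FitResult:
    """Best-fit parameters and quality-of-fit diagnostics of a global fit."""

    params: dict[str, float]
    derived: dict[str, float]
    scales: list[dict[str, float]]
    chi2_reduced: float
    chi2_total: float
    per_curve_chi2: list[dict[str, float]]
    residuals: list[dict[str, np.ndarray]]
    fitted: list[dict[str, np.ndarray]]
    n_free: int
    n_channels_total: int
    at_bounds: list[str]
    convergence: dict
    seed: int
    dimension: str
    warnings: list[str] = field(default_factory=list)

    def autocorrelations(self) -> list[dict[str, AutocorrelationResult]]:
        return [
            {role: residual_autocorrelation(res) for role, res in ds.items()}
            for ds in self.residuals
        ]


# ----------------------------------------------------------------------
# objective machinery


class _GlobalObjective:
    """Stacked weighted-residual vector over all datasets and curves.

    Caches the excited-state solution per distinct (mean, fwhm, D, tau_d)
    so that jacobian columns touching only local parameters (FRX, tau_a,
    background) do not re-solve the PDE.
    """

    def __init__(self, datasets: list[CurveSet], spec: FitSpec):
        self.spec = spec
        self.datasets = datasets
        self.times = datasets[0].time_grid
        for ds in datasets:
            if ds.time_grid != self.times:
                raise ContractError("all datasets must share one time grid")
        self.irfs = [ds.irf for ds in datasets]
        self.data = [
            {role: np.asarray(ds.curves()[role].counts, float) for role in ROLE_ORDER}
            for ds in datasets
        ]
        self._sol_cache: dict = {}
        self._growin_cache: dict = {}
        self._ab_warm: dict = {}
        self.last_scales: list[dict[str, float]] = []
        self.fwhm_clamped = False

    # -- population curves -------------------------------------------------

    def _population(self, mean, fwhm, d, tau_d):
        key = (round(mean, 10), round(fwhm, 10), round(d, 10), round(tau_d, 10))
        hit = self._sol_cache.get(key)
        if hit is not None:
            return hit
        grid = self.spec.grid
        x0 = self._ab_warm.get((round(mean, 4), round(fwhm, 4)))
        a, b = params_from_moments(mean, fwhm, grid, x0=x0)
        self._ab_warm[(round(mean, 4), round(fwhm, 4))] = (a, np.log(b))
        dist = DistanceDistribution(a=a, b=b, grid=grid)
        pop = SubPopulation(dist, d)
        probes = ProbePair(
            r0=self.spec.r0,
            tau_d0=tau_d,
            tau_a0=1.0,  # placeholder: tau_a enters only in the grow-in step
            direct_excitation_ratio=self.spec.direct_excitation_ratio,
        )
        sol = solve_hse(pop, probes, self.times)
        s_curve = np.clip(sol.project(np.ones(grid.n_points)), 0.0, None)
        phi = (self.spec.r0 / grid.nodes) ** 6 / tau_d
        amp, lam = sol.modal_amplitudes(phi)
        entry = {"S": s_curve, "amp": amp, "lam": lam, "sol": sol, "ab": (a, b)}
        if len(self._sol_cache) > 128:
            self._sol_cache.clear()
        self._sol_cache[key] = entry
        return entry

    def _growin(self, popkey_entry, tau_a):
        key = (id(popkey_entry), round(tau_a, 10))
        hit = self._growin_cache.get(key)
        if hit is not None:
            return hit
        g = growin_from_modes(
            popkey_entry["amp"],
            popkey_entry["lam"],
            self.times,
            tau_a,
            exp_lt=popkey_entry["sol"]._exp_lt,
        )
        if len(self._growin_cache) > 128:
            self._growin_cache.clear()
        self._growin_cache[key] = g
        return g

    # -- model curves -------------------------------------------------------

    def model_shapes(self, p: dict, dataset_index: int) -> dict[str, np.ndarray]:
        """Unit-scale IRF-convolved model shapes for one dataset."""
        t = self.times.times
        tau_d, tau_a = p["tau_d"], p["tau_a"]
        pops = [self._population(p["mean1"], p["fwhm1"], p["d1"], tau_d)]
        if self.spec.n_populations == 2:
            pops.append(self._population(p["mean2"], p["fwhm2"], p["d2"], tau_d))
            frx = p[f"frx_{dataset_index}"]
        else:
            frx = 1.0
        s_mix = frx * pops[0]["S"]
        g_mix = frx * self._growin(pops[0], tau_a)
        if len(pops) == 2:
            s_mix = s_mix + (1.0 - frx) * pops[1]["S"]
            g_mix = g_mix + (1.0 - frx) * self._growin(pops[1], tau_a)
        ao = np.exp(-t / tau_a)
        der = self.spec.direct_excitation_ratio
        shapes = {
            "DO": np.exp(-t / tau_d),
            "AO": ao,
            "DA": s_mix,
            "DAA": g_mix + der * ao,
        }
        irf = self.irfs[dataset_index]
        from .forward import convolve_irf

        return {role: convolve_irf(curve, irf) for role, curve in shapes.items()}

    @staticmethod
    def _project_scale(data: np.ndarray, shape: np.ndarray, bg: float) -> float:
        """Pearson-optimal scale: c* = sqrt(sum(d^2/s) / sum(s))."""
        mask = shape > shape.max() * 1e-12 if shape.max() > 0 else np.zeros_like(shape, bool)
        if not np.any(mask):
            return 0.0
        d = np.clip(data[mask] - bg, 0.0, None)
        s = shape[mask]
        num = float(np.sum(d * d / s))
        den = float(np.sum(s))
        if num <= 0 or den <= 0:
            return 0.0
        return float(np.sqrt(num / den))

    def predicted(self, p: dict) -> list[dict[str, np.ndarray]]:
        """Scaled model curves for every dataset; records the scales used."""
        out = []
        self.last_scales = []
        for i in range(len(self.datasets)):
            shapes = self.model_shapes(p, i)
            bg = p.get("background", 0.0)
            scales = {}
            fitted = {}
            for role in ROLE_ORDER:
                c = self._project_scale(self.data[i][role], shapes[role], bg)
                scales[role] = c
                fitted[role] = c * shapes[role] + bg
            self.last_scales.append(scales)
            out.append(fitted)
        return out

    def residual_vector(self, p: dict) -> np.ndarray:
        fitted = self.predicted(p)
        chunks = []
        for i in range(len(self.datasets)):
            for role in ROLE_ORDER:
                m = fitted[i][role]
                d = self.data[i][role]
                chunks.append((m - d) / np.sqrt(np.maximum(m, 1.0)))
        return np.concatenate(chunks)

    # -- lmfit adapter ------------------------------------------------------

    _PENALTY = 1e4

    def lmfit_residual(self, params: lmfit.Parameters) -> np.ndarray:
        p = _natural_params(params)
        try:
            return self.residual_vector(p)
        except ConvergenceError:
            # unreachable (mean, fwhm) corner of the parameter space: return
            # a large flat residual so the trust region retreats
            n = sum(len(self.data[i][r]) for i in range(len(self.datasets)) for r in ROLE_ORDER)
            return np.full(n, self._PENALTY)

    @property
    def n_channels_total(self) -> int:
        return sum(
            len(self.data[i][r])
            for i in range(len(self.datasets))
            for r in ROLE_ORDER
        )


def _natural_params(params: lmfit.Parameters) -> dict[str, float]:
    p = {}
    for name, par in params.items():
        if name.startswith("sqrt_d"):
            p["d" + name[6:]] = par.value**2
        else:
            p[name] = par.value
    return p


def _build_lmfit_params(spec: FitSpec) -> lmfit.Parameters:
    params = lmfit.Parameters()
    for name, ps in spec.params.items():
        if ps.value is None:
            raise ContractError(f"parameter {name} has no initial value")
        if name in ("d1", "d2"):
            params.add(
                "sqrt_" + name,
                value=float(np.sqrt(ps.value)),
                vary=ps.vary,
                min=0.0 if not np.isfinite(ps.min) else float(np.sqrt(max(ps.min, 0.0))),
                max=float(np.sqrt(ps.max)) if np.isfinite(ps.max) else np.inf,
            )
        else:
            params.add(name, value=float(ps.value), vary=ps.vary, min=ps.min, max=ps.max)
    return params


def _perturbed(params: lmfit.Parameters, rng: np.random.Generator, scale: float):
    new = copy.deepcopy(params)
    for name, par in new.items():
        if not par.vary:
            continue
        u = rng.uniform(-1.0, 1.0)
        if abs(par.value) > 1e-12:
            val = par.value * (1.0 + scale * u)
        else:
            span = par.max - par.min if np.isfinite(par.max - par.min) else 1.0
            val = par.value + scale * span * abs(u)
        lo = par.min + 1e-9 * (abs(par.min) + 1.0) if np.isfinite(par.min) else -np.inf
        hi = par.max - 1e-9 * (abs(par.max) + 1.0) if np.isfinite(par.max) else np.inf
        par.value = float(np.clip(val, lo, hi))
    return new


def _resolve_lifetime_initials(spec: FitSpec, datasets: list[CurveSet]) -> FitSpec:
    spec = copy.deepcopy(spec)
    if spec.params["tau_d"].value is None:
        spec.params["tau_d"].value = estimate_lifetime(datasets[0].do)
    if spec.params["tau_a"].value is None:
        spec.params["tau_a"].value = estimate_lifetime(datasets[0].ao)
    return spec


def _canonicalize(p: dict, spec: FitSpec, n_datasets: int) -> dict:
    """Order sub-populations by ascending mean; FRX -> 1-FRX on swap."""
    if spec.n_populations == 2 and p["mean1"] > p["mean2"]:
        p = dict(p)
        for base in ("mean", "fwhm", "d"):
            p[f"{base}1"], p[f"{base}2"] = p[f"{base}2"], p[f"{base}1"]
        for k in range(n_datasets):
            p[f"frx_{k}"] = 1.0 - p[f"frx_{k}"]
    return p


def fit_global(
    datasets: CurveSet | list[CurveSet], spec: FitSpec, seed: int = 0
) -> FitResult:
    """Minimize the global chi-square over all free parameters.

    Multi-start: the supplied initials plus ``spec.n_restarts - 1`` seeded
    perturbations are each run through bounded trust-region least squares;
    the best minimum is returned.  Deterministic for fixed inputs and seed.
    """
    if isinstance(datasets, CurveSet):
        datasets = [datasets]
    if not datasets:
        raise ContractError("need at least one dataset")
    spec = _resolve_lifetime_initials(spec, datasets)
    if spec.dimension == "two_population":
        if len(spec.frx_names) != len(datasets):
            raise ContractError(
                f"spec has {len(spec.frx_names)} frx parameters for "
                f"{len(datasets)} datasets"
            )
    obj = _GlobalObjective(datasets, spec)
    base = _build_lmfit_params(spec)
    rng = np.random.default_rng(seed)
    starts = [base] + [
        _perturbed(base, rng, spec.restart_scale) for _ in range(spec.n_restarts - 1)
    ]

    best = None
    start_costs = []
    total_nfev = 0
    errors = []
    for start in starts:
        try:
            res = lmfit.minimize(
                obj.lmfit_residual,
                start,
                method="least_squares",
                max_nfev=4000,
            )
        except Exception as exc:  # noqa: BLE001 - collected and re-raised
            errors.append(repr(exc))
            start_costs.append(np.inf)
            continue
        cost = float(np.sum(res.residual**2))
        start_costs.append(cost)
        total_nfev += res.nfev
        if best is None or cost < best[0]:
            best = (cost, res)
    if best is None:
        raise ConvergenceError(
            "no restart converged", details={"errors": errors}
        )

    cost, res = best
    p = _canonicalize(_natural_params(res.params), spec, len(datasets))

    # recompute curves/scales at the canonical optimum
    fitted = obj.predicted(p)
    scales = obj.last_scales
    residuals = []
    per_curve = []
    total_chi2 = 0.0
    for i in range(len(datasets)):
        res_i = {}
        chi_i = {}
        for role in ROLE_ORDER:
            d = obj.data[i][role]
            m = fitted[i][role]
            r = (d - m) / np.sqrt(np.maximum(m, 1.0))
            res_i[role] = r
            chi_i[role] = float(np.dot(r, r)) / len(d)
            total_chi2 += float(np.dot(r, r))
        residuals.append(res_i)
        per_curve.append(chi_i)

    n_vary = sum(1 for par in res.params.values() if par.vary)
    n_free = n_vary + 4 * len(datasets)  # projected scales count as free
    n_total = obj.n_channels_total
    chi2_reduced = total_chi2 / max(n_total - n_free, 1)

    at_bounds = []
    for name, par in res.params.items():
        if not par.vary:
            continue
        natural = "d" + name[6:] if name.startswith("sqrt_d") else name
        span = (par.max - par.min) if np.isfinite(par.max - par.min) else 1.0
        if np.isfinite(par.min) and abs(par.value - par.min) < 1e-6 * span:
            at_bounds.append(natural)
        elif np.isfinite(par.max) and abs(par.value - par.max) < 1e-6 * span:
            at_bounds.append(natural)

    derived = {}
    try:
        a1, b1 = params_from_moments(p["mean1"], p["fwhm1"], spec.grid)
        derived.update({"a1": a1, "b1": b1})
        if spec.n_populations == 2:
            a2, b2 = params_from_moments(p["mean2"], p["fwhm2"], spec.grid)
            derived.update({"a2": a2, "b2": b2})
    except ConvergenceError:
        pass

    fit_warnings = []
    if spec.n_populations == 2:
        for k in range(len(datasets)):
            frx = p[f"frx_{k}"]
            minority = min(frx, 1.0 - frx)
            if minority < 0.02:
                which = "pop2" if frx > 0.5 else "pop1"
                fit_warnings.append(
                    f"dataset {k}: mole fraction {frx:.4f} leaves {which} "
                    "essentially absent; its parameters are unidentifiable"
                )

    return FitResult(
        params=p,
        derived=derived,
        scales=scales,
        chi2_reduced=chi2_reduced,
        chi2_total=total_chi2,
        per_curve_chi2=per_curve,
        residuals=residuals,
        fitted=fitted,
        n_free=n_free,
        n_channels_total=n_total,
        at_bounds=at_bounds,
        convergence={
            "n_restarts": len(starts),
            "start_costs": start_costs,
            "total_nfev": total_nfev,
            "errors": errors,
        },
        seed=seed,
        dimension=spec.dimension,
        warnings=fit_warnings,
    )


# ----------------------------------------------------------------------
# rigorous error analysis


def _natural_name(name: str) -> str:
    name = name.lower()
    return name


def rigorous_interval(
    datasets: CurveSet | list[CurveSet],
    spec: FitSpec,
    fit: FitResult,
    parameter: str,
    level: float | None = None,
    scan_values=None,
    seed: int = 0,
) -> ConfidenceInterval:
    """Confidence interval by the rigorous-scan (exhaustive search) method.

    The parameter is fixed at each scan value and all other free parameters
    are re-minimized (warm-started from the best fit); the interval contains
    the values whose minimized global chi-square stays below

        chi2_best * (1 + p/(n-p) * F(p, n-p; level)).

    Interval edges are interpolated linearly in chi-square between scan
    points; an edge that never crosses the threshold inside the scan is
    clamped to the scan boundary.
    """
    if isinstance(datasets, CurveSet):
        datasets = [datasets]
    parameter = _natural_name(parameter)
    if parameter not in fit.params:
        raise ContractError(f"unknown parameter {parameter!r}")
    if level is None:
        level = 0.66 if parameter in ("d1", "d2") else 0.95
    v0 = fit.params[parameter]

    if scan_values is None:
        ps = spec.params[parameter]
        lo = ps.min if np.isfinite(ps.min) else v0 - max(abs(v0), 1.0)
        hi = ps.max if np.isfinite(ps.max) else v0 + max(abs(v0), 1.0)
        half = 0.25 * (hi - lo)
        scan_values = np.linspace(max(lo, v0 - half), min(hi, v0 + half), 9)
    scan_values = np.sort(np.asarray(scan_values, dtype=float))
    if not (scan_values[0] <= v0 <= scan_values[-1]):
        raise ContractError(
            f"scan grid [{scan_values[0]}, {scan_values[-1]}] does not "
            f"bracket the best-fit value {v0}"
        )

    n = fit.n_channels_total
    p_free = fit.n_free
    f_crit = stats.f.ppf(level, p_free, n - p_free)
    threshold = fit.chi2_total * (1.0 + p_free / (n - p_free) * f_crit)

    warm = copy.deepcopy(spec)
    for name, val in fit.params.items():
        if name in warm.params and warm.params[name].value is not None:
            ps = warm.params[name]
            ps.value = float(np.clip(val, ps.min, ps.max))
        elif name in warm.params:
            warm.params[name].value = float(val)
    warm.n_restarts = 2
    warm.restart_scale = 0.1

    chi2_scan = np.empty(len(scan_values))
    for j, v in enumerate(scan_values):
        s = copy.deepcopy(warm)
        s.params[parameter].value = float(np.clip(v, s.params[parameter].min, s.params[parameter].max))
        s.params[parameter].vary = False
        try:
            r = fit_global(datasets, s, seed=seed + 1000 + j)
            chi2_scan[j] = r.chi2_total
        except ConvergenceError:
            chi2_scan[j] = np.inf

    inside = chi2_scan <= threshold
    j0 = int(np.argmin(np.abs(scan_values - v0)))
    if not inside[j0]:
        # numerical jitter can lift the best point marginally above; anchor it
        inside[j0] = True

    lo_edge = scan_values[0]
    for j in range(j0, 0, -1):
        if not inside[j - 1]:
            x0, x1 = scan_values[j - 1], scan_values[j]
            y0, y1 = chi2_scan[j - 1], chi2_scan[j]
            lo_edge = x1 if not np.isfinite(y0) else x0 + (x1 - x0) * (
                (y0 - threshold) / (y0 - y1)
            )
            break
    hi_edge = scan_values[-1]
    for j in range(j0, len(scan_values) - 1):
        if not inside[j + 1]:
            x0, x1 = scan_values[j], scan_values[j + 1]
            y0, y1 = chi2_scan[j], chi2_scan[j + 1]
            hi_edge = x0 if not np.isfinite(y1) else x0 + (x1 - x0) * (
                (threshold - y0) / (y1 - y0)
            )
            break

    lo_edge = min(lo_edge, v0)
    hi_edge = max(hi_edge, v0)
    return ConfidenceInterval(
        parameter=parameter,
        lower=float(lo_edge),
        upper=float(hi_edge),
        level=level,
        scan_values=scan_values,
        scan_chi2=chi2_scan,
        threshold=threshold,
    )


@dataclass(frozen=True)
class ModelComparison:
    """One- vs two-population model comparison record."""

    fit_one: FitResult
    fit_two: FitResult
    f_statistic: float
    p_value: float
    delta_chi2: float
    band_violation_one: float
    band_violation_two: float
    degenerate: bool = False


def model_dimension_test(
    datasets: CurveSet | list[CurveSet],
    spec_one: FitSpec,
    spec_two: FitSpec,
    seed: int = 0,
) -> ModelComparison:
    """F-test on the chi-square improvement of the two-population model.

    Also reports the residual-autocorrelation white-noise-band violation
    fraction of both fits.  Identical specs are flagged degenerate.
    """
    fit1 = fit_global(datasets, spec_one, seed=seed)
    fit2 = fit_global(datasets, spec_two, seed=seed)

    def _violation(fit: FitResult) -> float:
        fracs = [
            ac.band_violation_fraction()
            for ds in fit.autocorrelations()
            for ac in ds.values()
        ]
        return float(np.mean(fracs))

    dp = fit2.n_free - fit1.n_free
    n = fit2.n_channels_total
    degenerate = dp == 0
    if degenerate:
        f_stat, p_value = 0.0, 1.0
    else:
        denom = fit2.chi2_total / (n - fit2.n_free)
        f_stat = max((fit1.chi2_total - fit2.chi2_total) / dp, 0.0) / denom
        p_value = float(stats.f.sf(f_stat, dp, n - fit2.n_free))
    return ModelComparison(
        fit_one=fit1,
        fit_two=fit2,
        f_statistic=float(f_stat),
        p_value=p_value,
        delta_chi2=float(fit1.chi2_total - fit2.chi2_total),
        band_violation_one=_violation(fit1),
        band_violation_two=_violation(fit2),
        degenerate=degenerate,
    )
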