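"""Synthetic TCSPC experiment generator.

Emulates the simulated trFRET experiments used to establish the resolution
limits of two-sub-population analysis: four decay curves (DO, AO, DA, DAA)
of 10,000 counts at the peak, 3000 channels of 0.0122 ns/channel, convolved
with a 50 ps (FWHM) Gaussian instrument response, with photon-counting noise
(Gaussian with variance equal to the expected counts, or Poisson) added per
channel.  Each curve is scaled to the target peak separately, as decay
curves accumulated to a fixed peak count are.

The canonical benchmark mixes a "rigid" sub-population typical of a stably
folded structure (mean 19.3 A, FWHM 8.0 A, D = 0 A^2/ns — frozen dynamics)
with a "flexible" one typical of a disordered chain (mean 39 A, FWHM 39 A,
D = 20 A^2/ns), probed with R0 = 32 A, tau_d0 = 10 ns, tau_a0 = 4 ns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ContractError, RangeError
from .forward import IRFCurve, model_curveset
from .hse import TimeGrid
from .model import (
    DistanceDistribution,
    MixtureModel,
    ProbePair,
    RadialGrid,
    SubPopulation,
)

__all__ = [
    "ROLES",
    "AcquisitionSettings",
    "DecayCurve",
    "CurveSet",
    "make_gaussian_irf",
    "simulate_curveset",
    "BENCHMARK_PROBES",
    "benchmark_populations",
    "benchmark_mixture",
    "make_benchmark_dataset",
]

ROLES = ("DO", "AO", "DA", "DAA", "IRF")

NOISE_MODELS = ("gaussian_counting", "poisson", "none")


@dataclass(frozen=True)
class AcquisitionSettings:
    """TCSPC acquisition parameters for the simulator."""

    n_channels: int = 3000
    dt: float = 0.0122          # ns per channel
    peak_counts: float = 10000.0
    irf_fwhm_ps: float = 50.0
    irf_center_channel: int = 30
    noise_model: str = "gaussian_counting"
    background_counts: float = 0.0

    def __post_init__(self):
        if self.n_channels < 1:
            raise RangeError("n_channels must be >= 1")
        if self.dt <= 0:
            raise RangeError("dt must be positive")
        if self.peak_counts <= 0:
            raise RangeError("peak_counts must be positive")
        if self.background_counts < 0:
            raise RangeError("background_counts must be >= 0")
        if self.noise_model not in NOISE_MODELS:
            raise RangeError(
                f"noise_model must be one of {NOISE_MODELS}, got {self.noise_model!r}"
            )

    @property
    def time_grid(self) -> TimeGrid:
        return TimeGrid(dt=self.dt, n_steps=self.n_channels)


@dataclass(frozen=True)
class DecayCurve:
    """A channelized photon-count histogram with a role tag."""

    times: np.ndarray
    counts: np.ndarray
    role: str
    acquisition: AcquisitionSettings
    mixture_label: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise ContractError(f"role must be one of {ROLES}, got {self.role!r}")
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.counts, dtype=float)
        if t.shape != c.shape:
            raise ContractError("times and counts have different lengths")
        if len(c) != self.acquisition.n_channels:
            raise ContractError("counts length does not match n_channels")
        if np.any(c < 0):
            raise RangeError("counts must be non-negative")
        t.setflags(write=False)
        c.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "counts", c)

    @property
    def time_grid(self) -> TimeGrid:
        return self.acquisition.time_grid


@dataclass(frozen=True)
class CurveSet:
    """One simulated (or measured) experiment set: the four decay curves plus
    the instrument response, on a shared time grid."""

    do: DecayCurve
    ao: DecayCurve
    da: DecayCurve
    daa: DecayCurve
    irf: IRFCurve
    mixture_label: str = ""

    def curves(self) -> dict[str, DecayCurve]:
        return {"DO": self.do, "AO": self.ao, "DA": self.da, "DAA": self.daa}

    @property
    def time_grid(self) -> TimeGrid:
        return self.do.time_grid


def make_gaussian_irf(
    settings: AcquisitionSettings, center_channel: int | None = None
) -> IRFCurve:
    """Unit-area Gaussian IRF of the configured FWHM on the channel grid.

    An FWHM below half a channel degenerates to a single-channel impulse
    (with a warning).
    """
    if center_channel is None:
        center_channel = settings.irf_center_channel
    if not (0 <= center_channel < settings.n_channels):
        raise RangeError("center_channel outside the channel range")
    times = settings.time_grid
    fwhm_ns = settings.irf_fwhm_ps * 1e-3
    if fwhm_ns <= 0:
        raise RangeError("irf_fwhm_ps must be positive")
    if fwhm_ns < settings.dt / 2:
        warnings.warn(
            "IRF FWHM below half a channel: using a single-channel impulse",
            stacklevel=2,
        )
        resp = np.zeros(settings.n_channels)
        resp[center_channel] = 1.0
        return IRFCurve(times=times, response=resp)
    sigma = fwhm_ns / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    t = times.times
    t0 = center_channel * settings.dt
    resp = np.exp(-0.5 * ((t - t0) / sigma) ** 2)
    return IRFCurve(times=times, response=resp / resp.sum())


def _apply_noise(expected: np.ndarray, model: str, rng: np.random.Generator):
    if model == "none":
        return expected
    if model == "poisson":
        return rng.poisson(expected).astype(float)
    noisy = expected + rng.normal(size=len(expected)) * np.sqrt(expected)
    return np.clip(noisy, 0.0, None)


def simulate_curveset(
    model: MixtureModel,
    settings: AcquisitionSettings,
    seed: int,
    mixture_label: str = "",
) -> CurveSet:
    """Simulate one four-curve experiment set.

    Each ideal curve is convolved with the IRF, scaled so its maximum equals
    ``peak_counts``, the constant background is added and counting noise is
    applied.  Deterministic for a given seed (noise is drawn in the fixed
    order DO, AO, DA, DAA).
    """
    rng = np.random.default_rng(seed)
    times = settings.time_grid
    irf = make_gaussian_irf(settings)
    ideal = model_curveset(model, times, irf=irf)

    curves = {}
    for role in ("DO", "AO", "DA", "DAA"):
        shape = ideal.by_role(role)
        peak = shape.max()
        if peak <= 0:
            expected = np.full(settings.n_channels, settings.background_counts)
        else:
            expected = (
                shape * (settings.peak_counts / peak) + settings.background_counts
            )
        counts = _apply_noise(expected, settings.noise_model, rng)
        curves[role] = DecayCurve(
            times=times.times,
            counts=counts,
            role=role,
            acquisition=settings,
            mixture_label=mixture_label,
        )
    return CurveSet(
        do=curves["DO"],
        ao=curves["AO"],
        da=curves["DA"],
        daa=curves["DAA"],
        irf=irf,
        mixture_label=mixture_label,
    )


# Canonical benchmark conditions: probe constants and the rigid/flexible
# sub-population pair used throughout the simulation studies.
BENCHMARK_PROBES = ProbePair(r0=32.0, tau_d0=10.0, tau_a0=4.0)
BENCHMARK_RIGID = {"mean": 19.3, "fwhm": 8.0, "d_coef": 0.0}
BENCHMARK_FLEXIBLE = {"mean": 39.0, "fwhm": 39.0, "d_coef": 20.0}
__all__ += ["BENCHMARK_RIGID", "BENCHMARK_FLEXIBLE"]


def benchmark_grid(n_points: int = 200) -> RadialGrid:
    """Radial grid for the benchmark: r_min = 0.1*R0; r_max raised above the
    2*R0 default to hold the broad flexible distribution."""
    return RadialGrid.for_forster_radius(
        BENCHMARK_PROBES.r0, r_max=80.0, n_points=n_points
    )


__all__.append("benchmark_grid")


def benchmark_populations(n_points: int = 200):
    """The canonical (rigid, flexible) sub-population pair."""
    grid = benchmark_grid(n_points)
    rigid = SubPopulation(
        DistanceDistribution.from_moments(
            BENCHMARK_RIGID["mean"], BENCHMARK_RIGID["fwhm"], grid
        ),
        BENCHMARK_RIGID["d_coef"],
    )
    flexible = SubPopulation(
        DistanceDistribution.from_moments(
            BENCHMARK_FLEXIBLE["mean"], BENCHMARK_FLEXIBLE["fwhm"], grid
        ),
        BENCHMARK_FLEXIBLE["d_coef"],
    )
    return rigid, flexible


def benchmark_mixture(frx: float, n_points: int = 200) -> MixtureModel:
    """Benchmark mixture at rigid mole fraction ``frx``."""
    rigid, flexible = benchmark_populations(n_points)
    return MixtureModel(pop1=rigid, pop2=flexible, frx=frx, probes=BENCHMARK_PROBES)


def make_benchmark_dataset(
    frx_list,
    seed: int,
    settings: AcquisitionSettings | None = None,
    n_points: int = 200,
) -> list[CurveSet]:
    """One simulated four-curve set per requested rigid mole fraction.

    Per-set seeds are derived from ``seed`` through a SeedSequence so the
    sets are independent but jointly reproducible.
    """
    frx_list = list(frx_list)
    if not frx_list:
        raise ContractError("frx_list must be non-empty")
    if settings is None:
        settings = AcquisitionSettings()
    rigid, flexible = benchmark_populations(n_points)
    child_seeds = np.random.SeedSequence(seed).generate_state(len(frx_list)) % (
        2**31
    )
    out = []
    for frx, s in zip(frx_list, child_seeds):
        model = MixtureModel(
            pop1=rigid, pop2=flexible, frx=float(frx), probes=BENCHMARK_PROBES
        )
        out.append(
            simulate_curveset(
                model, settings, int(s), mixture_label=f"frx={frx:g}"
            )
        )
    return out
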