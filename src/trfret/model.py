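"""Domain types and the skewed-Gaussian distance-distribution algebra.

The end-to-end (inter-probe) distance of a labeled chain is modeled by the
radial density

    N0(r) = 4 pi r^2 exp(-b (r - a)^2) / Z,      r in [r_min, r_max]

with location parameter ``a`` (Angstrom) and width parameter ``b``
(Angstrom^-2).  The r^2 prefactor skews the Gaussian, which accommodates the
non-Gaussian end-to-end statistics of short chain segments.  All quadrature
(normalization, moments, and the survival/sink integrals downstream) uses the
composite trapezoid rule on one shared radial grid so that the forward model
and the reported moments see the same discretization.

Distributions are reported to users as (mean, FWHM) pairs; the inverse map
:func:`params_from_moments` recovers ``(a, b)`` by a two-dimensional root
find, so fits and confidence scans can act directly on the moments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .exceptions import ConvergenceError, RangeError

__all__ = [
    "RadialGrid",
    "DistanceDistribution",
    "SubPopulation",
    "ProbePair",
    "MixtureModel",
    "Moments",
    "evaluate_density",
    "moments",
    "params_from_moments",
]

_MIN_GRID_POINTS = 50


@dataclass(frozen=True)
class RadialGrid:
    """Uniform grid of inter-probe distances on [r_min, r_max] (Angstrom).

    r_min is the distance of closest approach of the two probes (typically
    2 Angstrom, or at least 0.1*R0, below which transfer is saturated anyway);
    r_max should exceed ~2*R0 so that the weakly-transferring tail of the
    distribution is represented.
    """

    r_min: float
    r_max: float
    n_points: int = 200
    nodes: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if not (self.r_min > 0):
            raise RangeError(f"r_min must be positive, got {self.r_min}")
        if not (self.r_max > self.r_min):
            raise RangeError(
                f"r_max ({self.r_max}) must exceed r_min ({self.r_min})"
            )
        if self.n_points < _MIN_GRID_POINTS:
            raise RangeError(
                f"n_points must be >= {_MIN_GRID_POINTS} for quadrature "
                f"sanity, got {self.n_points}"
            )
        nodes = np.linspace(self.r_min, self.r_max, self.n_points)
        nodes.setflags(write=False)
        object.__setattr__(self, "nodes", nodes)

    @classmethod
    def for_forster_radius(
        cls, r0: float, r_max: float | None = None, n_points: int = 200
    ) -> "RadialGrid":
        """Default grid for a probe pair with Forster radius ``r0``.

        r_min = max(2 A, 0.1*r0); r_max defaults to 2*r0 (override it when
        the expected distribution extends further).
        """
        r_min = max(2.0, 0.1 * r0)
        if r_max is None:
            r_max = 2.0 * r0
        return cls(r_min=r_min, r_max=r_max, n_points=n_points)

    @property
    def dr(self) -> float:
        return (self.r_max - self.r_min) / (self.n_points - 1)

    @property
    def trapezoid_weights(self) -> np.ndarray:
        w = np.full(self.n_points, self.dr)
        w[0] *= 0.5
        w[-1] *= 0.5
        return w

    def __eq__(self, other):
        if not isinstance(other, RadialGrid):
            return NotImplemented
        return (
            self.r_min == other.r_min
            and self.r_max == other.r_max
            and self.n_points == other.n_points
        )

    def __hash__(self):
        return hash((self.r_min, self.r_max, self.n_points))


class Moments(tuple):
    """(mean, fwhm) pair with a ``clamped`` flag.

    ``clamped`` is True when one of the half-maximum crossings fell outside
    [r_min, r_max] and was clamped to the boundary, i.e. the reported FWHM is
    a lower bound.
    """

    def __new__(cls, mean: float, fwhm: float, clamped: bool = False):
        self = super().__new__(cls, (mean, fwhm))
        self.clamped = clamped
        return self

    @property
    def mean(self) -> float:
        return self[0]

    @property
    def fwhm(self) -> float:
        return self[1]

    def __repr__(self):
        return (
            f"Moments(mean={self[0]:.6g}, fwhm={self[1]:.6g},"
            f" clamped={self.clamped})"
        )


@dataclass(frozen=True)
class DistanceDistribution:
    """Normalized skewed-Gaussian radial density on a :class:`RadialGrid`.

    ``norm`` is the trapezoid integral of the unnormalized density over the
    grid; after construction the density integrates to 1 on the grid by the
    same rule.
    """

    a: float
    b: float
    grid: RadialGrid
    norm: float = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if not (self.b > 0):
            raise RangeError(f"width parameter b must be positive, got {self.b}")
        z = float(np.dot(self.grid.trapezoid_weights, self._unnormalized(self.grid.nodes)))
        if not (z > 0 and np.isfinite(z)):
            raise RangeError(
                f"density with a={self.a}, b={self.b} has no mass on the grid"
            )
        object.__setattr__(self, "norm", z)

    def _log_unnormalized(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=float)
        return np.log(4.0 * np.pi * r * r) - self.b * (r - self.a) ** 2

    def _unnormalized(self, r: np.ndarray) -> np.ndarray:
        # guard the exponent so steep tails underflow to 0 instead of raising
        expo = -self.b * (np.asarray(r, dtype=float) - self.a) ** 2
        return 4.0 * np.pi * np.asarray(r) ** 2 * np.exp(np.maximum(expo, -745.0))

    def density(self, r) -> np.ndarray:
        """Normalized density at distances ``r`` (must lie on [r_min, r_max])."""
        r = np.asarray(r, dtype=float)
        if np.any(r < self.grid.r_min) or np.any(r > self.grid.r_max):
            raise RangeError(
                f"distance outside [{self.grid.r_min}, {self.grid.r_max}]"
            )
        return self._unnormalized(r) / self.norm

    @property
    def on_grid(self) -> np.ndarray:
        """Density evaluated at the grid nodes."""
        return self._unnormalized(self.grid.nodes) / self.norm

    @property
    def peak_location(self) -> float:
        """Mode of the (untruncated) skewed Gaussian, clamped to the grid.

        d/dr ln[r^2 exp(-b(r-a)^2)] = 0 gives r = (a + sqrt(a^2 + 4/b))/2.
        """
        r_pk = 0.5 * (self.a + np.sqrt(self.a * self.a + 4.0 / self.b))
        return float(np.clip(r_pk, self.grid.r_min, self.grid.r_max))

    def moments(self) -> Moments:
        return moments(self)

    @classmethod
    def from_moments(
        cls, mean: float, fwhm: float, grid: RadialGrid
    ) -> "DistanceDistribution":
        a, b = params_from_moments(mean, fwhm, grid)
        return cls(a=a, b=b, grid=grid)


def evaluate_density(dist: DistanceDistribution, r) -> np.ndarray:
    """Normalized skewed-Gaussian density at distances ``r`` (Angstrom^-1)."""
    return dist.density(r)


def moments(dist: DistanceDistribution) -> Moments:
    """Mean and FWHM of the radial density on its grid.

    The mean is the trapezoid integral of r*N0(r).  The FWHM is the distance
    between the two half-maximum crossings of the continuous density, located
    by bisection; a crossing that does not occur inside [r_min, r_max] is
    clamped to the boundary and flagged.
    """
    w = dist.grid.trapezoid_weights
    dens = dist.on_grid
    mean = float(np.dot(w, dist.grid.nodes * dens))

    r_pk = dist.peak_location
    f_pk = float(dist._unnormalized(np.array([r_pk]))[0])
    half = 0.5 * f_pk

    def g(r):
        return float(dist._unnormalized(np.array([r]))[0]) - half

    clamped = False
    r_lo, r_hi = dist.grid.r_min, dist.grid.r_max
    if g(r_lo) >= 0.0:
        left = r_lo
        clamped = True
    else:
        left = optimize.brentq(g, r_lo, r_pk, xtol=1e-12, rtol=1e-14)
    if g(r_hi) >= 0.0:
        right = r_hi
        clamped = True
    else:
        right = optimize.brentq(g, r_pk, r_hi, xtol=1e-12, rtol=1e-14)
    return Moments(mean, right - left, clamped)


def params_from_moments(
    mean: float,
    fwhm: float,
    grid: RadialGrid,
    x0: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Invert (mean, FWHM) to the (a, b) parameters on the given grid.

    Two-dimensional root find (Powell hybrid) in (a, log b); the returned
    parameters round-trip through :func:`moments` to better than 1e-3
    relative.  Raises :class:`ConvergenceError` naming the offending moment
    when no skewed Gaussian on the grid achieves the request (e.g. FWHM too
    large for the interval).  ``x0`` optionally warm-starts the root find
    with a previous (a, log b) solution.
    """
    if not (grid.r_min < mean < grid.r_max):
        raise RangeError(
            f"requested mean {mean} outside grid ({grid.r_min}, {grid.r_max})"
        )
    if not (fwhm > 0):
        raise RangeError(f"requested fwhm must be positive, got {fwhm}")

    b0 = 4.0 * np.log(2.0) / fwhm**2
    a0 = mean - 1.0 / (b0 * mean)  # r^2 skew shifts the mean above a

    def residual(x):
        a, logb = x
        try:
            m = moments(DistanceDistribution(a=a, b=float(np.exp(logb)), grid=grid))
        except (RangeError, FloatingPointError):
            return np.array([1e6, 1e6])
        return np.array([(m.mean - mean) / mean, (m.fwhm - fwhm) / fwhm])

    start = list(x0) if x0 is not None else [a0, np.log(b0)]
    sol = optimize.root(residual, x0=start, method="hybr", tol=1e-12)
    if x0 is not None and not np.all(np.abs(residual(sol.x)) < 1e-3):
        sol = optimize.root(residual, x0=[a0, np.log(b0)], method="hybr", tol=1e-12)
    res = residual(sol.x)
    if not np.all(np.abs(res) < 1e-3):
        worst = "mean" if abs(res[0]) >= abs(res[1]) else "fwhm"
        raise ConvergenceError(
            f"no skewed Gaussian on [{grid.r_min}, {grid.r_max}] achieves "
            f"(mean={mean}, fwhm={fwhm}); failed to match the {worst}",
            details={"residuals": res, "x": sol.x},
        )
    a, b = float(sol.x[0]), float(np.exp(sol.x[1]))
    return a, b


@dataclass(frozen=True)
class SubPopulation:
    """A conformer sub-population: a distance distribution plus its
    intramolecular diffusion coefficient D (Angstrom^2/ns)."""

    distribution: DistanceDistribution
    d_coef: float

    def __post_init__(self):
        if self.d_coef < 0:
            raise RangeError(f"diffusion coefficient must be >= 0, got {self.d_coef}")


@dataclass(frozen=True)
class ProbePair:
    """Photophysical constants of the donor/acceptor pair.

    r0 : Forster critical distance (Angstrom); transfer rate is
        (1/tau_d0) * (r0/r)^6.
    tau_d0, tau_a0 : donor / acceptor excited-state lifetimes without FRET (ns).
    direct_excitation_ratio : fraction of acceptors excited directly at the
        donor excitation wavelength (absorbance ratio of the two probes).
    """

    r0: float
    tau_d0: float
    tau_a0: float
    direct_excitation_ratio: float = 0.0

    def __post_init__(self):
        if self.r0 <= 0 or self.tau_d0 <= 0 or self.tau_a0 <= 0:
            raise RangeError("r0, tau_d0 and tau_a0 must all be positive")
        if not (0.0 <= self.direct_excitation_ratio <= 1.0):
            raise RangeError("direct_excitation_ratio must lie in [0, 1]")


@dataclass(frozen=True)
class MixtureModel:
    """Two sub-populations mixed at mole fraction ``frx`` of pop1, with an
    overall proportionality scale ``c`` and shared probe constants."""

    pop1: SubPopulation
    pop2: SubPopulation
    frx: float
    probes: ProbePair
    c: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.frx <= 1.0):
            raise RangeError(f"mole fraction frx must lie in [0, 1], got {self.frx}")
        if not (self.c > 0):
            raise RangeError(f"scale c must be positive, got {self.c}")
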