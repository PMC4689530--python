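"""File formats and configuration.

Decay and IRF curves travel as two-column tab-separated text
(``time_ns<TAB>counts``) with ``#``-prefixed header lines carrying metadata
(``# role=DO``, ``# dt_ns=0.0122``, ``# mixture_label=...``).  Configurations
and fit reports are JSON.  Native instrument formats are out of scope; any
converter producing this TSV plugs in upstream.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .exceptions import ContractError, ParseError, RangeError
from .forward import IRFCurve
from .fitting import (
    ConfidenceInterval,
    FitResult,
    FitSpec,
    ParamSpec,
    residual_autocorrelation,
)
from .model import ProbePair, RadialGrid
from .simulate import ROLES, AcquisitionSettings, CurveSet, DecayCurve

__all__ = [
    "read_decay_tsv",
    "write_decay_tsv",
    "read_curveset",
    "write_curveset",
    "ExperimentConfig",
    "build_fit_spec",
    "write_fit_report",
    "read_fit_report",
]


def write_decay_tsv(curve: DecayCurve, path):
    path = Path(path)
    lines = [
        f"# role={curve.role}",
        f"# dt_ns={curve.acquisition.dt:.10g}",
    ]
    if curve.mixture_label:
        lines.append(f"# mixture_label={curve.mixture_label}")
    for t, c in zip(curve.times, curve.counts):
        lines.append(f"{t:.10g}\t{c:.10g}")
    path.write_text("\n".join(lines) + "\n")


def read_decay_tsv(path) -> DecayCurve:
    """Read a two-column decay TSV into a validated :class:`DecayCurve`.

    Negative counts are clamped to zero with a warning; ragged rows and
    non-monotone times raise :class:`ParseError` with the line number.
    """
    path = Path(path)
    meta = {}
    times, counts = [], []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(
                f"expected 2 tab-separated columns, got {len(parts)}", line=lineno
            )
        try:
            t, c = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ParseError(f"non-numeric value: {exc}", line=lineno) from None
        if times and t <= times[-1]:
            raise ParseError(
                f"time {t} not strictly increasing after {times[-1]}", line=lineno
            )
        times.append(t)
        counts.append(c)
    if len(times) < 2:
        raise ParseError(f"{path}: fewer than 2 data rows")
    times = np.array(times)
    counts = np.array(counts)
    if np.any(counts < 0):
        n_neg = int(np.sum(counts < 0))
        warnings.warn(
            f"{path.name}: clamped {n_neg} negative count(s) to 0", stacklevel=2
        )
        counts = np.clip(counts, 0.0, None)
    dt = float(meta.get("dt_ns", times[1] - times[0]))
    role = meta.get("role", "DO")
    settings = AcquisitionSettings(
        n_channels=len(counts), dt=dt, peak_counts=max(float(counts.max()), 1.0)
    )
    return DecayCurve(
        times=times,
        counts=counts,
        role=role,
        acquisition=settings,
        mixture_label=meta.get("mixture_label", ""),
    )


def _irf_from_curve(curve: DecayCurve) -> IRFCurve:
    return IRFCurve.from_counts(curve.time_grid, curve.counts)


def write_curveset(cs: CurveSet, directory, prefix: str = "curve"):
    """Write the four decay curves and the IRF as TSVs; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for role, curve in cs.curves().items():
        p = directory / f"{prefix}_{role.lower()}.tsv"
        write_decay_tsv(curve, p)
        paths[role] = p
    irf_curve = DecayCurve(
        times=cs.irf.times.times,
        counts=cs.irf.response * 1e6,  # scaled to countlike magnitudes
        role="IRF",
        acquisition=cs.do.acquisition,
        mixture_label=cs.mixture_label,
    )
    p = directory / f"{prefix}_irf.tsv"
    write_decay_tsv(irf_curve, p)
    paths["IRF"] = p
    return paths


def read_curveset(paths: dict, mixture_label: str = "") -> CurveSet:
    """Assemble a :class:`CurveSet` from a role -> path mapping."""
    required = {"DO", "AO", "DA", "DAA", "IRF"}
    missing = required - set(paths)
    if missing:
        raise ContractError(f"curve set missing roles: {sorted(missing)}")
    curves = {}
    for role in required:
        c = read_decay_tsv(paths[role])
        curves[role] = DecayCurve(
            times=c.times,
            counts=c.counts,
            role=role,
            acquisition=c.acquisition,
            mixture_label=c.mixture_label or mixture_label,
        )
    return CurveSet(
        do=curves["DO"],
        ao=curves["AO"],
        da=curves["DA"],
        daa=curves["DAA"],
        irf=_irf_from_curve(curves["IRF"]),
        mixture_label=mixture_label,
    )


# ----------------------------------------------------------------------
# configuration


@dataclass
class ExperimentConfig:
    """Structured configuration for simulation and fitting runs."""

    probes: ProbePair
    grid: RadialGrid
    acquisition: AcquisitionSettings
    dimension: str = "two_population"
    populations: list[dict] = field(default_factory=list)
    frx: list[float] = field(default_factory=list)
    datasets: list[dict] = field(default_factory=list)
    fit_options: dict = field(default_factory=dict)
    output_dir: str = "."
    seed: int = 0
    verbosity: int = 1

    @classmethod
    def from_json(cls, path) -> "ExperimentConfig":
        path = Path(path)
        try:
            raw = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: invalid JSON: {exc}") from None
        try:
            probes = ProbePair(**raw["probes"])
        except (KeyError, TypeError, RangeError) as exc:
            raise ContractError(
                f"invalid 'probes' section (need positive r0, tau_d0, tau_a0 "
                f"and direct_excitation_ratio in [0,1]): {exc}"
            ) from None
        grid_raw = raw.get("grid")
        if grid_raw is None:
            grid = RadialGrid.for_forster_radius(probes.r0)
        else:
            grid = RadialGrid(**grid_raw)
        acq = AcquisitionSettings(**raw.get("acquisition", {}))
        frx = [float(f) for f in raw.get("model", {}).get("frx", [])]
        for f in frx:
            if not (0.0 <= f <= 1.0):
                raise ContractError(f"mole fraction {f} outside [0, 1]")
        cfg = cls(
            probes=probes,
            grid=grid,
            acquisition=acq,
            dimension=raw.get("model", {}).get("dimension", "two_population"),
            populations=raw.get("model", {}).get("populations", []),
            frx=frx,
            datasets=raw.get("datasets", []),
            fit_options=raw.get("fit", {}),
            output_dir=raw.get("output_dir", "."),
            seed=int(raw.get("seed", 0)),
            verbosity=int(raw.get("verbosity", 1)),
        )
        for ds in cfg.datasets:
            for role, p in ds.get("curves", {}).items():
                if role not in ROLES:
                    raise ContractError(f"unknown curve role {role!r}")
                rp = (path.parent / p) if not Path(p).is_absolute() else Path(p)
                if not rp.exists():
                    raise ContractError(f"dataset file does not exist: {rp}")
        return cfg

    def resolve_dataset_paths(self, base: Path) -> list[dict]:
        out = []
        for ds in self.datasets:
            resolved = {
                role: (base / p if not Path(p).is_absolute() else Path(p))
                for role, p in ds["curves"].items()
            }
            out.append({"label": ds.get("label", ""), "curves": resolved})
        return out


def build_fit_spec(config: ExperimentConfig, n_datasets: int) -> FitSpec:
    """FitSpec from a config: defaults, overridden by configured populations
    (used as initial guesses) and fit options."""
    opts = config.fit_options
    spec = FitSpec.default(
        config.dimension,
        config.probes,
        config.grid,
        n_datasets=n_datasets,
        fix_lifetimes=bool(opts.get("fix_lifetimes", False)),
        n_restarts=int(opts.get("n_restarts", 8)),
    )
    for i, popraw in enumerate(config.populations[: 2 if config.dimension == "two_population" else 1]):
        for src, dst in (("mean", f"mean{i+1}"), ("fwhm", f"fwhm{i+1}"), ("d", f"d{i+1}")):
            if src in popraw:
                ps = spec.params[dst]
                ps.value = float(np.clip(popraw[src], ps.min, ps.max))
    for name, ov in opts.get("fixed", {}).items():
        if name not in spec.params:
            raise ContractError(f"unknown fit parameter {name!r} in fit.fixed")
        spec.params[name] = ParamSpec(float(ov), vary=False)
    return spec


# ----------------------------------------------------------------------
# fit reports


def write_fit_report(
    result: FitResult, intervals: list[ConfidenceInterval], out_dir
) -> dict:
    """Emit a JSON parameter report plus residual/autocorrelation and
    fitted-vs-observed TSV tables.  Returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    report = {
        "software": {"name": "trfret", "version": __version__},
        "dimension": result.dimension,
        "seed": result.seed,
        "chi2_reduced": result.chi2_reduced,
        "chi2_total": result.chi2_total,
        "per_curve_chi2": result.per_curve_chi2,
        "n_free": result.n_free,
        "n_channels_total": result.n_channels_total,
        "parameters": result.params,
        "derived": result.derived,
        "scales": result.scales,
        "at_bounds": result.at_bounds,
        "convergence": {
            k: v for k, v in result.convergence.items() if k != "errors"
        },
    }
    if intervals:
        report["intervals"] = [
            {
                "parameter": ci.parameter,
                "lower": ci.lower,
                "upper": ci.upper,
                "level": ci.level,
                "scan_values": list(ci.scan_values),
                "scan_chi2": [
                    (None if not np.isfinite(v) else v) for v in ci.scan_chi2
                ],
                "threshold": ci.threshold,
            }
            for ci in intervals
        ]
    json_path = out_dir / "fit_report.json"
    json_path.write_text(json.dumps(report, indent=2))

    paths = {"json": json_path}
    for i, (res_i, fit_i) in enumerate(zip(result.residuals, result.fitted)):
        rows = ["channel\t" + "\t".join(
            f"{r}_{w}" for r in res_i for w in ("fitted", "observed", "residual")
        )]
        n = len(next(iter(res_i.values())))
        for ch in range(n):
            cells = [str(ch)]
            for role in res_i:
                m = fit_i[role][ch]
                r = res_i[role][ch]
                obs = m + r * np.sqrt(max(m, 1.0))
                cells += [f"{m:.6g}", f"{obs:.6g}", f"{r:.6g}"]
            rows.append("\t".join(cells))
        p = out_dir / f"curves_dataset{i}.tsv"
        p.write_text("\n".join(rows) + "\n")
        paths[f"curves_{i}"] = p

        ac = {
            role: residual_autocorrelation(res_i[role]).values for role in res_i
        }
        n_lags = len(next(iter(ac.values())))
        rows = ["lag\t" + "\t".join(ac.keys())]
        for lag in range(n_lags):
            rows.append(
                "\t".join([str(lag)] + [f"{ac[r][lag]:.6g}" for r in ac])
            )
        p = out_dir / f"autocorrelation_dataset{i}.tsv"
        p.write_text("\n".join(rows) + "\n")
        paths[f"autocorrelation_{i}"] = p
    return paths


def read_fit_report(path) -> dict:
    """Read back a JSON fit report (bitwise parameter round trip)."""
    return json.loads(Path(path).read_text())
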