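"""End-to-end GSA-of-vegetation-indices workflow.

From a run configuration: build the quasi-random design over the model's
input variables, scale it to physical bounds, simulate top-of-canopy
reflectance for every design row (the base matrices P and Q plus the k
radial blocks — exactly N(k+2) model runs), optionally convolve the spectra
to a sensor's band settings, evaluate the requested vegetation indices as
new model outputs, and estimate first-order and total-effect Sobol' indices
per index.  The spectra are simulated once and shared across every index
and across the per-wavelength (spectral) analysis.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gsa import GSAResult, estimate_sobol_indices
from .rtm import (
    WAVELENGTHS_1NM,
    WAVELENGTHS_5NM,
    CanopyParamsINFORM,
    CanopyParamsSAIL,
    LeafParams,
    SpectralCoefficients,
    inform_toc,
    prospect4,
    sail_toc,
    synthetic_coefficients,
    synthetic_soil_spectrum,
    to_5nm_grid,
    toy_canopy,
)
from .sampling import VariableSpec, generate_unit_design, scale_design
from .sensors import Sensor, convolve_to_sensor, get_sensor
from .vi import (
    NativeGridView,
    VIDefinition,
    builtin_registry,
    evaluate_vi,
    get_index,
)

__all__ = [
    "RunConfig",
    "RunResult",
    "SpectrumSet",
    "default_variable_specs",
    "simulate_design",
    "run_vi_gsa",
    "run_spectral_gsa",
    "convergence",
]

MODELS = ("PROSAIL", "PROINFORM", "toy")

# Table-style default bounds: leaf biochemistry/structure, then canopy.
_LEAF_SPECS = [
    VariableSpec("N", 1.0, 2.6, "-"),
    VariableSpec("Cab", 0.0, 80.0, "ug/cm2"),
    VariableSpec("Cw", 0.001, 0.08, "cm"),
    VariableSpec("Cm", 0.001, 0.02, "g/cm2"),
]
_SHARED_CANOPY = [
    VariableSpec("LAD", 0.0, 90.0, "deg"),
    VariableSpec("SZA", 0.0, 60.0, "deg"),
    VariableSpec("soil_coeff", 0.0, 1.0, "-"),
]


def default_variable_specs(model: str) -> list[VariableSpec]:
    """Default sampled variables and bounds for a model.

    PROSAIL has 8 (leaf N, Cab, Cw, Cm plus LAD, SZA, soil coefficient and
    LAI); the forest model has 12 (the same seven plus single-tree LAI,
    understory LAI, stem density, tree height and crown diameter).
    """
    if model == "PROSAIL":
        return _LEAF_SPECS + _SHARED_CANOPY + [
            VariableSpec("LAI", 0.0, 10.0, "m2/m2"),
        ]
    if model == "PROINFORM":
        return _LEAF_SPECS + _SHARED_CANOPY + [
            VariableSpec("LAIs", 0.0, 10.0, "m2/m2"),
            VariableSpec("LAIu", 0.0, 5.0, "m2/m2"),
            VariableSpec("SD", 0.5, 1500.0, "1/ha"),
            VariableSpec("H", 0.5, 30.0, "m"),
            VariableSpec("CD", 0.1, 10.0, "m"),
        ]
    if model == "toy":
        from .rtm.toy import toy_specs

        return toy_specs(3)
    raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")


@dataclass
class SpectrumSet:
    """Simulated reflectance spectra on a fixed wavelength grid."""

    wavelengths: np.ndarray
    values: np.ndarray  # (n_sim, n_wl)
    grid_id: str        # 1nm-2101 | 5nm-421 | sensor-bands


@dataclass
class RunConfig:
    """Configuration of one GSA-VI run.

    vi_list entries may be registry abbreviations or inline expressions
    given as ``name=expression``.  ``sensor=None`` evaluates indices on the
    model's native grid with nominal role wavelengths.
    """

    model: str = "PROSAIL"
    variable_specs: list[VariableSpec] | None = None
    N: int = 2000
    scheme: str = "uniform-sobol"
    seed: int | None = None
    sensor: str | Sensor | None = None
    vi_list: list[str] | None = None
    srf_shape: str = "gaussian"
    output_dir: str | None = None
    coefficients: SpectralCoefficients | None = None
    soil_spectrum: np.ndarray | None = None
    toy_inert: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.variable_specs is None:
            self.variable_specs = default_variable_specs(self.model)
        names = [s.name for s in self.variable_specs]
        if len(set(names)) != len(names):
            raise ValueError("variable names must be unique")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        cfg = yaml.safe_load(open(path)) or {}
        specs = cfg.pop("variable_specs", None)
        if specs is not None:
            specs = [VariableSpec(**s) for s in specs]
        known = {
            "model", "N", "scheme", "seed", "sensor", "vi_list",
            "srf_shape", "output_dir", "toy_inert",
        }
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "toy_inert" in cfg:
            cfg["toy_inert"] = tuple(cfg["toy_inert"])
        return cls(variable_specs=specs, **cfg)

    @property
    def k(self) -> int:
        return len(self.variable_specs)

    def resolved_sensor(self) -> Sensor | None:
        if self.sensor is None:
            return None
        return self.sensor if isinstance(self.sensor, Sensor) else get_sensor(self.sensor)

    def resolved_vis(self) -> list[VIDefinition]:
        sensor = self.resolved_sensor()
        if self.vi_list is None:
            if sensor is None:
                return [get_index("NDVI")]
            return builtin_registry(sensor)
        out = []
        for item in self.vi_list:
            if "=" in item:
                name, expr = item.split("=", 1)
                out.append(
                    VIDefinition(
                        name=name.strip(), abbreviation=name.strip(),
                        expression=expr.strip(), target_variable="user",
                    )
                )
            else:
                out.append(get_index(item))
        return out

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "model": self.model,
                "specs": [
                    (s.name, s.min, s.max, s.unit, s.distribution)
                    for s in self.variable_specs
                ],
                "N": self.N,
                "scheme": self.scheme,
                "seed": self.seed,
                "sensor": getattr(self.resolved_sensor(), "name", None),
                "vi_list": self.vi_list,
                "srf_shape": self.srf_shape,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _model_runner(config: RunConfig):
    """Return ``(run, wavelengths, grid_id)``: run maps an (n, k) physical
    matrix to an (n, n_wl) spectra matrix."""
    names = [s.name for s in config.variable_specs]

    if config.model == "toy":
        specs = config.variable_specs

        def run(X: np.ndarray) -> np.ndarray:
            return toy_canopy(X, specs=specs, inert=config.toy_inert)

        return run, WAVELENGTHS_1NM, "1nm-2101"

    coeffs = config.coefficients or synthetic_coefficients()
    soil = (
        synthetic_soil_spectrum()
        if config.soil_spectrum is None
        else np.asarray(config.soil_spectrum, dtype=float)
    )
    idx = {n: names.index(n) for n in names}

    if config.model == "PROSAIL":
        def run(X: np.ndarray) -> np.ndarray:
            out = np.empty((X.shape[0], WAVELENGTHS_1NM.size))
            for j, row in enumerate(X):
                leaf = LeafParams(
                    row[idx["N"]], row[idx["Cab"]], row[idx["Cw"]], row[idx["Cm"]]
                )
                canopy = CanopyParamsSAIL(
                    LAI=row[idx["LAI"]], LAD=row[idx["LAD"]],
                    soil_coeff=row[idx["soil_coeff"]], SZA=row[idx["SZA"]],
                )
                out[j] = sail_toc(prospect4(leaf, coeffs), canopy, soil)
            return out

        return run, WAVELENGTHS_1NM, "1nm-2101"

    soil5 = to_5nm_grid(soil)

    def run(X: np.ndarray) -> np.ndarray:
        out = np.empty((X.shape[0], WAVELENGTHS_5NM.size))
        for j, row in enumerate(X):
            leaf = LeafParams(
                row[idx["N"]], row[idx["Cab"]], row[idx["Cw"]], row[idx["Cm"]]
            )
            forest = CanopyParamsINFORM(
                LAIs=row[idx["LAIs"]], LAIu=row[idx["LAIu"]],
                SD=row[idx["SD"]], H=row[idx["H"]], CD=row[idx["CD"]],
                LAD=row[idx["LAD"]], soil_coeff=row[idx["soil_coeff"]],
                SZA=row[idx["SZA"]],
            )
            rho, tau = prospect4(leaf, coeffs)
            out[j] = inform_toc((to_5nm_grid(rho), to_5nm_grid(tau)), forest, soil5)
        return out

    return run, WAVELENGTHS_5NM, "5nm-421"


@dataclass
class SimulatedBlocks:
    """Spectra for the design blocks, in evaluation order P, Q, radial 1..k."""

    wavelengths: np.ndarray
    grid_id: str
    P: np.ndarray
    Q: np.ndarray
    radial: list[np.ndarray]
    n_model_runs: int
    elapsed_s: float


def simulate_design(config: RunConfig) -> SimulatedBlocks:
    """Simulate spectra for all design blocks; exactly N(k+2) model runs."""
    design = generate_unit_design(
        config.k, config.N, scheme=config.scheme, seed=config.seed
    )
    run, wl, grid_id = _model_runner(config)
    t0 = time.perf_counter()
    n_runs = 0

    def evaluate(unit_block: np.ndarray) -> np.ndarray:
        nonlocal n_runs
        X = scale_design(unit_block, config.variable_specs)
        n_runs += X.shape[0]
        return run(X)

    P = evaluate(design.P)
    radial = [evaluate(M) for M in design.radial]
    Q = evaluate(design.Q)
    assert n_runs == design.n_model_runs
    return SimulatedBlocks(
        wavelengths=wl, grid_id=grid_id, P=P, Q=Q, radial=radial,
        n_model_runs=n_runs, elapsed_s=time.perf_counter() - t0,
    )


def _block_views(config: RunConfig, blocks: SimulatedBlocks):
    sensor = config.resolved_sensor()

    def view(values: np.ndarray):
        if sensor is None:
            return NativeGridView(blocks.wavelengths, values)
        return convolve_to_sensor(
            blocks.wavelengths, values, sensor, shape=config.srf_shape
        )

    return [view(blocks.P), view(blocks.Q)] + [view(r) for r in blocks.radial]


@dataclass
class RunResult:
    """Per-index GSA results plus run metadata."""

    config: RunConfig
    results: dict[str, GSAResult]
    manifest: dict

    def to_frame(self) -> pd.DataFrame:
        return pd.concat(
            [r.to_frame() for r in self.results.values()], ignore_index=True
        )

    def write(self, output_dir=None) -> Path:
        out = Path(output_dir or self.config.output_dir or ".")
        out.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(out / "gsa_results.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))
        return out


def run_vi_gsa(config: RunConfig, blocks: SimulatedBlocks | None = None) -> RunResult:
    """Full workflow: one GSAResult per requested vegetation index.

    ``blocks`` allows reusing already-simulated spectra (e.g. for several
    sensors over the same design)."""
    vis = config.resolved_vis()
    if not vis:
        raise ValueError("no vegetation indices resolved for this configuration")
    if blocks is None:
        blocks = simulate_design(config)
    views = _block_views(config, blocks)
    names = [s.name for s in config.variable_specs]

    results: dict[str, GSAResult] = {}
    excluded: dict[str, int] = {}
    for vi in vis:
        outputs = [evaluate_vi(vi, v) for v in views]
        res = estimate_sobol_indices(
            outputs[0], outputs[1], outputs[2:],
            variable_names=names, output_name=vi.abbreviation,
        )
        results[vi.abbreviation] = res
        excluded[vi.abbreviation] = res.n_excluded_rows

    manifest = {
        "model": config.model,
        "sensor": getattr(config.resolved_sensor(), "name", None),
        "scheme": config.scheme,
        "seed": config.seed,
        "N": config.N,
        "k": config.k,
        "n_model_runs": blocks.n_model_runs,
        "grid_id": blocks.grid_id,
        "variable_bounds": {s.name: [s.min, s.max] for s in config.variable_specs},
        "excluded_rows_per_vi": excluded,
        "config_hash": config.config_hash(),
        "simulation_seconds": round(blocks.elapsed_s, 2),
    }
    return RunResult(config=config, results=results, manifest=manifest)


def run_spectral_gsa(
    config: RunConfig, blocks: SimulatedBlocks | None = None
) -> pd.DataFrame:
    """Per-wavelength total-effect (and first-order) indices on the native grid.

    Returns a tidy table with one row per wavelength and columns
    ``wavelength`` plus ``STi_<var>`` and ``Si_<var>`` per variable; the
    matrix of STi values has shape (grid length, k).
    """
    if blocks is None:
        blocks = simulate_design(config)
    fP, fQ = blocks.P, blocks.Q
    N = fP.shape[0]
    f0 = fP.mean(axis=0)
    V = np.maximum((fP**2).mean(axis=0) - f0**2, 0.0)
    degenerate = V < 1e-12 * np.maximum(1.0, f0**2)
    Vs = np.where(degenerate, 1.0, V)

    out = {"wavelength": blocks.wavelengths}
    for i, spec in enumerate(config.variable_specs):
        R = blocks.radial[i]
        Si = np.einsum("nw,nw->w", fQ, R - fP) / (N * Vs)
        STi = ((fP - R) ** 2).sum(axis=0) / (2.0 * N * Vs)
        out[f"Si_{spec.name}"] = np.where(degenerate, 0.0, np.clip(Si, 0.0, None))
        out[f"STi_{spec.name}"] = np.where(degenerate, 0.0, STi)
    out["degenerate"] = degenerate
    return pd.DataFrame(out)


def convergence(
    config: RunConfig, n_grid: list[int], vi: str = "NDVI"
) -> pd.DataFrame:
    """Total-effect trajectories of one index over increasing sample counts.

    The design is built at ``max(n_grid)`` and estimators are applied to its
    leading prefixes (the nested quasi-random sequence makes the prefix the
    design of the smaller run).  Returns one row per (N, variable).
    """
    n_grid = sorted(set(int(n) for n in n_grid))
    cfg = RunConfig(**{**config.__dict__, "N": n_grid[-1], "vi_list": [vi]})
    blocks = simulate_design(cfg)
    views = _block_views(cfg, blocks)
    definition = cfg.resolved_vis()[0]
    outputs = [evaluate_vi(definition, v) for v in views]
    names = [s.name for s in cfg.variable_specs]

    rows = []
    for N in n_grid:
        res = estimate_sobol_indices(
            outputs[0][:N], outputs[1][:N], [o[:N] for o in outputs[2:]],
            variable_names=names, output_name=definition.abbreviation,
        )
        for name, si, sti in zip(names, res.Si, res.STi):
            rows.append(
                {"output_name": definition.abbreviation, "N": N,
                 "variable": name, "Si": si, "STi": sti}
            )
    return pd.DataFrame(rows)
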