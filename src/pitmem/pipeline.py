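"""End-to-end driver: generate -> voxelize -> pores -> flow -> mechanics.

The pipeline is configured by a YAML file validated against a strict
schema (unknown keys are rejected).  Physical quantities may be given as
plain numbers in canonical units (nm, Pa, Pa·s) or as strings with an
explicit unit suffix ("20 nm", "1 kPa", "9 GPa"), which guards against the
easiest silent error in this code base: mixing nm geometry with SI solver
quantities.

Every stage is seeded; rerunning a config reproduces every output number.
A failing seed is recorded in its report entry and never aborts the batch.
"""

from __future__ import annotations

import hashlib
import json
import time
import traceback
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, field_validator
from scipy import stats

from . import deposition as dep
from .deposition import DepositionParams, deposit_network, write_network_csv
from .flow import FluidProps, per_pore_flux, solve_stokes, summarize_flow
from .mechanics import FibrilMaterial, build_beam_model, uniaxial_tension
from .pores import extract_pore_graph
from .voxel import voxelize

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]

_UNIT_SCALES = {
    # canonical: nm for lengths, Pa for pressures/moduli, Pa·s for viscosity
    "nm": 1.0,
    "um": 1e3,
    "µm": 1e3,
    "mm": 1e6,
    "pa": 1.0,
    "kpa": 1e3,
    "mpa": 1e6,
    "gpa": 1e9,
    "pa·s": 1.0,
    "pa*s": 1.0,
    "pa.s": 1.0,
    "pas": 1.0,
    "mpa·s": 1e-3,
    "mpa*s": 1e-3,
    "mpa.s": 1e-3,
}


def parse_quantity(value: Union[int, float, str]) -> float:
    """Parse "NUMBER [unit]" into the canonical unit for its kind."""
    if isinstance(value, (int, float)):
        return float(value)
    parts = value.strip().split()
    if len(parts) == 1:
        return float(parts[0])
    if len(parts) == 2:
        num, unit = parts
        key = unit.lower()
        if key not in _UNIT_SCALES:
            raise ValueError(f"unknown unit {unit!r} in {value!r}")
        scale = _UNIT_SCALES[key]
        # viscosity units share the table; mPa·s vs MPa disambiguated by the dot
        if unit == "mPa" and key == "mpa":
            scale = 1e6
        return float(num) * scale
    raise ValueError(f"cannot parse quantity {value!r}")


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DepositionSection(_Section):
    domain_x: Union[float, str] = 500.0
    domain_y: Union[float, str] = 500.0
    fibril_diameter: Union[float, str] = 20.0
    fibril_length: Union[float, str] = 1000.0
    target_count: Optional[int] = None
    target_volume_fraction: Optional[float] = None
    candidates_per_step: int = 100
    clip_radius: Optional[Union[float, str]] = None

    @field_validator(
        "domain_x", "domain_y", "fibril_diameter", "fibril_length", "clip_radius"
    )
    @classmethod
    def _units(cls, v):
        return None if v is None else parse_quantity(v)

    def to_params(self, seed: int) -> DepositionParams:
        target_count = self.target_count
        if target_count is None and self.target_volume_fraction is None:
            target_count = DepositionParams().target_count
        return DepositionParams(
            domain_x=self.domain_x,
            domain_y=self.domain_y,
            fibril_diameter=self.fibril_diameter,
            fibril_length=self.fibril_length,
            target_count=target_count,
            target_volume_fraction=self.target_volume_fraction,
            candidates_per_step=self.candidates_per_step,
            clip_radius=self.clip_radius,
            seed=seed,
        )


class FluidSection(_Section):
    density: float = 998.0  # kg/m^3
    viscosity: Union[float, str] = 1e-3  # Pa·s

    @field_validator("viscosity")
    @classmethod
    def _units(cls, v):
        return parse_quantity(v)


class FlowSection(_Section):
    enabled: bool = True
    pressure_drop: Union[float, str] = 1000.0  # Pa
    rtol: float = 1e-8
    lateral: str = "periodic"

    @field_validator("pressure_drop")
    @classmethod
    def _units(cls, v):
        return parse_quantity(v)


class MechanicsSection(_Section):
    enabled: bool = False
    ef: Union[float, str] = 9e9  # Pa
    failure_strain: Optional[float] = None
    max_strain: float = 0.02
    steps: int = 5
    grip_axis: str = "y"

    @field_validator("ef")
    @classmethod
    def _units(cls, v):
        return parse_quantity(v)


class PipelineConfig(_Section):
    seeds: List[int] = [0]
    voxel_size: Union[float, str] = 2.5  # nm
    deposition: DepositionSection = DepositionSection()
    fluid: FluidSection = FluidSection()
    flow: FlowSection = FlowSection()
    mechanics: MechanicsSection = MechanicsSection()
    output_dir: Optional[str] = None

    @field_validator("voxel_size")
    @classmethod
    def _units(cls, v):
        return parse_quantity(v)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Aggregated per-seed results with provenance."""

    config_hash: str
    version: str
    seeds: List[int]
    entries: Dict[int, dict] = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "version": self.version,
            "seeds": self.seeds,
            "entries": {str(k): v for k, v in self.entries.items()},
        }

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=float))


def _run_seed(config: PipelineConfig, seed: int, out_dir: Optional[Path]) -> dict:
    entry: dict = {"seed": seed}
    t0 = time.perf_counter()
    params = config.deposition.to_params(seed)
    network = deposit_network(params)
    entry["n_fibrils"] = len(network)
    entry["thickness_nm"] = network.thickness
    entry["solid_volume_nm3"] = dep.analytic_solid_volume(network)
    area = network.domain[0] * network.domain[1]
    if network.thickness > 0:
        entry["volume_fraction"] = entry["solid_volume_nm3"] / (area * network.thickness)
    if out_dir is not None:
        write_network_csv(network, out_dir / f"network_seed{seed}.csv")

    grid = voxelize(network, config.voxel_size)
    entry["porosity"] = grid.porosity
    pg = extract_pore_graph(grid)
    diam = pg.constriction_diameters()
    entry["n_pores"] = len(pg)
    entry["n_constrictions"] = len(pg.constrictions)
    if diam.size:
        entry["constriction_diameter_nm"] = {
            "median": float(np.median(diam)),
            "mean": float(np.mean(diam)),
            "p10": float(np.percentile(diam, 10)),
            "p90": float(np.percentile(diam, 90)),
        }
    entry["percolates"] = pg.percolates()

    if config.flow.enabled:
        fluid = FluidProps(config.fluid.density, config.fluid.viscosity)
        char_d = (
            params.fibril_diameter
            if isinstance(params.fibril_diameter, float)
            else dep._spec_min(params.fibril_diameter)
        )
        fieldn = solve_stokes(
            grid,
            fluid,
            dp=config.flow.pressure_drop,
            rtol=config.flow.rtol,
            lateral=config.flow.lateral,
        )
        if not fieldn.percolating:
            entry["flow"] = {"percolating": False, "Q_m3_s": 0.0}
        else:
            summ = summarize_flow(fieldn, grid, fluid, characteristic_diameter=char_d)
            entry["flow"] = {
                "percolating": True,
                "Q_m3_s": summ.volumetric_flow_rate,
                "mean_velocity_m_s": summ.mean_velocity,
                "permeability_m2": summ.permeability,
                "conductivity_m_s_Pa": summ.conductivity_per_area,
                "reynolds": summ.reynolds,
                "flux_imbalance": summ.flux_imbalance,
                "solver_residual": fieldn.residual,
            }
            fractions = per_pore_flux(fieldn, pg)
            rows = []
            for pid, p in pg.pores.items():
                rows.append(
                    (
                        fractions.get(pid, 0.0),
                        p.diameter,
                        pg.obstruction_index(pid),
                    )
                )
            flux, diam_p, obst = map(np.array, zip(*rows)) if rows else ([], [], [])
            entry["pores"] = {
                "flux_fraction": list(map(float, flux)),
                "diameter_nm": list(map(float, diam_p)),
                "obstruction_index": list(map(float, obst)),
            }
            if len(rows) >= 3:
                r_open = stats.spearmanr(flux, 1.0 - obst).statistic
                r_diam = stats.spearmanr(flux, diam_p).statistic
                entry["flux_correlations"] = {
                    "vs_openness": float(r_open),
                    "vs_diameter": float(r_diam),
                }

    if config.mechanics.enabled:
        material = FibrilMaterial(
            Ef=config.mechanics.ef, failure_strain=config.mechanics.failure_strain
        )
        model = build_beam_model(network, grip_axis=config.mechanics.grip_axis)
        if model.connected:
            resp = uniaxial_tension(
                model,
                material,
                max_strain=config.mechanics.max_strain,
                steps=config.mechanics.steps,
            )
            entry["mechanics"] = {
                "effective_modulus_pa": resp.effective_modulus,
                "n_contacts": model.n_contacts,
                "failed": resp.failed,
            }
        else:
            entry["mechanics"] = {"error": "disconnected specimen"}

    entry["runtime_s"] = time.perf_counter() - t0
    return entry


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage for every seed; one failing seed never stops the rest."""
    from . import __version__

    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.hash(), version=__version__, seeds=list(config.seeds))
    for seed in config.seeds:
        try:
            report.entries[seed] = _run_seed(config, seed, out_dir)
        except Exception as exc:  # crash isolation per seed
            report.entries[seed] = {
                "seed": seed,
                "error": f"{type(exc).__name__}: {exc}",
                "traceback": traceback.format_exc(limit=5),
            }
    if out_dir is not None:
        report.write(out_dir / "report.json")
    return report
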