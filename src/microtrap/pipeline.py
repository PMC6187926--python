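"""Scenario orchestration: configuration, end-to-end runs, sweeps and CLI.

A scenario runs geometry -> flow -> transport (per species) -> metrics.  The
flow is solved once per geometry and reused for all species, since species
never feed back into the flow.  Configuration files are YAML with lengths in
micrometres and concentrations in mM (equal to mol/m^3); everything is
converted to SI at load time and unknown keys are rejected.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import click
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .analytic import HYPOXIC_THRESHOLD_MM
from .flow import FlowField, SolverSettings, flow_report, solve_flow
from .geometry import (
    GeometrySpec,
    LabeledGrid,
    Region,
    build_domain,
    domain_volumes,
)
from .params import (
    PhysicalParams,
    SpeciesSpec,
    UL_PER_MIN,
    default_physical_params,
    default_species,
)
from .postprocess import (
    SummaryMetrics,
    hypoxic_fraction,
    max_surface_shear,
    region_average,
    region_min,
    write_outputs,
)
from .transport import solve_species

log = logging.getLogger(__name__)

__all__ = ["Scenario", "SweepTable", "run_scenario", "run_sweep", "load_config", "cli"]


class Scenario(BaseModel):
    """A fully resolved simulation case (SI units throughout)."""

    model_config = ConfigDict(extra="forbid")

    name: str = "scenario"
    geometry: GeometrySpec = Field(default_factory=GeometrySpec)
    physical: PhysicalParams = Field(default_factory=default_physical_params)
    species: list[SpeciesSpec] = Field(
        default_factory=lambda: [default_species("oxygen"), default_species("glucose")]
    )
    solver: SolverSettings = Field(default_factory=SolverSettings)
    spacing: float = Field(default=10e-6, gt=0.0)
    coarse_ok: bool = False
    output_dir: Optional[str] = None
    seed: Optional[int] = None

    def resolved_config(self) -> dict:
        return json.loads(self.model_dump_json())


@dataclass
class SweepTable:
    """One metrics row per swept combination; failures isolated per row."""

    axis: str
    rows: list[dict] = dc_field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_scenario(
    scenario: Scenario, write: bool = False
) -> tuple[dict, SummaryMetrics]:
    """Run one scenario end to end; deterministic for a fixed configuration.

    Returns the solved fields (grid, flow, concentration per species) and the
    summary metrics.  When ``write`` is true and an output directory is set,
    VTI/CSV/JSON outputs are produced as well.
    """
    try:
        grid = build_domain(scenario.geometry, scenario.spacing, scenario.coarse_ok)
    except Exception as e:  # noqa: BLE001
        raise StageError("geometry", e) from e

    try:
        flow = solve_flow(grid, scenario.physical, scenario.solver)
    except Exception as e:  # noqa: BLE001
        raise StageError("flow", e) from e

    fields = {}
    for sp in scenario.species:
        try:
            fields[sp.name] = solve_species(grid, sp, flow, scenario.solver)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"transport:{sp.name}", e) from e

    try:
        metrics = SummaryMetrics(region_volumes=domain_volumes(grid))
        for name, f in fields.items():
            metrics.c_ave[name] = region_average(f, grid, Region.TISSUE)
            metrics.c_min[name] = region_min(f, grid, Region.TISSUE)
        if "oxygen" in fields:
            metrics.hypoxic_volume_fraction = hypoxic_fraction(
                fields["oxygen"], grid, HYPOXIC_THRESHOLD_MM
            )
        metrics.tau_max = max_surface_shear(flow, grid, Region.TISSUE)
        metrics.diagnostics = flow_report(flow)
        metrics.diagnostics["transport_iterations"] = {
            n: f.iterations for n, f in fields.items()
        }
    except Exception as e:  # noqa: BLE001
        raise StageError("postprocess", e) from e

    if write and scenario.output_dir:
        write_outputs(
            grid,
            flow,
            list(fields.values()),
            metrics,
            scenario.output_dir,
            resolved_config=scenario.resolved_config(),
            basename=scenario.name,
        )

    out = {"grid": grid, "flow": flow, "fields": fields}
    return out, metrics


_SWEEP_DEFAULTS = {
    "aspect_ratio": [1.5, 2.0, 2.5, 3.0],
    "minor_radius": [40e-6, 60e-6, 80e-6, 100e-6],
    "h_over_r": [5.0, 6.0, 7.5, 9.0],
    "trap_kind": ["u_barrier", "microwell"],
}

_AGG_KINDS = ["toroid_horizontal", "toroid_vertical", "spheroid"]


def run_sweep(
    base: Scenario,
    axis: str,
    values: Optional[list] = None,
    aggregate_kinds: Optional[list[str]] = None,
) -> SweepTable:
    """Sweep one geometry axis across aggregate kinds, one row per combo."""
    if axis not in _SWEEP_DEFAULTS:
        raise ValueError(f"unknown sweep axis {axis!r}; choose from {sorted(_SWEEP_DEFAULTS)}")
    values = list(values) if values is not None else _SWEEP_DEFAULTS[axis]
    if not values:
        raise ValueError("sweep values must be non-empty")
    aggregate_kinds = aggregate_kinds or _AGG_KINDS
    table = SweepTable(axis=axis)
    for v in values:
        for agg in aggregate_kinds:
            geo_update = {"aggregate_kind": agg}
            if axis == "aspect_ratio":
                geo_update["aspect_ratio"] = v
            elif axis == "minor_radius":
                geo_update["minor_radius"] = v
            elif axis == "h_over_r":
                geo_update["trap_height"] = v * base.geometry.minor_radius
            elif axis == "trap_kind":
                geo_update["trap_kind"] = v
            row = {"axis": axis, "value": v, "aggregate_kind": agg}
            try:
                geom = base.geometry.model_copy(update=geo_update)
                scen = base.model_copy(
                    update={"geometry": geom, "name": f"{base.name}_{axis}_{v}_{agg}"}
                )
                _, metrics = run_scenario(scen)
                row.update(metrics.to_row())
                row["failed"] = False
            except Exception as e:  # noqa: BLE001
                log.warning("sweep row failed (%s=%s, %s): %s", axis, v, agg, e)
                row["failed"] = True
                row["error"] = str(e)
            table.rows.append(row)
    return table


# --- configuration ---------------------------------------------------------

_GEOM_LENGTH_KEYS = {
    "trap_height",
    "trap_length",
    "barrier_wall_thickness",
    "minor_radius",
    "margin",
    "channel_width",
    "channel_height",
    "channel_length",
    "lid_thickness",
    "trap_center_x",
}


def _convert_geometry(cfg: dict) -> dict:
    out = {}
    for k, v in cfg.items():
        if k in _GEOM_LENGTH_KEYS and v is not None:
            out[k] = float(v) * 1e-6  # um -> m
        elif k == "trap_footprint_area":
            out[k] = float(v) * 1e-12  # um^2 -> m^2
        else:
            out[k] = v
    return out


def _convert_physical(cfg: dict) -> dict:
    out = dict(cfg)
    if "Q_ul_per_min" in out:
        out["Q"] = float(out.pop("Q_ul_per_min")) * UL_PER_MIN
    return out


def load_config(path) -> Scenario:
    """Load a YAML scenario; micrometre/mM units, unknown keys rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("config root must be a mapping")
    known = {
        "name",
        "geometry",
        "physical",
        "species",
        "solver",
        "spacing_um",
        "coarse_ok",
        "output_dir",
        "seed",
    }
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for key in ("name", "coarse_ok", "output_dir", "seed"):
        if key in raw:
            kwargs[key] = raw[key]
    if "spacing_um" in raw:
        kwargs["spacing"] = float(raw["spacing_um"]) * 1e-6
    if "geometry" in raw:
        kwargs["geometry"] = GeometrySpec(**_convert_geometry(raw["geometry"]))
    if "physical" in raw:
        kwargs["physical"] = PhysicalParams(**_convert_physical(raw["physical"]))
    if "species" in raw:
        specs = []
        for item in raw["species"]:
            if isinstance(item, str):
                specs.append(default_species(item))
            else:
                name = item.get("name")
                base = default_species(name).model_dump()
                base.update(item)
                specs.append(SpeciesSpec(**base))
        kwargs["species"] = specs
    if "solver" in raw:
        kwargs["solver"] = SolverSettings(**raw["solver"])
    return Scenario(**kwargs)


# --- command line ----------------------------------------------------------


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="debug logging")
def cli(verbose: bool):
    """Microfluidic trap microenvironment simulator."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(levelname)s %(name)s: %(message)s",
    )


@cli.command()
@click.argument("config", type=click.Path(exists=True))
def run(config):
    """Run one scenario from a YAML config."""
    scen = load_config(config)
    _, metrics = run_scenario(scen, write=True)
    click.echo(json.dumps(metrics.to_row(), indent=2))


@cli.command()
@click.argument("config", type=click.Path(exists=True))
@click.option("--axis", required=True)
@click.option("--values", default=None, help="comma-separated sweep values")
@click.option("--out", default=None, type=click.Path())
def sweep(config, axis, values, out):
    """Sweep one axis of a base scenario."""
    scen = load_config(config)
    vals = None
    if values:
        vals = [
            v if axis == "trap_kind" else float(v) * (1e-6 if axis == "minor_radius" else 1.0)
            for v in values.split(",")
        ]
    table = run_sweep(scen, axis, vals)
    df = table.to_dataframe()
    if out:
        df.to_csv(out, index=False)
    click.echo(df.to_string())
    if df.get("failed") is not None and df["failed"].any():
        raise SystemExit(1)


@cli.command("dump-grid")
@click.argument("config", type=click.Path(exists=True))
@click.option("--out", default="grid.vti", type=click.Path())
def dump_grid(config, out):
    """Voxelize the configured geometry and write a labeled VTI file."""
    from ._vtk import write_vti

    scen = load_config(config)
    grid = build_domain(scen.geometry, scen.spacing, scen.coarse_ok)
    # boundary tags painted onto the outermost cell layers for inspection
    tags = np.zeros(grid.shape)
    tags[0] = grid.face_tags["x-"]
    tags[-1] = np.maximum(tags[-1], grid.face_tags["x+"])
    tags[:, 0] = np.maximum(tags[:, 0], grid.face_tags["y-"])
    tags[:, -1] = np.maximum(tags[:, -1], grid.face_tags["y+"])
    tags[:, :, 0] = np.maximum(tags[:, :, 0], grid.face_tags["z-"])
    tags[:, :, -1] = np.maximum(tags[:, :, -1], grid.face_tags["z+"])
    write_vti(out, grid, {"label": grid.labels.astype(float), "boundary_tag": tags})
    click.echo(f"wrote {out}: shape {grid.shape}, volumes {domain_volumes(grid)}")


@cli.command()
def validate():
    """Fast end-to-end sanity checks at ci scale (exit nonzero on failure)."""
    from .fixtures import make_mini_chip, make_validation_sphere
    from .params import knudsen_number
    from .transport import solve_species as _solve

    failures = []
    if abs(knudsen_number(0.25e-9, 80e-6) - 3.125e-6) > 1e-18:
        failures.append("knudsen")
    fx = make_validation_sphere("ci")
    field = _solve(
        fx.grid,
        fx.species,
        None,
        SolverSettings(transport_residual_tol=1e-8),
        constant_rate=fx.constant_rate,
        surface_dirichlet=fx.surface_phi,
    )
    from .analytic import constant_rate_profile

    X, Y, Z = fx.grid.cell_centers()
    tissue = fx.grid.labels == int(Region.TISSUE)
    b = np.sqrt(X**2 + Y**2 + Z**2)[tissue]
    exact = constant_rate_profile(fx.model, np.clip(b, 0.0, fx.model.Rs))
    err = np.abs(field.c[tissue] - exact).max() / fx.model.c_surface
    if err > 0.05:
        failures.append(f"validation sphere (ci) error {err:.3f}")
    chip = make_mini_chip("ci", "spheroid", "u_barrier")
    try:
        _, metrics = run_scenario(chip.scenario)
        if metrics.diagnostics["mass_balance_rel"] > 1e-6:
            failures.append("mini chip mass balance")
    except Exception as e:  # noqa: BLE001
        failures.append(f"mini chip: {e}")
    if failures:
        click.echo("FAILED: " + "; ".join(failures), err=True)
        raise SystemExit(1)
    click.echo("all validation checks passed")


@cli.group()
def fixtures():
    """Fixture generation utilities."""


@fixtures.command("generate")
@click.argument("name")
@click.option("--outdir", default="fixtures_out", type=click.Path())
def fixtures_generate(name, outdir):
    """Emit scenario YAML + expected-values JSON for a named fixture."""
    from .fixtures import make_mini_chip, make_validation_sphere

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name.startswith("validation_sphere"):
        scale = name.split("_")[-1] if name[-1] != "e" else "desk"
        fx = make_validation_sphere(scale if scale in ("ci", "desk", "full") else "desk")
        payload = {"expected": fx.expected, "scale": fx.scale, "name": fx.name}
    elif name.startswith("mini_chip"):
        fx = make_mini_chip()
        (outdir / f"{fx.name}.yaml").write_text(
            yaml.safe_dump(fx.scenario.resolved_config())
        )
        payload = {"expected": fx.expected, "scale": fx.scale, "name": fx.name}
    else:
        raise click.UsageError(f"unknown fixture {name!r}")
    (outdir / f"{name}_expected.json").write_text(json.dumps(payload, indent=2))
    click.echo(f"wrote fixture data to {outdir}")
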