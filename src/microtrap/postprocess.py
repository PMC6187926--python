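"""Summary metrics from solved fields and standard file outputs.

Averages and minima are computed over voxel cells without sub-cell interface
correction; the surface shear uses one-sided velocity gradients extrapolated
to the wall and the analytic signed-distance normal (voxel normals are too
noisy for tractions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from ._vtk import write_vti
from .flow import FlowField
from .geometry import LabeledGrid, Region
from .transport import ConcentrationField

__all__ = [
    "SummaryMetrics",
    "region_average",
    "region_min",
    "hypoxic_fraction",
    "max_surface_shear",
    "write_outputs",
    "ProvenanceRecord",
]


@dataclass
class SummaryMetrics:
    """The per-scenario quantities reported by the comparison figures."""

    c_ave: dict[str, float] = dc_field(default_factory=dict)
    c_min: dict[str, float] = dc_field(default_factory=dict)
    tau_max: float = float("nan")
    hypoxic_volume_fraction: float = float("nan")
    region_volumes: dict[str, float] = dc_field(default_factory=dict)
    diagnostics: dict = dc_field(default_factory=dict)

    def to_row(self) -> dict:
        row: dict = {}
        for sp, v in sorted(self.c_ave.items()):
            row[f"c_ave_{sp}"] = v
        for sp, v in sorted(self.c_min.items()):
            row[f"c_min_{sp}"] = v
        row["tau_max"] = self.tau_max
        row["hypoxic_volume_fraction"] = self.hypoxic_volume_fraction
        for name, v in sorted(self.region_volumes.items()):
            row[f"vol_{name}"] = v
        return row


def _region_values(field: ConcentrationField, grid: LabeledGrid, region: Region):
    mask = grid.labels == int(region)
    if not mask.any():
        raise ValueError(f"region {Region(region).name} is empty")
    vals = field.c[mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(f"region {Region(region).name} holds no concentration data")
    return vals


def region_average(
    field: ConcentrationField, grid: LabeledGrid, region: Region = Region.TISSUE
) -> float:
    """Volume-weighted mean concentration over one region [mol/m^3]."""
    return float(_region_values(field, grid, region).mean())


def region_min(
    field: ConcentrationField, grid: LabeledGrid, region: Region = Region.TISSUE
) -> float:
    """Minimum concentration over one region [mol/m^3]."""
    return float(_region_values(field, grid, region).min())


def hypoxic_fraction(
    field: ConcentrationField, grid: LabeledGrid, threshold: float
) -> float:
    """Fraction of TISSUE volume with concentration below ``threshold``."""
    if threshold <= 0.0:
        raise ValueError("threshold must be positive")
    mask = grid.labels == int(Region.TISSUE)
    if not mask.any():
        return 0.0
    vals = field.c[mask]
    return float(np.mean(vals < threshold))


def _trilinear(fields: list[np.ndarray], grid: LabeledGrid, points: np.ndarray):
    """Trilinear sample of cell-centred fields at physical points."""
    h = grid.spacing
    rel = (points - grid.origin[None, :]) / h - 0.5
    n = np.array(grid.shape)
    base = np.floor(rel).astype(int)
    frac = rel - base
    out = np.zeros((points.shape[0], len(fields)))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                idx = base + np.array([dx, dy, dz])
                idx = np.clip(idx, 0, n - 1)
                wx = frac[:, 0] if dx else 1.0 - frac[:, 0]
                wy = frac[:, 1] if dy else 1.0 - frac[:, 1]
                wz = frac[:, 2] if dz else 1.0 - frac[:, 2]
                w = wx * wy * wz
                for k, f in enumerate(fields):
                    out[:, k] += w * f[idx[:, 0], idx[:, 1], idx[:, 2]]
    return out


def _shift(a: np.ndarray, axis: int, off: int, fill=0.0) -> np.ndarray:
    """Shifted copy: out[i] = a[i - off] with constant fill outside."""
    out = np.full_like(a, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if off > 0:
        src[axis] = slice(0, -off)
        dst[axis] = slice(off, None)
    elif off < 0:
        src[axis] = slice(-off, None)
        dst[axis] = slice(0, off)
    else:
        return a.copy()
    out[tuple(dst)] = a[tuple(src)]
    return out


def max_surface_shear(
    flow: FlowField,
    grid: LabeledGrid,
    surface_region: Region = Region.TISSUE,
    sdf: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> float:
    """Maximum tangential viscous traction on a region's surface [Pa].

    At a no-slip surface the tangential traction reduces to
    mu * d(u_t)/dn.  For every fluid cell adjacent to the surface the
    tangential velocity is sampled at the cell centre (wall distance from the
    analytic signed-distance value) and at a second probe one cell farther
    along the SDF normal; a quadratic fit through (surface, probe1, probe2)
    gives the wall-normal derivative at the true surface.  This is exact for
    linear and parabolic profiles and, unlike stencil gradients on the voxel
    staircase, insensitive to the O(h) wall-position error.
    """
    sdf = sdf or grid.aggregate_sdf
    if sdf is None:
        raise ValueError("a signed-distance function is required for normals")
    mu = float(flow.diagnostics.get("mu", 0.000692))
    fluid = grid.labels == int(Region.MEDIUM)
    region = grid.labels == int(surface_region)
    if not region.any():
        raise ValueError(f"region {Region(surface_region).name} is empty")
    near = np.zeros_like(fluid)
    for ax in range(3):
        for off in (+1, -1):
            near |= _shift(region, ax, off, fill=False)
    near &= fluid
    if not near.any():
        raise ValueError("no fluid faces adjacent to the requested surface")

    h = grid.spacing
    idx = np.argwhere(near)
    centers = (idx + 0.5) * h + grid.origin[None, :]
    d0 = np.asarray(sdf(centers), dtype=float)
    keep = d0 > -0.5 * h
    idx, centers, d0 = idx[keep], centers[keep], d0[keep]
    if len(idx) == 0:
        raise ValueError("no usable fluid cells next to the surface")

    eps = h * 1e-3
    n = np.zeros((len(idx), 3))
    for ax in range(3):
        dp = centers.copy()
        dm = centers.copy()
        dp[:, ax] += eps
        dm[:, ax] -= eps
        n[:, ax] = (np.asarray(sdf(dp)) - np.asarray(sdf(dm))) / (2 * eps)
    norm = np.linalg.norm(n, axis=1, keepdims=True)
    norm[norm == 0.0] = 1.0
    n /= norm

    # probes at fixed wall distances along the normal from the surface foot
    # point; fixed offsets keep the extrapolation well conditioned
    foot = centers - n * d0[:, None]
    d1, d2 = 1.5 * h, 3.0 * h
    uc, vc, wc = flow.cell_centered_velocity()
    v1 = _trilinear([uc, vc, wc], grid, foot + n * d1)
    v2 = _trilinear([uc, vc, wc], grid, foot + n * d2)

    def tangential(v):
        vn = np.einsum("na,na->n", v, n)
        return v - vn[:, None] * n

    t1 = tangential(v1)
    t2 = tangential(v2)
    # quadratic through (0, 0), (d1, t1), (d2, t2): slope at the surface
    slope = (t1 * d2**2 - t2 * d1**2) / (d1 * d2 * (d2 - d1))
    tau = mu * np.linalg.norm(slope, axis=1)
    return float(tau.max())


class ProvenanceRecord(BaseModel):
    """Schema for the JSON provenance written next to every scenario result."""

    model_config = ConfigDict(extra="forbid")

    package: str
    version: str
    resolved_config: dict
    grid_shape: tuple[int, int, int]
    spacing: float
    region_cell_counts: dict[str, int]
    metrics: dict


def write_outputs(
    grid: LabeledGrid,
    flow: Optional[FlowField],
    fields: list[ConcentrationField],
    metrics: SummaryMetrics,
    outdir,
    resolved_config: Optional[dict] = None,
    basename: str = "scenario",
) -> dict[str, Path]:
    """Write VTI fields, a metrics CSV row and a provenance JSON record."""
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    arrays: dict[str, np.ndarray] = {"label": grid.labels.astype(float)}
    if flow is not None:
        uc, vc, wc = flow.cell_centered_velocity()
        arrays["velocity"] = np.stack([uc, vc, wc])
        arrays["pressure"] = flow.p
    for f in fields:
        arrays[f"c_{f.species}"] = f.c
    vti = outdir / f"{basename}.vti"
    write_vti(vti, grid, arrays)
    paths["vti"] = vti

    csv = outdir / f"{basename}_metrics.csv"
    pd.DataFrame([metrics.to_row()]).to_csv(csv, index=False)
    paths["csv"] = csv

    record = ProvenanceRecord(
        package="microtrap",
        version=__version__,
        resolved_config=resolved_config or {},
        grid_shape=grid.shape,
        spacing=grid.spacing,
        region_cell_counts={r.name: grid.region_count(r) for r in Region},
        metrics=metrics.to_row(),
    )
    prov = outdir / f"{basename}_provenance.json"
    prov.write_text(record.model_dump_json(indent=2))
    paths["provenance"] = prov
    return paths
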