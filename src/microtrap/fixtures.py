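"""Synthetic fixture scenarios: small, fully specified test domains.

Every fixture is generated by code and carries its expected values, their
provenance and tolerances with it, so tests never hard-code magic numbers.
Reduced-scale fixtures shrink geometry while preserving the governing
dimensionless groups (consumption group A R^2 / (6 D c_s) for
reaction-diffusion, Peclet number for advection), which keeps the solution
structure identical at a fraction of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Literal, Optional

import numpy as np

from .analytic import SphereModel, constant_rate_profile
from .flow import SolverSettings
from .geometry import (
    GeometrySpec,
    LabeledGrid,
    Region,
    equal_volume_spheroid_radius,
    sphere_sdf,
    uniform_grid,
)
from .params import SpeciesSpec, default_physical_params, default_species
from .pipeline import Scenario

__all__ = [
    "FixtureCase",
    "make_validation_sphere",
    "make_mini_chip",
    "make_grid_independence_suite",
]

Scale = Literal["ci", "desk", "full"]


@dataclass
class FixtureCase:
    """A self-describing test case: inputs plus expected values.

    ``expected`` maps quantity names to dicts with ``value``, ``tol``
    (relative) and ``provenance`` describing where the number comes from.
    """

    name: str
    scale: str
    expected: dict[str, dict] = dc_field(default_factory=dict)
    grid: Optional[LabeledGrid] = None
    species: Optional[SpeciesSpec] = None
    scenario: Optional[Scenario] = None
    model: Optional[SphereModel] = None
    surface_phi: Optional[float] = None
    constant_rate: Optional[float] = None
    extras: dict = dc_field(default_factory=dict)


_SPHERE_SCALES = {
    # radius [m], spacing [m]
    "ci": (100e-6, 100e-6 / 12.0),
    "desk": (500e-6, 10e-6),
    "full": (500e-6, 6.25e-6),
}


def octant_sphere_grid(Rs: float, spacing: float, pad_cells: int = 2) -> LabeledGrid:
    """One octant of a sphere (centre at the origin corner), TISSUE inside.

    The three near box sides act as symmetry (no-flux) planes; the tissue
    surface is exposed through ``surface_dirichlet`` faces against EXTERIOR.
    """
    n = int(np.ceil(Rs / spacing)) + pad_cells
    grid = uniform_grid((n, n, n), spacing, label=Region.EXTERIOR)
    x = grid.axis_centers(0)
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    inside = X**2 + Y**2 + Z**2 < Rs**2
    grid.labels[inside] = int(Region.TISSUE)
    grid.aggregate_sdf = lambda p: sphere_sdf(p, Rs, center=(0.0, 0.0, 0.0))
    return grid


def make_validation_sphere(
    scale: Scale = "desk", reaction: Literal["constant", "mm"] = "constant"
) -> FixtureCase:
    """Sphere-only diffusion-reaction case with a Dirichlet surface value.

    At full/desk scale this is the published validation sphere (radius
    500 um, surface 0.2 mM, constant sink 0.005 mol/m^3/s, tissue oxygen
    diffusivity); the ci variant shrinks the radius and rescales the rate to
    keep A Rs^2 / (6 D c_surface) — and hence the normalized profile — fixed.
    """
    Rs_ref, A_ref, D, c_surf = 500e-6, 0.005, 1.83e-9, 0.2
    Rs, spacing = _SPHERE_SCALES[scale]
    A = A_ref * (Rs_ref / Rs) ** 2
    model = SphereModel(Rs=Rs, A=A, D=D, c_surface=c_surf)
    grid = octant_sphere_grid(Rs, spacing)
    # partition-free species: the closed-form comparison has no solubility
    # jump, so S_tissue = 1 and the surface value is imposed directly in phi
    species = SpeciesSpec(
        name="oxygen",
        D_medium=2.6e-9,
        D_tissue=D,
        S_tissue_vs_medium=1.0,
        Vmax=A,
        Km=1e-9,
        c_inlet=c_surf,
        pdms_permeable=False,
    )
    group = A * Rs**2 / (6.0 * D * c_surf)
    expected = {
        "surface_concentration": {
            "value": c_surf,
            "tol": 1e-12,
            "provenance": "imposed Dirichlet surface value",
        },
        "center_concentration": {
            "value": float(constant_rate_profile(model, 0.0)),
            "tol": 0.02,
            "provenance": "closed-form constant-rate sphere profile at b=0",
        },
        "dimensionless_group": {
            "value": group,
            "tol": 1e-12,
            "provenance": "A Rs^2 / (6 D c_surface), preserved across scales",
        },
        "max_profile_error": {
            "value": 0.01,
            "tol": 0.0,
            "provenance": "validation target: <=1% of the profile scale",
        },
    }
    return FixtureCase(
        name=f"validation_sphere_{scale}_{reaction}",
        scale=scale,
        expected=expected,
        grid=grid,
        species=species,
        model=model,
        surface_phi=c_surf,
        constant_rate=A if reaction == "constant" else None,
    )


_CHIP_SCALES = {
    # geometric scale factor, cells across the minor radius
    "ci": (0.25, 2.5),
    "desk": (0.5, 4.0),
    "full": (1.0, 8.0),
}


def make_mini_chip(
    scale: Scale = "ci",
    aggregate_kind: str = "toroid_horizontal",
    trap_kind: str = "u_barrier",
    aspect_ratio: float = 2.0,
    h_over_r: float = 7.5,
    fit_aspect_ratio: Optional[float] = None,
) -> FixtureCase:
    """Geometrically similar chip at reduced size for smoke/ordering tests.

    All lengths scale by ``s``; the flow rate scales by ``s`` (preserving the
    cell Peclet number) and the consumption rates by ``1/s^2`` (preserving
    the reaction-diffusion group), so concentration fields are directly
    comparable to the reference device.
    """
    s, cells_per_r = _CHIP_SCALES[scale]
    r = 80e-6 * s
    R = aspect_ratio * r
    # size the trap for the largest aggregate it must hold; passing
    # fit_aspect_ratio keeps the trap identical across an aspect-ratio sweep
    # (the reference footprint only accommodates R/r up to ~2)
    wall = 25e-6 * s
    margin = 1e-6 * s
    R_fit = max(aspect_ratio, fit_aspect_ratio or 0.0) * r
    need_half = max(
        R_fit + r, equal_volume_spheroid_radius(r, R_fit, "true_equal_volume")
    )
    need_width = 2.0 * (need_half + margin + wall) * 1.1
    length = max(600e-6 * s, need_width)
    footprint = max(0.321e-6 * s * s, need_width * length)
    geom = GeometrySpec(
        trap_kind=trap_kind,
        trap_height=h_over_r * r,
        trap_length=length,
        trap_footprint_area=footprint,
        barrier_wall_thickness=wall,
        aggregate_kind=aggregate_kind,
        minor_radius=r,
        aspect_ratio=aspect_ratio,
        margin=1e-6 * s,
        channel_width=1000e-6 * s,
        channel_height=800e-6 * s,
        channel_length=1800e-6 * s,
        lid_thickness=200e-6 * s,
        half_width_symmetry=True,
    )
    phys = default_physical_params().model_copy(
        update={"Q": default_physical_params().Q * s}
    )
    species = [
        sp.model_copy(update={"Vmax": sp.Vmax / (s * s)})
        for sp in (default_species("oxygen"), default_species("glucose"))
    ]
    scen = Scenario(
        name=f"mini_chip_{trap_kind}_{aggregate_kind}_{scale}",
        geometry=geom,
        physical=phys,
        species=species,
        solver=SolverSettings(transport_residual_tol=1e-6),
        spacing=r / cells_per_r,
        coarse_ok=True,
    )
    expected = {
        "mass_balance_rel": {
            "value": 0.0,
            "tol": 1e-8,
            "provenance": "incompressibility of the converged flow",
        }
    }
    return FixtureCase(
        name=scen.name, scale=scale, expected=expected, scenario=scen
    )


def make_grid_independence_suite(
    scenario: Scenario, spacings: list[float]
) -> list[FixtureCase]:
    """The same scenario at successive resolutions, finest last.

    The companion report checks that the tissue-average concentrations change
    by less than 0.5% between the two finest grids.
    """
    if len(spacings) < 3:
        raise ValueError("grid independence requires at least 3 spacings")
    ordered = sorted(spacings, reverse=True)
    cases = []
    for hsp in ordered:
        scen = scenario.model_copy(update={"spacing": hsp, "name": f"{scenario.name}_h{hsp * 1e6:.3g}um"})
        cases.append(
            FixtureCase(
                name=scen.name,
                scale="suite",
                scenario=scen,
                expected={
                    "finest_pair_rel_change": {
                        "value": 0.005,
                        "tol": 0.0,
                        "provenance": "grid-independence criterion (<0.5%)",
                    }
                },
            )
        )
    return cases
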