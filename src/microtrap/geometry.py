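"""Parametric device geometry and its voxelization onto a labeled Cartesian grid.

Coordinate convention: ``x`` streamwise, ``y`` spanwise, ``z`` vertical with
the origin at the inlet/floor/near-side corner.  All solids are represented by
signed-distance functions (negative inside) and rasterized at cell centers;
stair-step boundaries are accepted, with resolution-controlled error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Callable, Literal, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

log = logging.getLogger(__name__)

__all__ = [
    "Region",
    "FaceTag",
    "GeometrySpec",
    "LabeledGrid",
    "torus_sdf",
    "sphere_sdf",
    "equal_volume_spheroid_radius",
    "build_domain",
    "domain_volumes",
    "uniform_grid",
]


class Region(IntEnum):
    """Cell labels.  Every grid cell carries exactly one."""

    EXTERIOR = 0
    MEDIUM = 1
    PDMS = 2
    TISSUE = 3
    SOLID = 4


class FaceTag(IntEnum):
    """Boundary condition tags on the six outer faces of the grid box."""

    NONE = 0
    INLET = 1
    OUTLET = 2
    SYMMETRY = 3
    LID_AMBIENT = 4
    NOFLUX_WALL = 5


SIDES = ("x-", "x+", "y-", "y+", "z-", "z+")


class GeometrySpec(BaseModel):
    """Parametric description of channel, trap and aggregate (SI lengths).

    Defaults follow the reference device: a 1 mm wide channel with a 600 um
    long trap of ~0.321 mm^2 outer footprint centred on the floor, a 1 um
    margin gap between aggregate and trap walls, and an oxygen-permeable lid.
    Channel height/length and lid/wall thicknesses are declared defaults and
    fully configurable.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    trap_kind: Literal["u_barrier", "microwell"] = "u_barrier"
    trap_height: float = Field(default=600e-6, gt=0.0)
    trap_length: float = Field(default=600e-6, gt=0.0)
    trap_footprint_area: float = Field(default=0.321e-6, gt=0.0)
    # 25 um keeps the default toroid (outer diameter 480 um) clear of the
    # walls of a 535 um wide trap; configurable.
    barrier_wall_thickness: float = Field(default=25e-6, gt=0.0)
    aggregate_kind: Literal["toroid_horizontal", "toroid_vertical", "spheroid"] = (
        "toroid_horizontal"
    )
    minor_radius: float = Field(default=80e-6, gt=0.0)
    aspect_ratio: float = Field(default=2.0, gt=1.0)
    margin: float = Field(default=1e-6, ge=0.0)
    channel_width: float = Field(default=1000e-6, gt=0.0)
    channel_height: float = Field(default=800e-6, gt=0.0)
    channel_length: float = Field(default=2600e-6, gt=0.0)
    lid_thickness: float = Field(default=200e-6, ge=0.0)
    well_substrate_is_pdms: bool = True
    spheroid_mode: Literal["as_printed", "true_equal_volume"] = "true_equal_volume"
    #: model only y in [0, W/2] with a symmetry plane at mid-channel
    half_width_symmetry: bool = False
    trap_center_x: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "GeometrySpec":
        if self.trap_kind == "u_barrier" and self.trap_height >= self.channel_height:
            raise ValueError("u_barrier trap_height must be below channel_height")
        if self.trap_length >= self.channel_length:
            raise ValueError("trap_length must be below channel_length")
        if self.trap_width >= self.channel_width:
            raise ValueError("trap footprint wider than the channel")
        return self

    @property
    def trap_width(self) -> float:
        """Outer spanwise width implied by footprint area and length."""
        return self.trap_footprint_area / self.trap_length

    @property
    def major_radius(self) -> float:
        return self.aspect_ratio * self.minor_radius

    @property
    def spheroid_radius(self) -> float:
        return equal_volume_spheroid_radius(
            self.minor_radius, self.major_radius, self.spheroid_mode
        )


@dataclass
class LabeledGrid:
    """Uniform Cartesian cell grid with per-cell region labels.

    ``labels`` has shape ``(nx, ny, nz)``; ``face_tags`` maps each of the six
    box sides to a 2D array of :class:`FaceTag` codes for the boundary faces
    of the outermost cells on that side.
    """

    spacing: float
    labels: np.ndarray
    face_tags: dict[str, np.ndarray]
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    spec: Optional[GeometrySpec] = None
    aggregate_sdf: Optional[Callable[[np.ndarray], np.ndarray]] = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.labels.shape)  # type: ignore[return-value]

    @property
    def cell_volume(self) -> float:
        return float(self.spacing**3)

    def axis_centers(self, axis: int) -> np.ndarray:
        n = self.labels.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.spacing

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x, y, z = (self.axis_centers(a) for a in range(3))
        return np.meshgrid(x, y, z, indexing="ij")

    def region_volume(self, region: Region) -> float:
        return float(np.count_nonzero(self.labels == region)) * self.cell_volume

    def region_count(self, region: Region) -> int:
        return int(np.count_nonzero(self.labels == region))


def _as_points(point) -> np.ndarray:
    p = np.asarray(point, dtype=float)
    if p.shape[-1] != 3:
        raise ValueError("points must have a trailing dimension of 3")
    return p


def torus_sdf(point, R: float, r: float, axis=(0.0, 0.0, 1.0), center=(0.0, 0.0, 0.0)):
    """Signed distance to a solid torus (negative inside).

    ``R`` is the major (ring) radius, ``r`` the minor (tube) radius and
    ``axis`` the unit symmetry axis through ``center``.
    """
    if not (R > r > 0.0):
        raise ValueError("torus requires R > r > 0")
    a = np.asarray(axis, dtype=float)
    if abs(np.linalg.norm(a) - 1.0) > 1e-9:
        raise ValueError("axis must be a unit vector")
    p = _as_points(point) - np.asarray(center, dtype=float)
    axial = p @ a
    radial = np.linalg.norm(p - np.multiply.outer(axial, a), axis=-1)
    return np.hypot(radial - R, axial) - r


def sphere_sdf(point, Rs: float, center=(0.0, 0.0, 0.0)):
    """Signed distance to a sphere of radius ``Rs`` (negative inside)."""
    if Rs <= 0.0:
        raise ValueError("sphere radius must be positive")
    p = _as_points(point) - np.asarray(center, dtype=float)
    return np.linalg.norm(p, axis=-1) - Rs


def equal_volume_spheroid_radius(r: float, R: float, mode: str) -> float:
    """Radius of the sphere matched to a torus with minor/major radii r, R.

    ``true_equal_volume`` equates (4/3) pi Rs^3 with the torus volume
    2 pi^2 R r^2, giving Rs = ((3 pi / 2) r^2 R)^(1/3).  ``as_printed``
    evaluates Rs = ((3/2) r^2 R)^(1/3), the same expression without the
    factor of pi, kept for comparability with published numbers.
    """
    if r < 0.0 or R <= 0.0:
        raise ValueError("radii must be non-negative (r) and positive (R)")
    if mode == "as_printed":
        return float((1.5 * r * r * R) ** (1.0 / 3.0))
    if mode == "true_equal_volume":
        return float((1.5 * np.pi * r * r * R) ** (1.0 / 3.0))
    raise ValueError(f"unknown mode {mode!r}")


def uniform_grid(
    shape: tuple[int, int, int],
    spacing: float,
    label: Region = Region.MEDIUM,
    tags: Optional[dict[str, FaceTag]] = None,
    origin=(0.0, 0.0, 0.0),
) -> LabeledGrid:
    """Single-label box grid; handy for fixtures and verification cases."""
    labels = np.full(shape, int(label), dtype=np.uint8)
    tags = tags or {}
    face_tags = {}
    for side in SIDES:
        ax = "xyz".index(side[0])
        tr = tuple(shape[a] for a in range(3) if a != ax)
        tag = tags.get(side, FaceTag.NOFLUX_WALL)
        face_tags[side] = np.full(tr, int(tag), dtype=np.int8)
    return LabeledGrid(
        spacing=spacing,
        labels=labels,
        face_tags=face_tags,
        origin=np.asarray(origin, dtype=float),
    )


def _aggregate_geometry(spec: GeometrySpec, cy: float, floor_z: float, cx: float):
    """Return (sdf, half-extent dict, center) for the configured aggregate."""
    r, R = spec.minor_radius, spec.major_radius
    m = spec.margin
    if spec.aggregate_kind == "toroid_horizontal":
        cz = floor_z + m + r
        center = np.array([cx, cy, cz])
        half = {"x": R + r, "y": R + r, "z": r}
        sdf = lambda p: torus_sdf(p, R, r, axis=(0.0, 0.0, 1.0), center=center)
    elif spec.aggregate_kind == "toroid_vertical":
        cz = floor_z + m + R + r
        center = np.array([cx, cy, cz])
        half = {"x": r, "y": R + r, "z": R + r}
        sdf = lambda p: torus_sdf(p, R, r, axis=(1.0, 0.0, 0.0), center=center)
    else:
        Rs = spec.spheroid_radius
        cz = floor_z + m + Rs
        center = np.array([cx, cy, cz])
        half = {"x": Rs, "y": Rs, "z": Rs}
        sdf = lambda p: sphere_sdf(p, Rs, center=center)
    return sdf, half, center


def _check_clearance(name: str, available: float, required: float) -> None:
    if available < required - 1e-12:
        raise ValueError(
            f"aggregate collides with trap: clearance {name!r} is "
            f"{available * 1e6:.2f} um but {required * 1e6:.2f} um is required"
        )


def build_domain(
    spec: GeometrySpec, spacing: float, coarse_ok: bool = False
) -> LabeledGrid:
    """Voxelize the configured device into a region-labeled grid.

    The channel interior becomes MEDIUM, the lid (plus barrier walls or the
    microwell substrate) PDMS, the aggregate TISSUE.  Boundary faces are
    tagged with inlet/outlet/symmetry/lid/no-flux codes.
    """
    h = float(spacing)
    if h <= 0.0:
        raise ValueError("spacing must be positive")
    if h > spec.minor_radius / 4.0 and not coarse_ok:
        raise ValueError(
            "spacing must resolve the aggregate minor radius by >= 4 cells; "
            "pass coarse_ok=True to override"
        )
    if spec.margin < h:
        warnings.warn(
            f"margin {spec.margin * 1e6:.2f} um below grid spacing "
            f"{h * 1e6:.2f} um; the gap collapses to the stair-step surface",
            stacklevel=2,
        )
        log.warning("margin gap below spacing: collapsed to voxel surface")

    W = spec.channel_width / 2.0 if spec.half_width_symmetry else spec.channel_width
    Hc, Lx = spec.channel_height, spec.channel_length
    floor_z = spec.trap_height if spec.trap_kind == "microwell" else 0.0
    Lz = floor_z + Hc + spec.lid_thickness
    nx, ny, nz = (max(1, int(round(L / h))) for L in (Lx, W, Lz))
    labels = np.full((nx, ny, nz), int(Region.EXTERIOR), dtype=np.uint8)
    xc = (np.arange(nx) + 0.5) * h
    yc = (np.arange(ny) + 0.5) * h
    zc = (np.arange(nz) + 0.5) * h
    X = xc[:, None, None]
    Y = yc[None, :, None]
    Z = zc[None, None, :]

    cx = spec.trap_center_x if spec.trap_center_x is not None else Lx / 2.0
    cy = W if spec.half_width_symmetry else W / 2.0
    wt = spec.trap_width
    Lt = spec.trap_length
    t = spec.barrier_wall_thickness

    # channel interior and lid
    in_channel = (Z > floor_z) & (Z < floor_z + Hc)
    labels[np.broadcast_to(in_channel, labels.shape)] = int(Region.MEDIUM)
    if spec.lid_thickness > 0.0:
        in_lid = Z >= floor_z + Hc
        labels[np.broadcast_to(in_lid, labels.shape)] = int(Region.PDMS)

    in_foot = (
        (X >= cx - Lt / 2.0)
        & (X <= cx + Lt / 2.0)
        & (Y >= cy - wt / 2.0)
        & (Y <= cy + wt / 2.0)
    )
    if spec.trap_kind == "u_barrier":
        # U-shaped wall: opening faces upstream (-x); interior inset by the
        # wall thickness on the downstream end and both spanwise sides.
        in_interior = (
            (X >= cx - Lt / 2.0)
            & (X <= cx + Lt / 2.0 - t)
            & (Y >= cy - wt / 2.0 + t)
            & (Y <= cy + wt / 2.0 - t)
        )
        wall = (
            np.broadcast_to(in_foot, labels.shape)
            & ~np.broadcast_to(in_interior, labels.shape)
            & np.broadcast_to(Z < spec.trap_height, labels.shape)
            & np.broadcast_to(Z > floor_z, labels.shape)
        )
        labels[wall] = int(Region.PDMS)
        ag_x_half = Lt / 2.0 - t
        ag_y_half = wt / 2.0 - t
    else:
        # microwell: cavity recessed into a substrate slab below the channel
        substrate = np.broadcast_to(Z < floor_z, labels.shape)
        labels[substrate] = int(
            Region.PDMS if spec.well_substrate_is_pdms else Region.SOLID
        )
        cavity = np.broadcast_to(in_foot & (Z < floor_z), labels.shape)
        labels[cavity] = int(Region.MEDIUM)
        ag_x_half = Lt / 2.0
        ag_y_half = wt / 2.0

    ag_floor = 0.0 if spec.trap_kind == "microwell" else floor_z
    sdf, half, center = _aggregate_geometry(spec, cy, ag_floor, cx)
    _check_clearance("trap_x", ag_x_half, half["x"] + spec.margin)
    _check_clearance("trap_y", ag_y_half, half["y"] + spec.margin)
    if spec.half_width_symmetry:
        # aggregate centred on the modelled symmetry plane; only the near half
        # must clear the channel side wall
        _check_clearance("channel_y", W, half["y"] + spec.margin)
    top = center[2] + half["z"]
    _check_clearance("channel_z", floor_z + Hc, top + spec.margin)

    pts = np.stack(np.meshgrid(xc, yc, zc, indexing="ij"), axis=-1)
    inside = sdf(pts) < 0.0
    labels[inside & (labels == int(Region.MEDIUM))] = int(Region.TISSUE)

    face_tags = _tag_faces(labels)
    return LabeledGrid(
        spacing=h,
        labels=labels,
        face_tags=face_tags,
        origin=np.zeros(3),
        spec=spec,
        aggregate_sdf=sdf,
    )


def _tag_faces(labels: np.ndarray) -> dict[str, np.ndarray]:
    nx, ny, nz = labels.shape
    tags: dict[str, np.ndarray] = {}

    def classify(border: np.ndarray, medium_tag: FaceTag, other: FaceTag):
        out = np.full(border.shape, int(FaceTag.NONE), dtype=np.int8)
        out[border == int(Region.MEDIUM)] = int(medium_tag)
        nonmed = (border != int(Region.MEDIUM)) & (border != int(Region.EXTERIOR))
        out[nonmed] = int(other)
        return out

    tags["x-"] = classify(labels[0], FaceTag.INLET, FaceTag.NOFLUX_WALL)
    tags["x+"] = classify(labels[-1], FaceTag.OUTLET, FaceTag.NOFLUX_WALL)
    tags["y-"] = classify(labels[:, 0], FaceTag.SYMMETRY, FaceTag.SYMMETRY)
    tags["y+"] = classify(labels[:, -1], FaceTag.SYMMETRY, FaceTag.SYMMETRY)
    tags["z-"] = classify(labels[:, :, 0], FaceTag.NOFLUX_WALL, FaceTag.NOFLUX_WALL)
    bottomless = labels[:, :, 0] == int(Region.EXTERIOR)
    tags["z-"][bottomless] = int(FaceTag.NONE)
    top = labels[:, :, -1]
    tags["z+"] = np.full(top.shape, int(FaceTag.NONE), dtype=np.int8)
    tags["z+"][top == int(Region.PDMS)] = int(FaceTag.LID_AMBIENT)
    tags["z+"][(top != int(Region.PDMS)) & (top != int(Region.EXTERIOR))] = int(
        FaceTag.NOFLUX_WALL
    )
    return tags


def domain_volumes(grid: LabeledGrid) -> dict[str, float]:
    """Total cell volume per region label [m^3]."""
    return {r.name: grid.region_volume(r) for r in Region}
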