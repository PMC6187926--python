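"""Steady species transport across medium, PDMS and tissue regions.

The solver works in the partition-scaled variable ``phi = c / S_region``
(with S = 1 in the medium).  This is the key discretization decision: the
solubility jump conditions c_region = S * c_medium with flux continuity then
become an ordinary heterogeneous-coefficient diffusion problem in ``phi``,
with face coefficients given by harmonic means of D_region * S_region.
Converting back, ``c = S * phi``, reproduces the concentration jumps at every
interface by construction.

Advection (first-order upwind) acts only on medium-medium faces using the
staggered flow field; the saturating consumption term is handled by Picard
iterations with a lagged denominator, which preserves the M-matrix property
and hence positivity and the discrete maximum principle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional, Union

import numpy as np
import scipy.sparse as sp

from ._solvers import Multigrid, NetworkOp, SolverError, solve_sparse
from .flow import FlowField, SolverSettings
from .geometry import FaceTag, LabeledGrid, Region
from .params import SpeciesSpec

log = logging.getLogger(__name__)

__all__ = [
    "ConcentrationField",
    "TransportSystem",
    "mm_rate",
    "assemble_transport",
    "solve_species",
]


def mm_rate(c, Vmax: float, Km: float):
    """Saturating consumption rate Vmax * c / (c + Km) [mol/m^3/s].

    Monotone increasing in ``c`` and bounded by ``Vmax``; equals Vmax/2 at
    c = Km.  Negative concentrations are rejected.
    """
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0.0):
        raise ValueError("concentration must be non-negative")
    return Vmax * c_arr / (c_arr + Km)


@dataclass
class ConcentrationField:
    """Per-cell concentration on the species' admissible regions.

    ``c`` is NaN outside the admissible region; ``phi`` is the continuous
    partition-scaled variable the solver works in.
    """

    c: np.ndarray
    phi: np.ndarray
    species: str
    grid: LabeledGrid
    admissible: np.ndarray
    residuals: list = dc_field(default_factory=list)
    converged: bool = False
    iterations: int = 0


@dataclass
class TransportSystem:
    """Assembled linear transport operator plus bookkeeping for one species."""

    grid: LabeledGrid
    species: SpeciesSpec
    admissible: np.ndarray
    DS: np.ndarray
    op: NetworkOp  # diffusive + boundary-closure part (symmetric)
    A_lin: sp.csr_matrix  # diffusion + advection + boundary closures
    b: np.ndarray
    adv_diag: np.ndarray  # advective outflow diagonal (for preconditioning)
    tissue: np.ndarray
    has_advection: bool
    # boundary bookkeeping for flux audits: (rows, conductance, value)
    dirichlet_rows: np.ndarray = dc_field(default_factory=lambda: np.array([], int))
    dirichlet_g: np.ndarray = dc_field(default_factory=lambda: np.array([]))
    dirichlet_val: np.ndarray = dc_field(default_factory=lambda: np.array([]))
    inflow_rows: np.ndarray = dc_field(default_factory=lambda: np.array([], int))
    inflow_F: np.ndarray = dc_field(default_factory=lambda: np.array([]))
    inflow_val: np.ndarray = dc_field(default_factory=lambda: np.array([]))
    outflow_rows: np.ndarray = dc_field(default_factory=lambda: np.array([], int))
    outflow_F: np.ndarray = dc_field(default_factory=lambda: np.array([]))

    def boundary_influx(self, phi: np.ndarray) -> float:
        """Net boundary influx [mol/s] for a given solution, for audits."""
        ph = phi.ravel()
        total = float(np.sum(self.dirichlet_g * (self.dirichlet_val - ph[self.dirichlet_rows])))
        total += float(np.sum(self.inflow_F * self.inflow_val))
        total -= float(np.sum(self.outflow_F * ph[self.outflow_rows]))
        return total


def _region_DS(grid: LabeledGrid, species: SpeciesSpec) -> tuple[np.ndarray, np.ndarray]:
    """Admissible mask and effective diffusion coefficient D*S per cell."""
    labels = grid.labels
    admissible = (labels == int(Region.MEDIUM)) | (labels == int(Region.TISSUE))
    DS = np.zeros(grid.shape)
    DS[labels == int(Region.MEDIUM)] = species.D_medium
    DS[labels == int(Region.TISSUE)] = species.D_tissue * species.S_tissue_vs_medium
    if species.pdms_permeable:
        admissible |= labels == int(Region.PDMS)
        DS[labels == int(Region.PDMS)] = species.D_pdms * species.S_pdms_vs_medium
    return admissible, DS


def assemble_transport(
    grid: LabeledGrid,
    species: SpeciesSpec,
    flow: Optional[FlowField] = None,
    *,
    surface_dirichlet: Optional[float] = None,
    boundary_dirichlet: Optional[dict[str, Union[float, np.ndarray]]] = None,
    source: Optional[np.ndarray] = None,
) -> TransportSystem:
    """Build the conservative finite-volume system in the phi variable.

    Boundary data follow the grid tags: INLET is Dirichlet at the inlet
    concentration (plus advective influx), OUTLET carries advection out with
    zero diffusive flux, SYMMETRY and NOFLUX_WALL are no-flux, and
    LID_AMBIENT is Dirichlet phi = c_inlet (i.e. c = S*c0 on the lid top).
    ``surface_dirichlet`` pins phi on faces between admissible and
    non-admissible interior cells (validation fixtures); ``boundary_dirichlet``
    overrides the tag of whole box sides; ``source`` adds a volumetric
    production rate [mol/m^3/s] for manufactured solutions.
    """
    h = grid.spacing
    admissible, DS = _region_DS(grid, species)
    has_medium = bool((grid.labels == int(Region.MEDIUM)).any())
    if flow is None and has_medium:
        raise ValueError(
            "a flow field is required when MEDIUM cells are present "
            "(advected species); pass FlowField.zeros(grid) for still medium"
        )

    shape = grid.shape
    ncell = int(np.prod(shape))
    dde = np.zeros(shape)
    b = np.zeros(shape)
    gs = []
    dir_rows, dir_g, dir_val = [], [], []

    for axis in range(3):
        lo = [slice(None)] * 3
        hi = [slice(None)] * 3
        lo[axis] = slice(0, -1)
        hi[axis] = slice(1, None)
        a = DS[tuple(lo)]
        bb = DS[tuple(hi)]
        both = admissible[tuple(lo)] & admissible[tuple(hi)]
        with np.errstate(divide="ignore", invalid="ignore"):
            hm = np.where(both, 2.0 * a * bb / np.where(a + bb > 0, a + bb, 1.0), 0.0)
        gs.append(h * hm)
        if surface_dirichlet is not None:
            for sl_a, sl_n in ((lo, hi), (hi, lo)):
                m = admissible[tuple(sl_a)] & ~admissible[tuple(sl_n)]
                g = 2.0 * h * DS[tuple(sl_a)] * m
                dde[tuple(sl_a)] += g
                b[tuple(sl_a)] += g * surface_dirichlet

    idx = np.arange(ncell).reshape(shape)
    c_in = species.c_inlet

    def add_dirichlet(side_slice, mask2d, value, ds2d):
        g = 2.0 * h * ds2d * mask2d
        dde[side_slice][mask2d] += g[mask2d]
        val = np.broadcast_to(np.asarray(value, dtype=float), mask2d.shape)
        b[side_slice][mask2d] += (g * val)[mask2d]
        dir_rows.append(idx[side_slice][mask2d])
        dir_g.append(g[mask2d])
        dir_val.append(val[mask2d])

    side_slices = {
        "x-": (0, slice(None), slice(None)),
        "x+": (-1, slice(None), slice(None)),
        "y-": (slice(None), 0, slice(None)),
        "y+": (slice(None), -1, slice(None)),
        "z-": (slice(None), slice(None), 0),
        "z+": (slice(None), slice(None), -1),
    }
    overridden = set(boundary_dirichlet or ())
    for side, sl in side_slices.items():
        adm2 = admissible[sl]
        if side in overridden:
            add_dirichlet(sl, adm2, boundary_dirichlet[side], DS[sl])
            continue
        tags = grid.face_tags[side]
        inlet2 = (tags == int(FaceTag.INLET)) & adm2
        if inlet2.any():
            add_dirichlet(sl, inlet2, c_in, DS[sl])
        lid2 = (tags == int(FaceTag.LID_AMBIENT)) & adm2
        if lid2.any() and species.pdms_permeable:
            add_dirichlet(sl, lid2, c_in, DS[sl])

    # advection: upwind on medium-medium faces, plus inlet/outlet faces
    rowsA, colsA, valsA = [], [], []
    adv_diag = np.zeros(shape)
    inflow_rows = np.array([], dtype=int)
    inflow_F = np.array([])
    inflow_val = np.array([])
    outflow_rows = np.array([], dtype=int)
    outflow_F = np.array([])
    has_advection = False
    if flow is not None and has_medium:
        medium = grid.labels == int(Region.MEDIUM)
        h2 = h * h
        faces = [flow.u, flow.v, flow.w]
        for axis in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[axis] = slice(0, -1)
            hi[axis] = slice(1, None)
            interior = [slice(None)] * 3
            interior[axis] = slice(1, -1)
            F = faces[axis][tuple(interior)] * h2
            both = medium[tuple(lo)] & medium[tuple(hi)]
            F = np.where(both, F, 0.0)
            L = idx[tuple(lo)]
            R = idx[tuple(hi)]
            pos = F > 0.0
            neg = F < 0.0
            if pos.any():
                rowsA += [L[pos], R[pos]]
                colsA += [L[pos], L[pos]]
                valsA += [F[pos], -F[pos]]
                adv_diag[tuple(lo)] += np.where(pos, F, 0.0)
            if neg.any():
                rowsA += [L[neg], R[neg]]
                colsA += [R[neg], R[neg]]
                valsA += [F[neg], -F[neg]]
                adv_diag[tuple(hi)] += np.where(neg, -F, 0.0)
        has_advection = bool(rowsA)
        # inlet advective influx at Dirichlet concentration
        Fin = flow.u[0] * h2
        m_in = (grid.face_tags["x-"] == int(FaceTag.INLET)) & medium[0] & (Fin > 0)
        if m_in.any():
            inflow_rows = idx[0][m_in]
            inflow_F = Fin[m_in]
            inflow_val = np.full(inflow_rows.shape, c_in)
            b[0][m_in] += Fin[m_in] * c_in
            has_advection = True
        # outlet advective carry-out
        Fout = flow.u[-1] * h2
        m_out = (grid.face_tags["x+"] == int(FaceTag.OUTLET)) & medium[-1] & (Fout > 0)
        if m_out.any():
            outflow_rows = idx[-1][m_out]
            outflow_F = Fout[m_out]
            dde_out = np.zeros(shape)
            dde_out[-1][m_out] = Fout[m_out]
            adv_diag += dde_out
            has_advection = True

    if source is not None:
        b += source * h**3 * admissible

    op = NetworkOp(mask=admissible, g=tuple(gs), dde=dde)
    A = op.to_csr()
    if rowsA:
        Adv = sp.coo_matrix(
            (
                np.concatenate([v.ravel() for v in valsA]),
                (
                    np.concatenate([r.ravel() for r in rowsA]),
                    np.concatenate([c.ravel() for c in colsA]),
                ),
            ),
            shape=(ncell, ncell),
        ).tocsr()
        A = A + Adv
    if outflow_rows.size:
        A = A + sp.coo_matrix(
            (outflow_F, (outflow_rows, outflow_rows)), shape=(ncell, ncell)
        ).tocsr()

    b_flat = b.ravel().copy()
    b_flat[~admissible.ravel()] = 0.0

    if not dde.any() and not dir_rows and surface_dirichlet is None and not overridden:
        raise ValueError("transport system has no Dirichlet datum; ill-posed")

    return TransportSystem(
        grid=grid,
        species=species,
        admissible=admissible,
        DS=DS,
        op=op,
        A_lin=A,
        b=b_flat,
        adv_diag=adv_diag,
        tissue=grid.labels == int(Region.TISSUE),
        has_advection=has_advection,
        dirichlet_rows=np.concatenate(dir_rows) if dir_rows else np.array([], int),
        dirichlet_g=np.concatenate(dir_g) if dir_g else np.array([]),
        dirichlet_val=np.concatenate(dir_val) if dir_val else np.array([]),
        inflow_rows=inflow_rows,
        inflow_F=inflow_F,
        inflow_val=inflow_val,
        outflow_rows=outflow_rows,
        outflow_F=outflow_F,
    )


def solve_species(
    grid: LabeledGrid,
    species: SpeciesSpec,
    flow: Optional[FlowField] = None,
    settings: Optional[SolverSettings] = None,
    *,
    system: Optional[TransportSystem] = None,
    constant_rate: Optional[float] = None,
    **assemble_kwargs,
) -> ConcentrationField:
    """Solve steady transport for one species by Picard iteration on the sink.

    The Michaelis-Menten denominator is frozen at the previous iterate
    (optionally under-relaxed), which keeps every linear system an M-matrix.
    ``constant_rate`` replaces the saturating sink by a fixed volumetric
    consumption [mol/m^3/s] for validation against the closed-form sphere.
    """
    settings = settings or SolverSettings()
    sys_ = system or assemble_transport(grid, species, flow, **assemble_kwargs)
    adm = sys_.admissible
    adm_flat = adm.ravel()
    h3 = grid.spacing**3
    St = species.S_tissue_vs_medium
    tissue_flat = sys_.tissue.ravel()
    ncell = adm_flat.size

    phi = np.zeros(ncell)
    phi[adm_flat] = species.c_inlet if species.c_inlet > 0 else 1.0
    bnorm = float(np.linalg.norm(sys_.b))
    if bnorm == 0.0:
        bnorm = 1.0

    def reaction_terms(phi_vec):
        """Return (nonlinear rate vector, linearized diagonal) on tissue cells."""
        c_t = np.clip(St * phi_vec[tissue_flat], 0.0, None)
        if constant_rate is not None:
            rate = np.full(c_t.shape, constant_rate * h3)
            diag = np.zeros(ncell)
            return rate, diag
        denom = c_t + species.Km
        rate = h3 * species.Vmax * c_t / denom
        diag = np.zeros(ncell)
        diag[tissue_flat] = h3 * species.Vmax * St / denom
        return rate, diag

    residuals: list[float] = []
    relax = settings.picard_relaxation
    tol = settings.transport_residual_tol
    mg = None
    n_it = 0
    for n_it in range(1, settings.max_iterations + 1):
        rate, diag = reaction_terms(phi)
        r_vec = sys_.b - sys_.A_lin @ phi
        r_vec[tissue_flat] -= rate
        r_vec[~adm_flat] = 0.0
        rel = float(np.linalg.norm(r_vec)) / bnorm
        if residuals and rel > 0.9 * residuals[-1]:
            # stagnating or cycling (near-anoxic cores): damp harder
            relax = max(0.7 * relax, 0.2)
        residuals.append(rel)
        if rel <= tol:
            break
        if constant_rate is not None:
            A = sys_.A_lin
            b_eff = sys_.b.copy()
            b_eff[tissue_flat] -= rate
        else:
            A = sys_.A_lin + sp.diags(diag)
            b_eff = sys_.b
        op_pre = NetworkOp(
            mask=sys_.op.mask,
            g=sys_.op.g,
            dde=sys_.op.dde + sys_.adv_diag + diag.reshape(grid.shape),
        )
        if A.shape[0] > 6000:
            mg = Multigrid(op_pre, n_pre=1, n_post=1)
            M = mg.as_preconditioner()
        else:
            M = None
        phi_new = solve_sparse(
            A,
            b_eff,
            symmetric=not sys_.has_advection,
            M=M,
            rtol=settings.linear_rtol,
            x0=phi,
            maxiter=settings.max_linear_iterations,
            direct_threshold=6000,
        )
        phi = relax * phi_new + (1.0 - relax) * phi
        phi[~adm_flat] = 0.0
    else:
        raise SolverError(
            f"Picard iteration for {species.name} did not converge "
            f"(residual {residuals[-1]:.3e} after {n_it} iterations)",
            residuals,
        )

    phi3 = phi.reshape(grid.shape)
    S_cell = np.ones(grid.shape)
    S_cell[grid.labels == int(Region.TISSUE)] = St
    if species.pdms_permeable and species.S_pdms_vs_medium is not None:
        S_cell[grid.labels == int(Region.PDMS)] = species.S_pdms_vs_medium
    c = S_cell * phi3
    scale = max(species.c_inlet, float(np.nanmax(np.abs(c))) or 1.0)
    if float(c[adm].min()) < -1e-8 * scale:
        raise SolverError(
            f"negative concentration beyond tolerance for {species.name}: "
            f"min c = {float(c[adm].min()):.3e}"
        )
    c = np.where(adm, c, np.nan)
    return ConcentrationField(
        c=c,
        phi=phi3,
        species=species.name,
        grid=grid,
        admissible=adm,
        residuals=residuals,
        converged=True,
        iterations=n_it,
    )
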