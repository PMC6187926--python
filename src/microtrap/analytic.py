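"""Closed forms and independent 1D oracles used to validate the 3D solvers.

Everything here is deliberately independent of the finite-volume code paths:
the radial problems are solved with scipy's collocation BVP solver on a fine
1D mesh, and the slab/sphere formulas are evaluated in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_bvp

__all__ = [
    "SphereModel",
    "HYPOXIC_THRESHOLD_MM",
    "constant_rate_profile",
    "hypoxic_radius",
    "mm_radial_oracle",
    "two_layer_slab",
    "stokes_sphere_velocity",
    "stokes_sphere_max_shear",
    "manufactured_case",
]

#: oxygen concentration equivalent to a 10 mmHg partial pressure [mol/m^3],
#: stored exactly as the conversion is quoted
HYPOXIC_THRESHOLD_MM = 0.01322


@dataclass(frozen=True)
class SphereModel:
    """Constant-consumption sphere: radius, rate, diffusivity, surface value."""

    Rs: float
    A: float
    D: float
    c_surface: float
    c_threshold: float = HYPOXIC_THRESHOLD_MM

    def __post_init__(self):
        if min(self.Rs, self.A, self.D, self.c_surface, self.c_threshold) <= 0.0:
            raise ValueError("all SphereModel parameters must be positive")
        if self.c_threshold >= self.c_surface:
            raise ValueError("c_threshold must lie below c_surface")


def constant_rate_profile(model: SphereModel, b) -> np.ndarray:
    """Concentration at radius ``b`` for uniform consumption in a sphere.

    c(b) = A/(6D) * (b^2 - Rs^2) + c_surface.  May be negative near the
    centre; callers interpret negativity as the necrotic-core regime.
    """
    b_arr = np.asarray(b, dtype=float)
    if np.any(b_arr < 0.0) or np.any(b_arr > model.Rs * (1.0 + 1e-12)):
        raise ValueError("radius must lie in [0, Rs]")
    return model.A / (6.0 * model.D) * (b_arr**2 - model.Rs**2) + model.c_surface


def hypoxic_radius(model: SphereModel):
    """Radius where the constant-rate profile crosses the hypoxic threshold.

    Returns ``None`` when the whole sphere stays above the threshold
    (no hypoxic core) — this is a value, not an error.
    """
    arg = model.Rs**2 - 6.0 * model.D * (model.c_surface - model.c_threshold) / model.A
    if arg < 0.0:
        return None
    return float(np.sqrt(arg))


def mm_radial_oracle(
    Rs: float,
    D: float,
    Vmax: float,
    Km: float,
    c_surface: float,
    tol: float = 1e-9,
    n_nodes: int = 400,
):
    """High-resolution radial solution of diffusion with a saturating sink.

    Solves (1/b^2) d/db (b^2 D dc/db) = Vmax c/(c+Km) with dc/db(0) = 0 and
    c(Rs) = c_surface by collocation, handling the coordinate singularity via
    the solver's singular-term mechanism.  Returns a callable ``c(b)``.
    """
    if min(Rs, D, Vmax, Km, c_surface) <= 0.0:
        raise ValueError("parameters must be positive")

    def rhs(x, y):
        c = np.clip(y[0], 0.0, None)
        return np.vstack([y[1], (Vmax / D) * c / (c + Km)])

    def bc(ya, yb):
        return np.array([ya[1], yb[0] - c_surface])

    S = np.array([[0.0, 0.0], [0.0, -2.0]])
    x = np.linspace(0.0, Rs, n_nodes)
    y0 = np.vstack([np.full_like(x, c_surface), np.zeros_like(x)])
    sol = None
    # the singular-term collocation occasionally over-refines at very tight
    # tolerances; relax stepwise before giving up
    for attempt_tol in (tol, 10.0 * tol, 100.0 * tol):
        sol = solve_bvp(rhs, bc, x, y0, S=S, tol=attempt_tol, max_nodes=200_000)
        if sol.success:
            break
    if sol is None or not sol.success:
        raise RuntimeError(f"radial BVP solver failed: {sol.message}")

    def profile(b):
        return sol.sol(np.asarray(b, dtype=float))[0]

    profile.solution = sol  # type: ignore[attr-defined]
    return profile


def two_layer_slab(k1: float, k2: float, phi0: float, phiL: float):
    """Series-resistance interface value and flux for two slabs in contact.

    ``k_i = D_i S_i / L_i`` are layer conductances; returns
    (phi_interface, flux from side 0 into the interface).
    """
    if k1 <= 0.0 or k2 <= 0.0:
        raise ValueError("conductances must be positive")
    phi_star = (k1 * phi0 + k2 * phiL) / (k1 + k2)
    return phi_star, k1 * (phi0 - phi_star)


def stokes_sphere_velocity(points, U: float, a: float, center=(0.0, 0.0, 0.0)):
    """Creeping-flow velocity around a rigid sphere, far-field (U, 0, 0).

    Standard Stokes solution; used as boundary data and reference field for
    the immersed-sphere shear fixture.  Points inside the sphere get zero.
    """
    p = np.asarray(points, dtype=float) - np.asarray(center, dtype=float)
    r = np.linalg.norm(p, axis=-1)
    r = np.where(r == 0.0, 1e-300, r)
    ux = p[..., 0]
    f1 = 1.0 - 3.0 * a / (4.0 * r) - a**3 / (4.0 * r**3)
    f2 = -3.0 * a / (4.0 * r**3) + 3.0 * a**3 / (4.0 * r**5)
    vel = np.zeros(p.shape)
    vel[..., 0] = U * (f1 + f2 * ux * ux)
    vel[..., 1] = U * f2 * ux * p[..., 1]
    vel[..., 2] = U * f2 * ux * p[..., 2]
    vel[r < a] = 0.0
    return vel


def stokes_sphere_max_shear(mu: float, U: float, a: float) -> float:
    """Maximum tangential surface traction on a Stokes sphere: 3 mu U / (2 a)."""
    return 1.5 * mu * U / a


def _trig_streamfunction(kx: float = np.pi, ky: float = np.pi):
    def psi(x, y):
        return np.sin(kx * x) * np.sin(ky * y)

    def u(x, y):  # d psi / dy
        return ky * np.sin(kx * x) * np.cos(ky * y)

    def v(x, y):  # -d psi / dx
        return -kx * np.cos(kx * x) * np.sin(ky * y)

    return psi, u, v


def manufactured_case(name: str) -> dict:
    """Registered manufactured solutions for order-of-convergence tests.

    Each case returns callables for the exact fields on the unit box plus the
    forcing that makes them exact steady solutions; see the verification
    tests for usage.
    """
    if name == "divfree_trig":
        psi, u, v = _trig_streamfunction()
        return {
            "psi": psi,
            "velocity": lambda x, y, z: (u(x, y), v(x, y), np.zeros_like(x)),
        }
    if name == "diffusion_trig":
        k = np.pi

        def c_exact(x, y, z):
            # offset keeps the exact field positive (a physical concentration)
            return 2.0 + np.cos(k * x) * np.cos(k * y) * np.cos(k * z)

        def source(x, y, z, D):  # -D lap(c) = 3 D k^2 (c - 2)
            return 3.0 * D * k * k * (c_exact(x, y, z) - 2.0)

        return {"c": c_exact, "source": source}
    if name == "advection_diffusion_trig":
        k = np.pi
        u0 = (1.0, 0.5, 0.25)

        def c_exact(x, y, z):
            return 2.0 + np.cos(k * x) * np.cos(k * y) * np.cos(k * z)

        def source(x, y, z, D):
            dcdx = -k * np.sin(k * x) * np.cos(k * y) * np.cos(k * z)
            dcdy = -k * np.cos(k * x) * np.sin(k * y) * np.cos(k * z)
            dcdz = -k * np.cos(k * x) * np.cos(k * y) * np.sin(k * z)
            adv = u0[0] * dcdx + u0[1] * dcdy + u0[2] * dcdz
            return adv + 3.0 * D * k * k * (c_exact(x, y, z) - 2.0)
        return {"c": c_exact, "source": source, "velocity": u0}
    raise ValueError(f"unknown manufactured case {name!r}")
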