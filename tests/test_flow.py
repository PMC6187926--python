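import numpy as np
import pytest

import microtrap as mt
from microtrap.flow import SolverSettings, inlet_profile, solve_flow
from microtrap.geometry import FaceTag, Region, uniform_grid

from conftest import channel_grid, stokes_sphere_case


def _square_duct_max_over_mean(n_terms: int = 60) -> float:
    """Series solution for laminar flow in a square duct (independent oracle).

    u(y,z) ~ sum over odd n of (-1)^((n-1)/2)/n^3 [1 - cosh(n pi z / 2a) /
    cosh(n pi / 2 a ... )] cos(...); both the peak value and the exact
    cross-section integral are evaluated from the series.
    """
    a = 1.0
    ns = np.arange(1, 2 * n_terms, 2)
    sign = (-1.0) ** ((ns - 1) // 2)
    # peak at the centre (y = z = 0)
    peak = np.sum(sign / ns**3 * (1.0 - 1.0 / np.cosh(ns * np.pi / 2.0)))
    # exact integral over the cross-section
    integ = 0.0
    for n, s in zip(ns, sign):
        k = n * np.pi / (2 * a)
        int_cos = 2.0 * np.sin(n * np.pi / 2.0) / k  # over y in [-a, a]
        int_z = 2.0 * a - (2.0 / k) * np.tanh(k * a)
        integ += s / n**3 * int_cos * int_z
    mean = integ / (2 * a) ** 2
    return peak / mean


class TestInletProfile:
    def test_flux_matches_Q(self, phys):
        g = channel_grid((6, 14, 10))
        prof = inlet_profile(phys.Q, g)
        assert prof.sum() * g.spacing**2 == pytest.approx(phys.Q, rel=1e-12)

    def test_square_duct_ratio(self):
        g = channel_grid((4, 48, 48))
        prof = inlet_profile(1e-10, g)
        ratio = prof.max() / prof[prof > 0].mean()
        assert ratio == pytest.approx(_square_duct_max_over_mean(), rel=0.01)

    def test_wide_slot_limit(self):
        g = uniform_grid(
            (4, 120, 25),
            10e-6,
            tags={
                "x-": FaceTag.INLET,
                "x+": FaceTag.OUTLET,
                "y-": FaceTag.SYMMETRY,
                "y+": FaceTag.SYMMETRY,
            },
        )
        prof = inlet_profile(1e-10, g)
        mid = prof[60]
        assert mid.max() / mid.mean() == pytest.approx(1.5, rel=0.01)

    def test_blocked_inlet_errors(self):
        g = channel_grid((6, 8, 8))
        g.labels[0] = int(Region.SOLID)
        g.face_tags["x-"][:] = int(FaceTag.NOFLUX_WALL)
        with pytest.raises(ValueError, match="blocked"):
            inlet_profile(1e-10, g)


class TestEmptyChannel:
    @pytest.fixture(scope="class")
    def field(self, phys):
        return solve_flow(channel_grid((20, 12, 10)), phys)

    def test_fully_developed_invariance(self, field):
        rel = np.abs(field.u[0] - field.u[-1]).max() / field.u[0].max()
        assert rel < 1e-6

    def test_global_mass_balance(self, field):
        assert field.diagnostics["mass_balance_rel"] <= 1e-8

    def test_divergence_free(self, field):
        div = field.divergence()
        scale = field.diagnostics["max_speed"] / field.grid.spacing
        assert np.abs(div).max() <= 1e-8 * scale

    def test_transverse_velocity_vanishes(self, field):
        assert np.abs(field.v).max() <= 1e-12 * field.diagnostics["max_speed"]
        assert np.abs(field.w).max() <= 1e-12 * field.diagnostics["max_speed"]

    def test_report(self, field):
        rep = mt.flow_report(field)
        assert rep["reynolds"] < 1.0
        assert rep["mass_balance_rel"] <= 1e-8


def _obstacle_channel(shape=(20, 11, 10)):
    g = channel_grid(shape)
    nx, ny, nz = shape
    g.labels[nx // 2 - 1 : nx // 2 + 1, ny // 2 - 1 : ny // 2 + 2, : nz // 2] = int(
        Region.TISSUE
    )
    return g


class TestObstacleFlow:
    def test_no_slip_on_solid_faces(self, phys):
        g = _obstacle_channel()
        f = solve_flow(g, phys)
        fluid = g.labels == int(Region.MEDIUM)
        # every u-face touching a non-fluid cell carries exactly zero velocity
        bad = ~fluid[:-1] | ~fluid[1:]
        assert np.abs(f.u[1:-1][bad]).max() == 0.0

    def test_linearity_in_Q(self, phys):
        g = _obstacle_channel()
        f1 = solve_flow(g, phys)
        f2 = solve_flow(g, phys.model_copy(update={"Q": 2 * phys.Q}))
        assert np.allclose(f2.u, 2 * f1.u, rtol=1e-9, atol=1e-9 * f1.u.max())
        assert np.allclose(f2.w, 2 * f1.w, rtol=1e-9, atol=1e-9 * f1.u.max())

    def test_mirror_symmetry(self, phys):
        g = _obstacle_channel((20, 11, 10))  # symmetric obstacle about mid-y
        f = solve_flow(g, phys)
        assert np.allclose(f.u, f.u[:, ::-1, :], rtol=1e-8, atol=1e-10 * f.u.max())

    def test_mass_balance_with_obstacle(self, phys):
        f = solve_flow(_obstacle_channel(), phys)
        assert f.diagnostics["mass_balance_rel"] <= 1e-8

    def test_missing_outlet_errors(self, phys):
        g = channel_grid((8, 6, 6))
        g.face_tags["x+"][:] = int(FaceTag.NOFLUX_WALL)
        with pytest.raises(ValueError, match="OUTLET"):
            solve_flow(g, phys)

    def test_inertia_defect_correction_close_to_stokes(self, phys):
        g = _obstacle_channel((14, 8, 8))
        f0 = solve_flow(g, phys)
        f1 = solve_flow(
            g, phys, SolverSettings(include_inertia=True, flow_residual_tol=1e-8)
        )
        # Re << 1: inertia shifts the solution by a small relative amount
        rel = np.abs(f1.u - f0.u).max() / f0.u.max()
        assert rel < 0.05


class TestStokesSphere:
    def test_velocity_field_matches_analytic(self, phys):
        from microtrap.analytic import stokes_sphere_velocity

        g, bc, a, U = stokes_sphere_case(ncells=24)
        f = solve_flow(g, mt.PhysicalParams(rho=993.3, mu=6.92e-4, Q=1e-12),
                       velocity_bc=bc)
        X, Y, Z = g.cell_centers()
        pts = np.stack([X, Y, Z], axis=-1)
        uc, _, _ = f.cell_centered_velocity()
        exact = stokes_sphere_velocity(pts, U, a)[..., 0]
        fluid = g.labels == int(Region.MEDIUM)
        err = np.abs(uc - exact)[fluid].max() / U
        assert err < 0.05


class TestManufacturedStokes:
    @staticmethod
    def _solve_case(n: int, mu: float = 1.0e-3):
        # streamfunction velocity, p = cos(pi x) cos(pi y); body force chosen
        # so the pair solves the momentum equation exactly
        h = 1.0 / n
        g = uniform_grid((n, n, n), h)

        def u_ex(x, y):
            return np.pi * np.sin(np.pi * x) * np.cos(np.pi * y)

        def v_ex(x, y):
            return -np.pi * np.cos(np.pi * x) * np.sin(np.pi * y)

        bc = {}
        for side, ax, pos in [
            ("x-", 0, 0.0),
            ("x+", 0, 1.0),
            ("y-", 1, 0.0),
            ("y+", 1, 1.0),
            ("z-", 2, 0.0),
            ("z+", 2, 1.0),
        ]:
            axes = [i for i in range(3) if i != ax]
            c1 = g.axis_centers(axes[0])
            c2 = g.axis_centers(axes[1])
            A, B = np.meshgrid(c1, c2, indexing="ij")
            P = {ax: np.full(A.shape, pos), axes[0]: A, axes[1]: B}
            bc[side] = np.stack(
                [u_ex(P[0], P[1]), v_ex(P[0], P[1]), np.zeros(A.shape)]
            )

        def face_coords(axis):
            cs = []
            for ax2 in range(3):
                if ax2 == axis:
                    cs.append(np.arange(g.shape[ax2] + 1) * h)
                else:
                    cs.append((np.arange(g.shape[ax2]) + 0.5) * h)
            return np.meshgrid(*cs, indexing="ij")

        Xu, Yu, _ = face_coords(0)
        Xv, Yv, _ = face_coords(1)
        Xw, Yw, _ = face_coords(2)
        fx = (2 * mu * np.pi**2 - 1.0) * u_ex(Xu, Yu)
        fy = (2 * mu * np.pi**2 + 1.0) * v_ex(Xv, Yv)
        fz = np.zeros(Xw.shape)
        params = mt.PhysicalParams(rho=1000.0, mu=mu, Q=1e-12)
        f = solve_flow(g, params, velocity_bc=bc, body_force=[fx, fy, fz])
        eu = f.u - u_ex(Xu, Yu)
        ev = f.v - v_ex(Xv, Yv)
        return float(np.sqrt((eu**2).mean() + (ev**2).mean()) / np.pi)

    def test_order_of_convergence(self):
        # rms error; the L-inf pair at these sizes is still preasymptotic
        e1 = self._solve_case(16)
        e2 = self._solve_case(32)
        order = np.log2(e1 / e2)
        assert order >= 1.7


class TestSolverSettings:
    def test_invariants(self):
        with pytest.raises(Exception):
            SolverSettings(flow_residual_tol=-1.0)
        with pytest.raises(Exception):
            SolverSettings(picard_relaxation=1.5)

    def test_defaults_match_convergence_criteria(self):
        s = SolverSettings()
        assert s.flow_residual_tol == 1e-6
        assert s.transport_residual_tol == 1e-3
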