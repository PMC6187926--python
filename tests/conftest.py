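import warnings

import numpy as np
import pytest

import microtrap as mt
from microtrap.geometry import FaceTag, Region, uniform_grid


@pytest.fixture(autouse=True)
def _quiet_margin_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="margin gap below")
        yield


@pytest.fixture(scope="session")
def phys():
    return mt.default_physical_params()


@pytest.fixture(scope="session")
def oxygen():
    return mt.default_species("oxygen")


@pytest.fixture(scope="session")
def glucose():
    return mt.default_species("glucose")


def channel_grid(shape=(16, 10, 8), spacing=10e-6):
    """Open rectangular channel with inlet/outlet tags and solid walls."""
    return uniform_grid(
        shape,
        spacing,
        tags={
            "x-": FaceTag.INLET,
            "x+": FaceTag.OUTLET,
            "y-": FaceTag.NOFLUX_WALL,
            "y+": FaceTag.NOFLUX_WALL,
            "z-": FaceTag.NOFLUX_WALL,
            "z+": FaceTag.NOFLUX_WALL,
        },
    )


def stokes_sphere_case(ncells=32, a=50e-6, U=1e-4, box_factor=1.25):
    """Immersed sphere with analytic creeping-flow Dirichlet boundary data."""
    from microtrap.analytic import stokes_sphere_velocity
    from microtrap.geometry import sphere_sdf

    L = box_factor * a
    h = 2 * L / ncells
    g = uniform_grid((ncells,) * 3, h, label=Region.MEDIUM, origin=(-L, -L, -L))
    X, Y, Z = g.cell_centers()
    pts = np.stack([X, Y, Z], axis=-1)
    g.labels[np.linalg.norm(pts, axis=-1) < a] = int(Region.TISSUE)
    g.aggregate_sdf = lambda p: sphere_sdf(p, a)
    bc = {}
    for side, ax, pos in [
        ("x-", 0, -L),
        ("x+", 0, L),
        ("y-", 1, -L),
        ("y+", 1, L),
        ("z-", 2, -L),
        ("z+", 2, L),
    ]:
        axes = [i for i in range(3) if i != ax]
        c1 = g.axis_centers(axes[0])
        c2 = g.axis_centers(axes[1])
        A, B = np.meshgrid(c1, c2, indexing="ij")
        P = np.zeros(A.shape + (3,))
        P[..., ax] = pos
        P[..., axes[0]] = A
        P[..., axes[1]] = B
        v = stokes_sphere_velocity(P, U, a)
        bc[side] = np.stack([v[..., 0], v[..., 1], v[..., 2]])
    return g, bc, a, U


@pytest.fixture(scope="session")
def mini_chip_results():
    """Solved ci-scale chips, shared across ordering tests (expensive)."""
    from microtrap.fixtures import make_mini_chip
    from microtrap.pipeline import run_scenario

    results = {}
    for trap in ("u_barrier", "microwell"):
        for agg in ("toroid_horizontal", "toroid_vertical", "spheroid"):
            fx = make_mini_chip("ci", agg, trap)
            _, metrics = run_scenario(fx.scenario)
            results[(trap, agg)] = metrics
    return results
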