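"""Internal linear-solver infrastructure.

All discrete operators in this package reduce to 7-point "conductance
network" form on a (possibly masked) Cartesian lattice:

    (A x)_i = dde_i * x_i + sum_faces g_f * (x_i - x_nb)

with non-negative face conductances ``g`` and an extra diagonal ``dde``
(Dirichlet closures, reaction linearizations, advective outflow).  This
module provides CSR assembly, a matrix-free matvec, a geometric multigrid
V-cycle (piecewise-constant prolongation, Galerkin coarsening, damped
Jacobi smoothing) used as a preconditioner, and robust Krylov drivers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla


@dataclass
class NetworkOp:
    """Symmetric 7-point operator defined by face conductances and a diagonal.

    ``g[axis]`` has the grid shape reduced by one along ``axis`` and holds the
    conductance between node ``i`` and ``i+1``; it must be zero whenever either
    endpoint is inactive.  Inactive nodes behave as identity rows.
    """

    mask: np.ndarray
    g: tuple[np.ndarray, np.ndarray, np.ndarray]
    dde: np.ndarray

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.mask.shape)  # type: ignore[return-value]

    @property
    def n(self) -> int:
        return int(np.prod(self.mask.shape))

    def diag(self) -> np.ndarray:
        d = self.dde.copy()
        for ax in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[ax] = slice(0, -1)
            hi[ax] = slice(1, None)
            d[tuple(lo)] += self.g[ax]
            d[tuple(hi)] += self.g[ax]
        d[~self.mask] = 1.0
        d[d == 0.0] = 1.0  # isolated active nodes decouple harmlessly
        return d

    def matvec(self, x: np.ndarray) -> np.ndarray:
        y = self.dde * x
        for ax in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[ax] = slice(0, -1)
            hi[ax] = slice(1, None)
            f = self.g[ax] * (x[tuple(lo)] - x[tuple(hi)])
            y[tuple(lo)] += f
            y[tuple(hi)] -= f
        y[~self.mask] = x[~self.mask]
        return y

    def to_csr(self) -> sp.csr_matrix:
        shape = self.mask.shape
        n = self.n
        idx = np.arange(n).reshape(shape)
        rows = [np.arange(n)]
        cols = [np.arange(n)]
        vals = [self.diag().ravel()]
        for ax in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[ax] = slice(0, -1)
            hi[ax] = slice(1, None)
            a = idx[tuple(lo)].ravel()
            b = idx[tuple(hi)].ravel()
            gv = self.g[ax].ravel()
            nz = gv != 0.0
            rows += [a[nz], b[nz]]
            cols += [b[nz], a[nz]]
            vals += [-gv[nz], -gv[nz]]
        A = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        return A.tocsr()


def _pad_even(a: np.ndarray) -> np.ndarray:
    pads = [(0, s % 2) for s in a.shape]
    if any(p[1] for p in pads):
        a = np.pad(a, pads)
    return a


def _block_sum(a: np.ndarray) -> np.ndarray:
    a = _pad_even(a)
    s = a.shape
    return a.reshape(s[0] // 2, 2, s[1] // 2, 2, s[2] // 2, 2).sum(axis=(1, 3, 5))


def _coarsen(op: NetworkOp) -> NetworkOp:
    mask_c = _block_sum(op.mask.astype(np.int8)) > 0
    dde_c = _block_sum(op.dde)
    gs = []
    for ax in range(3):
        gf = op.g[ax]
        n = op.mask.shape[ax]
        # keep only fine faces crossing coarse-block interfaces (odd index)
        sl = [slice(None)] * 3
        sl[ax] = slice(1, n - 1, 2)
        crossing = gf[tuple(sl)]
        # sum transverse 2x2 patches; axis ax already has one entry per
        # coarse interface
        sh = list(crossing.shape)
        other = [a for a in range(3) if a != ax]
        a = crossing
        for oax in other:
            a = _pad_even_axis(a, oax)
            s = list(a.shape)
            s[oax] //= 2
            s.insert(oax + 1, 2)
            a = a.reshape(s).sum(axis=oax + 1)
        gs.append(a)
    return NetworkOp(mask=mask_c, g=tuple(gs), dde=dde_c)


def _pad_even_axis(a: np.ndarray, ax: int) -> np.ndarray:
    if a.shape[ax] % 2:
        pads = [(0, 0)] * a.ndim
        pads[ax] = (0, 1)
        a = np.pad(a, pads)
    return a


def _prolong(xc: np.ndarray, fine_shape: tuple[int, int, int]) -> np.ndarray:
    xf = np.repeat(np.repeat(np.repeat(xc, 2, 0), 2, 1), 2, 2)
    return xf[: fine_shape[0], : fine_shape[1], : fine_shape[2]]


class Multigrid:
    """Geometric V-cycle for :class:`NetworkOp`, usable as SPD preconditioner."""

    def __init__(
        self,
        op: NetworkOp,
        n_pre: int = 2,
        n_post: int = 2,
        omega: float = 0.8,
        coarse_n: int = 600,
        max_levels: int = 12,
    ):
        self.omega = omega
        self.n_pre = n_pre
        self.n_post = n_post
        self.levels: list[NetworkOp] = [op]
        self.diags: list[np.ndarray] = [op.diag()]
        while (
            int(self.levels[-1].mask.sum()) > coarse_n
            and max(self.levels[-1].shape) > 2
            and len(self.levels) < max_levels
        ):
            nxt = _coarsen(self.levels[-1])
            self.levels.append(nxt)
            self.diags.append(nxt.diag())
        coarse = self.levels[-1].to_csr().tocsc()
        # tiny shift guards against a singular all-Neumann coarse problem
        coarse = coarse + 1e-12 * sp.eye(coarse.shape[0], format="csc") * (
            abs(coarse.diagonal()).max() or 1.0
        )
        self._coarse_lu = spla.splu(coarse)
        self._coarse_shape = self.levels[-1].shape

    def _smooth(self, lvl: int, x: np.ndarray, b: np.ndarray, sweeps: int):
        op, d = self.levels[lvl], self.diags[lvl]
        for _ in range(sweeps):
            x += self.omega * (b - op.matvec(x)) / d
        return x

    def _cycle(self, lvl: int, b: np.ndarray) -> np.ndarray:
        op = self.levels[lvl]
        if lvl == len(self.levels) - 1:
            return self._coarse_lu.solve(b.ravel()).reshape(self._coarse_shape)
        x = self._smooth(lvl, np.zeros_like(b), b, self.n_pre)
        r = b - op.matvec(x)
        r[~op.mask] = 0.0
        rc = _block_sum(r)
        xc = self._cycle(lvl + 1, rc)
        corr = _prolong(xc, op.shape)
        corr[~op.mask] = 0.0
        x += corr
        return self._smooth(lvl, x, b, self.n_post)

    def solve_approx(self, b: np.ndarray) -> np.ndarray:
        return self._cycle(0, b)

    def as_preconditioner(self) -> spla.LinearOperator:
        shape = self.levels[0].shape
        n = int(np.prod(shape))

        def mv(v):
            v = np.asarray(v, dtype=float)
            return self._cycle(0, v.reshape(shape)).ravel()

        return spla.LinearOperator((n, n), matvec=mv)


class SolverError(RuntimeError):
    """Raised when a linear or nonlinear solve fails to converge."""

    def __init__(self, msg: str, history: Optional[list[float]] = None):
        super().__init__(msg)
        self.history = history or []


def solve_sparse(
    A: sp.spmatrix,
    b: np.ndarray,
    *,
    symmetric: bool,
    M: Optional[spla.LinearOperator] = None,
    rtol: float = 1e-10,
    x0: Optional[np.ndarray] = None,
    maxiter: int = 2000,
    direct_threshold: int = 40_000,
) -> np.ndarray:
    """Solve ``A x = b`` robustly: direct for small systems, else Krylov.

    Verifies the true residual and escalates (CG/BiCGStab -> GMRES -> direct)
    before raising :class:`SolverError`.
    """
    n = A.shape[0]
    bnorm = float(np.linalg.norm(b))
    if bnorm == 0.0:
        return np.zeros(n)
    if n <= direct_threshold:
        return spla.spsolve(A.tocsc(), b)

    def ok(x):
        return float(np.linalg.norm(A @ x - b)) <= max(rtol * bnorm * 10.0, 1e-300)

    if symmetric:
        x, info = spla.cg(A, b, rtol=rtol, atol=0.0, M=M, x0=x0, maxiter=maxiter)
    else:
        x, info = spla.bicgstab(A, b, rtol=rtol, atol=0.0, M=M, x0=x0, maxiter=maxiter)
    if info == 0 and ok(x):
        return x
    x, info = spla.gmres(
        A, b, rtol=rtol, atol=0.0, M=M, x0=x0, restart=80, maxiter=maxiter
    )
    if info == 0 and ok(x):
        return x
    try:
        ilu = spla.spilu(A.tocsc(), drop_tol=1e-5, fill_factor=12.0)
        Milu = spla.LinearOperator(A.shape, matvec=ilu.solve)
        x, info = spla.gmres(
            A, b, rtol=rtol, atol=0.0, M=Milu, restart=80, maxiter=maxiter
        )
        if info == 0 and ok(x):
            return x
    except Exception:
        pass
    raise SolverError(f"linear solve failed (n={n})")
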