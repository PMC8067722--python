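"""Quasi-static linear elasticity, von Mises stress, and stress-damped diffusion.

Tumor expansion loads the surrounding tissue: the displacement field u
solves the isotropic linear-elastic equilibrium equation with a body force
proportional to the tumor volume-fraction gradient,

    div(G grad u) + grad[G/(1-2 nu) (div u)] - lambda2 grad(phi_T) = 0,

with a slip boundary condition at the brain-mask edge (zero normal
displacement, free tangential motion).  The von Mises stress derived from
u exponentially damps the cell diffusion coefficient,
``D = D0 exp(-lambda1 sigma_vm)``, so mechanically confined regions invade
more slowly.

Discretization: collocated 7-point central differences on the masked grid,
harmonic averaging of G across voxel faces, ghost-voxel mirroring for the
slip condition (antisymmetric for the face-normal component, symmetric for
tangential components and scalars).  The operator depends only on the grid
and tissue properties, so it is assembled and LU-factorized once and reused
for every right-hand side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from .grids import Grid3D, LABEL_GRAY, LABEL_OTHER, LABEL_WHITE


@dataclass
class MechanicalParams:
    """Tissue mechanical properties and the two coupling constants.

    G (shear modulus, kPa) and nu (Poisson ratio) are per tissue label;
    lambda1 (1/kPa) couples von Mises stress to diffusion, lambda2 (kPa)
    scales the tumor-gradient body force.
    """

    G: dict = field(default_factory=lambda: {LABEL_WHITE: 2.1, LABEL_GRAY: 2.6, LABEL_OTHER: 2.6})
    nu: dict = field(default_factory=lambda: {LABEL_WHITE: 0.45, LABEL_GRAY: 0.45, LABEL_OTHER: 0.45})
    lambda1: float = 0.25
    lambda2: float = 1.0

    def __post_init__(self) -> None:
        if any(g <= 0 for g in self.G.values()):
            raise ValueError("shear moduli must be positive")
        if any(not (0 < v < 0.5) for v in self.nu.values()):
            raise ValueError("Poisson ratios must lie in (0, 0.5)")
        if self.lambda1 < 0:
            raise ValueError("lambda1 must be nonnegative")

    def _field(self, table: dict, grid: Grid3D) -> np.ndarray:
        out = np.empty(grid.shape, dtype=float)
        labels = grid.tissue_labels
        default = table.get(LABEL_OTHER, next(iter(table.values())))
        out[:] = default
        for lab, val in table.items():
            out[labels == lab] = val
        return out

    def G_field(self, grid: Grid3D) -> np.ndarray:
        return self._field(self.G, grid)

    def nu_field(self, grid: Grid3D) -> np.ndarray:
        return self._field(self.nu, grid)


@dataclass
class MechanicalState:
    u: np.ndarray          # (3, nx, ny, nz), mm
    sigma_vm: np.ndarray   # (nx, ny, nz), kPa


def _neighbor_indices(mask: np.ndarray, axis: int, direction: int) -> tuple[np.ndarray, np.ndarray]:
    """For each masked voxel (flattened order): index of the masked neighbor
    one step along ``axis`` in ``direction``, or -1 when outside mask/array."""
    idx = -np.ones(mask.shape, dtype=np.int64)
    idx[mask] = np.arange(int(mask.sum()))
    shifted = np.full(mask.shape, -1, dtype=np.int64)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if direction > 0:
        src[axis] = slice(1, None)
        dst[axis] = slice(None, -1)
    else:
        src[axis] = slice(None, -1)
        dst[axis] = slice(1, None)
    shifted[tuple(dst)] = idx[tuple(src)]
    return idx[mask], shifted[mask]


def _cdiff_matrix(mask: np.ndarray, axis: int, h: float, ghost_sign: float) -> sparse.csr_matrix:
    """Central-difference d/dx_axis over masked voxels.

    At a face with no masked neighbor, the ghost value is
    ``ghost_sign * u[v]`` (-1: antisymmetric / zero at the face; +1:
    symmetric mirror / zero normal derivative).
    """
    n = int(mask.sum())
    me, ip = _neighbor_indices(mask, axis, +1)
    _, im = _neighbor_indices(mask, axis, -1)
    rows, cols, vals = [], [], []
    c = 1.0 / (2.0 * h)
    has_p = ip >= 0
    rows.append(me[has_p]); cols.append(ip[has_p]); vals.append(np.full(has_p.sum(), +c))
    rows.append(me[~has_p]); cols.append(me[~has_p]); vals.append(np.full((~has_p).sum(), ghost_sign * c))
    has_m = im >= 0
    rows.append(me[has_m]); cols.append(im[has_m]); vals.append(np.full(has_m.sum(), -c))
    rows.append(me[~has_m]); cols.append(me[~has_m]); vals.append(np.full((~has_m).sum(), -ghost_sign * c))
    rows = np.concatenate(rows); cols = np.concatenate(cols); vals = np.concatenate(vals)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


def _lap_matrix(mask: np.ndarray, G: np.ndarray, spacing, normal_axis: int | None) -> sparse.csr_matrix:
    """div(G grad .) with harmonic face averaging of G.

    ``normal_axis`` marks the displacement component this operator acts on:
    at a boundary face whose normal equals that component's axis the ghost
    is antisymmetric (contributes -2 G/h^2 to the diagonal); at any other
    boundary face the flux is zero.
    """
    n = int(mask.sum())
    Gm = G[mask]
    rows, cols, vals = [], [], []
    for axis in range(3):
        h2 = spacing[axis] ** 2
        for direction in (+1, -1):
            me, nb = _neighbor_indices(mask, axis, direction)
            has = nb >= 0
            Gf = np.zeros(n)
            Gn = Gm[nb[has]]
            Gf[has] = 2.0 * Gm[has] * Gn / (Gm[has] + Gn)
            rows.append(me[has]); cols.append(nb[has]); vals.append(Gf[has] / h2)
            rows.append(me[has]); cols.append(me[has]); vals.append(-Gf[has] / h2)
            if normal_axis == axis:
                # slip: u_normal = 0 on the face -> ghost = -u[v]
                rows.append(me[~has]); cols.append(me[~has])
                vals.append(-2.0 * Gm[~has] / h2)
    rows = np.concatenate(rows); cols = np.concatenate(cols); vals = np.concatenate(vals)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()


class ElasticitySolver:
    """Assembles and factorizes the equilibrium operator once per grid."""

    def __init__(self, grid: Grid3D, mech: MechanicalParams):
        self.grid = grid
        self.mech = mech
        mask = grid.brain_mask
        self.mask = mask
        self.n = int(mask.sum())
        G = mech.G_field(grid)
        nu = mech.nu_field(grid)
        K = (G / (1.0 - 2.0 * nu))[mask]
        diagK = sparse.diags(K)
        spacing = grid.spacing
        # grad of displacement component a (antisymmetric ghost along its own axis)
        D_norm = [_cdiff_matrix(mask, a, spacing[a], ghost_sign=-1.0) for a in range(3)]
        # grad of a scalar (symmetric mirror ghost)
        self.D_scal = [_cdiff_matrix(mask, a, spacing[a], ghost_sign=+1.0) for a in range(3)]
        blocks = [[None] * 3 for _ in range(3)]
        for c in range(3):
            L = _lap_matrix(mask, G, spacing, normal_axis=c)
            for a in range(3):
                M = self.D_scal[c] @ diagK @ D_norm[a]
                if a == c:
                    M = M + L
                blocks[c][a] = M
        self.A = sparse.bmat(blocks, format="csc")
        try:
            self._lu = splu(self.A)
        except RuntimeError as exc:  # pragma: no cover - singular assembly
            raise RuntimeError(f"elasticity operator factorization failed: {exc}") from exc

    def rhs(self, phi_T: np.ndarray) -> np.ndarray:
        phi = np.asarray(phi_T, dtype=float)[self.mask]
        return np.concatenate([self.mech.lambda2 * (D @ phi) for D in self.D_scal])

    def solve(self, phi_T: np.ndarray, tol: float = 1e-8) -> np.ndarray:
        """Displacement field (3, nx, ny, nz); zero outside the brain mask."""
        b = self.rhs(phi_T)
        x = self._lu.solve(b)
        bnorm = np.linalg.norm(b)
        res = np.linalg.norm(self.A @ x - b) / max(bnorm, 1.0)
        if not np.isfinite(res) or res > tol:
            raise RuntimeError(f"elasticity solve did not converge: relative residual {res:.3e}")
        u = np.zeros((3,) + self.grid.shape, dtype=float)
        for c in range(3):
            comp = np.zeros(self.grid.shape)
            comp[self.mask] = x[c * self.n:(c + 1) * self.n]
            u[c] = comp
        return u


def solve_displacement(phi_T: np.ndarray, mech: MechanicalParams, grid: Grid3D,
                       solver: ElasticitySolver | None = None) -> np.ndarray:
    if solver is None:
        solver = ElasticitySolver(grid, mech)
    return solver.solve(phi_T)


def von_mises(u: np.ndarray, mech: MechanicalParams, grid: Grid3D) -> np.ndarray:
    """Von Mises stress (kPa) from a displacement field by central differences.

    The isotropic stress is sigma = 2 G eps + lam tr(eps) I with Lame
    lam = 2 G nu / (1 - 2 nu); the von Mises invariant uses only its
    deviatoric part, so pure hydrostatic strain yields zero.
    """
    u = np.asarray(u, dtype=float)
    if u.shape != (3,) + grid.shape:
        raise ValueError("displacement shape mismatch")
    G = mech.G_field(grid)
    nu = mech.nu_field(grid)
    lam = 2.0 * G * nu / (1.0 - 2.0 * nu)
    spacing = grid.spacing
    eps = np.empty((3, 3) + grid.shape, dtype=float)
    grads = [np.gradient(u[c], *spacing, edge_order=1) for c in range(3)]
    for i in range(3):
        for j in range(3):
            eps[i, j] = 0.5 * (grads[i][j] + grads[j][i])
    tr = eps[0, 0] + eps[1, 1] + eps[2, 2]
    s2 = np.zeros(grid.shape)
    for i in range(3):
        for j in range(3):
            sig = 2.0 * G * eps[i, j]
            if i == j:
                sig = sig + lam * tr - (2.0 * G * tr + 3.0 * lam * tr) / 3.0
            s2 += sig ** 2
    vm = np.sqrt(1.5 * s2)
    vm[~grid.brain_mask] = 0.0
    return vm


def damp_diffusion(D0: float, lambda1: float, sigma_vm: np.ndarray) -> np.ndarray:
    """Stress-damped diffusion coefficient ``D = D0 exp(-lambda1 sigma_vm)``."""
    if D0 < 0:
        raise ValueError("D0 must be nonnegative")
    return D0 * np.exp(-lambda1 * np.asarray(sigma_vm, dtype=float))
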