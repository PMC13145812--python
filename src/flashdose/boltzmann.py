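"""Discrete ordinates transport: sweeps, source iteration and dose scoring.

The classical small-angle fluence is the fixed source.  Each source
iteration (i) rebuilds the large-angle scatter source from the current
total fluence, (ii) solves the streaming-plus-removal operator by
diamond-difference upwind sweeps with vacuum boundaries, and (iii) re-adds
the classical fluence, which no iteration may change.  Ten iterations are
the default.  Scattered transport runs on the 4x volume-averaged coarse
grid, where the smooth large-angle component is well resolved; callers
resample its dose to the fine grid and add the fine-grid classical dose.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # numba accelerates the sweeps; a pure-python fallback keeps tiny tests honest
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap(a[0]) if a and callable(a[0]) else wrap

from .cross_sections import CrossSectionSet
from .materials import StoppingPowerTable, water_stopping_power
from .phantom import VoxelGrid
from .quadrature import AngularQuadrature, EnergyGrid

__all__ = ["FluenceField", "scatter_source", "transport_sweep", "solve", "dose"]


@dataclass
class FluenceField:
    """Total fluence Phi = Phi_scat + Phi_classical on (energy, ordinate, voxel)."""

    phi: np.ndarray          # (nE, nOrd, ni, nj, nk)
    phi_classical: np.ndarray
    iterations: int
    negative_fixups: int = 0

    @property
    def phi_scat(self) -> np.ndarray:
        return self.phi - self.phi_classical

    def scalar(self) -> np.ndarray:
        """Scalar fluence (summed over ordinates and energies)."""
        return self.phi.sum(axis=(0, 1))


def scatter_source(phi: np.ndarray, xs: CrossSectionSet, grid: VoxelGrid) -> np.ndarray:
    """Large-angle scatter source Q from the current total fluence.

    Q = rho_e * (Phi @ M_moller) + rho_c * (Phi @ M_mott), linear in Phi.
    """
    nE, nA = xs.egrid.n, xs.quad.n
    shape = phi.shape[2:]
    flat = phi.reshape(nE * nA, -1).T  # (nvox, nM)
    q_mol = (flat @ xs.moller).astype(np.float32)
    q_mot = (flat @ xs.mott).astype(np.float32)
    rho_e = np.asarray(grid.rho_e, np.float32).reshape(-1, 1)
    rho_c = np.asarray(grid.rho_c, np.float32).reshape(-1, 1)
    q = rho_e * q_mol + rho_c * q_mot
    return q.T.reshape(nE, nA, *shape)


@njit(cache=True, fastmath=True)
def _sweep_kernel(q, phi, mu, eta, xi, sig_e, sig_c, rho_e, rho_c, dx, dy, dz):
    nM, nx, ny, nz = q.shape
    nfix = 0
    for m in range(nM):
        am = abs(mu[m])
        ae = abs(eta[m])
        ax = abs(xi[m])
        cx = 2.0 * am / dx
        cy = 2.0 * ae / dy
        cz = 2.0 * ax / dz
        sx = 1 if mu[m] >= 0 else -1
        sy = 1 if eta[m] >= 0 else -1
        sz = 1 if xi[m] >= 0 else -1
        i0 = 0 if sx > 0 else nx - 1
        j0 = 0 if sy > 0 else ny - 1
        k0 = 0 if sz > 0 else nz - 1
        fx = np.zeros((ny, nz), dtype=np.float32)   # incoming x-face
        for ii in range(nx):
            i = i0 + sx * ii
            fy = np.zeros(nz, dtype=np.float32)      # incoming y-face
            for jj in range(ny):
                j = j0 + sy * jj
                fz = np.float32(0.0)                  # incoming z-face
                for kk in range(nz):
                    k = k0 + sz * kk
                    sigma = rho_e[i, j, k] * sig_e[m] + rho_c[i, j, k] * sig_c[m]
                    num = cx * fx[j, k] + cy * fy[k] + cz * fz + q[m, i, j, k]
                    den = cx + cy + cz + sigma
                    center = num / den
                    phi[m, i, j, k] = center
                    ox = 2.0 * center - fx[j, k]
                    oy = 2.0 * center - fy[k]
                    oz = 2.0 * center - fz
                    if ox < 0.0:
                        ox = 0.0
                        nfix += 1
                    if oy < 0.0:
                        oy = 0.0
                        nfix += 1
                    if oz < 0.0:
                        oz = 0.0
                        nfix += 1
                    fx[j, k] = ox
                    fy[k] = oy
                    fz = oz
    return nfix


def transport_sweep(
    q: np.ndarray,
    xs: CrossSectionSet,
    grid: VoxelGrid,
    quad: AngularQuadrature,
) -> tuple[np.ndarray, int]:
    """One diamond-difference upwind sweep of all ordinates and energies.

    Vacuum (zero) inflow on all faces; negative outgoing face fluxes are
    clamped to zero and counted.  Returns (Phi_scat, fixup count).
    """
    nE, nA = xs.egrid.n, quad.n
    shape = q.shape[2:]
    qf = np.ascontiguousarray(q.reshape(nE * nA, *shape), dtype=np.float32)
    phi = np.zeros_like(qf)
    mu = np.repeat(quad.mu[None, :], nE, 0).ravel()
    eta = np.repeat(quad.eta[None, :], nE, 0).ravel()
    xi = np.repeat(quad.xi[None, :], nE, 0).ravel()
    nfix = _sweep_kernel(
        qf, phi, mu, eta, xi,
        xs.sigma_moller_tot.ravel().astype(np.float64),
        xs.sigma_mott_tot.ravel().astype(np.float64),
        np.asarray(grid.rho_e, np.float32), np.asarray(grid.rho_c, np.float32),
        float(grid.spacing[0]), float(grid.spacing[1]), float(grid.spacing[2]),
    )
    return phi.reshape(nE, nA, *shape), int(nfix)


def solve(
    phi_classical: np.ndarray,
    xs: CrossSectionSet,
    grid: VoxelGrid,
    quad: AngularQuadrature,
    n_iter: int = 10,
    callback=None,
) -> FluenceField:
    """Source iteration: Q <- scatter(Phi); Phi_scat <- sweep(Q); Phi <- Phi_scat + classical."""
    phi_classical = np.asarray(phi_classical, np.float32)
    phi = phi_classical.copy()
    nfix_total = 0
    for it in range(n_iter):
        q = scatter_source(phi, xs, grid)
        phi_scat, nfix = transport_sweep(q, xs, grid, quad)
        nfix_total += nfix
        phi = phi_scat + phi_classical
        if callback is not None:
            callback(it + 1, phi)
    return FluenceField(phi, phi_classical, n_iter, nfix_total)


def dose(
    field: FluenceField | np.ndarray,
    grid: VoxelGrid,
    egrid: EnergyGrid,
    table: StoppingPowerTable | None = None,
) -> np.ndarray:
    """Absorbed dose: fluence times mass collision stopping power.

    D(r) = sum_e S(E_e) sum_n Phi(r, Omega_n, E_e); vacuum voxels score
    zero.  Units follow the fluence normalisation (relative dose).
    """
    if table is None:
        table = water_stopping_power()
    phi = field.phi if isinstance(field, FluenceField) else field
    S = table(egrid.centers)  # MeV cm^2 / g
    d = np.tensordot(S, phi.sum(axis=1), axes=(0, 0))
    d = np.asarray(d, np.float64)
    d[np.asarray(grid.rho) <= 0] = 0.0
    return d
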