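"""Gaussian pencil-beam source and the classical (fixed) fluence model.

The incident beam is a quasi-parallel elliptical Gaussian.  Along each
pencil-beam ray the engine tracks, by Fermi-Eyges moments of the local
scattering power T:

* the mean square angular spread  theta2(z) = theta2_i + int_0^z T(u) du,
* the mean square radial spread   r2(z) = r2_i + int_0^z (z-u)^2 T(u) du,
* the CSDA residual energy E(z),
* the scalar depth fluence phi_z(z), an empirical transmission-plus-buildup
  product evaluated at radiological depth.

The classical fluence is the product phi_r * phi_theta * phi_z.  It is the
fixed source of the Boltzmann solver and carries the multiple small-angle
scattering that discrete ordinates cannot resolve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .materials import (
    StoppingPowerTable,
    material_for_density,
    mass_scattering_power,
    extrapolated_range,
    water_stopping_power,
)
from .phantom import VoxelGrid, trace_ray
from .quadrature import AngularQuadrature, EnergyGrid

__all__ = [
    "BeamSource",
    "EnergySpectrum",
    "RayState",
    "angular_spread",
    "radial_spread",
    "angular_fluence",
    "depth_fluence",
    "OrdinateProjector",
    "ordinate_weights",
    "compute_ray_state",
    "classical_fluence",
    "classical_scalar_field",
    "beam_direction",
]

#: granularity of the Gaussian kernel bank in mean square width (mm^2)
KERNEL_MSQ_STEP = 0.1


def beam_direction(gantry_deg: float, couch_deg: float) -> np.ndarray:
    """Unit beam direction: gantry is the polar angle from +z, couch the azimuth."""
    g = np.deg2rad(gantry_deg)
    c = np.deg2rad(couch_deg)
    return np.array([np.sin(g) * np.cos(c), np.sin(g) * np.sin(c), np.cos(g)])


@dataclass
class EnergySpectrum:
    """Truncated Gaussian energy spectrum of the accelerator."""

    peak_MeV: float = 17.5
    fwhm_MeV: float = 0.3
    bounds_MeV: tuple[float, float] = (17.0, 18.0)

    def components(self, n_sub: int = 3) -> tuple[np.ndarray, np.ndarray]:
        """Discretize into n_sub equal-width sub-bins (energies, weights).

        Weights are the truncated-Gaussian masses of the sub-bins,
        renormalised to 1; zero weight falls outside the truncation bounds.
        """
        lo, hi = self.bounds_MeV
        sigma = self.fwhm_MeV / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        edges = np.linspace(lo, hi, n_sub + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        from scipy.stats import norm

        mass = norm.cdf(edges[1:], self.peak_MeV, sigma) - norm.cdf(edges[:-1], self.peak_MeV, sigma)
        w = mass / mass.sum()
        return centers, w

    def solver_weights(self, egrid: EnergyGrid, n_sub: int = 64) -> np.ndarray:
        """Spectrum projected onto the solver energy grid (sums to 1)."""
        E, w = self.components(n_sub)
        out = np.zeros(egrid.n)
        np.add.at(out, egrid.nearest_bin(E), w)
        return out


@dataclass
class BeamSource:
    """Quasi-parallel scanned Gaussian beam."""

    gantry_deg: float = 0.0
    couch_deg: float = 0.0
    isocenter: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sad_mm: float = 10_000.0
    sigma_x: float = 3.8
    sigma_y: float = 5.4
    theta_i_sq: float = 0.0  # parallel incident beam
    spectrum: EnergySpectrum = field(default_factory=EnergySpectrum)
    b: float = 2.0
    c: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("incident Gaussian widths must be positive")
        self.isocenter = np.asarray(self.isocenter, dtype=float)

    @property
    def direction(self) -> np.ndarray:
        return beam_direction(self.gantry_deg, self.couch_deg)

    def bev_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Orthonormal (u, v) basis of the beam's-eye-view plane."""
        d = self.direction
        ref = np.array([0.0, 0.0, 1.0])
        if abs(d @ ref) > 0.999:
            ref = np.array([1.0, 0.0, 0.0])
        u = np.cross(ref, d)
        u /= np.linalg.norm(u)
        v = np.cross(d, u)
        return u, v

    def spot_origin(self, x_mm: float, y_mm: float) -> np.ndarray:
        """A point on the spot's (parallel) ray, offset in the BEV plane."""
        u, v = self.bev_basis()
        return self.isocenter + x_mm * u + y_mm * v

    @property
    def r_i_sq(self) -> float:
        """Initial mean square radial spread <r^2> = sigma_x^2 + sigma_y^2."""
        return self.sigma_x**2 + self.sigma_y**2


def angular_spread(u: np.ndarray, T: np.ndarray, z: float, theta_i_sq: float = 0.0) -> float:
    """theta2(z) = theta2_i + int_0^z T(u) du by composite trapezoid."""
    u = np.asarray(u, float)
    T = np.asarray(T, float)
    if z <= 0:
        return theta_i_sq
    zz = np.concatenate([u[u < z], [z]])
    TT = np.concatenate([T[u < z], [np.interp(z, u, T)]])
    return theta_i_sq + float(np.trapezoid(TT, zz))


def radial_spread(u: np.ndarray, T: np.ndarray, z: float, r_i_sq: float = 0.0) -> float:
    """r2(z) = r2_i + int_0^z (z-u)^2 T(u) du by composite trapezoid."""
    u = np.asarray(u, float)
    T = np.asarray(T, float)
    if z <= 0:
        return r_i_sq
    zz = np.concatenate([u[u < z], [z]])
    TT = np.concatenate([T[u < z], [np.interp(z, u, T)]])
    return r_i_sq + float(np.trapezoid((z - zz) ** 2 * TT, zz))


def angular_fluence(theta: float | np.ndarray, theta_sq: float) -> np.ndarray:
    """Angular fluence phi_theta = (1/cos t)(1/(pi theta2)) exp(-t^2/theta2).

    The 1/cos factor converts planar to scalar fluence; the exponent uses
    the mean square directly (the Gaussian variance is half the mean
    square).  A zero spread is the delta-distribution limit and must be
    handled by the discretisation, not here.
    """
    theta = np.asarray(theta, float)
    if np.any(np.abs(theta) >= np.pi / 2):
        raise ValueError("angular fluence is defined for |theta| < pi/2")
    if theta_sq <= 0:
        raise ValueError("theta_sq must be positive (delta limit handled by caller)")
    return (1.0 / np.cos(theta)) * np.exp(-(theta**2) / theta_sq) / (np.pi * theta_sq)


def depth_fluence(z: float | np.ndarray, R_ex: float, b: float = 2.0, c: float = 0.1) -> np.ndarray:
    """Scalar depth fluence phi_z at radiological depth z (mm).

        phi_z = exp(-(1 - 1/b)^(1-b) (z/R_ex)^b) (1 + c z^(1/b))

    The exponential is the transmission of unscattered fluence, the bracket
    the buildup of scattered fluence.
    """
    if R_ex <= 0:
        raise ValueError("extrapolated range must be positive")
    z = np.asarray(z, float)
    k = (1.0 - 1.0 / b) ** (1.0 - b)
    return np.exp(-k * (z / R_ex) ** b) * (1.0 + c * np.maximum(z, 0.0) ** (1.0 / b))


class OrdinateProjector:
    """Bins the forward Gaussian angular fluence onto the quadrature.

    A dense equal-area lattice of forward-hemisphere directions around the
    beam axis is assigned once to its nearest ordinates; each angular
    spread then only reweights the lattice with the Gaussian profile.  This
    conserves the per-ordinate (Voronoi patch) mass, which a midpoint rule
    does not for spreads narrower than the ordinate spacing.
    """

    def __init__(self, quad: AngularQuadrature, axis: np.ndarray, n_dense: int = 16384):
        self.quad = quad
        axis = np.asarray(axis, float)
        # spherical Fibonacci lattice on the forward hemisphere around +axis
        i = np.arange(n_dense) + 0.5
        cos_t = 1.0 - i / n_dense        # equal-area in cos(theta), (0, 1]
        theta = np.arccos(cos_t)
        phi = np.pi * (1.0 + np.sqrt(5.0)) * i
        local = np.stack([np.sin(theta) * np.cos(phi),
                          np.sin(theta) * np.sin(phi), cos_t], axis=1)
        # rotate local +z onto the beam axis
        ref = np.array([0.0, 0.0, 1.0])
        if abs(axis @ ref) > 0.999:
            R = np.eye(3) * np.sign(axis @ ref)
            if axis @ ref < 0:
                R = -np.eye(3)
        else:
            w = np.cross(ref, axis)
            s = np.linalg.norm(w)
            c = float(ref @ axis)
            W = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
            R = np.eye(3) + W + W @ W * ((1 - c) / s**2)
        dirs = local @ R.T
        self.theta = theta
        self.nearest = np.argmax(dirs @ quad.directions.T, axis=1)
        self._fwd_ordinate = int(np.argmax(quad.directions @ axis))

    def weights(self, theta_sq: float) -> np.ndarray:
        if theta_sq <= 1e-12:
            out = np.zeros(self.quad.n)
            out[self._fwd_ordinate] = 1.0
            return out
        dens = np.exp(-self.theta**2 / theta_sq) / np.cos(self.theta)
        out = np.bincount(self.nearest, weights=dens, minlength=self.quad.n)
        return out / out.sum()

    def weight_table(self, theta_sq_values: np.ndarray) -> np.ndarray:
        return np.stack([self.weights(float(t)) for t in theta_sq_values])


def ordinate_weights(quad: AngularQuadrature, axis: np.ndarray, theta_sq: float) -> np.ndarray:
    """Project the angular fluence onto the ordinates; weights sum to 1.

    For theta_sq -> 0 all weight is assigned to the most forward ordinate
    (delta-distribution convention).
    """
    return OrdinateProjector(quad, axis).weights(theta_sq)


@dataclass
class RayState:
    """Classical fluence state sampled along one pencil-beam ray.

    Arrays are sampled at segment midpoints of the voxel traversal;
    ``z_geom`` is geometric depth from the grid entry point, ``z_rad`` the
    corresponding radiological depth.
    """

    z_geom: np.ndarray
    z_rad: np.ndarray
    E: np.ndarray          # residual CSDA energy, MeV
    theta_sq: np.ndarray   # rad^2
    r_sq_add: np.ndarray   # scattering contribution to <r^2>, mm^2
    phi_z: np.ndarray
    entry_point: np.ndarray
    direction: np.ndarray
    R_ex: float
    E0: float
    b: float = 2.0
    c: float = 0.1

    def interp(self, z: np.ndarray, name: str) -> np.ndarray:
        arr = getattr(self, name)
        left = {"E": self.E0, "theta_sq": 0.0, "r_sq_add": 0.0, "phi_z": 1.0,
                "z_rad": 0.0}[name]
        return np.interp(z, self.z_geom, arr, left=left, right=arr[-1] if len(arr) else left)


def compute_ray_state(
    grid: VoxelGrid,
    origin: np.ndarray,
    direction: np.ndarray,
    E0: float,
    table: StoppingPowerTable | None = None,
    R_ex: float | None = None,
    S_field: float | None = None,
    b: float = 2.0,
    c: float = 0.1,
    theta_i_sq: float = 0.0,
) -> RayState | None:
    """Trace one ray and integrate energy, spread moments and depth fluence.

    ``origin`` may be outside the grid; depths are measured from the grid
    entry point.  Returns None if the ray misses the grid.
    """
    if table is None:
        table = water_stopping_power()
    trace = trace_ray(grid, origin, direction)
    if len(trace) == 0:
        return None
    if R_ex is None:
        if S_field is None:
            S_field = 100.0
        R_ex = extrapolated_range(E0, S_field)

    n = len(trace)
    z_geom = np.empty(n)
    z_rad = np.empty(n)
    E = np.empty(n)
    theta_sq = np.empty(n)
    r_sq_add = np.empty(n)

    # cumulative moments of T for the (z - u)^2 lever arm
    m0 = m1 = m2 = 0.0
    th2 = theta_i_sq
    zg = zr = 0.0
    e = E0
    idx = trace.indices
    for s in range(n):
        i, j, k = idx[s]
        rho = float(grid.rho[i, j, k])
        rho_e = float(grid.rho_e[i, j, k])
        seg = float(trace.lengths[s])
        seg_rad = float(trace.rad_lengths[s])
        mat = material_for_density(rho)
        if e > 0 and rho > 0:
            # midpoint energy of the segment for second-order accuracy
            if rho_e > 0:
                s_half = float(table.linear_mm(e, rho=1.0))
                e_mid = max(e - 0.5 * seg_rad * s_half * rho / rho_e, 0.0)
            else:
                e_mid = e
            t_lin = mass_scattering_power(mat, max(e_mid, 0.2)) * rho * 0.1  # rad^2 / mm
        else:
            t_lin = 0.0
        zmid = zg + seg / 2.0
        # midpoint contribution of this segment to the moments
        m0_mid = m0 + t_lin * seg / 2.0
        m1_mid = m1 + t_lin * seg / 2.0 * zmid
        m2_mid = m2 + t_lin * seg / 2.0 * zmid**2
        z_geom[s] = zmid
        z_rad[s] = zr + seg_rad / 2.0
        E[s] = e_mid if (e > 0 and rho > 0) else e
        theta_sq[s] = th2 + t_lin * seg / 2.0
        r_sq_add[s] = zmid**2 * m0_mid - 2.0 * zmid * m1_mid + m2_mid
        # advance to segment end
        m0 += t_lin * seg
        m1 += t_lin * seg * zmid
        m2 += t_lin * seg * zmid**2
        th2 += t_lin * seg
        zg += seg
        zr += seg_rad
        if e > 0 and rho_e > 0:
            s_lin = float(table.linear_mm(e_mid if rho > 0 else e, rho=1.0))
            e = max(e - seg_rad * s_lin * rho / rho_e, 0.0)

    phi_z = depth_fluence(z_rad, R_ex, b, c)
    entry = np.asarray(origin, float) + trace.entry_t * np.asarray(direction, float)
    return RayState(z_geom, z_rad, E, theta_sq, r_sq_add, phi_z,
                    entry, np.asarray(direction, float), R_ex, E0, b, c)


def _quantize_msq(v: np.ndarray, step: float = KERNEL_MSQ_STEP) -> np.ndarray:
    """Nearest entry of the Gaussian kernel bank (mean square width ladder)."""
    return np.maximum(np.rint(v / step), 1.0) * step


def classical_scalar_field(
    beam: BeamSource,
    grid: VoxelGrid,
    spots: list[tuple[float, float, float]] | None = None,
    table: StoppingPowerTable | None = None,
    S_field: float | None = None,
    n_sub: int = 3,
    with_dose: bool = False,
) -> dict:
    """Scalar classical fluence (and optionally dose) on a voxel grid.

    ``spots`` is a list of (x_mm, y_mm, weight) in the beam's-eye view;
    default is a single unit-weight central spot.  Returns a dict with
    ``fluence`` (mm^-2 scalar classical fluence), ``dose`` (MeV cm^2 g^-1
    per mm^2, i.e. relative dose; only if requested) and per-spot ray
    states.
    """
    if table is None:
        table = water_stopping_power()
    if spots is None:
        spots = [(0.0, 0.0, 1.0)]
    u, v = beam.bev_basis()
    d = beam.direction
    comps_E, comps_w = beam.spectrum.components(n_sub)
    if S_field is None:
        if len(spots) > 1:
            xs = np.array([s[0] for s in spots])
            ys = np.array([s[1] for s in spots])
            span = max(np.ptp(xs), np.ptp(ys)) + 4.0
            S_field = max(span, 4.0)
        else:
            S_field = 2.355 * np.sqrt(beam.sigma_x * beam.sigma_y)  # FWHM-equivalent square

    X, Y, Z = grid.center_mesh()
    P = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    fluence = np.zeros(len(P), dtype=np.float64)
    dose = np.zeros(len(P), dtype=np.float64) if with_dose else None
    states: list[RayState] = []

    far = 2.0 * float(np.linalg.norm(grid.extent - grid.origin))
    missed = 0
    for sx, sy, w_spot in spots:
        if w_spot == 0.0:
            continue
        spot_pt = beam.spot_origin(sx, sy)
        ray_origin = spot_pt - far * d
        state0 = None
        for E0, w_c in zip(comps_E, comps_w):
            state = compute_ray_state(grid, ray_origin, d, E0, table,
                                      S_field=S_field, b=beam.b, c=beam.c,
                                      theta_i_sq=beam.theta_i_sq)
            if state is None:
                missed += 1
                break
            if state0 is None:
                state0 = state
                rel = P - state.entry_point
                z = rel @ d
                a_u = rel @ u
                a_v = rel @ v
                inside = z >= 0
            r2a = _quantize_msq(state.interp(z, "r_sq_add"))
            var_x = beam.sigma_x**2 + r2a / 2.0
            var_y = beam.sigma_y**2 + r2a / 2.0
            g = np.exp(-(a_u**2) / (2 * var_x) - (a_v**2) / (2 * var_y)) \
                / (2 * np.pi * np.sqrt(var_x * var_y))
            phi = w_spot * w_c * g * state.interp(z, "phi_z") * inside
            fluence += phi
            if with_dose:
                E_here = state.interp(z, "E")
                dose += phi * table(np.maximum(E_here, table.energy_MeV[0]))
        if state0 is not None:
            states.append(state0)
    if missed:
        warnings.warn(f"{missed} spot/component rays missed the grid; contributing zero")

    out = {"fluence": fluence.reshape(grid.shape).astype(np.float32), "states": states,
           "S_field": S_field}
    if with_dose:
        dose = dose.reshape(grid.shape)
        dose[np.asarray(grid.rho) <= 0] = 0.0
        out["dose"] = dose.astype(np.float32)
    return out


def classical_fluence(
    beam: BeamSource,
    grid: VoxelGrid,
    quad: AngularQuadrature,
    egrid: EnergyGrid,
    spots: list[tuple[float, float, float]] | None = None,
    table: StoppingPowerTable | None = None,
    S_field: float | None = None,
    n_sub: int = 3,
) -> np.ndarray:
    """Classical fluence resolved on (energy ordinate, angle ordinate, voxel).

    The scalar fluence of each spot and spectrum component is distributed
    over the angular ordinates with the depth-local angular spread and
    assigned to the energy ordinate nearest the local CSDA energy.  Summing
    the result over ordinates and energies recovers the scalar field.
    """
    if table is None:
        table = water_stopping_power()
    if spots is None:
        spots = [(0.0, 0.0, 1.0)]
    u, v = beam.bev_basis()
    d = beam.direction
    comps_E, comps_w = beam.spectrum.components(n_sub)
    if S_field is None:
        S_field = classical_scalar_field(beam, grid, spots, table, None, 1)["S_field"]

    projector = OrdinateProjector(quad, d)
    nvox = int(np.prod(grid.shape))
    Phi = np.zeros((egrid.n, quad.n, nvox), dtype=np.float32)
    X, Y, Z = grid.center_mesh()
    P = np.stack([X, Y, Z], axis=-1).reshape(-1, 3)
    far = 2.0 * float(np.linalg.norm(grid.extent - grid.origin))

    for sx, sy, w_spot in spots:
        if w_spot == 0.0:
            continue
        spot_pt = beam.spot_origin(sx, sy)
        ray_origin = spot_pt - far * d
        for E0, w_c in zip(comps_E, comps_w):
            state = compute_ray_state(grid, ray_origin, d, E0, table,
                                      S_field=S_field, b=beam.b, c=beam.c,
                                      theta_i_sq=beam.theta_i_sq)
            if state is None:
                continue
            rel = P - state.entry_point
            z = rel @ d
            inside = z >= 0
            a_u = rel @ u
            a_v = rel @ v
            r2a = _quantize_msq(state.interp(z, "r_sq_add"))
            var_x = beam.sigma_x**2 + r2a / 2.0
            var_y = beam.sigma_y**2 + r2a / 2.0
            g = np.exp(-(a_u**2) / (2 * var_x) - (a_v**2) / (2 * var_y)) \
                / (2 * np.pi * np.sqrt(var_x * var_y))
            scalar = w_spot * w_c * g * state.interp(z, "phi_z") * inside

            e_bin = egrid.nearest_bin(np.maximum(state.interp(z, "E"), egrid.centers[0]))
            # quantise the angular spread so ordinate weights are shared
            th2 = state.interp(z, "theta_sq")
            th2_q = np.round(th2 / 2e-3).astype(int)
            levels, level_of = np.unique(th2_q, return_inverse=True)
            w_table = projector.weight_table(levels * 2e-3)
            for li in range(len(levels)):
                sel = (level_of == li) & (scalar > 0)
                if not np.any(sel):
                    continue
                contrib = scalar[sel]
                bins = e_bin[sel]
                idx = np.flatnonzero(sel)
                for e in np.unique(bins):
                    m = bins == e
                    Phi[e][:, idx[m]] += np.outer(w_table[li], contrib[m]).astype(np.float32)
    return Phi.reshape(egrid.n, quad.n, *grid.shape)
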