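"""Moller and Mott cross sections discretised onto the solver ordinates.

The solver handles only *large-angle* scattering: deflections below an
angular cutoff (half the ordinate spacing by default) are already carried
by the classical small-angle fluence, so excluding them here prevents
double counting.

Moller (electron-electron) collisions link scattering angle and energy
exchange kinematically: an electron observed at kinetic energy E after
deflection by an angle theta from the incident direction must have come
from the initial energy

    T = 2 m E / ((E + 2m) cos^2(theta) - E),            m = 0.511 MeV

which is the free-electron collision relation.  By indistinguishability
the tracked outgoing electron is the faster one, so the energy transfer
never exceeds T/2 (E >= T/2): slower ejected electrons are not transported
-- their energy is already deposited locally through the unrestricted
collision stopping power.  Mott (electron-nucleus)
scattering is elastic, so it couples ordinates within one energy bin; the
differential form is a screened Rutherford cross section with the spin
factor and the orbital screening angle.

All macroscopic cross sections are per radiological mm of water; the voxel
rho_e / rho_c factors are applied by the scatter-source assembly.  The
scatter-out totals are accumulated from exactly the same discrete
redistribution coefficients, so particle balance between removal and
scatter-in holds to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse

from .materials import CONSTANTS, WATER, Material, beta_squared, screening_angles
from .quadrature import AngularQuadrature, EnergyGrid

__all__ = [
    "CrossSectionSet",
    "moller_dcs_energy",
    "moller_initial_energy",
    "moller_kinematics",
    "mott_dcs",
    "build_cross_sections",
]

M_E = CONSTANTS.electron_rest_MeV
#: default angular cutoff between the classical (small-angle) and solver
#: (large-angle) channels.  Deflections up to the ordinate spacing are
#: already represented by the classical Gaussian multiple-scattering model;
#: cutting just above it keeps the solver channel a genuine correction
#: instead of double counting the small-angle fluence.
DEFAULT_CUTOFF_DEG = 35.0
#: electrons per cm^3 of water
N_ELECTRON_WATER = 3.343e23
#: molecules ("atomic cores" reference unit) per cm^3 of water
N_CORE_WATER = CONSTANTS.N_A / WATER.M_A


def moller_dcs_energy(T: float, eps: float) -> float:
    """Moller cross section differential in energy transfer, cm^2/MeV per electron.

    ``T`` is the incident kinetic energy, ``eps`` the energy of one outgoing
    electron; the expression is symmetric under eps <-> T - eps.
    """
    if not 0 < eps < T:
        return 0.0
    tau = T / M_E
    b2 = float(beta_squared(T))
    x = eps / T
    bracket = (1.0 / x**2 + 1.0 / (1.0 - x) ** 2 + (tau / (tau + 1.0)) ** 2
               - (2.0 * tau + 1.0) / ((tau + 1.0) ** 2 * x * (1.0 - x)))
    if bracket <= 0:
        return 0.0
    C = 2.0 * np.pi * CONSTANTS.r_e_cm**2 * M_E / b2
    return C / T**2 * bracket


def moller_initial_energy(E_final: float, cos_theta: float) -> float | None:
    """Initial kinetic energy implied by an outgoing (E, theta) pair, or None.

    Inverts cos^2(theta) = E (T + 2m) / (T (E + 2m)); only deflections with
    cos(theta) > sqrt(E / (E + 2m)) are kinematically reachable, and the
    transfer T - E must not exceed T/2 (the tracked electron is the faster
    of the indistinguishable pair).
    """
    if cos_theta <= 0:
        return None
    denom = cos_theta**2 * (E_final + 2.0 * M_E) - E_final
    if denom <= 1e-12:
        return None
    T = 2.0 * M_E * E_final / denom
    if E_final < T / 2.0 - 1e-12:
        return None
    return T


def _moller_jacobian(T: float, cos_theta: float) -> float:
    """|d eps / d cos(theta)| at fixed T for the outgoing-electron relation."""
    A = T + 2.0 * M_E
    denom = A - T * cos_theta**2
    return 4.0 * M_E * T * A * abs(cos_theta) / denom**2


def moller_kinematics(E_final: float, cos_theta: float, egrid: EnergyGrid) -> list[tuple[int, float]]:
    """Initial-energy ordinate(s) feeding (E_final, theta), with fractions.

    Returns an empty list when the pair is kinematically impossible or the
    initial energy lies outside the grid; exact midpoints between two
    ordinates split 50/50.
    """
    if abs(cos_theta - 1.0) < 1e-12:
        return [(int(egrid.nearest_bin(E_final)), 1.0)]  # no interaction
    T = moller_initial_energy(E_final, cos_theta)
    if T is None:
        return []
    if T < egrid.edges[0] or T > egrid.edges[-1]:
        return []
    return egrid.nearest_split(T)


def mott_dcs(material: Material, E: float, cos_theta: float) -> float:
    """Screened Mott (elastic nuclear) cross section, cm^2/sr per atomic core."""
    tau = E / M_E
    b2 = float(beta_squared(E))
    _, theta_mu = screening_angles(material, tau, np.sqrt(b2))
    s2 = (1.0 - cos_theta) / 2.0  # sin^2(theta/2)
    screen = (theta_mu / 2.0) ** 2
    spin = 1.0 - b2 * s2
    pref = (material.Z * CONSTANTS.r_e_cm * (tau + 1.0) / (2.0 * tau * (tau + 2.0))) ** 2
    return pref * spin / (s2 + screen) ** 2


@dataclass
class CrossSectionSet:
    """Discrete scatter-in matrices and consistent scatter-out totals.

    ``moller`` and ``mott`` map flattened (energy, ordinate) fluence to
    scatter sources: Q_flat = rho_e * (Phi_flat @ moller) + rho_c *
    (Phi_flat @ mott).  ``sigma_moller_tot`` / ``sigma_mott_tot`` are the
    matching removal cross sections per (energy, ordinate), per
    radiological mm.
    """

    moller: sparse.csr_matrix
    mott: sparse.csr_matrix
    sigma_moller_tot: np.ndarray   # (nE, nOrd)
    sigma_mott_tot: np.ndarray     # (nE, nOrd)
    cutoff_deg: float
    egrid: EnergyGrid
    quad: AngularQuadrature


def build_cross_sections(
    quad: AngularQuadrature,
    egrid: EnergyGrid,
    cutoff_deg: float | None = None,
    material: Material = WATER,
) -> CrossSectionSet:
    """Assemble the discrete transfer matrices for the ordinate/energy grid."""
    if cutoff_deg is None:
        cutoff_deg = DEFAULT_CUTOFF_DEG
    cos_cut = np.cos(np.deg2rad(cutoff_deg))
    nE, nA = egrid.n, quad.n
    nM = nE * nA
    cos_tab = quad.cos_table()

    mol = sparse.lil_matrix((nM, nM), dtype=np.float64)
    mot = sparse.lil_matrix((nM, nM), dtype=np.float64)
    sig_mol = np.zeros((nE, nA))
    sig_mot = np.zeros((nE, nA))

    # macroscopic scaling per radiological mm of water
    k_mol = N_ELECTRON_WATER * 0.1
    k_mot = N_CORE_WATER * 0.1

    for n_in in range(nA):
        for n_out in range(nA):
            c = cos_tab[n_in, n_out]
            if c >= cos_cut:      # small-angle channel lives in the classical fluence
                continue
            w_out = quad.weights[n_out]
            # --- Mott: elastic, couples within each energy bin -------------
            for e in range(nE):
                E = egrid.centers[e]
                coeff = k_mot * mott_dcs(material, E, c) * w_out
                m_in = e * nA + n_in
                m_out = e * nA + n_out
                mot[m_in, m_out] += coeff
                sig_mot[e, n_in] += coeff
            # --- Moller: angle fixes the initial energy --------------------
            if c <= 0:
                continue
            for e_out in range(nE):
                E = egrid.centers[e_out]
                T = moller_initial_energy(E, c)
                if T is None or T < egrid.edges[0] or T > egrid.edges[-1]:
                    continue
                dcs = moller_dcs_energy(T, T - E) * _moller_jacobian(T, c) / (2.0 * np.pi)
                if dcs <= 0:
                    continue
                coeff = k_mol * dcs * w_out
                for e_in, frac in egrid.nearest_split(T):
                    m_in = e_in * nA + n_in
                    m_out = e_out * nA + n_out
                    mol[m_in, m_out] += coeff * frac
                    sig_mol[e_in, n_in] += coeff * frac

    return CrossSectionSet(mol.tocsr(), mot.tocsr(), sig_mol, sig_mot,
                           cutoff_deg, egrid, quad)
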