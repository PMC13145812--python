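"""Physical constants, material presets and electron interaction data.

The engine describes every material by its mass density ``rho`` (g cm^-3),
relative electron density ``rho_e`` (water = 1), relative atomic-core
density ``rho_c`` (water = 1) and an effective (Z, A, M_A) triple.  Electron
energy loss follows the continuous slowing down approximation (CSDA) with a
mass collision stopping power table for water, scaled to other media by
electron density.  Beam broadening uses the ICRU mass scattering power with
nuclear-size and orbital-screening cutoff angles.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

__all__ = [
    "CONSTANTS",
    "PhysicalConstants",
    "Material",
    "StoppingPowerTable",
    "WATER",
    "AIR",
    "BONE",
    "TISSUE",
    "material_for_density",
    "beta_squared",
    "screening_angles",
    "mass_scattering_power",
    "csda_step",
    "csda_range",
    "extrapolated_range",
    "water_stopping_power",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants used by the scattering-power and cross-section formulas."""

    r_e_cm: float = 2.8179403262e-13  # classical electron radius
    N_A: float = 6.02214076e23        # Avogadro's number, mol^-1
    alpha: float = 1.0 / 137.0        # fine structure constant
    electron_rest_MeV: float = 0.511  # electron rest energy


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class Material:
    """Bulk medium description.

    ``rho_e`` and ``rho_c`` are relative to water; ``Z`` is an effective
    atomic number, ``A`` the effective nucleon number and ``M_A`` the molar
    mass (g mol^-1) entering the scattering-power formula.
    """

    name: str
    rho: float          # g cm^-3
    rho_e: float        # relative electron density, water = 1
    rho_c: float        # relative atomic-core density, water = 1
    Z: float
    A: float
    M_A: float

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError(f"mass density must be >= 0, got {self.rho}")
        if self.rho_e < 0:
            raise ValueError(f"relative electron density must be >= 0, got {self.rho_e}")
        if self.rho > 0 and self.Z < 1:
            raise ValueError("effective Z must be >= 1 for matter")


# Effective compositions are an implementation choice: Z is the usual
# effective atomic number, A and M_A are set so that Z/A matches the
# material's electron content.  rho_c follows the rho_e convention
# (number of atomic cores relative to water).
WATER = Material("water", rho=1.0, rho_e=1.0, rho_c=1.0, Z=7.42, A=13.37, M_A=13.37)
TISSUE = Material("tissue", rho=1.0, rho_e=1.0, rho_c=1.0, Z=7.42, A=13.37, M_A=13.37)
AIR = Material("air", rho=1.2e-3, rho_e=1.1e-3, rho_c=1.0e-3, Z=7.64, A=14.78, M_A=14.78)
BONE = Material("bone", rho=1.85, rho_e=1.78, rho_c=1.91, Z=13.8, A=26.8, M_A=26.8)


def material_for_density(rho: float) -> Material:
    """Map a CT-like mass density to a preset material class.

    Thresholds: <= 0.05 g cm^-3 is air, >= 1.2 g cm^-3 is bone, anything in
    between is water-like tissue.
    """
    if rho <= 0.05:
        return AIR
    if rho >= 1.2:
        return BONE
    return WATER


class StoppingPowerTable:
    """Mass collision stopping power lookup, log-linear in energy.

    Energies below the table floor clamp to the floor value (the engine only
    scores dose from slowed-down electrons there, so the clamp is benign);
    energies above the ceiling clamp likewise.
    """

    def __init__(self, energy_MeV: np.ndarray, S_col: np.ndarray):
        energy_MeV = np.asarray(energy_MeV, dtype=float)
        S_col = np.asarray(S_col, dtype=float)
        if energy_MeV.ndim != 1 or energy_MeV.size < 2:
            raise ValueError("need at least two tabulated energies")
        if np.any(np.diff(energy_MeV) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(S_col <= 0):
            raise ValueError("stopping power must be positive")
        self.energy_MeV = energy_MeV
        self.S_col = S_col
        self._log_e = np.log(energy_MeV)

    def __call__(self, E: float | np.ndarray) -> np.ndarray:
        """Mass collision stopping power (MeV cm^2 g^-1) at energy E (MeV)."""
        E = np.clip(np.asarray(E, dtype=float), self.energy_MeV[0], self.energy_MeV[-1])
        return np.interp(np.log(E), self._log_e, self.S_col)

    def linear_mm(self, E: float | np.ndarray, rho: float = 1.0) -> np.ndarray:
        """Linear stopping power in MeV mm^-1 for a medium of density rho."""
        return self(E) * rho * 0.1


def water_stopping_power() -> StoppingPowerTable:
    """The embedded collision stopping power table for liquid water."""
    ref = importlib.resources.files("flashdose.data") / "water_stopping_power.csv"
    rows = [
        line.split(",")
        for line in ref.read_text().splitlines()
        if line and not line.startswith("#") and not line.startswith("energy")
    ]
    arr = np.array(rows, dtype=float)
    return StoppingPowerTable(arr[:, 0], arr[:, 1])


def beta_squared(E: float | np.ndarray) -> np.ndarray:
    """(v/c)^2 from kinetic energy E in MeV via tau = E / 0.511."""
    tau = np.asarray(E, dtype=float) / CONSTANTS.electron_rest_MeV
    return tau * (tau + 2.0) / (tau + 1.0) ** 2


def screening_angles(material: Material, tau: float, beta: float) -> tuple[float, float]:
    """Nuclear-size cutoff angle theta_m and orbital screening angle theta_mu.

    theta_m = 2 A^(-1/3) / (alpha beta (tau+1)) reflects the finite nuclear
    size; theta_mu = 1.130 alpha Z^(1/3) / (beta (tau+1)) the screening of
    the nuclear charge by orbital electrons.  Both in radians.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    if not 0 < beta < 1:
        raise ValueError(f"beta must be in (0, 1), got {beta}")
    denom = beta * (tau + 1.0)
    theta_m = 2.0 * material.A ** (-1.0 / 3.0) / (CONSTANTS.alpha * denom)
    theta_mu = 1.130 * CONSTANTS.alpha * material.Z ** (1.0 / 3.0) / denom
    return theta_m, theta_mu


def mass_scattering_power(material: Material, E: float) -> float:
    """Mass scattering power T/rho in radian^2 cm^2 g^-1 at energy E (MeV).

    ICRU-style small-angle multiple-scattering power:

        T/rho = pi (2 r_e Z / ((tau+1) beta^2))^2 (N_A / M_A)
                * { ln[1 + (theta_m/theta_mu)^2] - 1
                    + [1 + (theta_m/theta_mu)^2]^-1 }
    """
    if E <= 0:
        raise ValueError(f"energy must be positive, got {E}")
    tau = E / CONSTANTS.electron_rest_MeV
    b2 = float(beta_squared(E))
    beta = np.sqrt(b2)
    theta_m, theta_mu = screening_angles(material, tau, beta)
    x2 = (theta_m / theta_mu) ** 2
    bracket = np.log1p(x2) - 1.0 + 1.0 / (1.0 + x2)
    pref = np.pi * (2.0 * CONSTANTS.r_e_cm * material.Z / ((tau + 1.0) * b2)) ** 2
    return float(pref * (CONSTANTS.N_A / material.M_A) * bracket)


def scattering_power_per_mm(material: Material, E: float) -> float:
    """Linear scattering power T = (T/rho) * rho in radian^2 mm^-1."""
    return mass_scattering_power(material, E) * material.rho * 0.1


def csda_step(
    E0: float,
    dr_mm: float,
    material: Material = WATER,
    table: StoppingPowerTable | None = None,
) -> float:
    """One CSDA step over a radiological path increment dr_mm.

        E1 = E0 - dr * S(E0) * rho / rho_e   (clamped at zero)

    ``dr_mm`` is radiological path length; the rho/rho_e factor converts it
    to the physical path length over which the stopping power acts.
    """
    if E0 <= 0:
        return 0.0
    if dr_mm < 0:
        raise ValueError(f"path increment must be >= 0, got {dr_mm}")
    if table is None:
        table = water_stopping_power()
    if material.rho_e == 0:
        return E0  # vacuum: no energy loss
    s_lin = float(table.linear_mm(E0, rho=1.0))  # MeV per radiological mm of water
    E1 = E0 - dr_mm * s_lin * material.rho / material.rho_e
    return max(E1, 0.0)


def csda_range(E0: float, table: StoppingPowerTable | None = None, dr: float = 0.01) -> float:
    """Radiological CSDA range (mm) in water by fine-step integration."""
    if table is None:
        table = water_stopping_power()
    E, z = E0, 0.0
    while E > 0:
        E = csda_step(E, dr, WATER, table)
        z += dr
        if z > 1e4:  # pragma: no cover - guards a bad table
            raise RuntimeError("CSDA range integration did not terminate")
    return z


def extrapolated_range(E: float, S_field: float) -> float:
    """Extrapolated practical range R_ex (mm) for beam energy E (MeV).

        R_ex = 2.825 (1.0 + 0.0714 sqrt(S)) E

    with S the equivalent square field size in mm.
    """
    if E <= 0:
        raise ValueError(f"energy must be positive, got {E}")
    if S_field <= 0:
        raise ValueError(f"field size must be positive, got {S_field}")
    return 2.825 * (1.0 + 0.0714 * np.sqrt(S_field)) * E
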