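"""Discrete ordinates quadrature and the solver energy grid.

Ordinates are generated from a gantry x couch angle lattice: the gantry
angle acts as the polar angle from the +z axis and the couch angle as the
azimuth, both stepped at the same spacing.  Duplicate directions (the
poles, and the lower polar half of the lattice which re-creates existing
directions) are merged, and each surviving ordinate is weighted by the area
of its spherical patch so the weights partition 4*pi exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AngularQuadrature", "EnergyGrid", "build_quadrature"]


@dataclass
class AngularQuadrature:
    directions: np.ndarray   # (N, 3) unit vectors
    weights: np.ndarray      # (N,), sum = 4*pi
    spacing_deg: float

    @property
    def n(self) -> int:
        return len(self.weights)

    @property
    def mu(self) -> np.ndarray:
        return self.directions[:, 0]

    @property
    def eta(self) -> np.ndarray:
        return self.directions[:, 1]

    @property
    def xi(self) -> np.ndarray:
        return self.directions[:, 2]

    def cos_table(self) -> np.ndarray:
        """(N, N) table of Omega_n' . Omega_n, clipped to [-1, 1]."""
        return np.clip(self.directions @ self.directions.T, -1.0, 1.0)

    def angles_to(self, axis: np.ndarray) -> np.ndarray:
        """Angle (rad) of every ordinate to a given unit vector."""
        c = np.clip(self.directions @ np.asarray(axis, float), -1.0, 1.0)
        return np.arccos(c)


def build_quadrature(spacing_deg: float = 30.0) -> AngularQuadrature:
    """Ordinates on the gantry x couch lattice with patch-area weights."""
    if spacing_deg <= 0 or 360.0 % spacing_deg != 0:
        raise ValueError(f"spacing must divide 360, got {spacing_deg}")
    step = np.deg2rad(spacing_deg)
    polar = np.deg2rad(np.arange(0.0, 180.0 + 1e-9, spacing_deg))
    azim = np.deg2rad(np.arange(0.0, 360.0, spacing_deg))
    n_az = len(azim)

    dirs: list[np.ndarray] = []
    wts: list[float] = []
    for th in polar:
        lo = max(th - step / 2.0, 0.0)
        hi = min(th + step / 2.0, np.pi)
        band = np.cos(lo) - np.cos(hi)
        if th < 1e-12 or th > np.pi - 1e-12:
            # pole: all azimuths coincide -> single ordinate with the cap area
            dirs.append(np.array([0.0, 0.0, np.cos(th)]))
            wts.append(2.0 * np.pi * band)
            continue
        for ph in azim:
            dirs.append(np.array([np.sin(th) * np.cos(ph),
                                  np.sin(th) * np.sin(ph),
                                  np.cos(th)]))
            wts.append(step * band)

    directions = np.array(dirs)
    weights = np.array(wts)
    # merge any residual duplicates (robustness; the lattice above is unique)
    key = np.round(directions, 9)
    _, first, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
    merged_w = np.zeros(len(first))
    np.add.at(merged_w, inv, weights)
    order = np.argsort(first)
    directions = directions[first][order]
    weights = merged_w[order]
    return AngularQuadrature(directions, weights, spacing_deg)


@dataclass
class EnergyGrid:
    """Uniform energy ordinates, by default 1-18 MeV at 1 MeV spacing."""

    centers: np.ndarray
    spacing: float

    @classmethod
    def default(cls) -> "EnergyGrid":
        return cls(np.arange(1.0, 18.0 + 1e-9, 1.0), 1.0)

    @property
    def n(self) -> int:
        return len(self.centers)

    @property
    def edges(self) -> np.ndarray:
        return np.concatenate([self.centers - self.spacing / 2,
                               [self.centers[-1] + self.spacing / 2]])

    def nearest_bin(self, E: float | np.ndarray) -> np.ndarray:
        """Index of the nearest energy ordinate (clipped to the grid)."""
        idx = np.rint((np.asarray(E, float) - self.centers[0]) / self.spacing)
        return np.clip(idx, 0, self.n - 1).astype(int)

    def nearest_split(self, E: float) -> list[tuple[int, float]]:
        """Nearest ordinate(s) with fractions; exact midpoints split 50/50."""
        x = (E - self.centers[0]) / self.spacing
        lo = int(np.floor(x))
        frac = x - lo
        if abs(frac - 0.5) < 1e-12 and 0 <= lo and lo + 1 < self.n:
            return [(lo, 0.5), (lo + 1, 0.5)]
        idx = int(np.clip(round(x), 0, self.n - 1))
        return [(idx, 1.0)]
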