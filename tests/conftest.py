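"""Shared fixtures: quadrature, cross sections and solved water-tank case.

The water-tank solve is expensive (fine classical fluence on 100^3 voxels
plus twenty source iterations on the 4 mm coarse grid), so it is computed
once per session and shared by the solver and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from flashdose.beam_model import BeamSource, classical_fluence, classical_scalar_field
from flashdose.boltzmann import dose as boltzmann_dose
from flashdose.boltzmann import solve
from flashdose.cross_sections import build_cross_sections
from flashdose.materials import water_stopping_power
from flashdose.phantom import coarsen_grid, make_phantom
from flashdose.quadrature import EnergyGrid, build_quadrature


@pytest.fixture(scope="session")
def quad30():
    return build_quadrature(30.0)


@pytest.fixture(scope="session")
def egrid():
    return EnergyGrid.default()


@pytest.fixture(scope="session")
def xs30(quad30, egrid):
    return build_cross_sections(quad30, egrid)


@pytest.fixture(scope="session")
def stopping_table():
    return water_stopping_power()


@pytest.fixture(scope="session")
def watertank_case(quad30, egrid, xs30, stopping_table):
    """100 mm cube of water, central 17.5 MeV pencil beam, solved to 20 iterations.

    Captures the coarse-grid dose after iterations 10 and 20, the per-
    iteration total fluence sums, and the fine-grid classical fluence/dose.
    """
    phantom = make_phantom("watertank", shape=(100, 100, 100))
    grid = phantom.grid
    beam = BeamSource(gantry_deg=0.0, couch_deg=0.0,
                      isocenter=np.array([50.0, 50.0, 0.0]))
    fine = classical_scalar_field(beam, grid, with_dose=True)
    coarse = coarsen_grid(grid)
    phi_classical = classical_fluence(beam, coarse, quad30, egrid,
                                      S_field=fine["S_field"])

    doses = {}
    phi_sums = []

    def cb(it, phi):
        phi_sums.append(float(phi.sum()))
        if it in (10, 20):
            doses[it] = boltzmann_dose(phi, coarse, egrid, stopping_table)

    field = solve(phi_classical, xs30, coarse, quad30, n_iter=20, callback=cb)
    return {
        "phantom": phantom,
        "grid": grid,
        "coarse": coarse,
        "beam": beam,
        "fine": fine,
        "phi_classical": phi_classical,
        "field": field,
        "dose_iter10": doses[10],
        "dose_iter20": doses[20],
        "phi_sums": phi_sums,
        "dose_classical_coarse": boltzmann_dose(phi_classical, coarse, egrid,
                                                stopping_table),
    }


@pytest.fixture(scope="session")
def head_case():
    """Head phantom with a superficial 14 mm GTV, for planner tests."""
    return make_phantom("head", shape=(90, 90, 90), gtv_depth=15.0, gtv_diameter=14.0)
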