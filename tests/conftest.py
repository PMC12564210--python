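"""Shared fixtures: converged SCF runs reused across the suite.

The expensive runs (figure-preset grids) are session-scoped so that the
acceptance tests and the property tests measure the same solutions.
"""

from __future__ import annotations

import numpy as np
import pytest

from brushscf import BrushParameters, GraftArchitecture, solve_scf, topological_ratio
from brushscf.presets import (
    DC_N1_VALUES,
    FIG1_SIDE_CHAIN_LENGTHS,
    FORCE_H_GRID,
    MOMENT_GRID_ETA_SPECS,
    MOMENT_GRID_SIGMAS,
    get_preset,
)

FORCE_DH = 0.1


@pytest.fixture(scope="session")
def fig1_solutions():
    """Comb quartet (Nb=500, m=5, N*sigma=500): n -> (eta, sigma, solution)."""
    out = {}
    for run in get_preset("fig1").runs:
        n = run.arch.n1
        out[n] = (run.eta, run.params.sigma, solve_scf(run.arch, run.params))
    return out


@pytest.fixture(scope="session")
def force_grid_solutions():
    """Monodisperse comb (m=3, n=25, 20 arms): h -> solution on the force grid

    including the h +/- dh members used by the central-difference force.
    """
    arch = GraftArchitecture.comb(P=20, m=3, n=25)
    sols = {}
    for h in FORCE_H_GRID:
        for hh in (h - FORCE_DH, h, h + FORCE_DH):
            if hh not in sols:
                sols[hh] = solve_scf(arch, BrushParameters.from_spacing(hh))
    return arch, sols


@pytest.fixture(scope="session")
def moment_grid_solutions():
    """sigma x eta grid at N ~= 1000: list of (sigma, eta, solution)."""
    rows = []
    for sigma in MOMENT_GRID_SIGMAS:
        for eta, (P, m, n) in MOMENT_GRID_ETA_SPECS.items():
            arch = GraftArchitecture.comb(P=P, m=m, n=n)
            rows.append((sigma, eta, solve_scf(arch, BrushParameters(sigma=sigma))))
    return rows


@pytest.fixture(scope="session")
def dc_solutions():
    """Double-comb sweep at sigma=0.5: n1 -> solution (n1 + n2 = 50)."""
    out = {}
    for n1 in DC_N1_VALUES:
        arch = GraftArchitecture(P1=10, P2=10, m1=3, m2=3, n1=n1, n2=50 - n1)
        out[n1] = solve_scf(arch, BrushParameters(sigma=0.5))
    return out
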