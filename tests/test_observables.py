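"""Moments, dead-zone estimator, force, persistence length."""

import numpy as np
import pytest

from brushscf import (
    BrushParameters,
    GraftArchitecture,
    RadialProfile,
    SolverOptions,
    build_lattice,
    first_branch_distribution,
    mean_H,
    mean_He,
    dead_zone_width,
    persistence_length,
    solve_scf,
)
from brushscf.observables import ProfileKind, axial_force
from brushscf.fitting import fit_linear, fit_powerlaw
from tests.conftest import FORCE_DH


def _profile(values, kind=ProfileKind.DENSITY):
    lat = build_lattice(len(values))
    return RadialProfile(z=lat.z, values=np.asarray(values, float), L=lat.L, kind=kind)


def test_moments_on_delta_profiles():
    v = np.zeros(20)
    v[6] = 2.5  # shell z = 7
    assert mean_H(_profile(v)) == pytest.approx(7.0)
    e = np.zeros(20)
    e[9] = 1.0
    assert mean_He(_profile(e, ProfileKind.END_DISTRIBUTION)) == pytest.approx(10.0)
    # two equal deltas at z = 4 and 8: (16 + 64) / (4 + 8) with 2*pi*z weights
    g = np.zeros(20)
    g[3] = 1.0
    g[7] = 1.0
    assert mean_He(_profile(g, ProfileKind.END_DISTRIBUTION)) == pytest.approx(20 / 3)


def test_moment_of_uniform_profile():
    H = 400
    v = np.zeros(H + 50)
    v[:H] = 0.1
    assert mean_H(_profile(v)) == pytest.approx(2 / 3 * H, rel=2e-2)


def test_moment_of_exact_parabola_is_8_15():
    """Discretized parabola reproduces <H> = (8/15) H to 0.1% at H >= 100."""
    H = 150
    lat = build_lattice(160)
    z = lat.z
    v = np.where(z <= H, H**2 - z**2, 0.0)
    prof = RadialProfile(z=z, values=v, L=lat.L, kind=ProfileKind.DENSITY)
    assert mean_H(prof) == pytest.approx(8 / 15 * H, rel=1e-3)


def test_zero_mass_profile_has_no_moment():
    with pytest.raises(ValueError):
        mean_H(_profile(np.zeros(5)))


def test_dead_zone_width_bracketing_and_errors():
    g = np.zeros(30)
    g[11:] = 1.0  # support only at z >= 12
    z0 = dead_zone_width(_profile(g, ProfileKind.END_DISTRIBUTION))
    assert 11.0 < z0 < 12.0
    with pytest.raises(ValueError):
        dead_zone_width(_profile(np.zeros(5), ProfileKind.END_DISTRIBUTION))
    # threshold sensitivity is modest and monotone
    z0_half = dead_zone_width(_profile(g, ProfileKind.END_DISTRIBUTION), threshold=0.005)
    assert z0_half <= z0


def test_first_branch_distribution_normalization_and_support():
    # one branch at rank 2, zero field: the branch rank is one step from the
    # anchor, so its distribution is supported on shells {1, 2} only
    arch = GraftArchitecture(P1=1, P2=0, m1=2, m2=0, n1=3, n2=0)
    sol = solve_scf(arch, BrushParameters(sigma=1e-9),
                    options=SolverOptions(zmax=12))
    fb = first_branch_distribution(sol)
    assert fb.mass == pytest.approx(1e-9, rel=1e-6)
    w = fb.values * fb.L
    assert np.sum(w[:2]) / np.sum(w) == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        first_branch_distribution(
            solve_scf(GraftArchitecture.comb(P=3, m=2, n=0), BrushParameters(sigma=0.5))
        )


def test_axial_force_vanishes_for_isolated_grafts():
    arch = GraftArchitecture.comb(P=4, m=2, n=0)  # tiny ideal chain
    f = axial_force(arch, [50.0], dh=1.0)
    assert abs(f[0]) < 1e-4


def test_force_positive_and_scaling(force_grid_solutions):
    """Crowded combs pull on the backbone with f ~ h^(-3/2)."""
    arch, sols = force_grid_solutions
    grid = [2.0, 3.0, 4.0, 6.0, 8.0]
    f = axial_force(arch, grid, dh=FORCE_DH, solutions=sols)
    assert np.all(f > 0)
    fit = fit_powerlaw(grid, f)
    assert fit.exponent == pytest.approx(-1.5, abs=0.1)


def test_persistence_length_scaling(force_grid_solutions):
    """lp = F H^2 / h falls off as h^(-2)."""
    arch, sols = force_grid_solutions
    grid = [2.0, 3.0, 4.0, 6.0, 8.0]
    lp = [persistence_length(sols[h]) for h in grid]
    assert np.all(np.array(lp) > 0)
    fit = fit_powerlaw(grid, lp)
    assert fit.exponent == pytest.approx(-2.0, abs=0.1)


def test_proximal_heavy_dc_pulls_harder_than_peripheral_heavy(dc_solutions):
    """At equal N and h, mass in the proximal domain raises the axial tension.

    The free energy at fixed h orders the same way as the force for these
    monotone f(h) curves; compare the two extreme architectures directly.
    """
    dh = 0.05
    f = {}
    for n1 in (0, 50):
        arch = GraftArchitecture(P1=10, P2=10, m1=3, m2=3, n1=n1, n2=50 - n1)
        f[n1] = axial_force(arch, [2.0], dh=dh)[0]
    assert f[50] > f[0]


def test_mean_H_He_proportionality_monodisperse(moment_grid_solutions):
    """<H> and <He> are directly proportional across the comb grid."""
    H = [mean_H(s) for _, _, s in moment_grid_solutions]
    He = [mean_He(s) for _, _, s in moment_grid_solutions]
    fit = fit_linear(H, He)
    assert fit.r_squared > 0.995
    assert all(h < he for h, he in zip(H, He))


def test_analytic_mean_H_describes_scf_within_10pc(moment_grid_solutions):
    """SCF <H> vs the closed-form parabolic <H>: linear with unit slope."""
    from brushscf import theory

    Hs = [mean_H(s) for _, _, s in moment_grid_solutions]
    Ht = [
        theory.mean_H_analytic(s.arch.total_monomers, sigma, eta)
        for sigma, eta, s in moment_grid_solutions
    ]
    fit = fit_linear(Ht, Hs)
    assert fit.slope == pytest.approx(1.0, abs=0.1)
    assert np.allclose(np.array(Hs) / np.array(Ht), 1.0, atol=0.1)


def test_analytic_z0_lies_inside_scf_end_free_region(fig1_solutions):
    """The closed-form dead-zone boundary falls below the 1%-end radius."""
    from brushscf import theory

    for eta, sigma, sol in fig1_solutions.values():
        z0_analytic = theory.z0_and_H_widths(
            sol.arch.total_monomers, sigma, eta
        )[0]
        assert z0_analytic < dead_zone_width(sol)


def test_dc_potential_parabolic_in_end_zone(dc_solutions):
    """U(z) is linear in z^2 throughout the end-containing zone for every
    double-comb split, while the dead zone pulls the full-brush fit of the
    monodisperse comb away from a single straight line."""
    from brushscf import molecular_potential

    def parabola_r2(sol, from_z0):
        U = molecular_potential(sol).values
        z = sol.lattice.z
        z0 = dead_zone_width(sol)
        top = int(np.argmax(U < 0.05 * U[0])) or len(U)
        lo = int(z0) if from_z0 else 2
        return fit_linear(z[lo:top] ** 2, U[lo:top]).r_squared

    for sol in dc_solutions.values():
        assert parabola_r2(sol, from_z0=True) >= 0.99
    mono = dc_solutions[25]
    assert parabola_r2(mono, from_z0=False) < parabola_r2(mono, from_z0=True)


def test_first_branch_mode_shifts_outward_for_peripheral_heavy_dc(dc_solutions):
    """A massive peripheral domain stretches the root spacer outward."""
    def mean_fb(sol):
        return first_branch_distribution(sol).first_moment()

    assert mean_fb(dc_solutions[0]) > mean_fb(dc_solutions[50])
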