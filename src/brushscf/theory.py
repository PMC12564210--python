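"""Analytical theory of cylindrical comb brushes with a dead zone.

Strong-stretching SCF theory of a brush grafted to a line gives a parabolic
molecular potential U(z) = (3*pi^2/8) * (eta/N)^2 * (H^2 - z^2) and hence,
in a good solvent, a parabolic density phi = U/(2*nu).  On a *convex*
cylindrical brush the parabolic solution cannot support free ends near the
axis: an end-free "dead" zone of width z0 forms, inside which every graft
main chain is stretched and the density decays as a power law
phi ~ z^(-2/3).  This module implements:

* the no-dead-zone parabolic profile and its first moment <H> = (8/15) H;
* the dead-zone partition: the inner power-law profile (amplitude set by a
  scaling factor A), the outer shifted parabola, and the three matching
  conditions (continuity at z0, inner and outer mass normalization) solved
  numerically for (X, z0, H) with X the peripheral-zone mass fraction;
* closed-form expressions for X and z0/H re-derived from the same system,
  used as cross-checks of the numeric solution:

      z0/H = 2*pi*(1-X) / (3*sqrt(A)*X)
      X    = (12*pi^2 - 16*pi*sqrt(A)) / (12*pi^2 - 16*pi*sqrt(A) + 9*A)

* brush free energy per graft, axial force, and induced persistence length
  (lp/a = 0.046 * N * (a/h)^2 in the athermal case).

All lengths are in units of the monomer size a, energies in kBT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "AnalyticBrush",
    "DeadZoneSolution",
    "TheoryDomainError",
    "parabolic_height",
    "parabolic_profile",
    "solve_dead_zone",
    "dead_zone_profile",
    "mean_H_analytic",
    "free_energy_analytic",
    "axial_force_analytic",
    "free_energy_and_force_analytic",
    "persistence_length_analytic",
    "z0_and_H_widths",
    "dead_zone_ratio_closed_form",
    "peripheral_fraction_closed_form",
]

#: best-fit inner-zone scaling factor from SF-SCF profiles
A_BEST_FIT = 1.45


class TheoryDomainError(ValueError):
    """Raised when the analytic model has no solution for the parameters."""


def _check_solvent(nu: float) -> None:
    if nu <= 0:
        raise TheoryDomainError(f"good solvent required (nu > 0), got nu={nu}")


@dataclass(frozen=True)
class AnalyticBrush:
    """Parameter set of the analytic cylindrical brush model."""

    N: float
    sigma: float
    eta: float = 1.0
    nu: float = 0.5
    A: float = A_BEST_FIT

    def __post_init__(self) -> None:
        if self.N <= 0 or self.sigma <= 0 or self.A <= 0:
            raise TheoryDomainError("N, sigma and A must be positive")
        if self.eta < 1.0:
            raise TheoryDomainError(f"topological ratio eta must be >= 1, got {self.eta}")
        _check_solvent(self.nu)


def _c_inner(sigma: float, eta: float, nu: float, A: float) -> float:
    """Amplitude of the inner power law phi = c_in * z^(-2/3)."""
    return (3.0 * A * sigma**2 * eta**2 / (16.0 * nu * math.pi**2)) ** (1.0 / 3.0)


def _c_outer(N: float, X: float, eta: float, nu: float) -> float:
    """Amplitude of the outer parabola phi = c_out * (H^2 - (z-z0)^2)."""
    return 3.0 * math.pi**2 * eta**2 / (16.0 * nu * (N * X) ** 2)


def parabolic_height(N: float, sigma: float, eta: float = 1.0, nu: float = 0.5) -> float:
    """Brush thickness H of the no-dead-zone parabolic profile.

    From mass normalization of the cylindrical parabola:
    H = (32 nu / (3 pi^3))^(1/4) * N^(3/4) * sigma^(1/4) * eta^(-1/2).
    """
    _check_solvent(nu)
    return (32.0 * nu / (3.0 * math.pi**3)) ** 0.25 * N**0.75 * sigma**0.25 / math.sqrt(eta)


def parabolic_profile(N: float, sigma: float, eta: float = 1.0, nu: float = 0.5):
    """No-dead-zone parabolic profile.

    Returns ``(H, phi)`` where ``phi(z)`` evaluates the volume fraction
    (vectorized, zero outside [0, H]); its radial mass integral
    ``int phi 2 pi z dz`` equals N*sigma.
    """
    _check_solvent(nu)
    H = parabolic_height(N, sigma, eta, nu)
    c0 = 3.0 * math.pi**2 * eta**2 / (16.0 * nu * N**2)

    def phi(z):
        z = np.asarray(z, dtype=float)
        return np.where((z >= 0) & (z <= H), c0 * (H**2 - z**2), 0.0)

    return H, phi


@dataclass(frozen=True)
class DeadZoneSolution:
    """Self-consistent dead-zone partition of a convex cylindrical brush."""

    params: AnalyticBrush
    X: float      #: mass fraction in the peripheral (end-containing) zone
    z0: float     #: dead-zone width (units of a)
    H: float      #: peripheral-zone width (units of a)

    @property
    def ratio(self) -> float:
        """z0 / H."""
        return self.z0 / self.H

    @property
    def extent(self) -> float:
        """Total brush extent z0 + H."""
        return self.z0 + self.H

    def residuals(self) -> tuple[float, float, float]:
        """Relative residuals of the three matching conditions.

        (continuity at z0, inner mass = (1-X) N sigma, outer mass = X N sigma).
        """
        p = self.params
        c_in = _c_inner(p.sigma, p.eta, p.nu, p.A)
        c_out = _c_outer(p.N, self.X, p.eta, p.nu)
        cont = c_in * self.z0 ** (-2.0 / 3.0) - c_out * self.H**2
        inner = 1.5 * math.pi * c_in * self.z0 ** (4.0 / 3.0) - p.N * p.sigma * (1.0 - self.X)
        outer = (
            0.5 * math.pi * c_out * self.H**4 * (1.0 + 8.0 * self.z0 / (3.0 * self.H))
            - p.N * p.sigma * self.X
        )
        scale = c_out * self.H**2
        return (cont / scale, inner / (p.N * p.sigma), outer / (p.N * p.sigma))


def _solve_widths_for_X(p: AnalyticBrush, X: float) -> tuple[float, float]:
    """(z0, H) satisfying the inner and outer mass conditions for a given X."""
    c_in = _c_inner(p.sigma, p.eta, p.nu, p.A)
    c_out = _c_outer(p.N, X, p.eta, p.nu)
    z0 = (2.0 * p.N * p.sigma * (1.0 - X) / (3.0 * math.pi * c_in)) ** 0.75
    # outer mass: H^4 + (8/3) z0 H^3 = 2 N sigma X / (pi c_out); monotone in H
    rhs = 2.0 * p.N * p.sigma * X / (math.pi * c_out)

    def g(H: float) -> float:
        return H**4 + (8.0 / 3.0) * z0 * H**3 - rhs

    hi = rhs**0.25 + 1.0
    H = brentq(g, 1e-12, hi, xtol=1e-14, rtol=8.9e-16)
    return z0, H


def solve_dead_zone(
    N: float,
    sigma: float,
    eta: float = 1.0,
    nu: float = 0.5,
    A: float = A_BEST_FIT,
) -> DeadZoneSolution:
    """Solve the three dead-zone matching conditions for (X, z0, H).

    The two mass normalizations fix z0(X) and H(X); the remaining profile
    continuity condition at z0 is root-found in X on (0, 1).  The closed
    forms for X and z0/H are *not* used here (they serve as independent
    cross-checks); X is independent of N, sigma and eta by construction of
    the system.
    """
    p = AnalyticBrush(N=N, sigma=sigma, eta=eta, nu=nu, A=A)

    def continuity(X: float) -> float:
        z0, H = _solve_widths_for_X(p, X)
        c_in = _c_inner(sigma, eta, nu, A)
        c_out = _c_outer(N, X, eta, nu)
        return c_in * z0 ** (-2.0 / 3.0) - c_out * H**2

    lo, hi = 1e-9, 1.0 - 1e-12
    flo, fhi = continuity(lo), continuity(hi)
    if flo * fhi > 0:
        raise TheoryDomainError(
            f"no dead-zone solution with X in (0,1) for A={A} (brush too convex?)"
        )
    X = brentq(continuity, lo, hi, xtol=1e-15, rtol=8.9e-16)
    z0, H = _solve_widths_for_X(p, X)
    return DeadZoneSolution(params=p, X=X, z0=z0, H=H)


def dead_zone_profile(solution: DeadZoneSolution):
    """Piecewise analytic profile phi(z) of the dead-zone brush.

    Inner zone (0 < z <= z0): phi = c_in * z^(-2/3); outer zone
    (z0 <= z <= z0+H): shifted parabola.  Zero outside [0, z0+H] by
    convention.  Returns a vectorized callable.
    """
    p = solution.params
    c_in = _c_inner(p.sigma, p.eta, p.nu, p.A)
    c_out = _c_outer(p.N, solution.X, p.eta, p.nu)
    z0, H = solution.z0, solution.H

    def phi(z):
        z = np.asarray(z, dtype=float)
        inner = np.where(z > 0, c_in * np.maximum(z, 1e-300) ** (-2.0 / 3.0), 0.0)
        outer = c_out * (H**2 - (z - z0) ** 2)
        return np.select(
            [(z > 0) & (z <= z0), (z > z0) & (z <= z0 + H)], [inner, outer], 0.0
        )

    return phi


def mean_H_analytic(N: float, sigma: float, eta: float = 1.0, nu: float = 0.5) -> float:
    """First moment <H> = (8/15) H of the no-dead-zone parabolic brush."""
    return 8.0 / 15.0 * parabolic_height(N, sigma, eta, nu)


def free_energy_analytic(N: float, eta: float, h: float, nu: float = 0.5) -> float:
    """Free energy per grafted comb, F = 3 pi^5 eta^4/(128 nu N^4) * h * H^6.

    With the parabolic width H at sigma = 1/h this reduces to
    F = sqrt(2 pi nu / 3) * eta * N^(1/2) * h^(-1/2) (kBT).
    """
    _check_solvent(nu)
    H = parabolic_height(N, 1.0 / h, eta, nu)
    return 3.0 * math.pi**5 * eta**4 / (128.0 * nu * N**4) * h * H**6


def axial_force_analytic(N: float, eta: float, h: float, nu: float = 0.5) -> float:
    """Axial tension f(h) = -dF/dh = F/(2h), scaling as h^(-3/2) (kBT/a)."""
    return free_energy_analytic(N, eta, h, nu) / (2.0 * h)


def free_energy_and_force_analytic(
    N: float, eta: float, h: float, nu: float = 0.5
) -> tuple[float, float]:
    """(F, f) per grafted chain at spacing h."""
    F = free_energy_analytic(N, eta, h, nu)
    return F, F / (2.0 * h)


def persistence_length_analytic(N: float, h: float) -> float:
    """Induced persistence length lp/a = 0.046 * N * (a/h)^2 (athermal).

    Architecture-independent: only the total polymerization degree N of the
    graft and the grafting spacing h enter.
    """
    if N <= 0 or h <= 0:
        raise TheoryDomainError("N and h must be positive")
    return 0.046 * N / h**2


def dead_zone_ratio_closed_form(A: float, X: float) -> float:
    """Closed form z0/H = 2 pi (1 - X) / (3 sqrt(A) X) (cross-check)."""
    return 2.0 * math.pi * (1.0 - X) / (3.0 * math.sqrt(A) * X)


def peripheral_fraction_closed_form(A: float) -> float:
    """Closed form X(A) (cross-check of the numeric dead-zone solution)."""
    s = 12.0 * math.pi**2 - 16.0 * math.pi * math.sqrt(A)
    if s <= 0:
        raise TheoryDomainError(f"no dead-zone solution for A={A}")
    return s / (s + 9.0 * A)


def z0_and_H_widths(
    N: float,
    sigma: float,
    eta: float = 1.0,
    nu: float = 0.5,
    A: float = A_BEST_FIT,
    X: float | None = None,
) -> tuple[float, float]:
    """Closed-form dead-zone and peripheral widths (z0, H).

    z0 = (2/3) (8 nu/(pi A))^(1/4) (1-X)^(3/4) N^(3/4) sigma^(1/4) eta^(-1/2);
    H differs only in the prefactor, via the outer mass condition with the
    known ratio z0/H.  Both scale as N^(3/4) sigma^(1/4) eta^(-1/2).
    """
    _check_solvent(nu)
    if X is None:
        X = peripheral_fraction_closed_form(A)
    common = N**0.75 * sigma**0.25 / math.sqrt(eta)
    z0 = (2.0 / 3.0) * (8.0 * nu / (math.pi * A)) ** 0.25 * (1.0 - X) ** 0.75 * common
    r = dead_zone_ratio_closed_form(A, X)
    H = (
        (32.0 * nu / (3.0 * math.pi**3)) ** 0.25
        * (1.0 + 8.0 * r / 3.0) ** -0.25
        * X**0.75
        * common
    )
    return z0, H
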