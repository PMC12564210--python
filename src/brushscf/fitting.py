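"""Estimators connecting simulation to theory.

* ``fit_amplitude_A`` — the dead-zone scaling factor A, fitted jointly in
  log space to the inner-zone window of one or more SCF density profiles
  against the analytic power law phi = (3 A sigma^2 eta^2 /
  (16 nu pi^2 z^2))^(1/3).  The fit is a closed-form log-mean (ordinary
  least squares in ln A with a known slope), shared across profiles.
* ``fit_powerlaw`` — least-squares exponent/prefactor in log-log
  coordinates (force and persistence-length slopes).
* ``fit_linear`` — ordinary least squares (moment-moment proportionality).

All fits are deterministic and order-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PowerLawFit",
    "LinearFit",
    "AmplitudeFit",
    "FitError",
    "fit_powerlaw",
    "fit_linear",
    "fit_amplitude_A",
]


class FitError(ValueError):
    """Raised for degenerate or empty fitting problems."""


@dataclass(frozen=True)
class PowerLawFit:
    """y = exp(log_prefactor) * x**exponent over the fitted window."""

    exponent: float
    log_prefactor: float
    r_squared: float
    window: tuple[int, int]  #: index range [start, stop) used

    def predict(self, x):
        return np.exp(self.log_prefactor) * np.asarray(x, float) ** self.exponent


@dataclass(frozen=True)
class LinearFit:
    slope: float
    intercept: float
    r_squared: float

    def predict(self, x):
        return self.slope * np.asarray(x, float) + self.intercept


def _r2(y, yhat) -> float:
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot


def fit_powerlaw(x, y, window: tuple[int, int] | None = None) -> PowerLawFit:
    """Least-squares power law on (log x, log y) over ``window`` indices."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if window is None:
        window = (0, x.size)
    sl = slice(*window)
    xw, yw = x[sl], y[sl]
    if xw.size < 3:
        raise FitError(f"power-law fit needs >= 3 points, window has {xw.size}")
    if np.any(xw <= 0) or np.any(yw <= 0):
        raise FitError("power-law fit requires positive x and y in the window")
    lx, ly = np.log(xw), np.log(yw)
    slope, intercept = np.polyfit(lx, ly, 1)
    return PowerLawFit(
        exponent=float(slope),
        log_prefactor=float(intercept),
        r_squared=_r2(ly, slope * lx + intercept),
        window=tuple(window),
    )


def fit_linear(x, y) -> LinearFit:
    """Ordinary least squares y = slope * x + intercept."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3:
        raise FitError(f"linear fit needs >= 3 points, got {x.size}")
    if np.ptp(x) == 0:
        raise FitError("degenerate x values in linear fit")
    slope, intercept = np.polyfit(x, y, 1)
    return LinearFit(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=_r2(y, slope * x + intercept),
    )


@dataclass(frozen=True)
class AmplitudeFit:
    """Joint inner-zone amplitude fit."""

    A: float
    n_points: int
    windows: tuple[tuple[float, float], ...]  #: per-profile (z_lo, z_hi)
    rms_log_residual: float


def fit_amplitude_A(
    profiles,
    window_rule: tuple[float, float] = (2.0, 0.8),
) -> AmplitudeFit:
    """Best-fit dead-zone amplitude A shared across SCF profiles.

    Parameters
    ----------
    profiles : iterable of (sigma, eta, nu, z, phi, z0_est)
        Converged density profiles with their brush parameters and a
        dead-zone width estimate (e.g. from the end distribution).
    window_rule : (z_lo, frac)
        Each profile contributes shells with z_lo <= z <= frac * z0_est.

    The inner power law gives ln phi = (1/3) ln A + (1/3) ln(3 sigma^2
    eta^2 / (16 nu pi^2)) - (2/3) ln z, so the least-squares ln A is a
    closed-form mean of the per-point log residuals; rescaling profiles by
    the sigma^2 eta^2 amplitude factor leaves A unchanged.
    """
    z_lo, frac = window_rule
    residuals = []
    windows = []
    for sigma, eta, nu, z, phi, z0_est in profiles:
        z = np.asarray(z, float)
        phi = np.asarray(phi, float)
        z_hi = frac * z0_est
        mask = (z >= z_lo) & (z <= z_hi) & (phi > 0)
        if not np.any(mask):
            raise FitError(
                f"empty inner-zone window [{z_lo}, {z_hi:.2f}] for sigma={sigma}, eta={eta}"
            )
        base = math.log(3.0 * sigma**2 * eta**2 / (16.0 * nu * math.pi**2)) / 3.0
        residuals.append(np.log(phi[mask]) - base + (2.0 / 3.0) * np.log(z[mask]))
        windows.append((float(z_lo), float(z_hi)))
    res = np.concatenate(residuals)
    lnA = 3.0 * float(np.mean(res))
    return AmplitudeFit(
        A=math.exp(lnA),
        n_points=res.size,
        windows=tuple(windows),
        rms_log_residual=float(np.sqrt(np.mean((res - lnA / 3.0) ** 2))),
    )
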