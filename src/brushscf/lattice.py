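"""Cylindrical shell lattice around the brush axis.

Space is discretized into cylindrical shells of unit thickness (the monomer
size a) centred on the backbone.  Shell ``z`` (z >= 1) spans radii
[z - 1/2, z + 1/2], so its dimensionless cross-sectional area per unit
axial length is ``L(z) = 2*pi*z``.  Layer z = 0 is the phantom backbone:
it holds no polymer or solvent, and random-walk steps toward it are
reflected back into shell 1.

Step weights derive from the cubic-lattice fractions (1/6, 4/6, 1/6),
modulated by the circumference of the interface between adjacent shells so
that detailed balance ``L(z) * lam_out(z) = L(z+1) * lam_in(z+1)`` holds
exactly.  An optional ``radius_offset`` shifts all shells outward, which
reproduces a planar lattice in the large-offset limit (test harness only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CylindricalLattice", "build_lattice", "layer_average"]

_LAMBDA = 1.0 / 6.0  # cubic-lattice out-of-layer step fraction


class LatticeConfigError(ValueError):
    """Raised for unusable lattice configurations."""


@dataclass(frozen=True)
class CylindricalLattice:
    """Shell areas and step weights of the cylindrical lattice.

    Arrays are indexed 0..zmax-1 for shells z = 1..zmax.
    """

    zmax: int
    radius_offset: float = 0.0
    L: np.ndarray = field(repr=False, default=None)
    lam_in: np.ndarray = field(repr=False, default=None)    # step toward the axis
    lam_lat: np.ndarray = field(repr=False, default=None)   # step within the shell
    lam_out: np.ndarray = field(repr=False, default=None)   # step away from the axis

    @property
    def z(self) -> np.ndarray:
        """Shell-centre radii (units of a)."""
        return self.radius_offset + np.arange(1, self.zmax + 1, dtype=float)


def build_lattice(zmax: int, radius_offset: float = 0.0) -> CylindricalLattice:
    """Build the cylindrical lattice with ``zmax`` polymer-accessible shells.

    Shell z has area ``L(z) = 2*pi*(z + offset)``; the interface between
    shells z and z+1 has circumference ``2*pi*(z + offset + 1/2)``.  Step
    weights are ``lam_out(z) = lam * S(z)/L(z)``, ``lam_in(z) =
    lam * S(z-1)/L(z)`` with ``lam = 1/6``, which satisfies detailed balance
    by construction and tends to (1/6, 4/6, 1/6) as z grows.
    """
    if zmax < 3:
        raise LatticeConfigError(f"zmax must be >= 3, got {zmax}")
    if radius_offset < 0:
        raise LatticeConfigError("radius_offset must be non-negative")
    z = radius_offset + np.arange(1, zmax + 1, dtype=float)
    L = 2.0 * np.pi * z
    s_out = 2.0 * np.pi * (z + 0.5)   # interface to shell z+1
    s_in = 2.0 * np.pi * (z - 0.5)    # interface to shell z-1 (or the axis layer)
    lam_out = _LAMBDA * s_out / L
    lam_in = _LAMBDA * s_in / L
    lam_lat = 1.0 - lam_out - lam_in
    return CylindricalLattice(
        zmax=zmax, radius_offset=radius_offset,
        L=L, lam_in=lam_in, lam_lat=lam_lat, lam_out=lam_out,
    )


def layer_average(lattice: CylindricalLattice, f: np.ndarray) -> np.ndarray:
    """One random-walk step: <f>(z) = lam_in*f(z-1) + lam_lat*f(z) + lam_out*f(z+1).

    Both boundaries reflect: flux toward the phantom backbone layer returns
    to shell 1, flux past zmax returns to shell zmax.  With the
    detailed-balance weights this conserves the shell-weighted total
    ``sum(L * f)`` exactly and is self-adjoint in the L-weighted inner
    product (the basis of the end-symmetry of the chain partition function).
    """
    f = np.asarray(f, dtype=float)
    if f.shape != (lattice.zmax,):
        raise LatticeConfigError(
            f"field has shape {f.shape}, lattice expects ({lattice.zmax},)"
        )
    out = lattice.lam_lat * f
    out[1:] += lattice.lam_in[1:] * f[:-1]
    out[:-1] += lattice.lam_out[:-1] * f[1:]
    out[0] += lattice.lam_in[0] * f[0]      # reflection at the axis
    out[-1] += lattice.lam_out[-1] * f[-1]  # reflection at the outer wall
    return out
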