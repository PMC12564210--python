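"""Graft topology of comb and double-comb (DC) side chains.

A bottle-brush is modelled as a straight phantom backbone decorated with
identical grafts at axial spacing ``h`` (grafting density ``sigma = a/h``).
Each graft is itself a comb: a main chain of ``Nb = P1*m1 + P2*m2`` segments
carrying secondary side chains.  The proximal domain (adjacent to the
backbone) holds ``P1`` branch points on spacers of ``m1`` segments, each
bearing an arm of ``n1`` segments; the peripheral domain holds ``P2`` branch
points with spacers ``m2`` and arms ``n2``.  The monodisperse comb is the
special case ``n1 = n2``, ``m1 = m2``; aggrecan-like DC grafts have two
different arm lengths arranged block-wise, mimicking the KS/CS domains of
aggrecan monomers on hyaluronan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GraftArchitecture",
    "BrushParameters",
    "InvalidArchitectureError",
    "topological_ratio",
    "total_monomers",
    "backbone_length",
    "segment_map",
]


class InvalidArchitectureError(ValueError):
    """Raised for graft topologies the model cannot represent."""


@dataclass(frozen=True)
class GraftArchitecture:
    """Topology of one grafted double-comb chain.

    Parameters
    ----------
    P1, P2 : int
        Number of branch points in the proximal / peripheral domain.
    m1, m2 : int
        Spacer contour lengths (segments) between branch points in each
        domain.  A domain with ``P > 0`` must have ``m >= 1``.
    n1, n2 : int
        Contour lengths of the secondary side chains (arms) in each domain;
        ``n = 0`` means a bare spacer (no arm).
    """

    P1: int
    P2: int
    m1: int
    m2: int
    n1: int
    n2: int

    def __post_init__(self) -> None:
        for name in ("P1", "P2", "m1", "m2", "n1", "n2"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or isinstance(v, bool):
                raise InvalidArchitectureError(f"{name} must be an integer, got {v!r}")
            if v < 0:
                raise InvalidArchitectureError(f"{name} must be non-negative, got {v}")
        if self.P1 > 0 and self.m1 < 1:
            raise InvalidArchitectureError("proximal domain has branch points but m1 = 0")
        if self.P2 > 0 and self.m2 < 1:
            raise InvalidArchitectureError("peripheral domain has branch points but m2 = 0")
        if self.P1 + self.P2 == 0:
            raise InvalidArchitectureError("graft has no segments (P1 = P2 = 0)")

    @property
    def total_monomers(self) -> int:
        """Total polymerization degree N of the graft (main chain + arms)."""
        return self.P1 * (self.n1 + self.m1) + self.P2 * (self.n2 + self.m2)

    @property
    def backbone_length(self) -> int:
        """Number of segments Nb in the graft main chain."""
        return self.P1 * self.m1 + self.P2 * self.m2

    @property
    def is_monodisperse(self) -> bool:
        """True for a comb with identical arms and spacers in both domains."""
        return (self.n1 == self.n2 and self.m1 == self.m2) or self.P1 == 0 or self.P2 == 0

    @classmethod
    def comb(cls, P: int, m: int, n: int) -> "GraftArchitecture":
        """Monodisperse comb: ``P`` arms of length ``n`` on spacers ``m``."""
        return cls(P1=P, P2=0, m1=m, m2=0, n1=n, n2=0)


@dataclass(frozen=True)
class BrushParameters:
    """Grafting density and solvency of the brush.

    ``sigma = a/h`` is the number of grafts per lattice unit of backbone;
    the model covers 0 < sigma <= 2.  ``chi`` is the Flory-Huggins
    parameter (0 = athermal good solvent); ``nu = 1/2 - chi`` is the second
    virial coefficient used throughout the analytic theory.
    """

    sigma: float
    chi: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.sigma <= 2.0):
            raise InvalidArchitectureError(
                f"grafting density sigma must be in (0, 2], got {self.sigma}"
            )

    @classmethod
    def from_spacing(cls, h: float, chi: float = 0.0) -> "BrushParameters":
        """Build from the axial distance ``h`` between grafting points."""
        return cls(sigma=1.0 / h, chi=chi)

    @property
    def h(self) -> float:
        """Axial distance between grafting points, in units of a."""
        return 1.0 / self.sigma

    @property
    def nu(self) -> float:
        """Second virial coefficient nu = 1/2 - chi."""
        return 0.5 - self.chi


def topological_ratio(n: int, m: int) -> float:
    """Branching parameter eta = sqrt(1 + n/m) of a comb chain.

    Quantifies how arms of length ``n`` on spacers of length ``m`` stiffen
    the effective (Gaussian) elasticity of the comb; eta = 1 for a linear
    chain (n = 0).
    """
    if m < 1:
        raise InvalidArchitectureError("spacer length m must be >= 1 for the topological ratio")
    if n < 0:
        raise InvalidArchitectureError("side-chain length n must be non-negative")
    return math.sqrt(1.0 + n / m)


def total_monomers(arch: GraftArchitecture) -> int:
    """N = P1*(n1+m1) + P2*(n2+m2)."""
    return arch.total_monomers


def backbone_length(arch: GraftArchitecture) -> int:
    """Nb = P1*m1 + P2*m2."""
    return arch.backbone_length


@dataclass(frozen=True)
class SegmentMap:
    """Rank layout of a graft, consumed by the propagator engine.

    ``arm_length[s-1]`` is the arm length attached at main-chain rank ``s``
    (0 for no arm).  Arms sit on the *last* rank of each spacer, so the
    first branch point is ``m1`` ranks from the grafting point and the root
    spacer (ranks 1..m1) is well defined.
    """

    backbone_length: int
    arm_length: tuple[int, ...] = field(repr=False)

    @property
    def branch_ranks(self) -> tuple[int, ...]:
        """Main-chain ranks carrying an arm of positive length."""
        return tuple(s + 1 for s, n in enumerate(self.arm_length) if n > 0)

    @property
    def first_branch_rank(self) -> int:
        """Rank of the first branch point (the end of the root spacer)."""
        for s, n in enumerate(self.arm_length):
            if n > 0:
                return s + 1
        raise InvalidArchitectureError("architecture has no branch points with arms")

    @property
    def total_segments(self) -> int:
        return self.backbone_length + sum(self.arm_length)


def segment_map(arch: GraftArchitecture) -> SegmentMap:
    """Ordered segment ranks of the graft main chain with arm annotations.

    Ranks run 1..Nb outward from the grafting point; every ``m1``-th rank of
    the proximal domain carries an arm of length ``n1``, every ``m2``-th rank
    of the peripheral domain an arm of length ``n2``.
    """
    arm = [0] * arch.backbone_length
    for j in range(1, arch.P1 + 1):
        arm[j * arch.m1 - 1] = arch.n1
    off = arch.P1 * arch.m1
    for j in range(1, arch.P2 + 1):
        arm[off + j * arch.m2 - 1] = arch.n2
    return SegmentMap(backbone_length=arch.backbone_length, arm_length=tuple(arm))
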