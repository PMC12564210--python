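"""Self-consistent field solution for grafted comb chains on the cylinder.

The grafted macromolecules are freely-jointed chains in an external field
``u(z)`` on the cylindrical shell lattice.  Chain statistics are built by
the Scheutjens-Fleer propagator recursion

    q(s+1, z) = G(z) * <q(s, .)>(z),      G(z) = exp(-u(z)),

with the first segment of every graft anchored in shell z = 1.  At a branch
rank the free-end average of the side arm, W(z) = <q_arm(n, .)>(z), enters
the local statistical weight exactly once.  Segment densities follow from
the product of forward and complementary propagators, normalized per rank;
the total polymer volume fraction satisfies  sum_z phi(z) L(z) = N * sigma
by construction.

The self-consistent closure is lattice incompressibility,
phi(z) + phi_s(z) = 1, enforced through a Lagrange multiplier field
alpha(z): in the athermal case u = alpha and the solvent (a monomer-sized
molecule) has phi_s = exp(-u), so the residual phi + exp(-alpha) - 1 is
driven to zero by damped Picard iteration with optional Anderson
acceleration.  The free energy per grafted chain is

    F = -ln Q[u] - (1/sigma) * sum_z u(z) phi(z) L(z)      (kBT),

with ln Q referenced per anchor site (a one-segment graft in zero field has
ln Q = 0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .architecture import BrushParameters, GraftArchitecture, SegmentMap, segment_map
from .lattice import CylindricalLattice, build_lattice, layer_average
from . import theory

__all__ = [
    "SolverOptions",
    "SCFSolution",
    "Propagators",
    "DensityDecomposition",
    "SCFConvergenceError",
    "SCFNumericalError",
    "propagate",
    "compute_density",
    "solve_scf",
    "free_energy",
    "auto_zmax",
]


class SCFConvergenceError(RuntimeError):
    """Solver failed to reach the requested tolerance."""

    def __init__(self, message: str, residual: float, iterations: int):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class SCFNumericalError(RuntimeError):
    """Non-finite fields or overflowing Boltzmann weights."""


def effective_eta(arch: GraftArchitecture) -> float:
    """Topological ratio sqrt(N/Nb) of the graft (reduces to sqrt(1+n/m))."""
    return math.sqrt(arch.total_monomers / arch.backbone_length)


def auto_zmax(arch: GraftArchitecture, params: BrushParameters, margin: float = 1.75) -> int:
    """Lattice extent: ``margin`` times the analytic brush extent z0 + H.

    Falls back to a random-coil estimate when the dead-zone model has no
    solution for the parameters.  The converged profile is checked post hoc
    to satisfy phi(zmax) < 1e-6.
    """
    N = arch.total_monomers
    try:
        dz = theory.solve_dead_zone(N, params.sigma, effective_eta(arch), max(params.nu, 1e-3))
        extent = dz.extent
    except theory.TheoryDomainError:
        extent = theory.parabolic_height(N, params.sigma, effective_eta(arch), max(params.nu, 1e-3))
    coil = 2.2 * math.sqrt(N / 6.0)
    # +10 shells of slack for the near-Gaussian tail beyond the brush edge
    return max(10, int(math.ceil(margin * extent + 10.0)), int(math.ceil(coil)))


# ---------------------------------------------------------------------------
# pure-python reference propagators (small systems, tests, diagnostics)
# ---------------------------------------------------------------------------


@dataclass
class Propagators:
    """Forward and complementary propagator tables of one grafted comb.

    ``q[s]`` is the weight of the chain portion from the grafted end up to
    main-chain rank s+1 (local Boltzmann and arm factors included);
    ``sc[s]`` the step-averaged weight of everything beyond rank s+1 toward
    the free end; ``qs[n][k]`` the free-arm propagator of an arm of length
    n after k+1 segments; ``W[n]`` its average into the branch site.
    ``lnQ`` and ``lnQ_reverse`` are the log partition function (per anchor
    site) evaluated from the grafted and the free end; they agree to
    rounding.
    """

    smap: SegmentMap
    lattice: CylindricalLattice
    G: np.ndarray
    q: np.ndarray
    sc: np.ndarray
    prev_avg: np.ndarray
    qs: dict
    W: dict
    lnQ: float
    lnQ_reverse: float


def propagate(
    arch: GraftArchitecture | SegmentMap,
    lattice: CylindricalLattice,
    u: np.ndarray,
) -> Propagators:
    """Build propagator tables for one graft in the field ``u`` (reference path).

    Unscaled numpy implementation used for small systems and as the oracle
    partner of the accelerated kernel; the solver uses the numba kernel with
    identical mathematics.
    """
    smap = segment_map(arch) if isinstance(arch, GraftArchitecture) else arch
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise SCFNumericalError("field u contains non-finite values")
    if u.shape != (lattice.zmax,):
        raise SCFNumericalError(
            f"field shape {u.shape} does not match lattice ({lattice.zmax},)"
        )
    G = np.exp(-u)
    Nb = smap.backbone_length
    zmax = lattice.zmax
    avg = lambda f: layer_average(lattice, f)  # noqa: E731

    qs: dict[int, np.ndarray] = {}
    W: dict[int, np.ndarray] = {}
    for ln in sorted({n for n in smap.arm_length if n > 0}):
        t = np.zeros((ln, zmax))
        t[0] = G
        for k in range(1, ln):
            t[k] = G * avg(t[k - 1])
        qs[ln] = t
        W[ln] = avg(t[-1])

    def local_weight(s: int) -> np.ndarray:
        n = smap.arm_length[s]
        return G * W[n] if n > 0 else G

    q = np.zeros((Nb, zmax))
    prev_avg = np.zeros((Nb, zmax))
    prev_avg[0, 0] = 1.0
    q[0] = local_weight(0) * prev_avg[0]
    for s in range(1, Nb):
        prev_avg[s] = avg(q[s - 1])
        q[s] = local_weight(s) * prev_avg[s]

    sc = np.zeros((Nb, zmax))
    sc[Nb - 1] = 1.0
    qc = local_weight(Nb - 1) * sc[Nb - 1]
    for s in range(Nb - 2, -1, -1):
        sc[s] = avg(qc)
        qc = local_weight(s) * sc[s]

    L = lattice.L
    lnQ = math.log(float(np.sum(L * q[-1]))) - math.log(L[0])
    lnQ_reverse = math.log(float(qc[0]))
    return Propagators(
        smap=smap, lattice=lattice, G=G, q=q, sc=sc, prev_avg=prev_avg,
        qs=qs, W=W, lnQ=lnQ, lnQ_reverse=lnQ_reverse,
    )


@dataclass
class DensityDecomposition:
    """Rank-resolved segment densities of one graft, scaled by sigma.

    ``phi`` is the total polymer volume fraction; ``phi_main[s]`` the
    contribution of main-chain rank s+1; ``phi_arm`` the total side-arm
    contribution; ``end_profile`` / ``first_branch_profile`` the local
    volume fractions g(z) of the main-chain free end and of the first
    branch point (sum g L = sigma each).
    """

    phi: np.ndarray
    phi_main: np.ndarray
    phi_arm: np.ndarray
    end_profile: np.ndarray
    first_branch_profile: np.ndarray | None


def compute_density(props: Propagators, sigma: float) -> DensityDecomposition:
    """Segment densities from propagator tables (reference path).

    Each rank is normalized independently (sum_z L * n_s = 1), so the total
    obeys sum_z phi L = N * sigma exactly.
    """
    smap, lattice = props.smap, props.lattice
    L = lattice.L
    zmax = lattice.zmax
    Nb = smap.backbone_length
    avg = lambda f: layer_average(lattice, f)  # noqa: E731
    G = props.G

    phi_main = np.zeros((Nb, zmax))
    for s in range(Nb):
        rho = props.q[s] * props.sc[s] * L
        phi_main[s] = sigma * rho / (np.sum(rho) * L)
    end_profile = phi_main[Nb - 1].copy()

    phi_arm = np.zeros(zmax)
    for s in range(Nb):
        n = smap.arm_length[s]
        if n == 0:
            continue
        Eb = G * props.prev_avg[s] * props.sc[s]
        Eb = Eb / np.sum(L * G * props.W[n] * props.prev_avg[s] * props.sc[s])
        rbar = avg(Eb)
        for k in range(n - 1, -1, -1):
            rho = props.qs[n][k] * rbar * L
            phi_arm += sigma * rho / (np.sum(rho) * L)
            if k > 0:
                rbar = avg(G * rbar)

    fb = None
    if any(n > 0 for n in smap.arm_length):
        fb = phi_main[smap.first_branch_rank - 1].copy()
    return DensityDecomposition(
        phi=phi_main.sum(axis=0) + phi_arm,
        phi_main=phi_main,
        phi_arm=phi_arm,
        end_profile=end_profile,
        first_branch_profile=fb,
    )


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SolverOptions:
    """Numerical controls of the SCF iteration.

    ``mixing_step`` is the Picard step of the Lagrange-field update (must be
    < 1/2; halved automatically when the residual grows).  ``anderson_depth``
    enables Anderson (DIIS) acceleration of the same fixed-point map;
    depth 0 recovers plain Picard.  ``init='theory'`` starts from the
    analytic dead-zone potential 2*nu*phi(z), ``'zero'`` from alpha = 0.
    """

    tolerance: float = 1e-8
    mixing_step: float = 0.2
    max_iter: int = 200_000
    zmax: int | None = None
    zmax_margin: float = 1.75
    anderson_depth: int = 5
    init: str = "theory"
    tail_threshold: float = 1e-6

    def __post_init__(self) -> None:
        if not (0.0 < self.mixing_step < 0.5):
            raise ValueError(f"mixing_step must be in (0, 1/2), got {self.mixing_step}")
        if self.init not in ("theory", "zero"):
            raise ValueError(f"init must be 'theory' or 'zero', got {self.init!r}")


@dataclass
class SCFSolution:
    """Converged SCF state of the cylindrical brush."""

    arch: GraftArchitecture
    params: BrushParameters
    lattice: CylindricalLattice
    u: np.ndarray = field(repr=False, default=None)
    phi: np.ndarray = field(repr=False, default=None)
    phi_s: np.ndarray = field(repr=False, default=None)
    end_profile: np.ndarray = field(repr=False, default=None)
    first_branch_profile: np.ndarray | None = field(repr=False, default=None)
    lnQ: float = 0.0
    free_energy_per_chain: float | None = None
    free_energy_total: float | None = None
    iterations: int = 0
    residual: float = np.inf
    converged: bool = False


def _initial_alpha(
    arch: GraftArchitecture, params: BrushParameters, lattice: CylindricalLattice, how: str
) -> np.ndarray:
    if how == "zero":
        return np.zeros(lattice.zmax)
    try:
        dz = theory.solve_dead_zone(
            arch.total_monomers, params.sigma, effective_eta(arch), max(params.nu, 1e-3)
        )
        phi0 = theory.dead_zone_profile(dz)(lattice.z)
        return -np.log1p(-np.clip(phi0, 0.0, 0.99))
    except theory.TheoryDomainError:
        return np.zeros(lattice.zmax)


def solve_scf(
    arch: GraftArchitecture,
    params: BrushParameters,
    lattice: CylindricalLattice | None = None,
    options: SolverOptions | None = None,
) -> SCFSolution:
    """Solve the incompressible SCF equations for the cylindrical brush.

    Deterministic for fixed inputs.  Raises :class:`SCFConvergenceError`
    (carrying the last residual) if the tolerance is not met within
    ``max_iter`` iterations, and :class:`SCFNumericalError` on field
    overflow or saturation (phi -> 1).
    """
    from ._kernels import scf_density

    options = options or SolverOptions()
    if lattice is None:
        zmax = options.zmax or auto_zmax(arch, params, options.zmax_margin)
        lattice = build_lattice(zmax)
    smap = segment_map(arch)
    arm_len = np.asarray(smap.arm_length, dtype=np.int64)
    L = lattice.L
    li, ll, lo = lattice.lam_in, lattice.lam_lat, lattice.lam_out
    sigma, chi = params.sigma, params.chi
    N = arch.total_monomers

    alpha = _initial_alpha(arch, params, lattice, options.init)
    phi = np.zeros(lattice.zmax)

    def fields(alpha: np.ndarray, phi: np.ndarray):
        if chi == 0.0:
            return alpha, alpha
        phi_s = 1.0 - phi
        u_p = alpha + chi * (layer_average(lattice, phi_s) - 1.0)
        u_s = alpha + chi * layer_average(lattice, phi)
        return u_p, u_s

    def evaluate(alpha: np.ndarray, phi_prev: np.ndarray):
        u_p, u_s = fields(alpha, phi_prev)
        if np.max(u_p) > 500.0 or not np.all(np.isfinite(u_p)):
            raise SCFNumericalError("field overflow during iteration (phi -> 1 saturation?)")
        countL, endL, fbL, lnQ = scf_density(np.exp(-u_p), L, li, ll, lo, arm_len)
        phi = sigma * countL / L
        phi_s = np.exp(-u_s)
        res = phi + phi_s - 1.0
        return res, phi, phi_s, endL, fbL, lnQ, u_p

    depth = options.anderson_depth
    h = options.mixing_step
    x_hist: list[np.ndarray] = []
    f_hist: list[np.ndarray] = []
    best_rmax = np.inf
    prev_rmax = np.inf

    res, phi, phi_s, endL, fbL, lnQ, u_p = evaluate(alpha, phi)
    rmax = float(np.max(np.abs(res)))
    it = 0
    while rmax > options.tolerance and it < options.max_iter:
        it += 1
        x_hist.append(alpha.copy())
        f_hist.append(res.copy())
        if len(x_hist) > depth + 1:
            x_hist.pop(0)
            f_hist.pop(0)
        if depth > 0 and len(x_hist) >= 2:
            dF = np.stack([f_hist[i + 1] - f_hist[i] for i in range(len(f_hist) - 1)], axis=1)
            dX = np.stack([x_hist[i + 1] - x_hist[i] for i in range(len(x_hist) - 1)], axis=1)
            gamma, *_ = np.linalg.lstsq(dF, res, rcond=None)
            alpha_new = alpha + h * res - (dX + h * dF) @ gamma
        else:
            alpha_new = alpha + h * res
        try:
            res_new, phi, phi_s, endL, fbL, lnQ, u_p = evaluate(alpha_new, phi)
        except SCFNumericalError:
            if not x_hist:
                raise
            # accelerated step blew up: restart from plain Picard
            x_hist.clear()
            f_hist.clear()
            alpha_new = alpha + h * res
            res_new, phi, phi_s, endL, fbL, lnQ, u_p = evaluate(alpha_new, phi)
        rmax_new = float(np.max(np.abs(res_new)))
        if not math.isfinite(rmax_new) or rmax_new > 50.0 * max(best_rmax, options.tolerance):
            # diverging: drop history, damp, retry from the best-known state
            x_hist.clear()
            f_hist.clear()
            h = max(h / 2.0, 1e-3)
            alpha_new = alpha + h * res
            res_new, phi, phi_s, endL, fbL, lnQ, u_p = evaluate(alpha_new, phi)
            rmax_new = float(np.max(np.abs(res_new)))
        elif depth == 0 and rmax_new > prev_rmax:
            h = max(h / 2.0, 1e-3)
        alpha, res = alpha_new, res_new
        prev_rmax = rmax_new
        best_rmax = min(best_rmax, rmax_new)
        rmax = rmax_new

    solution = SCFSolution(
        arch=arch, params=params, lattice=lattice,
        u=u_p.copy(), phi=phi, phi_s=phi_s,
        end_profile=sigma * endL / L,
        first_branch_profile=(sigma * fbL / L) if fbL.any() else None,
        lnQ=lnQ, iterations=it, residual=rmax,
        converged=rmax <= options.tolerance,
    )
    if not solution.converged:
        raise SCFConvergenceError(
            f"SCF not converged after {it} iterations (residual {rmax:.3e})",
            residual=rmax, iterations=it,
        )
    if phi[-1] > options.tail_threshold:
        warnings.warn(
            f"phi(zmax) = {phi[-1]:.2e} exceeds {options.tail_threshold:.0e}; "
            "the lattice may be too small for this brush",
            stacklevel=2,
        )
    if chi == 0.0:
        solution.free_energy_per_chain = free_energy(solution)
        solution.free_energy_total = free_energy(solution, include_solvent_entropy=True)
    return solution


def free_energy(solution: SCFSolution, include_solvent_entropy: bool = False) -> float:
    """Free energy per grafted chain, F = -lnQ - (1/sigma) sum u phi L (kBT).

    With ``include_solvent_entropy`` the solvent translational term
    (1/sigma) sum L phi_s ln(phi_s) is added, giving the full mean-field
    free energy of the incompressible athermal brush.  Refuses unconverged
    solutions and non-athermal parameters.
    """
    if not solution.converged:
        raise SCFConvergenceError(
            "free energy of an unconverged solution is undefined",
            residual=solution.residual, iterations=solution.iterations,
        )
    if solution.params.chi != 0.0:
        raise NotImplementedError("free energy is implemented for the athermal case (chi = 0)")
    L = solution.lattice.L
    sigma = solution.params.sigma
    F = -solution.lnQ - float(np.sum(solution.u * solution.phi * L)) / sigma
    if include_solvent_entropy:
        phi_s = np.clip(solution.phi_s, 1e-300, 1.0)
        F += float(np.sum(L * phi_s * np.log(phi_s))) / sigma
    return F
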