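# Methods

## Model

`brushscf` models a cylindrical molecular bottle-brush: a straight, phantom
backbone carrying identical comb or double-comb (DC) grafts at axial
spacing `h` (grafting density `sigma = a/h`, with `a` the monomer size;
all lengths below are in units of `a`, energies in units of kT).  A graft
consists of a main chain of `Nb = P1*m1 + P2*m2` segments; every `m1`-th
rank of the proximal domain carries a secondary side chain (arm) of `n1`
segments, every `m2`-th rank of the peripheral domain an arm of `n2`
segments, so the total polymerization degree is
`N = P1*(n1+m1) + P2*(n2+m2)`.  Arms attach to the last rank of each
spacer; the root spacer between the grafting point and the first branch
point is therefore `m1` ranks long.  The architecture mimics
aggrecan–hyaluronan complexes, where the aggrecan domain proximal to the
junction carries shorter keratan-sulfate chains and the peripheral domain
longer chondroitin-sulfate chains.

Because neighbouring grafts overlap strongly and the backbone is stretched
on scales far beyond the brush cross-section, the density is taken
cylindrically symmetric around a straight axis.  The backbone itself is
phantom (no excluded volume at the axis).

## Lattice

Space is discretized into cylindrical shells of unit thickness; shell `z`
(z = 1..zmax) spans radii [z-1/2, z+1/2] and has dimensionless area
`L(z) = 2*pi*z` per unit axial length.  The source model states the
cylindrical-shell organization but not the area convention; the
[z-1/2, z+1/2] choice is the simplest one, and any alternative (e.g.
shells [z-1, z], L = pi(2z-1)) shifts profiles by at most half a layer.
Random-walk step weights start from the cubic-lattice fractions
(1/6, 4/6, 1/6) and are modulated by the circumference of the interface
between adjacent shells:

    lam_out(z) = (1/6)(z+1/2)/z,  lam_in(z) = (1/6)(z-1/2)/z,  lam_lat = 2/3,

which satisfies detailed balance `L(z) lam_out(z) = L(z+1) lam_in(z+1)`
exactly and tends to the planar fractions as `1/z`.  Both boundaries
reflect; reflection at z=1 implements the phantom backbone.  The layer
operator is then self-adjoint in the L-weighted inner product, which
guarantees exact mass conservation of a random walk and the end-symmetry
of the chain partition function.

`zmax` defaults to 1.75x the analytic brush extent `z0 + H`, plus ten
shells of slack for the near-Gaussian tail beyond the brush edge; each
converged run is checked post hoc for `phi(zmax) < 1e-6`.

## SCF equations and solver

Chains are freely jointed walks in a field `u(z)`; propagators obey
`q(s+1, z) = G(z) <q(s, .)>(z)` with `G = exp(-u)` and the first segment
anchored in shell 1.  At a branch rank the free-end average of the arm,
`W(z) = <q_arm(n, .)>(z)`, multiplies the local weight exactly once; arms
of equal length within a domain are propagated once and reused, and the
complementary arm propagator is likewise computed once per distinct length
by summing the (individually normalized) branch-environment weights over
branch points, which is exact by linearity.  Densities are composed from
forward and complementary propagators and normalized per rank, so
`sum_z phi L = N*sigma` holds to rounding by construction.  `ln Q` is
referenced per anchor site: a one-segment graft in zero field has
`ln Q = 0`.  Propagators are renormalized rank-by-rank with the log-norm
accumulated into `ln Q` (overflow guard).

Incompressibility `phi + phi_s = 1` closes the equations with a Lagrange
field `alpha`; in the athermal case `u = alpha` and the monomeric solvent
has `phi_s = exp(-u)` (normalized to 1 in the polymer-free far field).
For `chi != 0` the standard nearest-neighbour coupling is used
(`u_p = alpha + chi(<phi_s> - 1)`, `u_s = alpha + chi <phi>`); all
headline results are athermal.

The fixed point is reached by the damped update
`alpha <- alpha + h_mix (phi + phi_s - 1)` with `h_mix = 0.2 < 1/2`.  Two
accelerations are layered on top, both deterministic and both leaving the
fixed point unchanged: (i) the iteration starts from the analytic
dead-zone potential `-ln(1 - phi_analytic)` rather than zero, and (ii)
Anderson (DIIS) mixing with depth 5 extrapolates the same map.  Together
they converge typical brushes in ~20–80 iterations instead of many
thousands; a residual-growth safeguard clears the history, halves the
step and falls back to plain Picard (depth 0 reproduces the plain scheme
exactly).  Convergence is declared at `max|phi + phi_s - 1| <= 1e-8`
(at most 2e5 iterations; failure raises an error carrying the last
residual).  The solver is deterministic: identical inputs give
bit-identical outputs.

The free energy per grafted chain is taken literally as

    F = -ln Q - (1/sigma) sum_z u(z) phi(z) L(z),

the athermal expression of the source model.  This omits the solvent
translational entropy `(1/sigma) sum_z L phi_s ln phi_s`; the corrected
value (`free_energy_total`) is also computed, and at the incompressible
saddle `F_total + N` reproduces the analytic per-chain free energy
`sqrt(2 pi nu/3) eta N^(1/2) h^(-1/2)` within a few percent.  Both
variants give force and persistence-length scaling exponents within the
stated tolerances; the headline observables use the literal `F` above.

## Analytic theory

The no-dead-zone brush has the parabolic profile
`phi = 3 pi^2 eta^2/(16 nu N^2) (H^2 - z^2)` with
`H = (32 nu/(3 pi^3))^(1/4) N^(3/4) sigma^(1/4) eta^(-1/2)` and first
moment `<H> = (8/15) H`.  The dead-zone model matches an inner power law
`phi = (3 A sigma^2 eta^2 / (16 nu pi^2 z^2))^(1/3)` (amplitude scale
factor `A`) to an outer shifted parabola through three conditions:
continuity at `z0`, and the inner/outer mass normalizations
`N sigma (1-X)` / `N sigma X`.  `solve_dead_zone` root-finds `X` in (0,1)
on the continuity residual with `(z0, H)` eliminated through the mass
conditions; the closed forms

    z0/H = 2 pi (1-X) / (3 sqrt(A) X),
    X = (12 pi^2 - 16 pi sqrt(A)) / (12 pi^2 - 16 pi sqrt(A) + 9 A)

were re-derived from the same system and serve only as cross-checks (the
typeset closed forms in the source are ambiguous; the residual system is
authoritative).  At the best-fit `A = 1.45` this gives `X = 0.816`
(82%/18% mass split) and `z0/H = 0.392`, independent of `N`, `sigma`,
`eta`.  The induced persistence length under athermal conditions is
`lp/a = 0.046 N (a/h)^2`, architecture-independent.

## Observables and conventions

* Moments use the shell-area weighting: `<H> = sum phi L z / sum phi L`,
  and likewise `<He>` over the main-chain free-end distribution.
* The numeric dead-zone width `z0` is the radius below which the
  cumulative end fraction is 1% (linearly interpolated between shells).
  The threshold is a convention; moving it to 0.5% or 2% shifts `z0` by
  roughly the local shell spacing of the end-distribution rise (a few
  percent of `z0` for the quartet brushes) and none of the qualitative
  orderings.
* The axial force is `f(h) = -dF/dh` by central difference with step
  `dh = 0.1` (sigma = 1/h is continuous, so fractional spacings are well
  defined).  An integer-step difference (`dh = 1`) is available but
  biases the log-log slope of an exact `h^(-1/2)` free energy from -1.5
  to -1.61 on the h = 2..8 grid, so the small step is the default.
* The persistence length is reported as `lp = F H^2 / h` with
  `H = (15/8) <H>` (the outer thickness a parabolic brush with the same
  first moment would have) and unit prefactor.  The underlying relation
  is a proportionality: only slopes and relative comparisons of `lp` are
  meaningful, and the output metadata states the convention.
* The molecular potential is `U(z) = u(z) - u(zmax)`.
* The best-fit amplitude `A` is obtained jointly across profiles by a
  closed-form least-squares in `ln A` over the inner window
  `2 <= z <= 0.8 z0_est`, with `z0_est` taken from each run's own end
  distribution.  The SCF profile is not a pure power law near the
  dead-zone edge, so the fitted amplitude drifts slowly with the window:
  for the quartet, moving the window end between 0.7 and 0.9 z0 moves `A`
  by about 0.08 either side of the 0.8-z0 value.

## Preset study conditions

The presets are the study conditions, not tuning knobs:

* comb quartet: main chain 500, `m = 5`, `n in {0, 15, 40, 75}`
  (`eta = 1..4`), `sigma` chosen so every brush carries
  `N sigma = 500` monomers per unit length (h = 1, 4, 9, 16);
* moment grid: `sigma in {0.1, 0.5, 1, 2}` x `eta in {1, 1.5, 2, 2.5, 3}`
  at `N ~ 1000`.  Exact `N = 1000` is impossible for `eta in {1.5, 3}`
  with integer `(n, m)` (the repeat length `n + m` would need a factor of
  9), so those use `N = 999`; spacers are kept at `m in {3, 4, 5}`, the
  range of the simulated reference architectures;
* double-comb sweep: `sigma = 0.5`, `m = 3`, `P1 = P2 = 10`,
  `n1 + n2 = 50` with `n1 in {0, 12, 25, 38, 50}` (the fractions
  0.25/0.75 are not integer at 50, hence 12/38);
* force/persistence grid: comb `m = 3`, `n = 25`, 20 arms,
  `h in {2, 3, 4, 6, 8}` (plus `h ± 0.1` members for the derivative).

One measured relation deserves a note: across the moment grid the mass
moment is always *below* the end moment (`<H>/<He> ~ 0.68`, as the 8/15
parabolic moment against near-edge ends requires), so the printed
reference relation with coefficient 1.68 is meaningful only with the end
moment on the left-hand side; the moment-proportionality slope reported
by this package is the OLS slope of `<He>` on `<H>` (measured ~1.48 on
the grid above, R^2 > 0.998).

These problem sizes run the full acceptance recomputation in about a
minute on one core; every converged run satisfies the residual and mass
invariants at 1e-8.

## What the model does and does not capture

The simulator reproduces mean-field brush physics on a lattice: dead-zone
formation, profile shapes, moments, force and stiffness scalings.  It
does not describe: electrostatics of real glycosaminoglycan chains (the
athermal neutral-solvent model stands in for good-solvent GAGs),
liquid-crystalline ordering at finite concentration, explicit bent-brush
curvature coefficients (lp is evaluated through the F H^2/h relation on
the straight brush), fluctuation corrections beyond mean field, or
excluded volume of the backbone itself (phantom axis).  Lattice artifacts
are strongest for spacers of one segment and within the first shell or
two of the axis; fitted windows start at z = 2 for this reason.
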