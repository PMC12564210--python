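# brushscf

Scheutjens–Fleer lattice self-consistent-field (SF-SCF) modelling of
cylindrical bottle-brush polymers whose grafts are comb or double-comb
chains — the architecture of aggrecan–hyaluronan complexes in articular
cartilage, and of their synthetic biomimetic analogues.

A bottle-brush is a linear backbone densely grafted (spacing *h*, density
σ = a/h) with side chains; here each graft is itself a comb: a main chain
of N_b = P₁m₁ + P₂m₂ segments carrying secondary side chains of length n₁
(proximal domain) and n₂ (peripheral domain) on spacers of m₁, m₂
segments, total polymerization degree N = P₁(n₁+m₁) + P₂(n₂+m₂).  The
branching strength of a comb is the topological ratio η = (1 + n/m)^{1/2}.

The package answers, numerically and analytically, how this architecture
sets the brush structure and mechanics:

* **SF-SCF simulator** — freely-jointed-chain propagators for branched
  grafts on a cylindrical shell lattice (areas L(z) = 2πz, detailed-balance
  step weights), incompressibility φ(z) + φ_s(z) = 1 enforced through a
  Lagrange field, deterministic damped/Anderson iteration to a residual of
  1e-8.  Outputs: density φ(z), free-end and first-branch-point
  distributions, molecular potential U(z), free energy per graft
  F = −ln Q − (1/σ) Σ u φ L.
* **Dead-zone theory** — on a convex cylindrical brush the free ends are
  expelled from a zone of width z₀ around the axis; the density follows
  φ ∝ z^{−2/3} inside (amplitude scale factor A) and a shifted parabola
  outside.  Solving continuity plus the two mass normalizations gives the
  architecture-independent constants X = 0.816 (peripheral mass fraction)
  and z₀/H = 0.39 at the best-fit A = 1.45.
* **Observables** — radial moments ⟨H⟩ = Σ φLz / Σ φL and ⟨He⟩, numeric
  dead-zone width, axial tension f(h) = −dF/dh (slope −3/2 in log-log),
  induced persistence length lp ∼ F H²/h (slope −2; analytically
  lp/a = 0.046 N (a/h)²).
* **Fitting** — the amplitude A from SCF profiles, power-law slopes,
  moment–moment regressions.

## Worked example

```python
from brushscf import (GraftArchitecture, BrushParameters, solve_scf,
                      solve_dead_zone, topological_ratio,
                      mean_H, mean_He, dead_zone_width)

arch = GraftArchitecture.comb(P=100, m=5, n=40)      # comb graft, eta = 3
sigma = 500 / arch.total_monomers                    # 500 monomers per unit length
sol = solve_scf(arch, BrushParameters(sigma=sigma))
print(mean_H(sol), mean_He(sol), dead_zone_width(sol), sol.free_energy_per_chain)

dz = solve_dead_zone(arch.total_monomers, sigma, eta=3.0)
print(dz.z0, dz.H, dz.X)
```

prints (62.38, 91.90, 47.95, 32.488) and (33.19, 84.68, 0.816): the brush
of N = 4500 combs at σ = 1/9 extends ⟨H⟩ ≈ 62 monomer sizes from the
axis, its free ends sit further out (⟨He⟩ ≈ 92) leaving an end-free dead
zone of ≈ 48 lattice units, it costs ≈ 32.5 kT per graft, and the
analytic partition puts 81.6% of the monomers in the peripheral zone.

The same runs from the shell:

```
brushscf solve  --config run.yaml --out results/
brushscf preset --name fig8 --out results/force/     # f(h) and lp(h) grid
brushscf theory --N 1000 --sigma 0.5,1 --eta 1,2,3   # analytic table
brushscf fit    --out A.json                         # dead-zone amplitude A
```

Config files are small YAML documents (`architecture`, `brush`, `solver`
blocks); every output TSV/JSON carries a provenance header with the
architecture, solver diagnostics and a config hash, and presets
regenerate byte-identical numbers.

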