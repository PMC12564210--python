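"""Preset experiments: the parameter sets behind the reference figures.

Each preset bundles an architecture grid with solver options and the
observables to extract.  Presets are deterministic: rerunning one
regenerates bit-identical numeric output.

* ``fig1`` / ``fig2`` — monodisperse comb quartet: graft main chain
  Nb = 500, spacer m = 5, arms n in {0, 15, 40, 75} (eta = 1..4), grafting
  density chosen so every brush holds N*sigma = 500 monomers per unit
  length of backbone.  End distributions (fig1) and density profiles with
  the analytic dead-zone overlay (fig2).
* ``fig3`` / ``fig4`` — moment grid: sigma in {0.1, 0.5, 1, 2} x eta in
  {1, 1.5, 2, 2.5, 3} at N ~= 1000 (spacers m in {3,4,5} as in the
  simulated figures; N within 0.1% of 1000 where exact integer topologies
  do not exist).
* ``fig5``-``fig7``, ``fig9`` — double-comb sweeps: sigma = 0.5, m = 3,
  P1 = P2 = 10, n1 + n2 = 50 with n1 in {0, 12, 25, 38, 50}.
* ``fig8`` / ``fig10`` — force and persistence-length grid: monodisperse
  comb m = 3, n = 25, 20 arms per graft, spacing h in {2, 3, 4, 6, 8}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .architecture import BrushParameters, GraftArchitecture, topological_ratio

__all__ = [
    "ExperimentPreset",
    "PresetRun",
    "get_preset",
    "PRESET_NAMES",
    "FIG1_SIDE_CHAIN_LENGTHS",
    "MOMENT_GRID_SIGMAS",
    "MOMENT_GRID_ETA_SPECS",
    "DC_N1_VALUES",
    "FORCE_H_GRID",
]

FIG1_SIDE_CHAIN_LENGTHS = (0, 15, 40, 75)
FIG1_SPACER = 5
FIG1_BRANCH_POINTS = 100
FIG1_MASS_PER_LENGTH = 500.0

MOMENT_GRID_SIGMAS = (0.1, 0.5, 1.0, 2.0)
#: eta -> (P, m, n): spacers kept in the simulated 3-5 range, N within 0.1% of 1000
MOMENT_GRID_ETA_SPECS = {
    1.0: (200, 5, 0),
    1.5: (111, 4, 5),
    2.0: (50, 5, 15),
    2.5: (40, 4, 21),
    3.0: (37, 3, 24),
}

DC_N1_VALUES = (0, 12, 25, 38, 50)
DC_TOTAL_ARM = 50
DC_SPACER = 3
DC_BRANCH_POINTS = 10  # per domain
DC_SIGMA = 0.5

FORCE_COMB = dict(P=20, m=3, n=25)
FORCE_H_GRID = (2.0, 3.0, 4.0, 6.0, 8.0)


@dataclass(frozen=True)
class PresetRun:
    """One member run of a preset: label + architecture + brush parameters."""

    label: str
    arch: GraftArchitecture
    params: BrushParameters
    eta: float


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    description: str
    runs: tuple[PresetRun, ...]
    outputs: tuple[str, ...] = ("profiles", "metrics")


def _fig1_runs() -> tuple[PresetRun, ...]:
    runs = []
    for n in FIG1_SIDE_CHAIN_LENGTHS:
        arch = GraftArchitecture.comb(P=FIG1_BRANCH_POINTS, m=FIG1_SPACER, n=n)
        sigma = FIG1_MASS_PER_LENGTH / arch.total_monomers
        runs.append(
            PresetRun(
                label=f"n{n}",
                arch=arch,
                params=BrushParameters(sigma=sigma),
                eta=topological_ratio(n, FIG1_SPACER),
            )
        )
    return tuple(runs)


def _moment_grid_runs() -> tuple[PresetRun, ...]:
    runs = []
    for sigma in MOMENT_GRID_SIGMAS:
        for eta, (P, m, n) in MOMENT_GRID_ETA_SPECS.items():
            arch = GraftArchitecture.comb(P=P, m=m, n=n)
            runs.append(
                PresetRun(
                    label=f"sigma{sigma}_eta{eta}",
                    arch=arch,
                    params=BrushParameters(sigma=sigma),
                    eta=eta,
                )
            )
    return tuple(runs)


def _dc_runs(sigma: float = DC_SIGMA) -> tuple[PresetRun, ...]:
    runs = []
    for n1 in DC_N1_VALUES:
        n2 = DC_TOTAL_ARM - n1
        arch = GraftArchitecture(
            P1=DC_BRANCH_POINTS, P2=DC_BRANCH_POINTS,
            m1=DC_SPACER, m2=DC_SPACER, n1=n1, n2=n2,
        )
        runs.append(
            PresetRun(
                label=f"n1_{n1}_n2_{n2}",
                arch=arch,
                params=BrushParameters(sigma=sigma),
                eta=topological_ratio(n1 + n2, 2 * DC_SPACER),
            )
        )
    return tuple(runs)


def _force_runs() -> tuple[PresetRun, ...]:
    arch = GraftArchitecture.comb(**FORCE_COMB)
    eta = topological_ratio(FORCE_COMB["n"], FORCE_COMB["m"])
    return tuple(
        PresetRun(
            label=f"h{h:g}",
            arch=arch,
            params=BrushParameters.from_spacing(h),
            eta=eta,
        )
        for h in FORCE_H_GRID
    )


_BUILDERS = {
    "fig1": ("comb quartet end distributions (Nb=500, m=5, N*sigma=500)", _fig1_runs,
             ("profiles", "metrics")),
    "fig2": ("comb quartet density profiles + analytic overlay", _fig1_runs,
             ("profiles", "metrics", "fit")),
    "fig3": ("moment grid sigma x eta at N~=1000", _moment_grid_runs, ("metrics",)),
    "fig4": ("moment grid, SCF <H> vs analytic <H>", _moment_grid_runs, ("metrics",)),
    "fig5": ("double-comb end distributions (sigma=0.5)", _dc_runs, ("profiles", "metrics")),
    "fig6": ("double-comb molecular potentials vs z^2", _dc_runs, ("profiles", "metrics")),
    "fig7": ("double-comb moments vs n1/(n1+n2)", _dc_runs, ("metrics",)),
    "fig8": ("axial force vs grafting spacing (comb m=3, n=25)", _force_runs,
             ("metrics", "force")),
    "fig9": ("double-comb first-branch-point distributions", _dc_runs,
             ("profiles", "metrics")),
    "fig10": ("induced persistence length vs grafting spacing", _force_runs,
              ("metrics", "force")),
}

PRESET_NAMES = tuple(_BUILDERS)


def get_preset(name: str) -> ExperimentPreset:
    """Look up a named preset experiment."""
    try:
        desc, builder, outputs = _BUILDERS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {', '.join(_BUILDERS)}") from None
    return ExperimentPreset(name=name, description=desc, runs=builder(), outputs=outputs)
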