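"""Config-file handling: YAML schema, validation, round-trip emit.

A run configuration has three blocks::

    architecture: {P1: 10, P2: 10, m1: 3, m2: 3, n1: 25, n2: 25}
    brush:        {sigma: 0.5, chi: 0.0}       # or h: 2.0 instead of sigma
    solver:       {tolerance: 1.0e-8, mixing_step: 0.2, max_iter: 200000,
                   zmax: auto, anderson_depth: 5, init: theory}

Unknown keys raise a schema error naming the offending key path;
``parse -> emit -> parse`` is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import yaml

from .architecture import BrushParameters, GraftArchitecture
from .scf import SolverOptions

__all__ = ["RunConfig", "ConfigError", "load_config", "parse_config", "emit_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


@dataclass(frozen=True)
class RunConfig:
    arch: GraftArchitecture
    params: BrushParameters
    options: SolverOptions

    def to_dict(self) -> dict:
        zmax = self.options.zmax
        return {
            "architecture": {
                k: getattr(self.arch, k) for k in ("P1", "P2", "m1", "m2", "n1", "n2")
            },
            "brush": {"sigma": self.params.sigma, "chi": self.params.chi},
            "solver": {
                "tolerance": self.options.tolerance,
                "mixing_step": self.options.mixing_step,
                "max_iter": self.options.max_iter,
                "zmax": "auto" if zmax is None else zmax,
                "zmax_margin": self.options.zmax_margin,
                "anderson_depth": self.options.anderson_depth,
                "init": self.options.init,
            },
        }


_ARCH_KEYS = {"P1", "P2", "m1", "m2", "n1", "n2"}
_BRUSH_KEYS = {"sigma", "h", "chi"}
_SOLVER_KEYS = {
    "tolerance", "mixing_step", "max_iter", "zmax", "zmax_margin",
    "anderson_depth", "init",
}


def _check_keys(block: dict, allowed: set, path: str) -> None:
    for key in block:
        if key not in allowed:
            raise ConfigError(f"unknown config key '{path}.{key}'")


def parse_config(data: dict) -> RunConfig:
    """Validate a parsed mapping into a :class:`RunConfig`."""
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(data, {"architecture", "brush", "solver"}, path="")
    arch_block = data.get("architecture")
    if not isinstance(arch_block, dict):
        raise ConfigError("missing or invalid 'architecture' block")
    _check_keys(arch_block, _ARCH_KEYS, "architecture")
    try:
        arch = GraftArchitecture(**{k: arch_block.get(k, 0) for k in _ARCH_KEYS})
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"architecture: {exc}") from exc

    brush_block = data.get("brush", {})
    _check_keys(brush_block, _BRUSH_KEYS, "brush")
    if "sigma" in brush_block and "h" in brush_block:
        raise ConfigError("brush: give either 'sigma' or 'h', not both")
    chi = float(brush_block.get("chi", 0.0))
    try:
        if "h" in brush_block:
            params = BrushParameters.from_spacing(float(brush_block["h"]), chi)
        else:
            params = BrushParameters(float(brush_block.get("sigma", 1.0)), chi)
    except ValueError as exc:
        raise ConfigError(f"brush: {exc}") from exc

    solver_block = data.get("solver", {})
    _check_keys(solver_block, _SOLVER_KEYS, "solver")
    kwargs = dict(solver_block)
    if kwargs.get("zmax") in ("auto", None):
        kwargs["zmax"] = None
    try:
        options = SolverOptions(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"solver: {exc}") from exc
    return RunConfig(arch=arch, params=params, options=options)


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML config file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return parse_config(data)


def emit_config(config: RunConfig) -> str:
    """Serialize a config; ``parse(emit(c))`` equals ``c``."""
    return yaml.safe_dump(config.to_dict(), sort_keys=True)
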