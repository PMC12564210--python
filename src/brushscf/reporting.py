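"""Tabular output: TSV profiles with provenance headers, JSON metrics.

Profiles are written as two-column TSV (z, value) preceded by ``#``
metadata lines carrying the package version, a hash of the configuration,
the architecture, and solver diagnostics, so any output file identifies
the run that produced it.  Numeric columns are locale-independent
full-precision ``repr`` values.
"""

from __future__ import annotations

import hashlib
import io
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import __version__
from .scf import SCFSolution

__all__ = ["provenance_header", "write_profile_tsv", "write_metrics_json", "config_hash"]


def config_hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def provenance_header(solution: SCFSolution, extra: dict | None = None) -> str:
    arch = solution.arch
    meta = {
        "brushscf_version": __version__,
        "architecture": {k: getattr(arch, k) for k in ("P1", "P2", "m1", "m2", "n1", "n2")},
        "N": arch.total_monomers,
        "Nb": arch.backbone_length,
        "sigma": solution.params.sigma,
        "chi": solution.params.chi,
        "zmax": solution.lattice.zmax,
        "iterations": solution.iterations,
        "residual": solution.residual,
    }
    if extra:
        meta.update(extra)
    meta["config_hash"] = config_hash(json.dumps(meta, sort_keys=True, default=str))
    lines = [f"# {k}\t{json.dumps(v, default=str)}" for k, v in meta.items()]
    return "\n".join(lines)


def write_profile_tsv(
    path: str | Path,
    solution: SCFSolution,
    columns: dict[str, np.ndarray],
    extra_meta: dict | None = None,
) -> None:
    """Write per-shell columns keyed by name, with a provenance header."""
    buf = io.StringIO()
    buf.write(provenance_header(solution, extra_meta))
    buf.write("\nz\t" + "\t".join(columns) + "\n")
    z = solution.lattice.z
    arrays = [np.asarray(v, float) for v in columns.values()]
    for i in range(z.size):
        buf.write(repr(float(z[i])))
        for arr in arrays:
            buf.write("\t" + repr(float(arr[i])))
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


def write_metrics_json(path: str | Path, records: list[dict] | dict) -> None:
    """Write scalar metric records (dataclasses allowed) as JSON."""

    def default(obj):
        try:
            return asdict(obj)
        except TypeError:
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            return str(obj)

    Path(path).write_text(json.dumps(records, indent=2, default=default) + "\n")
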