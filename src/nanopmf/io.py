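"""Run configuration, result tables, manifests, and structure dumps.

Configurations are YAML with explicit units in the key names; unknown keys
are errors so that typos cannot silently fall back to defaults.  Every run
directory carries a JSON manifest with the fully resolved configuration and
the seeds actually used, and is named by a short hash of that manifest so a
replay reproduces the tables byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from importlib import metadata as _metadata
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .results import PMFCurve
from .state import MCState
from .system import SystemSpec, build_geometry, symmetric_salt

_CONFIG_SCHEMA = {
    "nanoparticles": {"count", "counts", "charge_e", "radius_A"},
    "salt": {"valence", "concentration_M", "ion_radius_A"},
    "conditions": {"temperature_K", "dielectric"},
    "run": {"separations_A", "x_ref_A", "replicates", "seed", "intervals",
            "threshold_kT", "max_steps", "burn_in", "max_cell_edge_A"},
    "pb": {"enabled", "levels", "tol", "omega", "max_sweeps"},
}


class ConfigError(ValueError):
    pass


def _check_keys(section: str, mapping: dict) -> None:
    allowed = _CONFIG_SCHEMA[section]
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in '{section}': {sorted(unknown)}; "
                          f"allowed: {sorted(allowed)}")


def load_config(path) -> dict:
    """Load and validate a run configuration; unknown keys are errors."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    unknown = set(raw) - set(_CONFIG_SCHEMA)
    if unknown:
        raise ConfigError(f"unknown top-level sections: {sorted(unknown)}")
    for section in raw:
        if not isinstance(raw[section], dict):
            raise ConfigError(f"section '{section}' must be a mapping")
        _check_keys(section, raw[section])
    cfg = {
        "nanoparticles": {"counts": [2, 4], "charge_e": -24.0,
                          "radius_A": 10.0},
        "salt": {"valence": 1, "concentration_M": 0.05, "ion_radius_A": 2.0},
        "conditions": {"temperature_K": 298.15, "dielectric": 78.0},
        "run": {"separations_A": [25.0], "x_ref_A": 40.0, "replicates": 3,
                "seed": 1, "intervals": 20, "threshold_kT": None,
                "max_steps": 3_000_000, "burn_in": 50_000,
                "max_cell_edge_A": 1300.0},
        "pb": {"enabled": False, "levels": None, "tol": 1e-4, "omega": 1.9,
               "max_sweeps": 30_000},
    }
    for section, vals in raw.items():
        cfg[section].update(vals)
    npc = cfg["nanoparticles"]
    if "count" in npc:
        npc["counts"] = [npc.pop("count")]
    return cfg


def spec_from_config(cfg: dict, count: int, separation: float) -> SystemSpec:
    npc = cfg["nanoparticles"]
    salt = cfg["salt"]
    cond = cfg["conditions"]
    npset = build_geometry(count, separation, charge=float(npc["charge_e"]),
                           radius=float(npc["radius_A"]))
    cat, an = symmetric_salt(int(salt["valence"]),
                             float(salt["concentration_M"]),
                             radius=float(salt["ion_radius_A"]))
    return SystemSpec(nanoparticles=npset, cation=cat, anion=an,
                      temperature=float(cond["temperature_K"]),
                      dielectric=float(cond["dielectric"]))


def package_version() -> str:
    try:
        return _metadata.version("nanopmf")
    except _metadata.PackageNotFoundError:  # editable corner cases
        return "unknown"


def manifest_hash(manifest: dict) -> str:
    blob = json.dumps(manifest, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_manifest(outdir: Path, manifest: dict) -> Path:
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path


def write_pmf_table(curve: PMFCurve, path) -> None:
    """PMF curve as tab-separated text with a commented header block."""
    path = Path(path)
    df = pd.DataFrame({
        "separation_A": curve.separations,
        "dG_kT": curve.dg,
        "stderr_kT": curve.stderr,
    })
    with open(path, "w") as fh:
        fh.write(f"# label: {curve.label}\n")
        fh.write(f"# x_ref_A: {curve.x_ref}\n")
        for key, val in sorted(curve.metadata.items()):
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_pmf_table(path) -> PMFCurve:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body = []
    for line in lines:
        if line.startswith("# "):
            key, _, val = line[2:].partition(":")
            meta[key.strip()] = val.strip()
        else:
            body.append(line)
    from io import StringIO
    df = pd.read_csv(StringIO("".join(body)), sep="\t")
    label = meta.pop("label", "unknown")
    x_ref = float(meta.pop("x_ref_A", 40.0))
    for k in ("M", "replicates", "seed"):
        if k in meta:
            meta[k] = int(float(meta[k]))
    for k in ("Z", "concentration", "cell_edge", "factor"):
        if k in meta:
            meta[k] = float(meta[k])
    return PMFCurve(separations=df["separation_A"].to_numpy(),
                    dg=df["dG_kT"].to_numpy(),
                    stderr=df["stderr_kT"].to_numpy(),
                    x_ref=x_ref, label=label, metadata=meta)


def write_ti_trace(ti, path) -> None:
    """Per-beta trace table: lam, steps, <U>, stderr, acceptance, converged."""
    df = pd.DataFrame({
        "lam": ti.lambdas,
        "steps": ti.steps,
        "mean_U_kT": ti.mean_energy,
        "stderr_kT": ti.stderr,
        "acceptance": ti.acceptance,
        "converged": ti.converged.astype(int),
    })
    with open(path, "w") as fh:
        fh.write("# thermodynamic-integration trace (energies in k_BT)\n")
        if ti.seed is not None:
            fh.write(f"# seed: {ti.seed}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def write_xyz(path, spec: SystemSpec, state: MCState, comment: str = "") -> None:
    """XYZ snapshot: 'P' tags nanoparticles, 'C'/'A' tag cat-/anions."""
    npset = spec.nanoparticles
    with open(path, "w") as fh:
        fh.write(f"{npset.count + state.n_ions}\n{comment}\n")
        for c in npset.centers:
            fh.write(f"P {c[0]:.4f} {c[1]:.4f} {c[2]:.4f}\n")
        for pos, v in zip(state.positions, state.valences):
            tag = "C" if v > 0 else "A"
            fh.write(f"{tag} {pos[0]:.4f} {pos[1]:.4f} {pos[2]:.4f}\n")


def write_field(path_prefix, field: np.ndarray, origin, spacing: float) -> None:
    """Gridded field as raw array plus a plain-text JSON header sidecar."""
    path_prefix = Path(path_prefix)
    np.save(path_prefix.with_suffix(".npy"), field)
    header = {"shape": list(field.shape),
              "origin_A": [float(o) for o in origin],
              "spacing_A": float(spacing)}
    with open(path_prefix.with_suffix(".json"), "w") as fh:
        json.dump(header, fh, indent=2)
        fh.write("\n")
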