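"""Configuration, ensemble containers, analytics files and run manifests.

Ensembles are stored in a compact binary array container (NumPy ``.npz``
with a JSON metadata record and an explicit frame count for truncation
detection) plus an optional human-readable text export: one
``locus_index x y z`` line per locus, frames separated by ``# frame k``
header lines, floats printed with 17 significant digits so the round trip
is bit-exact.

Run configs are YAML with strict unknown-key rejection; every run writes
back the fully resolved config it actually used.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import yaml

from .chain import ChromosomeSpec, EnergyModel, NuclearGeometry, TetherSpec
from .sampler import Ensemble, SamplerSchedule

__all__ = [
    "ConfigError",
    "EnsembleFormatError",
    "FORMAT_VERSION",
    "load_config",
    "dump_config",
    "write_ensemble",
    "read_ensemble",
    "write_conformations_text",
    "read_conformations_text",
    "write_matrix",
    "write_table",
    "write_manifest",
]

FORMAT_VERSION = 1


class ConfigError(ValueError):
    """Malformed run configuration."""


class EnsembleFormatError(IOError):
    """Corrupt, truncated or incompatible ensemble container."""


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_SCHEMA: dict[str, set[str]] = {
    "": {"scenario", "geometry", "seed", "outdir", "plots", "excluded_volume"},
    "scenario": {
        "experiment",
        "condition",
        "chromosome",
        "chromosome_b",
        "persistence_nm",
        "scale",
        "nu",
        "n_loci",
        "schedule",
    },
    "scenario.schedule": {"n_total", "n_burn_in", "thin"},
    "geometry": {"diameter_nm"},
}

_DEFAULTS = {
    "scenario": {
        "experiment": "homologue",
        "condition": "no_tether",
        "chromosome": "chrI",
        "persistence_nm": 200.0,
        "scale": "desk",
    },
    "geometry": {"diameter_nm": 2000.0},
    "seed": 0,
    "outdir": "bundle",
    "plots": False,
    "excluded_volume": False,
}


def _check_keys(block: dict, path: str) -> None:
    allowed = _SCHEMA.get(path)
    if allowed is None:
        return
    for key in block:
        if key not in allowed:
            where = path or "top level"
            raise ConfigError(f"unknown config key {key!r} in {where}")
        sub = f"{path}.{key}" if path else key
        if isinstance(block[key], dict):
            _check_keys(block[key], sub)


def load_config(path: str | Path) -> dict:
    """Read and validate a YAML run config, applying defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(raw, "")
    cfg = json.loads(json.dumps(_DEFAULTS))  # deep copy
    for key, value in raw.items():
        if isinstance(value, dict):
            cfg.setdefault(key, {}).update(value)
        else:
            cfg[key] = value
    return cfg


def dump_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


# ---------------------------------------------------------------------------
# Ensemble containers
# ---------------------------------------------------------------------------


def _ensemble_meta(ens: Ensemble) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "retained_count": ens.retained_count,
        "n_loci": ens.n_loci,
        "acceptance_rate": ens.acceptance_rate,
        "final_step_angles": list(ens.final_step_angles),
        "spec": asdict(ens.spec),
        "geometry": asdict(ens.model.geometry),
        "tether": asdict(ens.model.tether),
        "persistence_length_nm": ens.model.persistence_length_nm,
        "beta": ens.model.beta,
        "excluded_volume_enabled": ens.model.excluded_volume_enabled,
        "ev_min_dist_nm": ens.model.ev_min_dist_nm,
        "schedule": asdict(ens.schedule),
    }


def write_ensemble(ens: Ensemble, path: str | Path) -> Path:
    """Write an ensemble to a binary .npz container with JSON metadata."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        positions=ens.positions,
        metadata=np.frombuffer(
            json.dumps(_ensemble_meta(ens)).encode(), dtype=np.uint8
        ),
    )
    return path


def read_ensemble(path: str | Path) -> Ensemble:
    """Lossless load of :func:`write_ensemble` output, verifying frame counts."""
    try:
        with np.load(path) as data:
            positions = data["positions"]
            meta = json.loads(bytes(data["metadata"]).decode())
    except (OSError, KeyError, ValueError) as exc:
        raise EnsembleFormatError(f"cannot read ensemble container {path}: {exc}") from exc
    if meta.get("format_version") != FORMAT_VERSION:
        raise EnsembleFormatError(
            f"unsupported format version {meta.get('format_version')!r}"
        )
    if positions.ndim != 3 or positions.shape[0] != meta["retained_count"] or (
        positions.shape[1] != meta["n_loci"]
    ):
        raise EnsembleFormatError(
            f"frame count mismatch in {path}: stored shape {positions.shape}, "
            f"metadata says {meta['retained_count']} x {meta['n_loci']}"
        )
    spec = ChromosomeSpec(**meta["spec"])
    geometry = NuclearGeometry(
        radius_nm=meta["geometry"]["radius_nm"],
        spb_direction=tuple(meta["geometry"]["spb_direction"]),
    )
    tether = TetherSpec(
        mode=meta["tether"]["mode"],
        nu=meta["tether"]["nu"],
        mu=tuple(meta["tether"]["mu"]),
    )
    model = EnergyModel(
        spec=spec,
        geometry=geometry,
        tether=tether,
        persistence_length_nm=meta["persistence_length_nm"],
        beta=meta["beta"],
        excluded_volume_enabled=meta["excluded_volume_enabled"],
        ev_min_dist_nm=meta["ev_min_dist_nm"],
    )
    sched_kwargs = dict(meta["schedule"])
    sched_kwargs["move_mix"] = tuple(sched_kwargs["move_mix"])
    sched_kwargs["target_acceptance"] = tuple(sched_kwargs["target_acceptance"])
    schedule = SamplerSchedule(**sched_kwargs)
    return Ensemble(
        positions=positions,
        spec=spec,
        model=model,
        schedule=schedule,
        acceptance_rate=meta["acceptance_rate"],
        final_step_angles=tuple(meta["final_step_angles"]),
    )


def write_conformations_text(positions: np.ndarray, path: str | Path) -> None:
    """Human-readable per-frame coordinate blocks (bit-exact round trip)."""
    positions = np.asarray(positions, dtype=float)
    with open(path, "w") as fh:
        for frame_idx, frame in enumerate(positions):
            fh.write(f"# frame {frame_idx}\n")
            for locus_idx, (x, y, z) in enumerate(frame):
                fh.write(f"{locus_idx} {x:.17g} {y:.17g} {z:.17g}\n")


def read_conformations_text(path: str | Path) -> np.ndarray:
    """Inverse of :func:`write_conformations_text`."""
    frames: list[list[list[float]]] = []
    expected_frame = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line.split()
                if len(parts) != 3 or parts[1] != "frame" or int(parts[2]) != expected_frame:
                    raise EnsembleFormatError(f"bad frame header {line!r}")
                frames.append([])
                expected_frame += 1
                continue
            parts = line.split()
            if len(parts) != 4 or not frames:
                raise EnsembleFormatError(f"bad coordinate line {line!r}")
            if int(parts[0]) != len(frames[-1]):
                raise EnsembleFormatError(f"locus index out of order: {line!r}")
            frames[-1].append([float(parts[1]), float(parts[2]), float(parts[3])])
    if not frames:
        raise EnsembleFormatError(f"no frames in {path}")
    n_loci = len(frames[0])
    if any(len(f) != n_loci for f in frames):
        raise EnsembleFormatError(f"truncated frame detected in {path}")
    return np.asarray(frames, dtype=float)


# ---------------------------------------------------------------------------
# Analytics files and manifests
# ---------------------------------------------------------------------------


def write_matrix(matrix: np.ndarray, path: str | Path, header: str = "") -> None:
    """Delimited numeric matrix with a commented header."""
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.10g", header=header)


def write_table(columns: dict[str, np.ndarray], path: str | Path) -> None:
    """Tab-delimited table with a single header row."""
    names = list(columns)
    arr = np.column_stack([np.asarray(columns[n], dtype=float) for n in names])
    np.savetxt(path, arr, fmt="%.10g", delimiter="\t", header="\t".join(names))


def write_manifest(outdir: str | Path, extra: dict | None = None) -> Path:
    """List every artifact in ``outdir`` with its SHA-256 content hash."""
    outdir = Path(outdir)
    entries = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            entries[str(p.relative_to(outdir))] = hashlib.sha256(
                p.read_bytes()
            ).hexdigest()
    manifest = {"files": entries}
    if extra:
        manifest.update(extra)
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
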