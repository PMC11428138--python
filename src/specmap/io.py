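"""File formats, trajectory adapters, run configuration and reports.

Feature matrices travel as ``.npy`` or delimited text with a JSON
sidecar (``<file>.json``) holding ``dt`` and feature names.  Coordinates
are always nanometers internally; angstrom inputs must be converted at
the boundary with an explicit flag.  Indices are 0-based everywhere.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import pathlib
from typing import Optional, Sequence

import numpy as np

from .features import FeatureMatrix

__all__ = [
    "RunConfig",
    "read_trajectory",
    "read_matrix",
    "write_matrix",
    "load_features",
    "save_features",
    "write_report",
    "get_logger",
]

logger = logging.getLogger("specmap")


def get_logger(level: str = "INFO") -> logging.Logger:
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


@dataclasses.dataclass
class RunConfig:
    """Merged run configuration persisted next to every output set."""

    seed: int = 0
    out_dir: str = "."
    log_level: str = "INFO"
    extra: dict = dataclasses.field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))

    def write(self, path) -> None:
        pathlib.Path(path).write_text(self.to_json())


def read_trajectory(
    path: str,
    topology: str,
    selection: str = "name CA",
    units: str = "angstrom",
) -> np.ndarray:
    """Load coordinates via MDAnalysis; returns (T, N, 3) in nanometers.

    ``units`` names the file's length unit ("angstrom" or "nm"); there
    is no silent guessing.  MDAnalysis reports angstrom for standard
    formats, the default.
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading DCD/XTC/PDB trajectories requires the optional "
            "MDAnalysis dependency (pip install specmap[md])"
        ) from exc
    if units not in ("angstrom", "nm"):
        raise ValueError(f"units must be 'angstrom' or 'nm', got {units!r}")
    factor = 0.1 if units == "angstrom" else 1.0
    u = mda.Universe(topology, path)
    atoms = u.select_atoms(selection)
    if atoms.n_atoms == 0:
        raise ValueError(f"selection {selection!r} matches no atoms")
    coords = np.stack([atoms.positions.copy() for _ in u.trajectory])
    return coords * factor


def write_matrix(path, values: np.ndarray, sidecar: Optional[dict] = None) -> None:
    """Write an array as .npy or delimited text (by extension) + sidecar."""
    path = pathlib.Path(path)
    values = np.asarray(values)
    if path.suffix == ".npy":
        np.save(path, values)
    elif path.suffix in (".txt", ".tsv", ".csv", ".dat"):
        delim = "," if path.suffix == ".csv" else "\t"
        np.savetxt(path, values, delimiter=delim)
    else:
        raise ValueError(f"unsupported matrix format {path.suffix!r}")
    if sidecar is not None:
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar, indent=2)
        )


def read_matrix(path):
    """Inverse of write_matrix; returns (values, sidecar-or-None)."""
    path = pathlib.Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npy":
        values = np.load(path)
    elif path.suffix in (".txt", ".tsv", ".csv", ".dat"):
        delim = "," if path.suffix == ".csv" else None
        values = np.loadtxt(path, delimiter=delim)
    else:
        raise ValueError(f"unsupported matrix format {path.suffix!r}")
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else None
    return values, sidecar


def save_features(path, fm: FeatureMatrix) -> None:
    write_matrix(path, fm.values, sidecar={"dt": fm.dt, "names": fm.names})


def load_features(path) -> FeatureMatrix:
    values, sidecar = read_matrix(path)
    dt = 1.0
    names = None
    if sidecar:
        dt = float(sidecar.get("dt", 1.0))
        names = sidecar.get("names")
    return FeatureMatrix(values=values, dt=dt, names=names)


def write_report(out_dir, sections: dict) -> pathlib.Path:
    """Write a structured JSON run report; arrays are converted to lists."""

    def _convert(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        if isinstance(obj, dict):
            return {str(k): _convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_convert(v) for v in obj]
        return obj

    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "report.json"
    path.write_text(json.dumps(_convert(sections), indent=2))
    return path
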