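"""File formats, configuration and run manifests.

Canonical units: molar for concentrations, nm for trajectory coordinates
and RGYR outputs, Angstrom for structure files (PDB convention).  All CSV
is comma-separated UTF-8 with a mandatory header and '.' decimals.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from biotite import structure as bst
from biotite.structure.io import pdb as bpdb

from .errors import IntegrityError, ParseError, SchemaError
from .rgyr import Trajectory
from .synthetic import Structure

NM_PER_ANGSTROM = 0.1

_UNIT_TO_MOLAR = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "μM": 1e-6, "nM": 1e-9}

#: group tag <-> 3-letter PDB residue-name code
_GROUP_TO_RES = {
    "protein": "PRT",
    "flavonoid_core": "FLV",
    "glycoside": "GLC",
    "other": "OTH",
}
_RES_TO_GROUP = {v: k for k, v in _GROUP_TO_RES.items()}

_ELEMENT_MASS = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "NA": 22.990, "CL": 35.45, "X": 12.011,
}

REQUIRED_COLUMNS = (
    "compound_id",
    "enzyme_id",
    "concentration",
    "replicate",
    "percent_inhibition",
)


# ---------------------------------------------------------------------------
# inhibition tables
# ---------------------------------------------------------------------------


def read_inhibition_table(path) -> pd.DataFrame:
    """Read and validate a tidy inhibition CSV.

    Required columns: compound_id, enzyme_id, concentration (or
    concentration_m), replicate, percent_inhibition.  An optional
    ``concentration_unit`` column (M/mM/uM/nM) converts to molar; without
    it, concentrations are taken as molar.  Duplicate
    (compound, enzyme, concentration, replicate) keys are an integrity
    error; non-numeric concentrations report the offending row.
    """
    df = pd.read_csv(path)
    cols = dict.fromkeys(df.columns)
    if "concentration_m" in cols and "concentration" not in cols:
        df = df.rename(columns={"concentration_m": "concentration"})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column {col!r}")
    conc = pd.to_numeric(df["concentration"], errors="coerce")
    if conc.isna().any():
        row = int(conc.index[conc.isna()][0]) + 2  # 1-based incl. header
        raise ParseError(row, f"non-numeric concentration {df['concentration'][row - 2]!r}")
    if "concentration_unit" in df.columns:
        factors = df["concentration_unit"].map(_UNIT_TO_MOLAR)
        if factors.isna().any():
            bad = df["concentration_unit"][factors.isna()].iloc[0]
            raise SchemaError(f"unknown concentration unit {bad!r}")
        conc = conc * factors
    if (conc <= 0).any():
        row = int(conc.index[conc <= 0][0]) + 2
        raise ParseError(row, "concentration must be > 0")
    out = df.copy()
    out["concentration_m"] = conc.astype(float)
    out = out.drop(columns=[c for c in ("concentration", "concentration_unit") if c in out])
    key = ["compound_id", "enzyme_id", "concentration_m", "replicate"]
    if out.duplicated(subset=key).any():
        dup = out[out.duplicated(subset=key)].iloc[0]
        raise IntegrityError(
            f"duplicate record for {dup['compound_id']}/{dup['enzyme_id']} "
            f"at {dup['concentration_m']} M replicate {dup['replicate']}"
        )
    return out[["compound_id", "enzyme_id", "concentration_m", "replicate", "percent_inhibition"]]


def write_inhibition_table(table: pd.DataFrame, path) -> None:
    out = table.rename(columns={"concentration_m": "concentration"}).copy()
    out["concentration_unit"] = "M"
    out.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# structures and trajectories
# ---------------------------------------------------------------------------


def _mass_for_element(element: str, fallback=None) -> float:
    key = element.strip().upper()
    if key in _ELEMENT_MASS:
        return _ELEMENT_MASS[key]
    if fallback is not None:
        return float(fallback)
    raise SchemaError(f"unknown element {element!r} and no masses provided")


def _molecule_numbers(mol_ids) -> np.ndarray:
    order = dict.fromkeys(mol_ids)
    lut = {m: i + 1 for i, m in enumerate(order)}
    return np.array([lut[m] for m in mol_ids], dtype=int)


def _to_atom_array(coords_ang: np.ndarray, tags: pd.DataFrame, elements) -> bst.AtomArray:
    n = coords_ang.shape[0]
    arr = bst.AtomArray(n)
    arr.coord = np.asarray(coords_ang, dtype=np.float32)
    arr.chain_id = np.full(n, "A")
    arr.res_id = _molecule_numbers(tags["molecule_id"])
    arr.res_name = np.array([_GROUP_TO_RES.get(g, "OTH") for g in tags["group"]])
    arr.atom_name = np.array([f"{e}{i % 99 + 1}" for i, e in enumerate(elements)])
    arr.element = np.asarray(elements)
    arr.hetero = np.full(n, True)
    return arr


def write_pdb(path, coords_ang: np.ndarray, tags: pd.DataFrame, elements=None) -> None:
    """Write a (possibly multi-model) PDB; ``coords_ang`` is (atoms, 3) or
    (frames, atoms, 3), in Angstrom."""
    coords_ang = np.asarray(coords_ang, dtype=float)
    if coords_ang.ndim == 2:
        coords_ang = coords_ang[None]
    n_atoms = coords_ang.shape[1]
    if elements is None:
        elements = ["C"] * n_atoms
    models = [_to_atom_array(frame, tags, elements) for frame in coords_ang]
    stack = bst.stack(models)
    f = bpdb.PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def structure_to_pdb(structure: Structure, path) -> None:
    write_pdb(path, structure.coordinates, structure.atom_tags)


def trajectory_to_pdb(traj: Trajectory, path) -> None:
    write_pdb(path, traj.coordinates / NM_PER_ANGSTROM, traj.atom_tags)


def load_trajectory(path, frame_times=None, masses=None) -> Trajectory:
    """Load a multi-model PDB as a Trajectory (coordinates converted to nm).

    Masses come from the element column unless ``masses`` is given; group
    tags are decoded from the residue names written by :func:`write_pdb`
    (unknown residue names map to 'other').  ``frame_times`` defaults to
    1 ns per model.
    """
    f = bpdb.PDBFile.read(str(path))
    stack = f.get_structure(model=None)
    coords = np.asarray(stack.coord, dtype=float) * NM_PER_ANGSTROM
    if coords.ndim == 2:
        coords = coords[None]
    n_frames, n_atoms = coords.shape[:2]
    if masses is None:
        masses = np.array([_mass_for_element(e) for e in stack.element])
    tags = pd.DataFrame(
        {
            "molecule_id": [f"M{r:03d}" for r in stack.res_id],
            "group": [_RES_TO_GROUP.get(r, "other") for r in stack.res_name],
        }
    )
    if frame_times is None:
        frame_times = np.arange(n_frames, dtype=float)
    return Trajectory(
        coordinates=coords,
        masses=np.asarray(masses, dtype=float),
        frame_times=np.asarray(frame_times, dtype=float),
        atom_tags=tags,
    )


def write_xyz(path, coords_ang: np.ndarray, elements=None, frame_times=None) -> None:
    """Multi-frame XYZ (Angstrom); one block per frame with a time comment."""
    coords_ang = np.asarray(coords_ang, dtype=float)
    if coords_ang.ndim == 2:
        coords_ang = coords_ang[None]
    n_frames, n_atoms = coords_ang.shape[:2]
    if elements is None:
        elements = ["C"] * n_atoms
    if frame_times is None:
        frame_times = np.arange(n_frames, dtype=float)
    with open(path, "w") as fh:
        for f in range(n_frames):
            fh.write(f"{n_atoms}\n")
            fh.write(f"t={frame_times[f]:.6f} ns\n")
            for e, (x, y, z) in zip(elements, coords_ang[f]):
                fh.write(f"{e} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path) -> tuple[np.ndarray, list, np.ndarray]:
    """Read a multi-frame XYZ; returns (coords_ang, elements, frame_times).

    All frames must have the same atom count and element order.
    """
    frames, times = [], []
    elements: list = []
    with open(path) as fh:
        lines = fh.readlines()
    i, lineno = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ParseError(i + 1, f"expected atom count, got {lines[i].strip()!r}")
        comment = lines[i + 1].strip() if i + 1 < len(lines) else ""
        t = float(comment.split("=")[1].split()[0]) if "t=" in comment else float(len(frames))
        block = lines[i + 2 : i + 2 + n]
        if len(block) < n:
            raise ParseError(i + 2, f"frame truncated: expected {n} atom lines")
        coords, els = [], []
        for k, line in enumerate(block):
            parts = line.split()
            if len(parts) < 4:
                raise ParseError(i + 3 + k, f"malformed atom line {line.strip()!r}")
            els.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        if frames and len(coords) != frames[0].shape[0]:
            raise ParseError(i + 1, "atom count differs between frames")
        frames.append(np.asarray(coords))
        times.append(t)
        elements = els
        i += 2 + n
    if not frames:
        raise ParseError(1, "no frames found")
    return np.stack(frames), elements, np.asarray(times)


def write_tags(path, tags: pd.DataFrame, masses: np.ndarray, elements=None) -> None:
    """Sidecar tags CSV for XYZ trajectories."""
    out = tags.copy()
    out.insert(0, "atom_index", np.arange(len(tags)))
    out["mass"] = np.asarray(masses, dtype=float)
    if elements is not None:
        out["element"] = elements
    out.to_csv(path, index=False)


def load_xyz_trajectory(xyz_path, tags_path) -> Trajectory:
    """Assemble a Trajectory from a multi-frame XYZ plus its tags sidecar."""
    coords_ang, _, times = read_xyz(xyz_path)
    tags = pd.read_csv(tags_path)
    for col in ("molecule_id", "group", "mass"):
        if col not in tags.columns:
            raise SchemaError(f"tags file missing column {col!r}")
    if len(tags) != coords_ang.shape[1]:
        raise IntegrityError(
            f"tags rows ({len(tags)}) != atoms per frame ({coords_ang.shape[1]})"
        )
    return Trajectory(
        coordinates=coords_ang * NM_PER_ANGSTROM,
        masses=tags["mass"].to_numpy(dtype=float),
        frame_times=times,
        atom_tags=tags[["molecule_id", "group"]],
    )


# ---------------------------------------------------------------------------
# configs and manifests
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise SchemaError("config root must be a mapping")
    return cfg


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, seed=None, config_path=None, inputs=(), extra=None) -> dict:
    """Reproducibility manifest: version, config hash, input digests, seed."""
    from . import __version__

    manifest = {
        "tool": "flavokit",
        "version": __version__,
        "seed": seed,
        "config": {
            "path": str(config_path) if config_path else None,
            "sha256": sha256_of(config_path) if config_path else None,
        },
        "inputs": {str(p): sha256_of(p) for p in inputs},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
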