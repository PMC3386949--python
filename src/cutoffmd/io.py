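"""File formats: XYZ and PDB structures, JSON system sidecars, multi-frame
XYZ trajectories with CSV feature tables, and YAML run configuration.

PDB files are read for coordinates and topology hints only; charges, LJ
parameters and masses cannot be stored in XYZ/PDB, so generators write a
JSON sidecar carrying the full parameter set, which simulate/eval-forces
consume.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import Bond, ParticleSystem
from .dynamics import Trajectory

_DEFAULT_MASS = 12.0


class FormatError(ValueError):
    pass


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("pdb", "xyz", "json"):
        return suffix
    raise FormatError(f"cannot infer format from {path.name!r}")


def read_structure(path, format: str | None = None, box_edge: float | None = None) -> ParticleSystem:
    """Read coordinates/labels/residues from a PDB, XYZ or JSON system file.

    For PDB/XYZ the returned system is partial: charges and LJ parameters
    are zero and masses default to 12 amu; the box is taken from the file
    where available (XYZ comment "box_edge=L", JSON), from the box_edge
    argument, or sized to the coordinate span plus 20 A.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "json":
        return read_system_json(path)
    if fmt == "xyz":
        return _read_xyz(path, box_edge)
    if fmt == "pdb":
        return _read_pdb(path, box_edge)
    raise FormatError(f"unknown format {fmt!r}")


def _auto_box(positions: np.ndarray, box_edge: float | None) -> float:
    if box_edge is not None:
        return box_edge
    span = float(np.max(positions.max(axis=0) - positions.min(axis=0)))
    return span + 20.0


def _read_xyz(path: Path, box_edge: float | None) -> ParticleSystem:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise FormatError(f"{path}:1: expected an atom count header")
    comment = lines[1] if len(lines) > 1 else ""
    if box_edge is None and "box_edge=" in comment:
        box_edge = float(comment.split("box_edge=")[1].split()[0])
    body = lines[2 : 2 + n]
    if len(body) < n:
        raise FormatError(
            f"{path}: count header says {n} atoms but only {len(body)} lines follow"
        )
    labels, coords = [], []
    for ln, line in enumerate(body, start=3):
        parts = line.split()
        if len(parts) < 4:
            raise FormatError(f"{path}:{ln}: malformed XYZ record {line!r}")
        labels.append(parts[0])
        try:
            coords.append([float(x) for x in parts[1:4]])
        except ValueError:
            raise FormatError(f"{path}:{ln}: non-numeric coordinate in {line!r}")
    pos = np.array(coords)
    return ParticleSystem(
        positions=pos,
        box_edge=_auto_box(pos, box_edge),
        masses=_DEFAULT_MASS,
        labels=labels,
    )


def _read_pdb(path: Path, box_edge: float | None) -> ParticleSystem:
    import warnings

    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    labels, coords, res_idx = [], [], []
    residues = {}
    for atom in structure.get_atoms():
        res = atom.get_parent()
        key = (res.get_parent().id, res.id)
        residues.setdefault(key, len(residues))
        labels.append(atom.get_name())
        coords.append(atom.coord)
        res_idx.append(residues[key])
    if not coords:
        raise FormatError(f"{path}: no ATOM/HETATM records found")
    pos = np.array(coords, dtype=float)
    return ParticleSystem(
        positions=pos,
        box_edge=_auto_box(pos, box_edge),
        masses=_DEFAULT_MASS,
        labels=labels,
        residue_index=np.array(res_idx),
    )


def write_structure(system: ParticleSystem, path, format: str | None = None) -> None:
    """Write coordinates as XYZ (with a box_edge comment) or PDB."""
    path = Path(path)
    fmt = format or _infer_format(path)
    labels = system.labels or ["C"] * system.n_particles
    if fmt == "xyz":
        lines = [str(system.n_particles), f"box_edge={system.box_edge:.6f}"]
        for lab, (x, y, z) in zip(labels, system.positions):
            lines.append(f"{lab:<4s} {x:14.8f} {y:14.8f} {z:14.8f}")
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "pdb":
        # without residue assignments every particle gets its own residue so
        # that (residue, atom name) identities stay unique for PDB parsers
        res = (
            system.residue_index
            if system.residue_index is not None
            else np.arange(system.n_particles)
        )
        lines = [
            f"CRYST1{system.box_edge:9.3f}{system.box_edge:9.3f}"
            f"{system.box_edge:9.3f}  90.00  90.00  90.00 P 1           1"
        ]
        seen_in_res: dict[tuple[int, str], int] = {}
        for k, (lab, (x, y, z)) in enumerate(zip(labels, system.positions)):
            name = lab[:4]
            count = seen_in_res.get((int(res[k]), name), 0)
            seen_in_res[(int(res[k]), name)] = count + 1
            if count:
                name = f"{lab[:2]}{count}"[:4]
            lines.append(
                f"ATOM  {k + 1:5d} {name:^4s} GLY A{int(res[k]) + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            )
        lines.append("END")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise FormatError(f"unknown structure format {fmt!r}")


def write_system_json(system: ParticleSystem, path) -> None:
    """Full-fidelity JSON system file (all nonbonded parameters included)."""
    payload = {
        "box_edge": system.box_edge,
        "positions": system.positions.tolist(),
        "velocities": system.velocities.tolist(),
        "charges": system.charges.tolist(),
        "lj_sigma": system.lj_sigma.tolist(),
        "lj_epsilon": system.lj_epsilon.tolist(),
        "masses": system.masses.tolist(),
        "bonds": [[b.i, b.j, b.length, b.k] for b in system.bonds],
        "constrained_bonds": [
            [b.i, b.j, b.length, b.k] for b in system.constrained_bonds
        ],
        "exclusions": sorted(map(list, system.exclusions)),
        "labels": system.labels,
        "residue_index": (
            system.residue_index.tolist() if system.residue_index is not None else None
        ),
    }
    Path(path).write_text(json.dumps(payload))


def read_system_json(path) -> ParticleSystem:
    d = json.loads(Path(path).read_text())
    return ParticleSystem(
        positions=np.array(d["positions"]),
        box_edge=d["box_edge"],
        charges=np.array(d["charges"]),
        lj_sigma=np.array(d["lj_sigma"]),
        lj_epsilon=np.array(d["lj_epsilon"]),
        masses=np.array(d["masses"]),
        velocities=np.array(d["velocities"]),
        bonds=[Bond(int(i), int(j), l, k) for i, j, l, k in d["bonds"]],
        constrained_bonds=[
            Bond(int(i), int(j), l, k) for i, j, l, k in d["constrained_bonds"]
        ],
        exclusions={(int(i), int(j)) for i, j in d["exclusions"]},
        labels=d.get("labels"),
        residue_index=(
            np.array(d["residue_index"]) if d.get("residue_index") is not None else None
        ),
    )


def write_trajectory(traj: Trajectory, xyz_path, csv_path=None) -> None:
    """Multi-frame XYZ (when coordinates are present) plus a CSV feature
    table with the time column first. csv_path defaults to the XYZ path with
    a .features.csv suffix."""
    if traj.n_frames == 0:
        raise ValueError("refusing to write an empty trajectory")
    xyz_path = Path(xyz_path)
    csv_path = Path(csv_path) if csv_path else xyz_path.with_suffix(".features.csv")
    if traj.positions is not None:
        chunks = []
        n = traj.positions.shape[1]
        for t, frame in zip(traj.times, traj.positions):
            chunks.append(f"{n}\ntime={t:.6f}")
            for x, y, z in frame:
                chunks.append(f"X    {x:14.8f} {y:14.8f} {z:14.8f}")
        xyz_path.write_text("\n".join(chunks) + "\n")
    df = pd.DataFrame({"time": traj.times, **traj.features})
    df.to_csv(csv_path, index=False, float_format="%.12g")


def read_trajectory_features(csv_path) -> Trajectory:
    """Feature-table CSV (time column first) back into a Trajectory."""
    df = pd.read_csv(csv_path)
    if "time" not in df.columns:
        raise FormatError(f"{csv_path}: no time column")
    feats = {c: df[c].to_numpy() for c in df.columns if c != "time"}
    return Trajectory(times=df["time"].to_numpy(), features=feats)


def load_config(path) -> dict:
    """YAML run configuration; returns a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: top level must be a mapping")
    return cfg
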