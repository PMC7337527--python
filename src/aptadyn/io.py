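"""Readers and writers: multi-model PDB, XYZ trajectories, nonbonded
parameter tables (TSV) and result tables.

The PDB dialect is the wwPDB v3.3 fixed-width layout; MODEL/ENDMDL records
delimit frames (an implicit single model is allowed), HETATM is treated
like ATOM and only the first altloc of an atom is kept.  Coordinates are Å
everywhere; energies are written in kcal/mol.
"""

from __future__ import annotations

import dataclasses
import os
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .model import AtomRecord, Frame, Topology, Trajectory

PARAMETER_COLUMNS = ["residue_name", "atom_name", "charge", "lj_epsilon", "lj_rmin_half"]


class ParameterTable:
    """Nonbonded parameters keyed on (residue_name, atom_name).

    A row whose residue_name is ``*`` acts as an atom-name fallback for any
    residue, so generic element-level entries can back up specific ones.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in PARAMETER_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"parameter table missing columns {missing}")
        frame = frame[PARAMETER_COLUMNS].copy()
        for col in ("charge", "lj_epsilon", "lj_rmin_half"):
            frame[col] = pd.to_numeric(frame[col], errors="raise")
            if not np.all(np.isfinite(frame[col].to_numpy())):
                raise ValueError(f"non-finite value in column {col!r}")
        keys = list(zip(frame["residue_name"], frame["atom_name"]))
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate parameter keys: {dupes}")
        self.frame = frame
        self._map = {k: (row.charge, row.lj_epsilon, row.lj_rmin_half)
                     for k, row in zip(keys, frame.itertuples())}

    def __len__(self) -> int:
        return len(self.frame)

    def lookup(self, residue_name: str, atom_name: str) -> tuple[float, float, float]:
        """(charge, lj_epsilon, lj_rmin_half); falls back to residue '*'."""
        key = (residue_name, atom_name)
        if key in self._map:
            return self._map[key]
        star = ("*", atom_name)
        if star in self._map:
            return self._map[star]
        raise KeyError(f"no parameters for {residue_name}:{atom_name}")


def read_parameters(path: str | os.PathLike) -> ParameterTable:
    """Read a tab-separated parameter table with a header row."""
    frame = pd.read_csv(path, sep="\t", dtype={"residue_name": str, "atom_name": str})
    return ParameterTable(frame)


def write_parameters(table: ParameterTable, path: str | os.PathLike) -> None:
    table.frame.to_csv(path, sep="\t", index=False)


def apply_parameters(topology: Topology, table: ParameterTable) -> Topology:
    """Return a topology whose atoms carry charges/LJ parameters from *table*."""
    atoms = []
    for a in topology.atoms:
        q, eps, rmin = table.lookup(a.residue_name, a.name)
        atoms.append(dataclasses.replace(a, charge=q, lj_epsilon=eps, lj_rmin_half=rmin))
    new = Topology(atoms)
    for name, idx in topology.groups.items():
        new.add_group(name, idx)
    return new


# ---------------------------------------------------------------- PDB

def _guess_element(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if len(stripped) >= 2 and stripped[:2].upper() in ("NA", "CL", "MG", "ZN"):
        return stripped[:2].upper()
    return stripped[:1].upper() if stripped else "X"


def read_pdb(path: str | os.PathLike) -> Trajectory:
    """Parse a (multi-model) PDB file into a Trajectory.

    One Frame per MODEL block; the atom order must be identical across
    models and only the first altloc of each atom is kept.
    """
    models: list[list[tuple]] = []
    current: list[tuple] = []
    in_model = False
    seen_altloc: set[tuple] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6].strip()
            if rec == "MODEL":
                if current:
                    models.append(current)
                current = []
                in_model = True
                seen_altloc = set()
            elif rec == "ENDMDL":
                models.append(current)
                current = []
                in_model = False
            elif rec in ("ATOM", "HETATM"):
                if len(line.rstrip("\n")) < 54:
                    raise ValueError(f"{path}:{lineno}: truncated ATOM record")
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    altloc = line[16].strip()
                    res_name = line[17:21].strip()
                    chain = line[21].strip() or "A"
                    res_id = int(line[22:26])
                    xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: malformed fixed-width record") from exc
                atom_key = (chain, res_id, name)
                if altloc:
                    if atom_key in seen_altloc:
                        continue  # keep first altloc only
                    seen_altloc.add(atom_key)
                element = line[76:78].strip() if len(line) >= 78 else ""
                element = element or _guess_element(name)
                current.append((serial, name, element, res_name, res_id, chain, xyz))
    if current:
        models.append(current)
    models = [m for m in models if m]
    if not models:
        raise ValueError(f"{path}: no ATOM/HETATM records found")
    n0 = len(models[0])
    for i, m in enumerate(models):
        if len(m) != n0:
            raise ValueError(
                f"{path}: model {i + 1} has {len(m)} atoms, model 1 has {n0}")
    atoms = [AtomRecord(serial=s, name=n, element=e, residue_name=rn,
                        residue_id=ri, chain_id=c)
             for (s, n, e, rn, ri, c, _) in models[0]]
    top = Topology(atoms)
    frames = [Frame(np.array([rec[6] for rec in m]), frame_index=i)
              for i, m in enumerate(models)]
    return Trajectory(top, frames)


def write_pdb(trajectory: Trajectory, path: str | os.PathLike) -> None:
    """Write a Trajectory as a multi-model PDB (single frame: no MODEL cards)."""
    top = trajectory.topology
    multi = trajectory.n_frames > 1
    with open(path, "w") as fh:
        for imodel, frame in enumerate(trajectory.frames, start=1):
            if multi:
                fh.write(f"MODEL     {imodel:4d}\n")
            for a, (x, y, z) in zip(top.atoms, frame.coordinates):
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                rec = "HETATM" if a.is_water or a.residue_name in ("ATP", "AMP") else "ATOM"
                fh.write(f"{rec:<6s}{a.serial % 100000:5d} {name:<4s} "
                         f"{a.residue_name[:3]:<3s} {a.chain_id[:1]}{a.residue_id:4d}    "
                         f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                         f"          {a.element:>2s}\n")
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------- XYZ

def read_xyz_trajectory(path: str | os.PathLike, topology: Topology) -> Trajectory:
    """Read a concatenated XYZ file (count / comment / N element-x-y-z lines)."""
    frames: list[Frame] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}: expected atom count at line {pos + 1}") from exc
        if count != topology.n_atoms:
            raise ValueError(f"{path}: frame has {count} atoms, topology has "
                             f"{topology.n_atoms}")
        block = lines[pos + 2: pos + 2 + count]
        if len(block) < count:
            raise ValueError(f"{path}: truncated frame starting at line {pos + 1}")
        coords = np.empty((count, 3))
        for i, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: short coordinate line {pos + 3 + i}")
            try:
                coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric coordinate at line "
                                 f"{pos + 3 + i}") from exc
        frames.append(Frame(coords, frame_index=len(frames)))
        pos += 2 + count
    if not frames:
        raise ValueError(f"{path}: empty XYZ file")
    return Trajectory(topology, frames)


def write_xyz_trajectory(trajectory: Trajectory, path: str | os.PathLike,
                         comment: str = "aptadyn frame") -> None:
    top = trajectory.topology
    with open(path, "w") as fh:
        for frame in trajectory.frames:
            fh.write(f"{top.n_atoms}\n{comment} {frame.frame_index}\n")
            for a, (x, y, z) in zip(top.atoms, frame.coordinates):
                fh.write(f"{a.element:<2s} {x:14.6f} {y:14.6f} {z:14.6f}\n")


# ---------------------------------------------------------------- results

def write_results(tables: Mapping[str, object], out_dir: str | os.PathLike) -> list[Path]:
    """Write analysis results as TSV files; returns the files written.

    GeometrySeries → one per-frame table each plus a joint ``summary.tsv``
    of mean ± std per observable (2-decimal presentation); an
    EnergyDecomposition → its residue table; a FreeEnergyProfile →
    (bin_center, free_energy) rows.
    """
    from .energetics import EnergyDecomposition
    from .free_energy import FreeEnergyProfile
    from .geometry import GeometrySeries

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    summary_rows = []
    for name, obj in tables.items():
        safe = name.replace(" ", "_")
        if isinstance(obj, GeometrySeries):
            p = out / f"{safe}.tsv"
            pd.DataFrame({"frame": np.arange(len(obj.values)),
                          "value": obj.values}).to_csv(p, sep="\t", index=False)
            written.append(p)
            summary_rows.append({
                "observable": obj.label or name, "unit": obj.unit,
                "n_frames": len(obj.values),
                "mean": round(obj.mean, 6), "std": round(obj.std, 6),
                "summary": f"{obj.mean:.2f} (±{obj.std:.2f})"})
        elif isinstance(obj, EnergyDecomposition):
            p = out / f"{safe}.tsv"
            obj.table.to_csv(p, sep="\t", index=False)
            written.append(p)
        elif isinstance(obj, FreeEnergyProfile):
            p = out / f"{safe}.tsv"
            pd.DataFrame({"bin_center": obj.bin_centers,
                          "free_energy": obj.values}).to_csv(p, sep="\t", index=False)
            written.append(p)
        else:
            raise TypeError(f"cannot write result of type {type(obj).__name__}")
    summary = out / "summary.tsv"
    cols = ["observable", "unit", "n_frames", "mean", "std", "summary"]
    pd.DataFrame(summary_rows, columns=cols).to_csv(summary, sep="\t", index=False)
    written.append(summary)
    return written
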