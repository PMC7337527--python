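"""Pairwise nonbonded interaction energies between atom groups.

The model is the classic fixed-charge force-field form: Coulomb
electrostatics with a configurable relative dielectric plus a 12-6
Lennard-Jones term with geometric-mean well depths and additive Rmin/2
radii.  Only intermolecular (cross-group) pairs are summed, so bonded
exclusions never arise.  Three cutoff schemes are provided:

* ``infinite`` — full-range sum (used by the brute-force oracles),
* ``truncate`` — hard cutoff at r ≤ cutoff,
* ``switch``   — CHARMM-style switching function between r_switch and
  cutoff, applied multiplicatively to both terms (default, 10 → 12 Å).

The per-residue decomposition mirrors the standard "interaction energy of
the ligand with each binding-site base" analysis: for every frame the
ligand–residue electrostatic and van-der-Waals sums are recorded, then
summarized as mean ± std over frames (kcal/mol throughout).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .model import Topology, Trajectory, Frame
from .units import COULOMB_CONSTANT

SCHEMES = ("infinite", "truncate", "switch")


def pair_energy(q_i: float, q_j: float, eps_i: float, eps_j: float,
                rmin_half_i: float, rmin_half_j: float, r: float,
                dielectric: float = 1.0) -> tuple[float, float]:
    """(electrostatic, van der Waals) energy of one atom pair, kcal/mol.

    elec = 332.0636·q_i·q_j/(ε_r·r); vdw = ε_ij[(Rmin_ij/r)¹² − 2(Rmin_ij/r)⁶]
    with ε_ij = sqrt(ε_i·ε_j) and Rmin_ij = rmin_half_i + rmin_half_j.
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    elec = COULOMB_CONSTANT * q_i * q_j / (dielectric * r)
    eps_ij = np.sqrt(eps_i * eps_j)
    if eps_ij > 0:
        ratio6 = ((rmin_half_i + rmin_half_j) / r) ** 6
        vdw = eps_ij * (ratio6 * ratio6 - 2.0 * ratio6)
    else:
        vdw = 0.0
    return float(elec), float(vdw)


def switching_function(r: np.ndarray, r_switch: float, cutoff: float) -> np.ndarray:
    """CHARMM switching factor: 1 below r_switch, 0 beyond cutoff, C¹ between."""
    r = np.asarray(r, dtype=float)
    s = np.ones_like(r)
    off2, on2, r2 = cutoff ** 2, r_switch ** 2, r ** 2
    mid = (r > r_switch) & (r <= cutoff)
    denom = (off2 - on2) ** 3
    s[mid] = ((off2 - r2[mid]) ** 2 * (off2 + 2.0 * r2[mid] - 3.0 * on2)) / denom
    s[r > cutoff] = 0.0
    return s


def _group_params(topology: Topology, idx: np.ndarray):
    q = np.array([topology.atoms[i].charge for i in idx])
    eps = np.array([topology.atoms[i].lj_epsilon for i in idx])
    rmin = np.array([topology.atoms[i].lj_rmin_half for i in idx])
    return q, eps, rmin


def group_interaction_energy(frame: Frame, topology: Topology,
                             group_a: Sequence[int], group_b: Sequence[int],
                             cutoff: float = 12.0, scheme: str = "switch",
                             r_switch: float = 10.0, dielectric: float = 1.0
                             ) -> tuple[float, float]:
    """(elec, vdw) sum over all cross pairs of two disjoint groups, kcal/mol."""
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if np.intersect1d(a, b).size:
        raise ValueError("groups overlap; interaction energy is cross-group only")
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    if scheme != "infinite" and cutoff <= 0:
        raise ValueError("cutoff must be positive")
    qa, ea, ra = _group_params(topology, a)
    qb, eb, rb = _group_params(topology, b)
    r = cdist(frame.coordinates[a], frame.coordinates[b])
    if np.any(r == 0):
        raise ValueError("coincident atoms across groups (r = 0)")
    elec = COULOMB_CONSTANT * np.outer(qa, qb) / (dielectric * r)
    eps_ij = np.sqrt(np.outer(ea, eb))
    rmin_ij = ra[:, None] + rb[None, :]
    with np.errstate(divide="ignore"):
        ratio6 = np.where(eps_ij > 0, (rmin_ij / r) ** 6, 0.0)
    vdw = eps_ij * (ratio6 ** 2 - 2.0 * ratio6)
    if scheme == "truncate":
        mask = r <= cutoff
        elec, vdw = elec * mask, vdw * mask
    elif scheme == "switch":
        s = switching_function(r, r_switch, cutoff)
        elec, vdw = elec * s, vdw * s
    return float(elec.sum()), float(vdw.sum())


@dataclass
class EnergyDecomposition:
    """Per-residue ligand interaction energies averaged over a trajectory.

    ``table`` has one row per residue plus grand-total rows, with columns
    label, elec_mean, elec_std, vdw_mean, vdw_std, total_mean, total_std.
    ``per_frame`` maps each row label to an (n_frames, 2) array of
    (elec, vdw) values for downstream statistics.
    """

    table: pd.DataFrame
    per_frame: dict[str, np.ndarray]

    def row(self, label: str) -> pd.Series:
        match = self.table[self.table["label"] == label]
        if match.empty:
            raise KeyError(f"no decomposition row {label!r}")
        return match.iloc[0]


def _summary_row(label: str, ev: np.ndarray) -> dict:
    elec, vdw = ev[:, 0], ev[:, 1]
    total = elec + vdw
    return {"label": label,
            "elec_mean": elec.mean(), "elec_std": elec.std(),
            "vdw_mean": vdw.mean(), "vdw_std": vdw.std(),
            "total_mean": total.mean(), "total_std": total.std()}


def decompose_by_residue(trajectory: Trajectory, topology: Topology,
                         ligand_group: Sequence[int],
                         residue_list: Sequence[int],
                         cutoff: float = 12.0, scheme: str = "switch",
                         r_switch: float = 10.0, dielectric: float = 1.0,
                         receptor_group: Sequence[int] | None = None
                         ) -> EnergyDecomposition:
    """Ligand interaction energy decomposed over the listed residues.

    Also reports two grand totals: ``site`` (union of the listed residues)
    and ``receptor`` (the full receptor group, defaulting to every
    non-ligand, non-water atom).
    """
    if not len(residue_list):
        raise ValueError("residue list is empty")
    lig = np.asarray(ligand_group, dtype=int)
    res_idx: dict[str, np.ndarray] = {}
    for rid in residue_list:
        idx = np.asarray(topology.residue_atoms(rid), dtype=int)
        if np.intersect1d(idx, lig).size:
            raise ValueError(f"residue {rid} overlaps the ligand group")
        name = topology.atoms[idx[0]].residue_name
        res_idx[f"{name}{rid}"] = idx
    if receptor_group is None:
        lig_set = set(lig.tolist())
        receptor_group = [i for i, a in enumerate(topology.atoms)
                          if i not in lig_set and not a.is_water]
    rec = np.asarray(receptor_group, dtype=int)
    site = np.concatenate(list(res_idx.values()))
    kw = dict(cutoff=cutoff, scheme=scheme, r_switch=r_switch, dielectric=dielectric)

    n = trajectory.n_frames
    per_frame = {label: np.empty((n, 2)) for label in res_idx}
    per_frame["site"] = np.empty((n, 2))
    per_frame["receptor"] = np.empty((n, 2))
    for k, frame in enumerate(trajectory.frames):
        for label, idx in res_idx.items():
            per_frame[label][k] = group_interaction_energy(
                frame, topology, lig, idx, **kw)
        per_frame["site"][k] = group_interaction_energy(
            frame, topology, lig, site, **kw)
        per_frame["receptor"][k] = group_interaction_energy(
            frame, topology, lig, rec, **kw)
    rows = [_summary_row(label, ev) for label, ev in per_frame.items()]
    return EnergyDecomposition(table=pd.DataFrame(rows), per_frame=per_frame)


def interaction_energy_definition(e_complex: float, e_monomer_1: float,
                                  e_monomer_2: float) -> float:
    """Supermolecular interaction energy ΔE_int = E_complex − (E_1 + E_2)."""
    vals = (e_complex, e_monomer_1, e_monomer_2)
    if not all(np.isfinite(vals)):
        raise ValueError("energies must be finite")
    return e_complex - e_monomer_1 - e_monomer_2


def total_potential_energy(frame: Frame, topology: Topology,
                           indices: Sequence[int] | None = None,
                           dielectric: float = 1.0) -> float:
    """Full-range pairwise nonbonded energy of one atom set (kcal/mol).

    Intended for small rigid toys where ΔE_int from single-point energies
    can be compared with the direct cross-group sum.
    """
    idx = (np.arange(topology.n_atoms) if indices is None
           else np.asarray(indices, dtype=int))
    q, eps, rmin = _group_params(topology, idx)
    xyz = frame.coordinates[idx]
    r = cdist(xyz, xyz)
    iu = np.triu_indices(len(idx), k=1)
    rij = r[iu]
    if np.any(rij == 0):
        raise ValueError("coincident atoms")
    elec = COULOMB_CONSTANT * np.outer(q, q)[iu] / (dielectric * rij)
    eps_ij = np.sqrt(np.outer(eps, eps))[iu]
    rmin_ij = (rmin[:, None] + rmin[None, :])[iu]
    ratio6 = np.where(eps_ij > 0, (rmin_ij / rij) ** 6, 0.0)
    vdw = eps_ij * (ratio6 ** 2 - 2.0 * ratio6)
    return float(elec.sum() + vdw.sum())
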