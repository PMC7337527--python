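"""Water-mediated contact analysis.

A water is a *bridge* in a frame iff it simultaneously hydrogen-bonds
(water as donor or acceptor, same geometric thresholds as
:func:`aptadyn.geometry.detect_hbonds`) to at least one ligand atom and at
least one receptor atom.  Cavity hydration is quantified as the number of
water oxygens within a radius of the binding-site centroid.

Hydrogen attachment is inferred geometrically (an H within 1.2 Å of a
polar heavy atom), so no bond topology is required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .geometry import GeometrySeries, _angle_deg
from .model import Frame, Topology, Trajectory

POLAR_ELEMENTS = ("N", "O")
H_COVALENT_CUTOFF = 1.2  # Å


@dataclass(frozen=True)
class WaterBridgeRecord:
    """One water bridging the ligand and the receptor in one frame."""

    frame_index: int
    water_residue_id: int
    ligand_atom: int
    receptor_atom: int
    ligand_hbond_length: float
    ligand_hbond_angle: float
    receptor_hbond_length: float
    receptor_hbond_angle: float

    def to_dict(self) -> dict:
        return asdict(self)


def _polar_partners(topology: Topology, frame: Frame, group: Sequence[int]
                    ) -> tuple[list[tuple[int, int]], list[int]]:
    """(donor (D,H) pairs, acceptor heavy atoms) within one atom group."""
    xyz = frame.coordinates
    group = list(group)
    heavies = [i for i in group if topology.atoms[i].element in POLAR_ELEMENTS]
    hydrogens = [i for i in group if topology.atoms[i].element == "H"]
    donors = []
    for h in hydrogens:
        if not heavies:
            break
        d = min(heavies, key=lambda j: np.linalg.norm(xyz[h] - xyz[j]))
        if np.linalg.norm(xyz[h] - xyz[d]) <= H_COVALENT_CUTOFF:
            donors.append((d, h))
    return donors, heavies


def _hbonded(xyz: np.ndarray, donors: Sequence[tuple[int, int]],
             acceptors: Sequence[int], d_max: float, angle_min: float
             ) -> tuple[int, int, float, float] | None:
    """Best (closest) donor→acceptor contact meeting the thresholds, if any."""
    best = None
    for d, h in donors:
        for a in acceptors:
            if a in (d, h):
                continue
            r = float(np.linalg.norm(xyz[a] - xyz[h]))
            if r == 0 or r > d_max:
                continue
            ang = _angle_deg(xyz[d] - xyz[h], xyz[a] - xyz[h])
            if ang >= angle_min and (best is None or r < best[2]):
                best = (h, a, r, ang)
    return best


def water_bridges(trajectory: Trajectory, topology: Topology,
                  ligand_group: Sequence[int], receptor_group: Sequence[int],
                  d_max: float = 2.5, angle_min: float = 120.0
                  ) -> tuple[list[WaterBridgeRecord], GeometrySeries]:
    """All ligand–water–receptor bridges plus the per-frame count series."""
    waters = topology.water_residues()
    if not waters:
        warnings.warn("no water residues in topology; bridge analysis is empty")
        counts = np.zeros(trajectory.n_frames)
        return [], GeometrySeries("water_bridge_count", counts, "count")

    records: list[WaterBridgeRecord] = []
    counts = np.zeros(trajectory.n_frames)
    for k, frame in enumerate(trajectory.frames):
        xyz = frame.coordinates
        lig_don, lig_acc = _polar_partners(topology, frame, ligand_group)
        rec_don, rec_acc = _polar_partners(topology, frame, receptor_group)
        for (chain, rid), widx in waters:
            w_don, w_acc = _polar_partners(topology, frame, widx)
            # water↔ligand: water donates to ligand acceptor OR accepts from
            # a ligand donor; same on the receptor side.
            lig_hit = (_hbonded(xyz, w_don, lig_acc, d_max, angle_min)
                       or _hbonded(xyz, lig_don, w_acc, d_max, angle_min))
            if lig_hit is None:
                continue
            rec_hit = (_hbonded(xyz, w_don, rec_acc, d_max, angle_min)
                       or _hbonded(xyz, rec_don, w_acc, d_max, angle_min))
            if rec_hit is None:
                continue
            lig_atom = lig_hit[1] if lig_hit[1] in set(ligand_group) else lig_hit[0]
            rec_atom = rec_hit[1] if rec_hit[1] in set(receptor_group) else rec_hit[0]
            records.append(WaterBridgeRecord(
                frame_index=k, water_residue_id=rid,
                ligand_atom=int(lig_atom), receptor_atom=int(rec_atom),
                ligand_hbond_length=lig_hit[2], ligand_hbond_angle=lig_hit[3],
                receptor_hbond_length=rec_hit[2], receptor_hbond_angle=rec_hit[3]))
            counts[k] += 1
    return records, GeometrySeries("water_bridge_count", counts, "count")


def cavity_water_count(trajectory: Trajectory, topology: Topology,
                       site_group: Sequence[int], radius: float = 5.0
                       ) -> GeometrySeries:
    """Number of water oxygens within *radius* Å of the site centroid, per frame."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    site = np.asarray(site_group, dtype=int)
    if site.size == 0:
        raise ValueError("site group is empty")
    oxy = [idx[0] if topology.atoms[idx[0]].element == "O"
           else next(i for i in idx if topology.atoms[i].element == "O")
           for _, idx in topology.water_residues()]
    counts = np.zeros(trajectory.n_frames)
    for k, frame in enumerate(trajectory.frames):
        centroid = frame.coordinates[site].mean(axis=0)
        if oxy:
            d = np.linalg.norm(frame.coordinates[oxy] - centroid, axis=1)
            counts[k] = int(np.sum(d <= radius))
    return GeometrySeries("cavity_water_count", counts, "count")
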