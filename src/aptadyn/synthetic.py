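"""Synthetic desk-scale fixtures with the statistical structure the
analyses assume.

:func:`generate_binding_site_ensemble` builds a 27-residue single-strand
DNA topology with an intercalated adenosine-triphosphate ligand and poses,
frame by frame, the binding-site geometry so that every named observable
(the two ligand–G22 hydrogen bonds H1/H2, the base6–ligand and
base23–ligand stacking distance and plane angle) **equals** a value drawn
from a configurable Gaussian.  Draws are censored (clamped) at the
observable's valid range; the defaults are the wild-type literature
reference values, with mutant variants available.  Because the geometry is
solved exactly per frame, the geometry engine recovers the configured
means to sampling error — the generator tests analysis code, not MD
physics, and observables are drawn independently (no cross-correlations).

Waters use the rigid 3-site geometry (O–H 0.9572 Å, H–O–H 104.52°);
bridging waters are planted with ideal hydrogen-bond geometry on a
per-frame schedule, bulk waters are placed uniformly outside a clash
shell.  :func:`make_toy_potential` supplies analytic 1-D potentials (with
exact PMFs) for the free-energy engine, and :func:`generate_energy_toy`
random charged systems for energetics oracles.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .io import ParameterTable, write_parameters, write_pdb, write_xyz_trajectory
from .model import (AtomRecord, Frame, HBondDefinition, RingDefinition,
                    Topology, Trajectory, build_topology)

OH_BOND = 0.9572       # Å, rigid 3-site water
HOH_ANGLE = 104.52     # degrees
NH_BOND = 1.01         # Å
RING_BOND = 1.39       # Å, aromatic C–C/C–N

PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")

#: 27-mer single-strand sequence used for fixtures; the binding site is
#: residues 5, 6, 21, 22, 23 (G G G G A) with a second pocket at 9/10/19.
SEQUENCE = "ACCTGGGGGAGTATTGCGGAGGAAGGT"

#: Wild-type and mutant observable defaults: (mean, std) for H-bond H1/H2
#: length (Å) and angle (deg) and base6/base23 stacking distance (Å) and
#: plane angle (deg).  ``None`` marks an observable the variant lacks.
VARIANT_OBSERVABLES: dict[str, dict[str, tuple[float, float] | None]] = {
    "wt": {"h1_length": (2.07, 0.16), "h1_angle": (162.0, 9.5),
           "h2_length": (2.03, 0.13), "h2_angle": (161.4, 9.9),
           "stack6_distance": (4.09, 0.22), "stack6_angle": (13.4, 6.9),
           "stack23_distance": (3.80, 0.24), "stack23_angle": (22.0, 7.8)},
    "G6A": {"h1_length": (2.12, 0.18), "h1_angle": (154.9, 11.9),
            "h2_length": (2.15, 0.39), "h2_angle": (151.0, 19.3),
            "stack6_distance": (3.75, 0.18), "stack6_angle": (7.2, 5.4),
            "stack23_distance": (3.69, 0.19), "stack23_angle": (6.5, 5.3)},
    "A23G": {"h1_length": (2.11, 0.15), "h1_angle": (159.4, 10.5),
             "h2_length": (1.84, 0.15), "h2_angle": (172.6, 8.6),
             "stack6_distance": (4.68, 0.21), "stack6_angle": (20.2, 7.5),
             "stack23_distance": (4.05, 0.19), "stack23_angle": (22.2, 4.7)},
    "G6C_A23C": {"h1_length": None, "h1_angle": None,
                 "h2_length": None, "h2_angle": None,
                 "stack6_distance": (4.04, 0.18), "stack6_angle": (13.3, 5.4),
                 "stack23_distance": (3.79, 0.38), "stack23_angle": (10.9, 7.4)},
}

_VARIANT_BASE = {"G6A": {6: "A"}, "A23G": {23: "G"}, "G6C_A23C": {6: "C", 23: "C"}}

_OBSERVABLE_RANGE = {
    "h1_length": (0.5, 10.0), "h2_length": (0.5, 10.0),
    "h1_angle": (0.0, 180.0), "h2_angle": (0.0, 180.0),
    "stack6_distance": (0.5, 20.0), "stack23_distance": (0.5, 20.0),
    "stack6_angle": (0.0, 90.0), "stack23_angle": (0.0, 90.0),
}


@dataclass
class EnsembleSpec:
    """Full description of one synthetic binding-site ensemble."""

    n_frames: int = 2000
    seed: int = 0
    variant: str = "wt"
    observables: dict[str, tuple[float, float] | None] = field(default_factory=dict)
    terminal_noise: float = 1.2    # Å rigid jitter for residues 1 and 27
    loop_noise: float = 0.8        # Å for the loop residues 12–16
    backbone_noise: float = 0.12   # Å elsewhere
    n_bulk_waters: int = 12
    bridge_schedule: dict[int, int] = field(default_factory=dict)  # frame → 0/1/2

    def __post_init__(self) -> None:
        if self.variant not in VARIANT_OBSERVABLES:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose from {sorted(VARIANT_OBSERVABLES)}")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        merged = dict(VARIANT_OBSERVABLES[self.variant])
        merged.update(self.observables)
        self.observables = merged
        for key, ms in self.observables.items():
            if ms is not None and ms[1] < 0:
                raise ValueError(f"negative std for {key}")
        for f, n in self.bridge_schedule.items():
            if n not in (0, 1, 2):
                raise ValueError("bridge schedule values must be 0, 1 or 2")


# ------------------------------------------------------------ templates

def _rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    x, y, z = axis
    return np.array([
        [c + x * x * (1 - c), x * y * (1 - c) - z * s, x * z * (1 - c) + y * s],
        [y * x * (1 - c) + z * s, c + y * y * (1 - c), y * z * (1 - c) - x * s],
        [z * x * (1 - c) - y * s, z * y * (1 - c) + x * s, c + z * z * (1 - c)]])


def _base_template(base: str) -> dict[str, np.ndarray]:
    """Idealized planar base template (z = 0), ring centroid at the origin.

    Purines carry the fused 9-atom bicyclic ring, pyrimidines the 6-ring;
    exocyclic donor/acceptor atoms are attached in-plane.
    """
    hexagon = {}
    for i, nm in enumerate(PYRIMIDINE_RING):
        ang = math.radians(90.0 + 60.0 * i)
        hexagon[nm] = np.array([RING_BOND * math.cos(ang),
                                RING_BOND * math.sin(ang), 0.0])
    atoms = dict(hexagon)
    purine = base in ("A", "G")
    if purine:
        p4, p5 = hexagon["C4"], hexagon["C5"]
        mid = 0.5 * (p4 + p5)
        out = mid / np.linalg.norm(mid)
        s = float(np.linalg.norm(p5 - p4))
        cp = mid + (s / (2.0 * math.tan(math.pi / 5))) * out
        rp = s / (2.0 * math.sin(math.pi / 5))
        a4 = math.atan2(p4[1] - cp[1], p4[0] - cp[0])
        a5 = math.atan2(p5[1] - cp[1], p5[0] - cp[0])
        d = math.atan2(math.sin(a4 - a5), math.cos(a4 - a5))
        step = -math.copysign(math.radians(72.0), d)
        for j, nm in enumerate(("N7", "C8", "N9"), start=1):
            ang = a5 + j * step
            atoms[nm] = cp + rp * np.array([math.cos(ang), math.sin(ang), 0.0])

    def _exo(parent: str, dist: float) -> np.ndarray:
        p = atoms[parent]
        u = p[:2] / np.linalg.norm(p[:2])
        return p + dist * np.array([u[0], u[1], 0.0])

    if base == "A":
        atoms["N6"] = _exo("C6", 1.34)
        u = (atoms["N6"] - atoms["C6"])[:2]
        u = u / np.linalg.norm(u)
        rot60 = np.array([[math.cos(math.radians(60)), -math.sin(math.radians(60))],
                          [math.sin(math.radians(60)), math.cos(math.radians(60))]])
        atoms["H61"] = atoms["N6"] + NH_BOND * np.array([*(rot60 @ u), 0.0])
        atoms["H62"] = atoms["N6"] + NH_BOND * np.array([*(rot60.T @ u), 0.0])
    elif base == "G":
        atoms["O6"] = _exo("C6", 1.23)
        atoms["N2"] = _exo("C2", 1.34)
        u = (atoms["N2"] - atoms["C2"])[:2]
        u = u / np.linalg.norm(u)
        rot60 = np.array([[math.cos(math.radians(60)), -math.sin(math.radians(60))],
                          [math.sin(math.radians(60)), math.cos(math.radians(60))]])
        atoms["H21"] = atoms["N2"] + NH_BOND * np.array([*(rot60 @ u), 0.0])
        atoms["H22"] = atoms["N2"] + NH_BOND * np.array([*(rot60.T @ u), 0.0])
    elif base == "C":
        atoms["O2"] = _exo("C2", 1.23)
        atoms["N4"] = _exo("C4", 1.34)
    elif base == "T":
        atoms["O2"] = _exo("C2", 1.23)
        atoms["O4"] = _exo("C4", 1.23)
    else:
        raise ValueError(f"unknown base {base!r}")
    ring = PURINE_RING if purine else PYRIMIDINE_RING
    centroid = np.mean([atoms[nm] for nm in ring], axis=0)
    return {nm: pos - centroid for nm, pos in atoms.items()}


def _ligand_template() -> dict[str, np.ndarray]:
    """Adenine ring of the ligand plus a short charged triphosphate tail."""
    atoms = _base_template("A")
    n9 = atoms["N9"]
    u = n9[:2] / np.linalg.norm(n9[:2])
    e = np.array([u[0], u[1], 0.0])
    dn = np.array([0.0, 0.0, -1.0])
    atoms["C1'"] = n9 + 1.47 * e + 0.4 * dn
    chain = atoms["C1'"]
    tail = ["O5'", "PA", "O1A", "PB", "O1B", "PG", "O1G", "O2G"]
    for i, nm in enumerate(tail, start=1):
        chain = atoms["C1'"] + 1.55 * i * e + 0.35 * i * dn
        atoms[nm] = chain
    return atoms


def _default_charge(residue_name: str, atom_name: str, element: str) -> float:
    if residue_name == "HOH":
        return -0.834 if element == "O" else 0.417
    if element == "P":
        return 1.10
    if element == "O":
        return -0.60
    if element == "H":
        return 0.32
    if element == "N":
        return -0.70 if atom_name in ("N2", "N4", "N6") else -0.50
    return 0.25  # aromatic carbons and the sugar carbon


_LJ_BY_ELEMENT = {"N": (0.20, 1.85), "C": (0.07, 1.99), "O": (0.12, 1.70),
                  "H": (0.046, 0.40), "P": (0.585, 2.15)}


def default_parameter_table(topology: Topology) -> ParameterTable:
    """Element-typed charges and LJ parameters for every fixture atom."""
    rows, seen = [], set()
    for a in topology.atoms:
        key = (a.residue_name, a.name)
        if key in seen:
            continue
        seen.add(key)
        eps, rmin = _LJ_BY_ELEMENT[a.element]
        rows.append({"residue_name": a.residue_name, "atom_name": a.name,
                     "charge": _default_charge(a.residue_name, a.name, a.element),
                     "lj_epsilon": eps, "lj_rmin_half": rmin})
    return ParameterTable(pd.DataFrame(rows))


# ------------------------------------------------------------- posing

def _perp_unit(v: np.ndarray, azimuth: float) -> np.ndarray:
    """A unit vector perpendicular to v at the given azimuth angle (rad)."""
    v = v / np.linalg.norm(v)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, v)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    p1 = np.cross(v, helper)
    p1 /= np.linalg.norm(p1)
    p2 = np.cross(v, p1)
    return math.cos(azimuth) * p1 + math.sin(azimuth) * p2


def _draw(rng: np.random.Generator, mean_std: tuple[float, float],
          lo: float, hi: float) -> float:
    mean, std = mean_std
    return float(min(max(rng.normal(mean, std), lo), hi))


@dataclass
class SyntheticEnsemble:
    """Generated trajectory plus everything needed to analyze it."""

    trajectory: Trajectory
    topology: Topology
    parameters: ParameterTable
    spec: EnsembleSpec
    h1: HBondDefinition | None
    h2: HBondDefinition | None
    ring_ligand: RingDefinition
    ring6: RingDefinition
    ring23: RingDefinition
    nonwc_donors: list[tuple[int, int]]
    nonwc_acceptors: list[int]


def generate_binding_site_ensemble(spec: EnsembleSpec) -> SyntheticEnsemble:
    """Generate the posed binding-site ensemble described by *spec*.

    Deterministic per seed.  Residues 1–27 are the DNA strand, residue 28
    the ligand, residues 29+ the waters (planted bridge waters first).
    """
    rng = np.random.default_rng(spec.seed)
    bases = {i + 1: b for i, b in enumerate(SEQUENCE)}
    for rid, b in _VARIANT_BASE.get(spec.variant, {}).items():
        bases[rid] = b
    templates = {b: _base_template(b) for b in "AGCT"}
    lig_template = _ligand_template()

    # --- static atom list (topology) -----------------------------------
    records: list[AtomRecord] = []
    index_of: dict[tuple[int, str], int] = {}

    def _add(rid: int, rname: str, aname: str, element: str) -> None:
        index_of[(rid, aname)] = len(records)
        records.append(AtomRecord(serial=len(records) + 1, name=aname,
                                  element=element, residue_name=rname,
                                  residue_id=rid))

    for rid in range(1, 28):
        b = bases[rid]
        for aname in templates[b]:
            _add(rid, f"D{b}", aname, aname.strip("'")[0])
    for aname in lig_template:
        _add(28, "ATP", aname, aname.strip("'")[0])
    n_bridge = 2 if any(v == 2 for v in spec.bridge_schedule.values()) else (
        1 if any(v == 1 for v in spec.bridge_schedule.values()) else 0)
    n_bridge = max(n_bridge, max(spec.bridge_schedule.values(), default=0))
    n_waters = n_bridge + spec.n_bulk_waters
    for w in range(n_waters):
        rid = 28 + 1 + w
        for aname, el in (("O", "O"), ("H1", "H"), ("H2", "H")):
            _add(rid, "HOH", aname, el)

    group_spec = {
        "ligand": {"residue_ids": [28]},
        "site": {"residue_ids": [5, 6, 21, 22, 23]},
        "receptor": {"residue_ids": list(range(1, 28))},
    }
    topology = build_topology(records, group_spec)
    n_atoms = len(records)

    def idx(rid: int, aname: str) -> int:
        return index_of[(rid, aname)]

    # --- static layout of the non-posed strand -------------------------
    path_center = np.array([14.0, 0.0, 0.0])
    base_position: dict[int, np.ndarray] = {}
    for rid in range(1, 28):
        ang = 2.0 * math.pi * (rid - 1) / 27.0
        base_position[rid] = path_center + 10.0 * np.array(
            [math.cos(ang), math.sin(ang), 0.15 * (rid - 14)])
    # keep the posed site residues near the ligand at the origin
    base_position[22] = np.array([6.8, 0.0, 0.0])
    base_position[21] = np.array([6.4, 4.2, 1.2])
    base_position[5] = np.array([6.4, -4.2, -1.2])
    base_position[6] = np.array([0.0, 0.0, 4.1])
    base_position[23] = np.array([0.0, 0.0, -3.8])

    jitter_sigma = {}
    for rid in range(1, 28):
        if rid in (1, 27):
            jitter_sigma[rid] = spec.terminal_noise
        elif 12 <= rid <= 16:
            jitter_sigma[rid] = spec.loop_noise
        else:
            jitter_sigma[rid] = spec.backbone_noise

    obs = spec.observables
    has_hbonds = obs["h1_length"] is not None
    lig_names = list(lig_template)
    lig_idx = np.array([idx(28, nm) for nm in lig_names])
    lig_xyz = np.array([lig_template[nm] for nm in lig_names])

    donor6 = {"G": ("N2", "H21"), "A": ("N6", "H61")}.get(bases[6])
    donor23 = {"G": ("N2", "H21"), "A": ("N6", "H61")}.get(bases[23])

    bridge_partners = []   # (ligand acceptor, receptor override atom)
    if n_bridge >= 1:
        bridge_partners.append((idx(28, "N7"), idx(22, "O6") if bases[22] == "G"
                                else idx(22, "N3")))
    if n_bridge >= 2:
        bridge_partners.append((idx(28, "O1G"), idx(21, "O6") if bases[21] == "G"
                                else idx(21, "N3")))

    frames: list[Frame] = []
    for f in range(spec.n_frames):
        xyz = np.zeros((n_atoms, 3))
        # ligand: static pose at the origin, adenine ring in the z=0 plane
        xyz[lig_idx] = lig_xyz

        # stacked bases 6 and 23: exact centroid distance and plane angle
        for rid, dist_key, ang_key, zsign in (
                (6, "stack6_distance", "stack6_angle", +1.0),
                (23, "stack23_distance", "stack23_angle", -1.0)):
            d = _draw(rng, obs[dist_key], *_OBSERVABLE_RANGE[dist_key])
            th = _draw(rng, obs[ang_key], *_OBSERVABLE_RANGE[ang_key])
            rot = _rotation(np.array([1.0, 0.0, 0.0]), zsign * th)
            shift = np.array([0.0, 0.0, zsign * d])
            for aname, pos in templates[bases[rid]].items():
                xyz[idx(rid, aname)] = rot @ pos + shift

        # remaining strand residues: rigid template + per-residue jitter
        for rid in range(1, 28):
            if rid in (6, 23):
                continue
            shift = base_position[rid] + rng.normal(0.0, jitter_sigma[rid], 3)
            for aname, pos in templates[bases[rid]].items():
                xyz[idx(rid, aname)] = pos + shift

        # hydrogen bonds H1/H2: pose G22 partner atoms exactly
        if has_hbonds:
            n6 = xyz[idx(28, "N6")]
            h61 = xyz[idx(28, "H61")]
            u = (h61 - n6) / np.linalg.norm(h61 - n6)
            l1 = _draw(rng, obs["h1_length"], *_OBSERVABLE_RANGE["h1_length"])
            a1 = _draw(rng, obs["h1_angle"], *_OBSERVABLE_RANGE["h1_angle"])
            p = _perp_unit(u, rng.uniform(0.0, 2.0 * math.pi))
            w_dir = math.cos(math.radians(a1)) * (-u) + math.sin(math.radians(a1)) * p
            xyz[idx(22, "N3")] = h61 + l1 * w_dir

            n1 = xyz[idx(28, "N1")]
            v = n1 / np.linalg.norm(n1)   # radially outward from the ring
            l2 = _draw(rng, obs["h2_length"], *_OBSERVABLE_RANGE["h2_length"])
            a2 = _draw(rng, obs["h2_angle"], *_OBSERVABLE_RANGE["h2_angle"])
            h22 = n1 + l2 * v
            p2 = _perp_unit(v, rng.uniform(0.0, 2.0 * math.pi))
            a_dir = math.cos(math.radians(a2)) * (-v) + math.sin(math.radians(a2)) * p2
            xyz[idx(22, "H22")] = h22
            xyz[idx(22, "N2")] = h22 + NH_BOND * a_dir

        # planted non-Watson–Crick pairs: base6→G21 and base23→G5
        for (rid_d, donor, rid_a) in ((6, donor6, 21), (23, donor23, 5)):
            if donor is None:
                continue
            dn, hn = donor
            dpos, hpos = xyz[idx(rid_d, dn)], xyz[idx(rid_d, hn)]
            u = (hpos - dpos) / np.linalg.norm(hpos - dpos)
            p = _perp_unit(u, rng.uniform(0.0, 2.0 * math.pi))
            w_dir = (math.cos(math.radians(170.0)) * (-u)
                     + math.sin(math.radians(170.0)) * p)
            xyz[idx(rid_a, "N3")] = hpos + 1.90 * w_dir

        # waters: planted bridges per schedule, the rest parked/bulk
        n_active = spec.bridge_schedule.get(f, 0)
        solute = xyz[: lig_idx.max() + 1]
        placed_oxygens: list[np.ndarray] = []
        hoh_half = math.radians(HOH_ANGLE)
        for w in range(n_waters):
            rid = 29 + w
            o_i, h1_i, h2_i = idx(rid, "O"), idx(rid, "H1"), idx(rid, "H2")
            if w < len(bridge_partners) and w < n_active:
                acc_idx, rec_idx = bridge_partners[w]
                acc = xyz[acc_idx]
                e = np.array([1.0, 1.0, 0.45]) if w == 0 else np.array([-0.4, 1.0, -0.8])
                e = e / np.linalg.norm(e)
                ow = acc + (OH_BOND + 1.90) * e
                xyz[o_i] = ow
                xyz[h1_i] = ow - OH_BOND * e   # donates to the ligand acceptor
                p = _perp_unit(e, rng.uniform(0.0, 2.0 * math.pi))
                e2 = math.cos(hoh_half) * (-e) + math.sin(hoh_half) * p
                xyz[h2_i] = ow + OH_BOND * e2
                # receptor partner posed collinear with the second O–H bond
                xyz[rec_idx] = ow + (OH_BOND + 1.90) * e2
                placed_oxygens.append(ow)
            else:
                if w < len(bridge_partners):
                    ow = np.array([40.0 + 6.0 * w, 40.0, 40.0])  # parked
                else:
                    for _ in range(1000):
                        ow = rng.uniform(-20.0, 20.0, 3)
                        if placed_oxygens and np.min(np.linalg.norm(
                                np.array(placed_oxygens) - ow, axis=1)) < 3.0:
                            continue
                        if np.min(np.linalg.norm(solute - ow, axis=1)) >= 3.6:
                            break
                    else:
                        raise RuntimeError("could not place bulk water (draw cap)")
                    placed_oxygens.append(ow)
                e = _perp_unit(np.array([0.0, 0.0, 1.0]),
                               rng.uniform(0.0, 2.0 * math.pi))
                p = _perp_unit(e, rng.uniform(0.0, 2.0 * math.pi))
                e2 = math.cos(hoh_half) * e + math.sin(hoh_half) * p
                xyz[o_i] = ow
                xyz[h1_i] = ow + OH_BOND * e
                xyz[h2_i] = ow + OH_BOND * e2
        frames.append(Frame(xyz, frame_index=f))

    trajectory = Trajectory(topology, frames)
    parameters = default_parameter_table(topology)
    ring_of = lambda rid: RingDefinition(
        tuple(idx(rid, nm) for nm in
              (PURINE_RING if bases[rid] in "AG" else PYRIMIDINE_RING)),
        label=f"{bases[rid]}{rid}")
    h1 = h2 = None
    if has_hbonds:
        h1 = HBondDefinition(idx(28, "N6"), idx(28, "H61"), idx(22, "N3"), "H1")
        h2 = HBondDefinition(idx(22, "N2"), idx(22, "H22"), idx(28, "N1"), "H2")
    nonwc_donors = []
    nonwc_acceptors = []
    for (rid_d, donor, rid_a) in ((6, donor6, 21), (23, donor23, 5)):
        if donor is None:
            continue
        nonwc_donors.append((idx(rid_d, donor[0]), idx(rid_d, donor[1])))
        nonwc_acceptors.append(idx(rid_a, "N3"))
    return SyntheticEnsemble(
        trajectory=trajectory, topology=topology, parameters=parameters,
        spec=spec, h1=h1, h2=h2,
        ring_ligand=RingDefinition(tuple(idx(28, nm) for nm in PURINE_RING),
                                   label="ATP"),
        ring6=ring_of(6), ring23=ring_of(23),
        nonwc_donors=nonwc_donors, nonwc_acceptors=nonwc_acceptors)


def write_ensemble(ensemble: SyntheticEnsemble, out_dir: str | Path) -> dict[str, str]:
    """Write PDB + XYZ + parameter TSV + provenance JSON; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"pdb": str(out / "ensemble.pdb"),
             "xyz": str(out / "ensemble.xyz"),
             "parameters": str(out / "parameters.tsv"),
             "provenance": str(out / "provenance.json")}
    write_pdb(ensemble.trajectory, paths["pdb"])
    write_xyz_trajectory(ensemble.trajectory, paths["xyz"])
    write_parameters(ensemble.parameters, paths["parameters"])
    spec_dict = asdict(ensemble.spec)
    spec_dict["bridge_schedule"] = {str(k): v for k, v
                                    in ensemble.spec.bridge_schedule.items()}
    with open(paths["provenance"], "w") as fh:
        json.dump({"spec": spec_dict, "n_atoms": ensemble.topology.n_atoms},
                  fh, indent=2, default=list)
    return paths


# -------------------------------------------------------- toy potentials

@dataclass
class ToyPotentialSpec:
    kind: str = "double_well"   # harmonic | double_well | piecewise_pmf
    params: dict = field(default_factory=dict)


@dataclass
class ToyPotential:
    """Analytic 1-D potential with gradient and exact PMF."""

    kind: str
    potential: Callable
    gradient: Callable
    analytic_pmf: Callable
    params: dict


def make_toy_potential(spec: ToyPotentialSpec) -> ToyPotential:
    """Build (potential, gradient, analytic PMF) for the requested kind.

    * harmonic: U = ½k(x−c)²
    * double_well: U = h((x/b)² − 1)² — minima at ±b, barrier h at 0
    * piecewise_pmf: monotone piecewise-cubic through configurable knots
      shaped like a ligand-dissociation profile (bound minimum, interior
      barrier, flat plateau)
    """
    p = dict(spec.params)
    if spec.kind == "harmonic":
        k = p.setdefault("k", 2.0)
        c = p.setdefault("center", 0.0)
        pot = lambda x: 0.5 * k * (x - c) ** 2
        grad = lambda x: k * (x - c)
        return ToyPotential(spec.kind, pot, grad, pot, p)
    if spec.kind == "double_well":
        h = p.setdefault("barrier", 3.0)
        b = p.setdefault("half_separation", 2.0)
        pot = lambda x: h * ((x / b) ** 2 - 1.0) ** 2
        grad = lambda x: 4.0 * h * x * ((x / b) ** 2 - 1.0) / b ** 2
        return ToyPotential(spec.kind, pot, grad, pot, p)
    if spec.kind == "piecewise_pmf":
        barrier = p.setdefault("barrier", 7.4)
        plateau = p.setdefault("plateau", 5.4)
        knots = p.setdefault("knots", [
            (2.0, 8.0), (4.0, 0.0), (12.0, barrier),
            (15.0, plateau), (25.0, plateau)])
        xs = np.array([q[0] for q in knots])
        ys = np.array([q[1] for q in knots])
        interp = PchipInterpolator(xs, ys, extrapolate=True)
        deriv = interp.derivative()
        pot = lambda x: np.asarray(interp(x), dtype=float)[()]
        grad = lambda x: np.asarray(deriv(x), dtype=float)[()]
        return ToyPotential(spec.kind, pot, grad, pot, p)
    raise ValueError(f"unknown toy potential kind {spec.kind!r}")


# ------------------------------------------------------ energetics toys

def generate_energy_toy(n_atoms: int, seed: int, box: float = 20.0,
                        min_sep: float = 3.0) -> tuple[Topology, Frame]:
    """Reproducible random charged system split into groups 'a' and 'b'.

    The minimum separation keeps every pair outside the steep LJ core so
    that total energies stay O(10²) kcal/mol and brute-force comparisons
    are numerically meaningful at tight absolute tolerances.
    """
    if n_atoms < 2:
        raise ValueError("need at least 2 atoms")
    rng = np.random.default_rng(seed)
    coords = np.empty((n_atoms, 3))
    n_placed = 0
    tries = 0
    while n_placed < n_atoms:
        tries += 1
        if tries > 100_000:
            raise RuntimeError("could not place atoms at the requested density")
        cand = rng.uniform(0.0, box, 3)
        if n_placed == 0 or np.min(
                np.linalg.norm(coords[:n_placed] - cand, axis=1)) >= min_sep:
            coords[n_placed] = cand
            n_placed += 1
    elements = ["C", "N", "O"]
    half = n_atoms // 2
    records = []
    for i in range(n_atoms):
        rid = 1 if i < half else 2
        records.append(AtomRecord(
            serial=i + 1, name=f"X{i + 1}", element=elements[i % 3],
            residue_name="TOY", residue_id=rid,
            charge=float(rng.uniform(-0.8, 0.8)),
            lj_epsilon=float(rng.uniform(0.05, 0.3)),
            lj_rmin_half=float(rng.uniform(1.2, 2.2))))
    top = Topology(records, groups={"a": range(half), "b": range(half, n_atoms)})
    return top, Frame(coords)
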