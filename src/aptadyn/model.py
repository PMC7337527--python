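"""Core domain types shared by every analysis stage.

A :class:`Topology` is the static molecular description (atoms, residues,
named atom groups); a :class:`Trajectory` is an ordered list of
:class:`Frame` coordinate sets over that topology.  Selections are
deliberately simple — residue ids plus an optional atom-name list — since
the analyses only ever need residue-level and named-group addressing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .units import mass_of

WATER_RESIDUE_NAMES = frozenset({"HOH", "WAT", "TIP3", "TIP", "SOL"})


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its force-field nonbonded parameters.

    charge is in elementary-charge units; lj_epsilon (well depth, >= 0) in
    kcal/mol; lj_rmin_half (half the pair-minimum distance) in Å.
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str = "A"
    charge: float = 0.0
    lj_epsilon: float = 0.0
    lj_rmin_half: float = 0.0

    def __post_init__(self) -> None:
        if self.lj_epsilon < 0:
            raise ValueError(f"lj_epsilon must be >= 0, got {self.lj_epsilon}")
        if self.lj_epsilon > 0 and self.lj_rmin_half <= 0:
            raise ValueError("lj_rmin_half must be > 0 when lj_epsilon > 0")

    @property
    def mass(self) -> float:
        return mass_of(self.element)

    @property
    def is_water(self) -> bool:
        return self.residue_name.upper() in WATER_RESIDUE_NAMES


class Topology:
    """Ordered atom list with residue grouping and named index groups."""

    def __init__(self, atoms: Sequence[AtomRecord],
                 groups: Mapping[str, Iterable[int]] | None = None) -> None:
        self.atoms: list[AtomRecord] = list(atoms)
        if not self.atoms:
            raise ValueError("Topology needs at least one atom")
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise ValueError("duplicate atom serials in topology")
        # residues keyed (chain_id, residue_id), insertion-ordered
        self._residues: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            self._residues.setdefault((a.chain_id, a.residue_id), []).append(i)
        self.groups: dict[str, np.ndarray] = {}
        if groups:
            for name, idx in groups.items():
                self.add_group(name, idx)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def residues(self) -> dict[tuple[str, int], list[int]]:
        return self._residues

    def add_group(self, name: str, indices: Iterable[int]) -> None:
        idx = np.asarray(sorted(set(int(i) for i in indices)), dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= self.n_atoms):
            raise IndexError(f"group {name!r} references out-of-range atom index")
        self.groups[name] = idx

    def residue_name(self, residue_id: int, chain_id: str = "A") -> str:
        return self.atoms[self.residue_atoms(residue_id, chain_id)[0]].residue_name

    def residue_atoms(self, residue_id: int, chain_id: str = "A") -> list[int]:
        """Atom indices of one residue; KeyError if it does not exist."""
        key = (chain_id, residue_id)
        if key not in self._residues:
            raise KeyError(f"no residue {residue_id} in chain {chain_id!r}")
        return list(self._residues[key])

    def atom_index(self, residue_id: int, atom_name: str, chain_id: str = "A") -> int:
        for i in self.residue_atoms(residue_id, chain_id):
            if self.atoms[i].name == atom_name:
                return i
        raise KeyError(f"no atom {atom_name!r} in residue {residue_id}")

    def select(self, residue_ids: Iterable[int] | None = None,
               atom_names: Iterable[str] | None = None,
               residue_names: Iterable[str] | None = None,
               chain_id: str | None = None) -> np.ndarray:
        """Select atom indices by residue id / atom name / residue name."""
        rid = set(residue_ids) if residue_ids is not None else None
        anm = set(atom_names) if atom_names is not None else None
        rnm = set(residue_names) if residue_names is not None else None
        out = [i for i, a in enumerate(self.atoms)
               if (rid is None or a.residue_id in rid)
               and (anm is None or a.name in anm)
               and (rnm is None or a.residue_name in rnm)
               and (chain_id is None or a.chain_id == chain_id)]
        return np.asarray(out, dtype=int)

    def masses(self, indices: Iterable[int] | None = None) -> np.ndarray:
        idx = range(self.n_atoms) if indices is None else indices
        return np.asarray([self.atoms[i].mass for i in idx], dtype=float)

    def water_residues(self) -> list[tuple[tuple[str, int], list[int]]]:
        """(residue key, atom indices) for every water residue."""
        return [(key, idx) for key, idx in self._residues.items()
                if self.atoms[idx[0]].is_water]


@dataclass
class Frame:
    """One coordinate snapshot (N×3, Å)."""

    coordinates: np.ndarray
    frame_index: int = 0
    time: float | None = None  # ps

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be N×3")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


class Trajectory:
    """A topology plus one or more frames with matching atom counts."""

    def __init__(self, topology: Topology, frames: Sequence[Frame]) -> None:
        if not frames:
            raise ValueError("Trajectory needs at least one frame")
        for f in frames:
            if f.n_atoms != topology.n_atoms:
                raise ValueError(
                    f"frame {f.frame_index} has {f.n_atoms} atoms, "
                    f"topology has {topology.n_atoms}")
        self.topology = topology
        self.frames: list[Frame] = list(frames)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def coords(self) -> np.ndarray:
        """All coordinates stacked as (n_frames, n_atoms, 3)."""
        return np.stack([f.coordinates for f in self.frames])


@dataclass(frozen=True)
class HBondDefinition:
    """Donor–hydrogen–acceptor atom-index triple."""

    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    label: str = ""

    def __post_init__(self) -> None:
        if len({self.donor_index, self.hydrogen_index, self.acceptor_index}) != 3:
            raise ValueError("donor, hydrogen and acceptor must be distinct atoms")


@dataclass(frozen=True)
class RingDefinition:
    """Ordered heavy-atom indices of one aromatic ring (π domain)."""

    atom_indices: tuple[int, ...]
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "atom_indices", tuple(int(i) for i in self.atom_indices))
        if len(self.atom_indices) < 3:
            raise ValueError("a ring needs at least 3 atoms")


def build_topology(atom_table: Sequence[AtomRecord],
                   group_spec: Mapping[str, Mapping] | None = None) -> Topology:
    """Build a Topology and resolve named selections into index groups.

    Each selection is a mapping with optional keys ``residue_ids``,
    ``atom_names``, ``residue_names``, ``chain_id``.  An empty selection
    result is an error — it signals a naming mismatch in the input.
    """
    top = Topology(atom_table)
    for name, sel in (group_spec or {}).items():
        if sel.get("residue_ids") is not None:
            known = {rid for (_, rid) in top.residues}
            missing = set(sel["residue_ids"]) - known
            if missing:
                raise KeyError(f"group {name!r} references unknown residues {sorted(missing)}")
        idx = top.select(residue_ids=sel.get("residue_ids"),
                         atom_names=sel.get("atom_names"),
                         residue_names=sel.get("residue_names"),
                         chain_id=sel.get("chain_id"))
        if idx.size == 0:
            raise ValueError(f"selection for group {name!r} matched no atoms")
        top.add_group(name, idx)
    return top


def residue_atoms(topology: Topology, residue_id: int, chain_id: str = "A") -> list[int]:
    """Functional alias for :meth:`Topology.residue_atoms`."""
    return topology.residue_atoms(residue_id, chain_id)
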