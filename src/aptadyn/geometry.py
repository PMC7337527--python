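"""Per-frame structural observables.

Covers optimal rigid superposition (Kabsch), RMSD/RMSF time series,
hydrogen-bond length/angle series and geometric detection, least-squares
base-plane fitting, and the two π-stacking metrics used for nucleobase
pairs: ring-centroid distance and the angle between fitted plane normals.

Conventions
-----------
* Hydrogen-bond length is the H···A distance (Å), not D···A; the angle is
  the D–H···A angle at the hydrogen, in degrees ∈ [0, 180].
* The stacking "vector angle" is the angle between the two plane normals
  folded into [0°, 90°] (near-parallel stacked bases give small angles).
* All observables are invariant under global rigid motion of a frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model import Frame, HBondDefinition, RingDefinition, Trajectory

__all__ = [
    "GeometrySeries", "PlaneFit", "kabsch_superpose", "rmsd_series",
    "rmsf_per_residue", "hbond_series", "detect_hbonds", "fit_ring_plane",
    "stacking_series",
]


@dataclass
class GeometrySeries:
    """A per-frame observable with its summary statistics."""

    label: str
    values: np.ndarray
    unit: str
    mean: float = field(init=False)
    std: float = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mean = float(np.mean(self.values)) if self.values.size else float("nan")
        self.std = float(np.std(self.values)) if self.values.size else float("nan")

    def __len__(self) -> int:
        return self.values.size

    def summary(self) -> str:
        return f"{self.mean:.2f} (±{self.std:.2f}) {self.unit}"


@dataclass
class PlaneFit:
    """Least-squares plane through a set of ring atoms."""

    centroid: np.ndarray
    normal: np.ndarray
    rms_deviation: float


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t minimizing weighted RMSD.

    Returns (R, t, rmsd) with ``R @ mobile_i + t ≈ reference_i``.  R is
    guaranteed proper (det = +1).  Raises for degenerate (collinear) inputs.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching N×3 arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points to superpose")
    if weights is None:
        w = np.full(n, 1.0 / n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("weights must be non-negative with positive sum")
        w = w / w.sum()
    cm = w @ mobile
    cr = w @ reference
    p = mobile - cm
    q = reference - cr
    h = (p * w[:, None]).T @ q
    u, s, vt = np.linalg.svd(h)
    # collinear point sets leave the rotation about the line undetermined
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise ValueError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = cr - rot @ cm
    moved = mobile @ rot.T + t
    rmsd = float(np.sqrt(np.sum(w[:, None] * (moved - reference) ** 2)))
    return rot, t, rmsd


def rmsd_series(trajectory: Trajectory, selection: Sequence[int],
                reference_frame: int = 0,
                fit_selection: Sequence[int] | None = None,
                label: str = "rmsd") -> GeometrySeries:
    """Best-fit RMSD of *selection* vs a reference frame, per frame.

    The superposition is computed on *fit_selection* (defaults to
    *selection*) and then applied before measuring the RMSD of *selection*.
    """
    sel = np.asarray(selection, dtype=int)
    fit = sel if fit_selection is None else np.asarray(fit_selection, dtype=int)
    if sel.size < 3 or fit.size < 3:
        raise ValueError("selections must contain at least 3 atoms")
    ref = trajectory.frames[reference_frame].coordinates
    out = np.empty(trajectory.n_frames)
    for i, frame in enumerate(trajectory.frames):
        xyz = frame.coordinates
        rot, t, _ = kabsch_superpose(xyz[fit], ref[fit])
        moved = xyz[sel] @ rot.T + t
        out[i] = np.sqrt(np.mean(np.sum((moved - ref[sel]) ** 2, axis=1)))
    return GeometrySeries(label, out, "Å")


def rmsf_per_residue(trajectory: Trajectory, selection: Sequence[int] | None = None,
                     fit_selection: Sequence[int] | None = None,
                     max_iter: int = 3, tol: float = 1e-6) -> dict[int, float]:
    """Residue-averaged RMSF (Å) about the iteratively aligned mean structure.

    Frames are superposed (on *fit_selection*, defaulting to *selection*)
    onto their running mean structure, up to *max_iter* passes or until the
    mean moves < *tol* Å RMS; then RMSF_i = sqrt(⟨|r_i − ⟨r_i⟩|²⟩) is
    averaged over each residue's atoms.
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    top = trajectory.topology
    sel = (np.arange(top.n_atoms) if selection is None
           else np.asarray(selection, dtype=int))
    fit = sel if fit_selection is None else np.asarray(fit_selection, dtype=int)
    all_xyz = trajectory.coords.copy()
    mean_fit = all_xyz[0, fit].copy()
    for _ in range(max_iter):
        for k in range(all_xyz.shape[0]):
            rot, t, _ = kabsch_superpose(all_xyz[k, fit], mean_fit)
            all_xyz[k] = all_xyz[k] @ rot.T + t
        new_mean = all_xyz[:, fit].mean(axis=0)
        shift = np.sqrt(np.mean(np.sum((new_mean - mean_fit) ** 2, axis=1)))
        mean_fit = new_mean
        if shift < tol:
            break
    coords = all_xyz[:, sel, :]
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    rmsf_of = dict(zip(sel.tolist(), per_atom))
    out: dict[int, float] = {}
    for (chain, rid), idx in top.residues.items():
        vals = [rmsf_of[i] for i in idx if i in rmsf_of]
        if vals:
            out[rid] = float(np.mean(vals))
    return out


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-length vector in angle computation")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def hbond_geometry(frame: Frame, hbond: HBondDefinition) -> tuple[float, float]:
    """(H···A length Å, D–H···A angle deg) for one frame."""
    xyz = frame.coordinates
    d = xyz[hbond.donor_index]
    h = xyz[hbond.hydrogen_index]
    a = xyz[hbond.acceptor_index]
    length = float(np.linalg.norm(a - h))
    if length == 0 or np.linalg.norm(d - h) == 0:
        raise ValueError("coincident atoms in hydrogen-bond geometry")
    angle = _angle_deg(d - h, a - h)
    return length, angle


def hbond_series(trajectory: Trajectory, hbond: HBondDefinition
                 ) -> tuple[GeometrySeries, GeometrySeries]:
    """Per-frame H···A length and D–H···A angle series for one bond."""
    lengths = np.empty(trajectory.n_frames)
    angles = np.empty(trajectory.n_frames)
    for i, frame in enumerate(trajectory.frames):
        lengths[i], angles[i] = hbond_geometry(frame, hbond)
    tag = hbond.label or "hbond"
    return (GeometrySeries(f"{tag}_length", lengths, "Å"),
            GeometrySeries(f"{tag}_angle", angles, "deg"))


def detect_hbonds(frame: Frame,
                  donors: Sequence[tuple[int, int]],
                  acceptors: Sequence[int],
                  d_max: float = 2.5,
                  angle_min: float = 120.0) -> list[HBondDefinition]:
    """Geometric hydrogen-bond detection in one frame.

    *donors* are (heavy donor index, attached hydrogen index) pairs;
    *acceptors* are heavy-atom indices.  A hit requires H···A ≤ *d_max* Å
    and D–H···A ≥ *angle_min* degrees.  Hits are sorted by H···A distance.
    """
    xyz = frame.coordinates
    hits: list[tuple[float, HBondDefinition]] = []
    for d_idx, h_idx in donors:
        for a_idx in acceptors:
            if a_idx in (d_idx, h_idx):
                continue
            r = float(np.linalg.norm(xyz[a_idx] - xyz[h_idx]))
            if r > d_max or r == 0:
                continue
            ang = _angle_deg(xyz[d_idx] - xyz[h_idx], xyz[a_idx] - xyz[h_idx])
            if ang >= angle_min:
                hits.append((r, HBondDefinition(d_idx, h_idx, a_idx,
                                                label=f"{d_idx}-{h_idx}..{a_idx}")))
    hits.sort(key=lambda t: t[0])
    return [hb for _, hb in hits]


def fit_ring_plane(frame: Frame, ring: RingDefinition) -> PlaneFit:
    """Least-squares plane through the ring atoms.

    The centroid is the unweighted mean; the normal is the singular vector
    of the centered coordinates with the smallest singular value (the
    direction minimizing the sum of squared perpendicular distances).
    """
    pts = frame.coordinates[list(ring.atom_indices)]
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-10 * max(s[0], 1e-300):
        raise ValueError(f"ring {ring.label!r}: atoms are collinear")
    normal = vt[2]
    normal = normal / np.linalg.norm(normal)
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return PlaneFit(centroid=centroid, normal=normal, rms_deviation=rms)


def stacking_geometry(frame: Frame, ring_a: RingDefinition, ring_b: RingDefinition
                      ) -> tuple[float, float]:
    """(centroid distance Å, plane-normal angle deg ∈ [0, 90]) for one frame."""
    fa = fit_ring_plane(frame, ring_a)
    fb = fit_ring_plane(frame, ring_b)
    dist = float(np.linalg.norm(fa.centroid - fb.centroid))
    # fold: plane normals are sign-ambiguous
    c = np.clip(abs(np.dot(fa.normal, fb.normal)), 0.0, 1.0)
    angle = float(np.degrees(np.arccos(c)))
    return dist, angle


def stacking_series(trajectory: Trajectory, ring_a: RingDefinition,
                    ring_b: RingDefinition) -> tuple[GeometrySeries, GeometrySeries]:
    """Per-frame π-stacking distance and plane-angle series for a ring pair."""
    dists = np.empty(trajectory.n_frames)
    angles = np.empty(trajectory.n_frames)
    for i, frame in enumerate(trajectory.frames):
        dists[i], angles[i] = stacking_geometry(frame, ring_a, ring_b)
    tag = f"{ring_a.label or 'ringA'}_{ring_b.label or 'ringB'}"
    return (GeometrySeries(f"{tag}_distance", dists, "Å"),
            GeometrySeries(f"{tag}_angle", angles, "deg"))
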