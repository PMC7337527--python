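"""End-to-end orchestration: configuration, block execution, manifests.

A run is described by a YAML configuration with one section per analysis
block (geometry, energetics, hydration, free_energy), each carrying an
``enabled`` flag and the block's options.  Blocks execute in a fixed
order; a failure in one block is recorded in the manifest and later
independent blocks still run.  The manifest (JSON) records package and
numpy versions, the seed, a hash of the resolved configuration and every
output file, which is sufficient to re-run the bundle.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .energetics import decompose_by_residue
from .free_energy import (FreeEnergyConfig, annotate_profile, convergence_report,
                          estimate_pmf, run_meta_eabf)
from .geometry import (GeometrySeries, rmsd_series, rmsf_per_residue,
                       hbond_series, stacking_series)
from .hydration import cavity_water_count, water_bridges
from .io import (apply_parameters, read_parameters, read_pdb,
                 read_xyz_trajectory, write_results)
from .model import HBondDefinition, RingDefinition, Trajectory
from .synthetic import (PURINE_RING, PYRIMIDINE_RING, ToyPotentialSpec,
                        make_toy_potential)

log = logging.getLogger("aptadyn")

BLOCK_ORDER = ("geometry", "energetics", "hydration", "free_energy")


class ConfigError(ValueError):
    """Raised before any computation when the run configuration is invalid."""


@dataclass
class RunConfig:
    structure: str
    output_dir: str
    seed: int = 0
    trajectory: str | None = None
    parameters: str | None = None
    log_level: str = "INFO"
    groups: dict[str, dict] = field(default_factory=dict)
    geometry: dict = field(default_factory=lambda: {"enabled": False})
    energetics: dict = field(default_factory=lambda: {"enabled": False})
    hydration: dict = field(default_factory=lambda: {"enabled": False})
    free_energy: dict = field(default_factory=lambda: {"enabled": False})

    def block(self, name: str) -> dict:
        return getattr(self, name)

    def enabled(self, name: str) -> bool:
        return bool(self.block(name).get("enabled", False))


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return make_config(raw, base_dir=Path(path).parent)


def make_config(raw: Mapping[str, Any], base_dir: Path | None = None) -> RunConfig:
    """Validate a raw mapping into a RunConfig; raises ConfigError."""
    if not isinstance(raw, Mapping):
        raise ConfigError("configuration root must be a mapping")
    inp = raw.get("input", {})
    structure = inp.get("structure")
    if not structure:
        raise ConfigError("missing required field: input.structure")
    out = raw.get("output_dir")
    if not out:
        raise ConfigError("missing required field: output_dir")

    def _resolve(p):
        if p is None:
            return None
        p = Path(p)
        if base_dir is not None and not p.is_absolute():
            p = base_dir / p
        return str(p)

    cfg = RunConfig(
        structure=_resolve(structure), output_dir=_resolve(out),
        seed=int(raw.get("seed", 0)),
        trajectory=_resolve(inp.get("trajectory")),
        parameters=_resolve(inp.get("parameters")),
        log_level=str(raw.get("log_level", "INFO")),
        groups=dict(raw.get("groups", {})),
        geometry=dict(raw.get("geometry", {"enabled": False})),
        energetics=dict(raw.get("energetics", {"enabled": False})),
        hydration=dict(raw.get("hydration", {"enabled": False})),
        free_energy=dict(raw.get("free_energy", {"enabled": False})),
    )
    if not Path(cfg.structure).exists():
        raise ConfigError(f"input.structure does not exist: {cfg.structure}")
    if cfg.trajectory and not Path(cfg.trajectory).exists():
        raise ConfigError(f"input.trajectory does not exist: {cfg.trajectory}")
    if cfg.enabled("energetics"):
        if not cfg.parameters:
            raise ConfigError("energetics is enabled but input.parameters is missing")
        if not Path(cfg.parameters).exists():
            raise ConfigError(f"input.parameters does not exist: {cfg.parameters}")
        if not cfg.energetics.get("ligand_group"):
            raise ConfigError("energetics.ligand_group is required")
        if not cfg.energetics.get("residues"):
            raise ConfigError("energetics.residues is required")
    if cfg.enabled("free_energy") and "n_steps" not in cfg.free_energy:
        raise ConfigError("free_energy.n_steps is required")
    return cfg


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.__dict__, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _resolve_ring(traj: Trajectory, spec: Mapping) -> RingDefinition:
    top = traj.topology
    rid = int(spec["residue"])
    names = spec.get("atoms")
    if names is None:
        rname = top.residue_name(rid)
        purine = rname in ("DA", "DG", "ATP", "AMP", "A", "G")
        names = PURINE_RING if purine else PYRIMIDINE_RING
    return RingDefinition(tuple(top.atom_index(rid, n) for n in names),
                          label=spec.get("label", f"ring{rid}"))


def _resolve_atom(traj: Trajectory, spec: Mapping) -> int:
    return traj.topology.atom_index(int(spec["residue"]), spec["atom"])


def _run_geometry(cfg: RunConfig, traj: Trajectory, out: Path) -> list[str]:
    blk = cfg.geometry
    results: dict[str, GeometrySeries] = {}
    for hb in blk.get("hbonds", []):
        defn = HBondDefinition(_resolve_atom(traj, hb["donor"]),
                               _resolve_atom(traj, hb["hydrogen"]),
                               _resolve_atom(traj, hb["acceptor"]),
                               label=hb.get("label", "hbond"))
        length, angle = hbond_series(traj, defn)
        results[length.label] = length
        results[angle.label] = angle
    for pair in blk.get("stacking", []):
        ra = _resolve_ring(traj, pair["ring_a"])
        rb = _resolve_ring(traj, pair["ring_b"])
        dist, ang = stacking_series(traj, ra, rb)
        results[dist.label] = dist
        results[ang.label] = ang
    for sel in blk.get("rmsd", []):
        gname = sel["group"]
        idx = traj.topology.groups[gname]
        series = rmsd_series(traj, idx, reference_frame=sel.get("reference_frame", 0),
                             label=f"rmsd_{gname}")
        results[series.label] = series
    files = [str(p) for p in write_results(results, out)]
    if blk.get("rmsf", False) and traj.n_frames >= 2:
        rmsf = rmsf_per_residue(traj)
        p = out / "rmsf.tsv"
        pd.DataFrame({"residue_id": list(rmsf), "rmsf": list(rmsf.values())}
                     ).to_csv(p, sep="\t", index=False)
        files.append(str(p))
    return files


def _run_energetics(cfg: RunConfig, traj: Trajectory, out: Path) -> list[str]:
    blk = cfg.energetics
    table = read_parameters(cfg.parameters)
    top = apply_parameters(traj.topology, table)
    decomp = decompose_by_residue(
        traj, top, ligand_group=top.groups[blk["ligand_group"]],
        residue_list=[int(r) for r in blk["residues"]],
        cutoff=float(blk.get("cutoff", 12.0)),
        scheme=blk.get("scheme", "switch"),
        r_switch=float(blk.get("r_switch", 10.0)),
        dielectric=float(blk.get("dielectric", 1.0)))
    p = out / "energy_decomposition.tsv"
    decomp.table.to_csv(p, sep="\t", index=False)
    return [str(p)]


def _run_hydration(cfg: RunConfig, traj: Trajectory, out: Path) -> list[str]:
    blk = cfg.hydration
    top = traj.topology
    lig = top.groups[blk.get("ligand_group", "ligand")]
    rec = top.groups[blk.get("receptor_group", "receptor")]
    records, counts = water_bridges(
        traj, top, lig, rec,
        d_max=float(blk.get("d_max", 2.5)),
        angle_min=float(blk.get("angle_min", 120.0)))
    files = []
    p = out / "water_bridges.json"
    with open(p, "w") as fh:
        json.dump({"thresholds": {"d_max": blk.get("d_max", 2.5),
                                  "angle_min": blk.get("angle_min", 120.0)},
                   "records": [r.to_dict() for r in records]}, fh, indent=2)
    files.append(str(p))
    p = out / "water_bridge_counts.tsv"
    pd.DataFrame({"frame": np.arange(len(counts.values)),
                  "bridges": counts.values.astype(int)}).to_csv(p, sep="\t", index=False)
    files.append(str(p))
    site_name = blk.get("site_group", "site")
    if site_name in top.groups:
        cav = cavity_water_count(traj, top, top.groups[site_name],
                                 radius=float(blk.get("cavity_radius", 5.0)))
        p = out / "cavity_water_counts.tsv"
        pd.DataFrame({"frame": np.arange(len(cav.values)),
                      "waters": cav.values.astype(int)}).to_csv(p, sep="\t", index=False)
        files.append(str(p))
    return files


def _run_free_energy(cfg: RunConfig, out: Path) -> list[str]:
    blk = dict(cfg.free_energy)
    blk.pop("enabled", None)
    pot_spec = blk.pop("potential", {"kind": "double_well"})
    regions = blk.pop("annotate", None)
    toy = make_toy_potential(ToyPotentialSpec(kind=pot_spec.get("kind", "double_well"),
                                              params=pot_spec.get("params", {})))
    blk.setdefault("seed", cfg.seed)
    fe_cfg = FreeEnergyConfig(**blk)
    result = run_meta_eabf(toy.potential, toy.gradient, fe_cfg)
    profile = estimate_pmf(result.bias, method="czar")
    files = []
    p = out / "pmf_czar.tsv"
    pd.DataFrame({"bin_center": profile.bin_centers, "free_energy": profile.values,
                  "sampled": profile.sampled}).to_csv(p, sep="\t", index=False)
    files.append(str(p))
    p = out / "hills.tsv"
    pd.DataFrame(result.bias.hills,
                 columns=["step", "center", "height", "width"]
                 ).to_csv(p, sep="\t", index=False)
    files.append(str(p))
    if result.checkpoints:
        profiles = [estimate_pmf(b, method="czar") for b in result.checkpoints]
        profiles.append(profile)
        rep = convergence_report(profiles, tolerance=float(
            cfg.free_energy.get("convergence_tolerance", 0.5)))
        p = out / "convergence.json"
        with open(p, "w") as fh:
            json.dump({"rms_to_final": rep["rms_to_final"].tolist(),
                       "converged_at": rep["converged_at"],
                       "tolerance": rep["tolerance"]}, fh, indent=2)
        files.append(str(p))
    if regions:
        ann = annotate_profile(profile, tuple(regions["bound"]),
                               tuple(regions["plateau"]))
        p = out / "pmf_annotations.json"
        with open(p, "w") as fh:
            json.dump(ann.annotations, fh, indent=2)
        files.append(str(p))
    return files


def run_pipeline(config: RunConfig | Mapping) -> dict:
    """Execute all enabled blocks; returns the manifest (also written to disk).

    Accepts a RunConfig, a raw nested mapping, or the resolved flat
    mapping a previous manifest recorded under ``config`` — so a manifest
    is sufficient to re-run its bundle.
    """
    if isinstance(config, RunConfig):
        cfg = config
    elif isinstance(config, Mapping) and "structure" in config:
        cfg = RunConfig(**{k: v for k, v in config.items()
                           if k in RunConfig.__dataclass_fields__})
    else:
        cfg = make_config(config)
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO),
                        format="%(asctime)s %(levelname)s %(message)s")
    out_root = Path(cfg.output_dir)
    out_root.mkdir(parents=True, exist_ok=True)
    traj = read_pdb(cfg.structure)
    if cfg.trajectory:
        traj = read_xyz_trajectory(cfg.trajectory, traj.topology)
    for name, sel in cfg.groups.items():
        idx = traj.topology.select(
            residue_ids=sel.get("residue_ids"), atom_names=sel.get("atom_names"),
            residue_names=sel.get("residue_names"), chain_id=sel.get("chain_id"))
        if idx.size == 0:
            raise ConfigError(f"group {name!r} matched no atoms")
        traj.topology.add_group(name, idx)

    manifest: dict = {
        "package": "aptadyn", "version": __version__,
        "numpy_version": np.__version__, "seed": cfg.seed,
        "config_hash": _config_hash(cfg), "config": {
            k: v for k, v in cfg.__dict__.items()},
        "blocks": {},
    }
    runners = {"geometry": lambda o: _run_geometry(cfg, traj, o),
               "energetics": lambda o: _run_energetics(cfg, traj, o),
               "hydration": lambda o: _run_hydration(cfg, traj, o),
               "free_energy": lambda o: _run_free_energy(cfg, o)}
    for name in BLOCK_ORDER:
        if not cfg.enabled(name):
            manifest["blocks"][name] = {"status": "disabled"}
            continue
        block_out = out_root / name
        block_out.mkdir(parents=True, exist_ok=True)
        try:
            files = runners[name](block_out)
            manifest["blocks"][name] = {"status": "ok", "outputs": files}
            log.info("block %s finished (%d files)", name, len(files))
        except Exception as exc:  # recorded; later blocks still run
            manifest["blocks"][name] = {"status": "failed", "error": str(exc)}
            log.error("block %s failed: %s", name, exc)
    with open(out_root / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def compare_variants(runs: Sequence[tuple[str, Mapping[str, tuple | None]]],
                     observables: Sequence[str] | None = None) -> pd.DataFrame:
    """Cross-variant table of mean ± std per observable.

    *runs* is a sequence of (variant name, {observable → (mean, std) or
    None}); a missing observable is printed as "/" (an interaction the
    variant does not form).
    """
    if len(runs) < 2:
        raise ValueError("need at least two completed runs to compare")
    if observables is None:
        observables = list(runs[0][1].keys())
    rows = []
    for name, summary in runs:
        row = {"variant": name}
        for obs in observables:
            if obs not in summary:
                raise KeyError(f"run {name!r} lacks observable {obs!r}")
            ms = summary[obs]
            row[obs] = "/" if ms is None else f"{ms[0]:.2f} (±{ms[1]:.2f})"
        rows.append(row)
    return pd.DataFrame(rows)


CONFIG_TEMPLATE = """\
# aptadyn run configuration (YAML).  Defaults shown are the packaged
# reference values; every analysis block has an `enabled` switch.
seed: 0
output_dir: out
log_level: INFO
input:
  structure: fixture/ensemble.pdb     # multi-model PDB (one frame per MODEL)
  trajectory: null                    # optional XYZ overriding the PDB frames
  parameters: fixture/parameters.tsv  # TSV: residue_name atom_name charge lj_epsilon lj_rmin_half
groups:
  ligand:   {residue_ids: [28]}
  site:     {residue_ids: [5, 6, 21, 22, 23]}   # ligand-intercalating region
  receptor: {residue_ids: [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14,
                           15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26, 27]}
geometry:
  enabled: true
  hbonds:   # ligand-G22 bonds of the reference wild-type complex
    - {label: H1, donor: {residue: 28, atom: N6}, hydrogen: {residue: 28, atom: H61},
       acceptor: {residue: 22, atom: N3}}
    - {label: H2, donor: {residue: 22, atom: N2}, hydrogen: {residue: 22, atom: H22},
       acceptor: {residue: 28, atom: N1}}
  stacking:
    - {ring_a: {residue: 6, label: G6}, ring_b: {residue: 28, label: ATP}}
    - {ring_a: {residue: 23, label: A23}, ring_b: {residue: 28, label: ATP}}
  rmsd: [{group: site}]
  rmsf: true
energetics:
  enabled: true
  ligand_group: ligand
  residues: [6, 22, 23]
  cutoff: 12.0        # Å, conventional nonbonded radius
  r_switch: 10.0      # Å, CHARMM-style switching onset
  scheme: switch      # infinite | truncate | switch
  dielectric: 1.0
hydration:
  enabled: true
  d_max: 2.5          # Å, H···A hydrogen-bond threshold
  angle_min: 120.0    # degrees, D-H···A threshold
  cavity_radius: 5.0  # Å around the site centroid
free_energy:
  enabled: true
  potential: {kind: double_well, params: {barrier: 3.0, half_separation: 2.0}}
  xi_min: -4.5
  xi_max: 4.5
  bin_width: 0.1      # Å, reference binning of the collective variable
  hill_height: 0.0239006  # kcal/mol (= 0.1 kJ/mol, reference hill height)
  hill_width: 1.2     # Å, reference hill width
  hill_period: 500    # steps between depositions (package default)
  n_steps: 1000000
  dt: 0.02
  friction: 1.0
  coupling_k: 150.0   # kcal/mol/Å² extended-spring constant
  x0: -2.0
  annotate: {bound: [-3.0, -1.0], plateau: [1.0, 3.0]}
"""


def config_template() -> str:
    """A fully commented YAML template with the packaged defaults."""
    return CONFIG_TEMPLATE


def summary_from_run(out_dir: str | Path) -> dict[str, tuple | None]:
    """Read a geometry block's summary.tsv back into {observable: (mean, std)}."""
    p = Path(out_dir) / "geometry" / "summary.tsv"
    frame = pd.read_csv(p, sep="\t")
    return {r.observable: (float(r.mean), float(r.std)) for r in frame.itertuples()}
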