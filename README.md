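# aptadyn

Trajectory analysis and free-energy tooling for studying how a 27-mer
single-stranded DNA aptamer recognizes ATP — and, more generally, for any
nucleic-acid–ligand system where recognition is carried by a small number
of hydrogen bonds, π-stacking contacts and bridging waters.

The package is aimed at molecular-modelling practitioners who have (or
simulate) conformational ensembles of an aptamer–ligand complex and want
reproducible, scriptable answers to the questions that decide whether a
binding site works:

* **Geometry** — are the named hydrogen bonds (e.g. ATP:H61···N3:G22 and
  ATP:N1···H22:G22, the two ligand–G22 bonds of the classic ATP aptamer)
  intact, and how tightly do the stacked bases clamp the ligand?  Per-frame
  series of H···A length, D–H···A angle, ring-centroid distance and
  base-plane angle, plus RMSD/RMSF via Kabsch superposition.
* **Energetics** — which bases pay for binding?  Pairwise Coulomb + 12-6
  Lennard-Jones interaction energies (E = 332.0636·q₁q₂/εr + ε₁₂[(R/r)¹² −
  2(R/r)⁶] kcal/mol) decomposed per residue with CHARMM-style switching,
  and the supermolecular definition ΔE_int = E_complex − (E₁ + E₂).
* **Hydration** — which waters bridge ligand and receptor (simultaneous
  hydrogen bonds to both), and how many waters occupy the cavity?
* **Free energy** — a meta-eABF engine on a 1-D collective variable (the
  ligand–base center-of-mass separation): extended-system adaptive biasing
  force plus metadynamics hills, with CZAR, naive mean-force and
  hills-only PMF estimators, convergence reporting and automatic
  barrier/ΔG annotation of the profile.
* **Synthetic ensembles** — a generator that *poses* a 27-residue
  binding-site ensemble so every named observable equals a draw from a
  configured Gaussian (wild-type defaults: H1 2.07 ± 0.16 Å / 162.0 ±
  9.5°, H2 2.03 ± 0.13 Å / 161.4 ± 9.9°, G6–ligand stack 4.09 ± 0.22 Å /
  13.4 ± 6.9°, A23–ligand stack 3.80 ± 0.24 Å / 22.0 ± 7.8°, with G6A,
  A23G and G6C/A23C mutant parameter sets), planted water bridges, and
  analytic toy potentials with exact PMFs for estimator validation.

Everything is plain numpy/scipy/pandas over simple dataclasses
(`Topology`, `Trajectory`, `GeometrySeries`, `EnergyDecomposition`,
`FreeEnergyProfile`); I/O covers multi-model PDB, XYZ trajectories and
TSV parameter/result tables.

## Worked example

Generate a 500-frame wild-type ensemble and recover its binding-site
statistics:

```python
from aptadyn.synthetic import EnsembleSpec, generate_binding_site_ensemble
from aptadyn.geometry import hbond_series, stacking_series

ens = generate_binding_site_ensemble(EnsembleSpec(n_frames=500, seed=7))
traj = ens.trajectory
h1_len, h1_ang = hbond_series(traj, ens.h1)
s6_d, s6_a = stacking_series(traj, ens.ring6, ens.ring_ligand)
s23_d, s23_a = stacking_series(traj, ens.ring23, ens.ring_ligand)
print(f"H1  (ATP:H61···N3:G22)  {h1_len.summary()}   angle {h1_ang.summary()}")
print(f"π-stack G6·ATP          {s6_d.summary()}   plane angle {s6_a.summary()}")
print(f"π-stack A23·ATP         {s23_d.summary()}   plane angle {s23_a.summary()}")
```

prints

```
H1  (ATP:H61···N3:G22)  2.07 (±0.16) Å   angle 162.51 (±9.20) deg
π-stack G6·ATP          4.10 (±0.22) Å   plane angle 13.55 (±6.96) deg
π-stack A23·ATP         3.79 (±0.23) Å   plane angle 21.33 (±7.85) deg
```

i.e. the analysis round-trips the ensemble's configured statistics to
within sampling error: the H1 hydrogen bond averages 2.07 Å at a nearly
linear 162°, and the ligand adenine is clamped between base 6 (4.1 Å,
planes 14° from parallel) and base 23 (3.8 Å, 21°).

The same battery runs from the shell on any multi-model PDB via a YAML
configuration:

```bash
aptadyn generate --variant wt --frames 200 --seed 0 --out fixture/
aptadyn run analysis.yaml       # geometry → energetics → hydration → free_energy
aptadyn compare out_wt out_mt3  # Table-style cross-variant summary ("/" = absent)
```

For the free-energy engine on an analytic double well (barrier 3
kcal/mol), `aptadyn fe-sim` or:

```python
from aptadyn.synthetic import ToyPotentialSpec, make_toy_potential
from aptadyn.free_energy import (double_well_validation_config,
                                 run_meta_eabf, estimate_pmf)

toy = make_toy_potential(ToyPotentialSpec("double_well",
                                          {"barrier": 3.0, "half_separation": 2.0}))
cfg = double_well_validation_config(seed=7, n_steps=1_000_000)
result = run_meta_eabf(toy.potential, toy.gradient, cfg)
pmf = estimate_pmf(result.bias, method="czar")
```

recovers the double-well PMF with an RMS error of about 0.1 kcal/mol and
the 3 kcal/mol barrier to a few percent.

## Documentation

`docs/methods.md` describes the models, estimators, default parameters
and their rationale, what the synthetic generator does and does not
emulate, and known limitations.
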