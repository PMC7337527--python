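# Methods

This note documents the models and estimators implemented in `aptadyn`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the package's known limitations.

## Structural observables

**Superposition.** Rigid-body fits use the Kabsch algorithm (SVD of the
weighted covariance, with the determinant correction that guarantees a
proper rotation, det R = +1, even for reflection-like correspondences).
Collinear point sets are rejected: the rotation about the line is
undetermined. RMSD series fit on a configurable selection and measure on
another, so "fit on the site, measure the ligand" analyses are direct.
RMSF aligns all frames to their running mean structure (3 iterations or
until the mean moves < 1e-6 Å RMS — a deterministic variant of the usual
iterate-to-convergence scheme), then averages atomic fluctuations over
each residue's atoms.

**Hydrogen bonds.** A bond is described by an explicit
donor–hydrogen–acceptor atom triple. The reported length is the H···A
distance (not D···A; with typical N–H ≈ 1.0 Å the two differ by ~1 Å, and
the ~2.05 Å values this package is tuned around are H···A readings). The
angle is D–H···A at the hydrogen, in [0°, 180°], 180° = linear.
Geometric detection accepts a (D–H, A) pair when H···A ≤ `d_max` and
D–H···A ≥ `angle_min`; the defaults 2.5 Å / 120° are the common
moderate-strictness choice and both are configurable — detection counts
are only meaningful relative to their thresholds, which are therefore
recorded in output headers.

**π-stacking.** Each base ring ("π domain") is the full heavy-atom
aromatic system — nine atoms for purines (N1 C2 N3 C4 C5 C6 N7 C8 N9),
six for pyrimidines — configurable per ring. The plane is the
least-squares fit (smallest principal axis of the centered ring
coordinates via SVD); the metrics are the centroid–centroid distance and
the angle between plane normals folded into [0°, 90°] (normals are
sign-ambiguous; |n₁·n₂| is clamped to 1 before arccos). The folded
normal-normal angle is the natural reading for near-parallel stacked
bases, where values of 10–25° describe slight propeller/tilt.

## Nonbonded energetics

Pair energies are fixed-charge force-field style, kcal/mol throughout:

* electrostatics: E = 332.0636·qᵢqⱼ/(ε_r·r), relative dielectric
  configurable (default 1). No Ewald/PME: the decomposition is a
  pairwise *analysis* of given configurations, not a simulation
  energy, and periodicity is out of scope.
* van der Waals: 12-6 Lennard-Jones, ε[(R/r)¹² − 2(R/r)⁶], with
  geometric-mean ε and additive Rmin/2 combining (CHARMM convention).

Only cross-group (intermolecular) pairs are summed, so bonded exclusions
never arise. Cutoff schemes: `infinite` (oracle comparisons), `truncate`,
and the default `switch` — the CHARMM C¹ switching polynomial from 10 Å
to 12 Å, matching the conventional 12 Å nonbonded radius, applied
multiplicatively to both terms. Because switching acts per pair, the
per-residue decomposition is exactly additive: the residue rows sum to
the group total under any scheme.

Parameters live on atoms, fed from a TSV table keyed on
(residue_name, atom_name) with a `*`-residue fallback, which keeps the
energetics independent of any force-field file format. The
supermolecular definition ΔE_int = E_complex − (E₁ + E₂) is provided and,
for rigid non-interacting-monomer toys, equals the cross-group sum
identically (tested).

## Hydration

A water bridges ligand and receptor in a frame iff it hydrogen-bonds
(donor **or** acceptor role, same thresholds as detection above) to at
least one atom of each. Hydrogen attachment is inferred geometrically
(H within 1.2 Å of an N/O), so no bond topology is needed. Cavity
occupancy counts water oxygens within a configurable radius (default
5 Å) of the site centroid. Fixture waters use the rigid 3-site geometry
(O–H 0.9572 Å, H–O–H 104.52°); only the geometry is used, never the
water model's energetics.

## Meta-eABF free energy

The collective variable is the mass-weighted center-of-mass separation
ξ of two atom groups; its analytic coordinate gradient is validated by
finite differences. The sampling engine runs one-dimensional model
systems: a BAOAB-Langevin particle in U(ξ), harmonically coupled
(k/2·(ξ−λ)²) to an extended variable λ that also evolves by BAOAB.
Two biases act on λ only:

* **ABF** — the per-λ-bin running mean of the instantaneous gradient
  estimate k(λ−ξ) is applied back with a linear ramp over `n_full` = 200
  samples/bin (the conventional guard against early noise), flattening
  the mean force on λ;
* **metadynamics** — Gaussian hills of height 0.1 kJ/mol (0.0239
  kcal/mol) and width 1.2 Å deposited every 500 steps (the deposition
  period is a package choice; height/width/bin width 0.1 Å follow the
  standard meta-eABF practice for this problem class). The hill force is
  tabulated on the bin grid and linearly interpolated, so per-step cost
  is independent of the hill count; the exact hill list is kept for the
  `hills_only` estimator.

Both coordinates see reflecting walls at the CV range edges; leaving the
range by more than two hill widths aborts with a diagnostic. Runs are
deterministic per seed (noise is pre-drawn from one generator).

**Estimators.**

* `czar`: A′(ξ) = −k_BT·d/dξ ln ρ̃(ξ) + k·⟨λ−ξ⟩_ξ, with the biased
  histogram differentiated by central differences and the correction
  accumulated as the *deviation* λ−ξ per ξ-bin. (Accumulating ⟨λ⟩ and
  subtracting the bin center is numerically wrong: the in-bin density
  slope offsets ⟨ξ⟩ from the center and the stiff k amplifies that
  offset into ~1 kcal/mol profile errors.)
* `naive`: trapezoid integration of the per-λ-bin mean of k(λ−ξ). This
  estimator resolves the free energy of λ (spring-convolved) and, like
  every binned mean-force estimator, is systematically shallow where the
  within-bin force variation exceeds a few k_BT (|A′|·bin ≳ 4 k_BT, i.e.
  the steep wall wings). CZAR is therefore the default.
* `hills_only`: the negated hill sum, the coarse metadynamics view.

Profiles are min-anchored at 0 over sampled bins; unsampled bins are
flagged. `annotate_profile` reports the bound minimum, the barrier (path
maximum between the bound minimum and the plateau region, relative to
the minimum) and ΔG = A(plateau mean) − A(bound minimum) — plateau-mean
rather than endpoint, since the flat tail is the physically defined
reference; `delta_g_bind` is its negative. `convergence_report` compares
checkpoint profiles to the final one by RMS over mutually sampled bins.

**Units and integrator.** Energies kcal/mol, k_B = 0.0019872041
kcal/mol/K, lengths Å. The toy dynamics use reduced masses (no
kcal→amu·Å/ps² conversion), so timestep and friction are in matching
reduced units; all thermodynamic outputs (variances, PMFs) are
conversion-free.

**Validation settings** (`double_well_validation_config`): the reference
check runs the 3 kcal/mol double well (U = h[(ξ/b)²−1]², b = 2 Å) for
1e6 steps with dt = 0.02, friction 1, coupling k = 150 kcal/mol/Å², CV
walls at ±4.5 Å and analysis window |ξ| ≤ 3.5 Å. The wall buffer keeps
reflecting-wall pile-up out of the compared region; the spring is softer
than the generic stiff default (10 k_BT/bin² ≈ 592) because the CZAR
correction absorbs spring softness while the noise of the k(λ−ξ) term
grows like √k. Under these settings CZAR reproduces the analytic PMF to
≲ 0.15 kcal/mol RMS and the barrier to better than 10% across seeds;
unbiased BAOAB sampling passes a χ² test against the Boltzmann density
(the general-purpose `FreeEnergyConfig` defaults remain the
conservative stiff-spring, small-timestep choices).

## Synthetic ensembles

The generator *poses* geometry rather than simulating physics: per
frame, every named observable is drawn from its configured Gaussian and
the relevant atoms are placed so the measured value **equals** the draw
(stacked rings rotated/translated exactly; hydrogen-bond partner atoms
placed at the drawn length and angle with a random azimuth). This makes
the round-trip property exact — the geometry engine must recover the
configured means/stds to pure sampling error — which is precisely what
makes the fixtures usable as quantitative validation targets.
Consequences to keep in mind:

* Draws are **censored** (clamped) at the observable's valid range
  ([0°, 90°] for plane angles, [0°, 180°] for bond angles, positive
  lengths). Censoring biases a mean by at most σ·φ(μ/σ) — ≈ 0.07° for
  the widest default (13.4 ± 6.9°) — whereas rejection-redraw would
  bias it by ~0.4°, a visible distortion; clamping is therefore the
  implemented policy.
* Observables are drawn independently; the cross-correlations of real
  trajectories (e.g. stacking distance vs hydrogen-bond length) are not
  emulated. Passing round-trip tests demonstrates the correctness of
  the measurement code, not the realism of the ensemble.
* The strand is a 27-mer with binding-site residues 5, 6, 21, 22, 23
  (G G G G A; 1-based numbering kept verbatim from the input). Bases are
  idealized planar templates on a coarse circular backbone; residues 1
  and 27 get large rigid jitter (default 1.2 Å) and loop residues 12–16
  intermediate jitter (0.8 Å) so RMSF profiles show the expected
  terminal/loop pattern; everything else gets 0.12 Å. Non-Watson–Crick
  pairs base6→G21 and base23→G5 are planted at 1.90 Å/170° for
  detection tests. The ligand's triphosphate is a short charged tail —
  enough for tail-energetics analyses, with no conformational realism.
* Variants: `wt`, `G6A`, `A23G`, `G6C_A23C`, each with its own
  observable table; the double mutant has no ligand–G22 hydrogen bonds
  (its `h1`/`h2` are None and comparison tables print "/").
* Bridge waters are planted with ideal geometry against one ligand and
  one receptor partner per a frame→{0,1,2} schedule (parked far away
  when inactive, so the atom count is constant); bulk waters are placed
  uniformly in a 40 Å box at ≥ 3.6 Å from any solute atom, which
  guarantees they can never satisfy the 2.5 Å bridge threshold.
* Parameter tables carry element-typed charges/LJ values — sufficient
  for oracle tests and additivity checks, not a calibrated force field.
* Random energy toys enforce a 3 Å minimum separation: pairs inside the
  LJ core would produce ~10⁵ kcal/mol totals on which tight absolute
  oracle comparisons are below double-precision resolution.

## Pipeline

A YAML configuration drives the block order geometry → energetics →
hydration → free_energy; a failed block is recorded in the manifest and
later blocks still run. The manifest records package/numpy versions,
seed, a configuration hash and every output file; identical
configuration + seed reproduces numeric outputs byte-for-byte
(timestamps excluded). Configuration errors (missing files, missing
required fields) are raised before any computation; the CLI maps them to
exit code 2 and runtime failures to 1.

## Known limitations

* The free-energy engine samples 1-D CV-space model potentials; it does
  not propagate Cartesian many-atom systems (the CV machinery and the
  energetics module are there to analyze externally generated
  trajectories).
* No periodic boundary conditions or reciprocal-space electrostatics;
  absolute interaction energies of solvated systems are out of scope by
  design.
* The PDB dialect is the fixed-width v3.3 subset (first altloc kept,
  HETATM = ATOM); mmCIF and binary trajectory formats are not read.
* detect_hbonds enumerates given donor/acceptor lists; it does not
  infer protonation or tautomers.
* 2-D free-energy surfaces and well-tempered metadynamics are not
  implemented.
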