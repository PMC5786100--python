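# Methods

This note documents the models implemented in `glycoccs`, the
conventions chosen where published practice leaves freedom, the
numerical controls, and what the synthetic fixtures do and do not
emulate.

## Units and containers

Coordinates are Å, charges elementary, masses u, energies kJ/mol,
velocities Å/ps (so kinetic energy is 0.005·m·v² kJ/mol and k_B =
0.008314462618 kJ/mol/K).  A `ConformerEnsemble` is one shared atom
table plus M coordinate sets; the system is gas-phase throughout — no
periodic boundaries, no solvent.  Atom indices are 0-based internally;
PDB serials are converted at the I/O boundary.  Hydrogens are required
only by the H-bond module; CCS and clustering run happily without them
(clustering and RMSF use heavy atoms by default, since hydrogen
positions are the noisiest and the observables are set by the heavy-atom
skeleton).

## Drift-time calibration

Unweighted ordinary least squares of reference CCS on drift time,
CCS = a·t + b, with the coefficient of determination as the fit
diagnostic.  No power-law (t^B) variant and no charge-state or
reduced-mass correction: the packaged calibrant set is homogeneous
(doubly protonated polyalanine) and its linearity is excellent
(R² = 0.996).  Calibrant CCS uncertainty is not propagated to analytes;
the report carries R² and per-calibrant residuals instead.

All internal values are full precision; integer rounding of CCS happens
only in rendering.  One reproducibility caveat worth recording: tables
print drift times to 0.01 ms, and a slope of ~41 Å²/ms makes the last
printed digit worth ~0.2 Å².  An analyte whose unrounded CCS sits within
that band of a rounding boundary can therefore round differently when
recomputed from the printed drift time than it did from the raw one
(in the packaged table this affects exactly one of ten analytes, whose
recomputed 439.5 Å² prints as 439 rather than 440).  The test suite
checks both exact reproduction where the printed inputs support it and
consistency within the print precision everywhere.

Averages of percentage differences are reported in two conventions: the
mean of full-precision values, and the mean of values rounded to one
decimal (`*_printed`), which is the convention a one-decimal table
implies and the one that reproduces published state averages (7.8/7.9%).

## Projection approximation

Ω is the mean over uniformly random rotations (normalized Gaussian
quaternions) of the projected area of the union of disks of combined
atom + gas hard-sphere radius, each area estimated by uniform darts in
the orientation's bounding box.  The standard error is taken across
orientations, which dominates the dart-level variance at the default
settings (300 orientations × 4000 darts).  Coordinates are centered
first, making the estimate exactly translation invariant at fixed seed.

## Trajectory method

Ω(1,1) = π b²ₘₐₓ ⟨1 − cos χ⟩ with Monte Carlo sampling of

- orientation: uniform random rotations of the molecule,
- impact parameter: b = b_max·√u (area-uniform on [0, b_max]),
- relative speed: the momentum-transfer weight p(g) ∝ g⁵ e^(−μg²/2kT),
  sampled exactly as g = √(2kT·x/μ) with x ~ Gamma(3).

The probe carries the gas–molecule reduced mass μ and moves in
V = Σ 4ε[(σ/r)¹² − (σ/r)⁶] − (α/2)·k_C·|Σ qᵢ r̂ᵢ/rᵢ²|², with analytic
forces.  Trajectories integrate with adaptive RK45 (rtol 1e−10,
atol 1e−12) from z₀ = −(b_max + 5 Å) until the probe re-crosses its
starting radius outward; χ is the angle between asymptotic velocities.
Per-trajectory relative energy drift must stay below 1e−6; violations
and non-escaping (orbiting) trajectories are resampled and counted,
with a warning recorded above a 1% failure rate.

Conventions chosen where the standard tooling leaves them implicit:

- b_max = molecular radial extent + σ_max + 10 Å (asymptotic-region
  criterion; configurable).
- The Monte Carlo loop is organized as cycles of 25 (orientation, b, g)
  samples; cycles repeat until the standard error over cycle means falls
  below 1% of Ω or a cycle cap (default 40) is reached.  The per-cycle
  sample count is the conventional "integration points" knob.
- N₂ is a single isotropic pseudo-atom carrying the N₂ mass and
  polarizability with effective per-element 12-6 parameters — a
  deliberate simplification of four-site N₂ models.  The parameter
  table (`data/gas_params.yaml`) is data, not code, and can be replaced
  wholesale; no quantitative claim in the test suite depends on the
  shipped values, which the engine checks are property-based
  (circle-area limit, quadrature cross-checks, conservation,
  invariances).
- Temperature defaults to 300 K, matching the ensemble-analysis
  temperature; configurable.
- With no charge sidecar, charges default to zero: the induced-dipole
  term vanishes and a warning-free neutral computation results (useful
  for fixtures; real doubly protonated species should carry their
  force-field charges).

The independent reference used in tests and in `scripts/acceptance.py`
is a deterministic two-dimensional quadrature of the same collision
integral for a single Lennard-Jones center: the radial deflection
integral χ(E, b) (with the u = u₀(1 − s²) substitution removing the
turning-point singularity), Gauss–Legendre in b, and generalized
Gauss–Laguerre (α = 2) in the speed variable.

## Clustering and weighted CCS distributions

Conformers are superposed onto the first conformer (heavy atoms), and
radius-limited k-means runs on the flattened coordinates: Lloyd
iterations from the global mean, then repeated splitting — the cluster
with the largest member-to-centroid RMSD is reseeded at its two most
distant members — until every member lies within the threshold RMSD of
its cluster centroid.  The algorithm is deterministic by construction
(the `seed` argument is accepted for interface stability but not
consumed).  Cluster representatives are medoids — actual conformers
minimizing mean pairwise fitted RMSD to co-members — because a physical
structure is required for CCS computation.  By the triangle inequality
in the aligned-coordinate metric, members lie within 2× the threshold
of their medoid.  Fine distributions (0.5 Å threshold) are capped at
2,625 clusters with a warning when the cap binds.

Weighted CCS distributions assign each cluster's medoid Ω its
population fraction; the weighted mean and a fixed-width histogram
(default 2 Å² bins) are reported.  "Major conformers" are clusters
holding more than 10% of the population.

Superposition is Kabsch (SVD with a determinant guard for proper
rotations); degenerate masked sets (< 3 atoms or collinear) are
rejected.  RMSF iterates superposition onto the running mean structure
to convergence (1e−6 Å) before taking per-atom root-mean-square
deviations; exactly identical frames short-circuit to exact zeros.

Shape is summarized by the gyration tensor: eigenvalues λ1 ≥ λ2 ≥ λ3,
gyration radius, and relative shape anisotropy
κ² = 1 − 3(λ1λ2 + λ2λ3 + λ3λ1)/(λ1+λ2+λ3)².  The rod-like/globular
label uses a κ² threshold of 0.4 — a package convention for
operationalizing a visual classification, not a community standard —
and is configurable.

## Hydrogen-bond networks

The criterion is donor-centered: R_XY < 3.5 Å between heavy atoms and
θ_HXY < 30° between the X–H bond vector and the X–Y vector.  The common
alternative angle at the hydrogen (X–H···Y) is deliberately *not* used.
Hydrogens are assigned to their nearest heavy atom within 1.2 Å
(orphans are errors); only N/O parents act as donors, N/O as acceptors
(configurable); intra-residue bonds are excluded by default.

Residue-pair occupancy counts "≥ 1 bond in a frame" (per-pair bond
multiplicity is reported separately as a mean count).  Category
summaries pool bonds across frames — percentages are over the pooled
categorized bonds, not averages of per-frame percentages — with the PA
tag counted as part of the reducing-end core and fucose-involving bonds
reported outside the four inter-unit categories.

## Comparison statistics

Percentage difference is signed, (calc − exp)/exp × 100; magnitudes are
used in table-style renderings.  Per-state regressions include all
glycans, the two single-protonation-state species contributing their
only calculated value to both states; per-state averages use only the
glycans that actually carry that state's value.  Isomer ΔCCS is
globular − rod at the states fixed in the pair specification (packaged
as `data/isomer_pairs.csv`).  Reconstructing the packaged study table
yields −27, −21 and −13 Å² for the three pairs; the −13 differs by one
unit from the originally printed −12, an internal inconsistency of the
printed source values that the package reports as reconstructed rather
than forces into agreement.  Likewise one printed per-glycan
percentage-difference pair (the G1F(6) row) is consistent only with
unrounded CCS values; recomputation from the printed columns gives
8.0/6.1 vs the printed 8.2/6.4.

## Synthetic data: what it emulates and what it does not

The generators stand in for undeposited simulation trajectories:

- `make_calibrants` — a linear drift-time/CCS series with Gaussian CCS
  noise, evenly spaced drift times, and the true line recorded.
- `make_two_state_ensemble` — a mixture of two rigid bead-chain
  conformations whose pairwise fitted RMSD equals the requested
  separation (bisection-solved, accurate to ~1e−6), with per-frame state
  labels drawn first and per-atom Gaussian noise second from one seeded
  stream, both recorded as ground truth.  Defaults (60/40 mixture, 10 Å
  separation, 0.1 Å noise) make a cleanly bimodal ensemble.
- `make_glycan_mimic` — a branched bead-residue chain with the N-glycan
  unit topology (PA tag, linear core, α1-3/α1-6 arms from the core
  terminus, optional fucose), each residue a rigid C/O/H group with a
  hydroxyl donor/acceptor, jittered and retried until atoms of
  different residues stay ≥ 1.5 Å apart.
- `plant_hbond` — appends an O–H donor and an O acceptor on an outward
  axis with the requested (R_XY, θ_HXY) realized to machine precision;
  frames not selected get the acceptor displaced far away, enabling
  exact fractional occupancies.

These fixtures exercise every operator contract — mixture recovery,
criterion boundaries, category bookkeeping, occupancy arithmetic — but
they are not carbohydrates: no real sugar geometry, stereochemistry,
force-field energetics or thermal conformational exchange.  Passing
tests therefore demonstrate the correctness of the analysis machinery,
not the accuracy of any specific glycan CCS prediction, which depends on
the quality of the input ensemble and charge set.  In particular the
per-glycan calculated CCS values in the packaged study table are inputs
(they require the original trajectories and bespoke charges to
regenerate), and the engine checks are property-based by design.

## Determinism

Every stochastic component takes an explicit seed; per-conformer CCS
seeds derive from the base seed and the conformer index, so duplicate
requests are bitwise identical and list order is irrelevant.  Pipeline
reports serialize with sorted keys and no timestamps: identical config
and seed give byte-identical JSON.

## Known limitations

- The N₂ pseudo-atom ignores the quadrupole and anisotropy of real N₂;
  absolute N₂ CCS values carry the corresponding systematic uncertainty.
- No exact-hard-sphere-scattering (EHSS) engine, quantum corrections or
  diffuse-scattering models.
- Single-reference superposition before clustering (not pairwise
  all-to-all), appropriate for the compact ensembles targeted here.
- The trajectory engine integrates one probe at a time through SciPy's
  RK45; it is sized for desk-scale molecules (tens to hundreds of
  atoms), not proteins.
- Problem sizes in tests and in the acceptance script (e.g. 1,500
  trajectory samples for the single-center cross-check, 200-frame
  synthetic ensembles) are chosen to give comfortable statistical margins
  at interactive runtimes; all scale up through parameters.
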