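# Methods

## Model

fmkit implements two-stage force matching of QM/MM reference data.  Each
stored snapshot *l* carries the total forces **F**^QM on the QM atoms, the
electrostatic potential V^ρ and field **E**^ρ of the QM charge density at
the short-range (SR) MM atom positions, and the QM/SR positions.

**Stage 1 — D-RESP charges.**  The penalty

σ²-style χ²({q}) = Σ_l Σ_{β∈SR_l} [w_V (ΔV_βl)² + w_E |Δ**E**_βl|²]
+ w_H Σ_α (q_α − q_α^H)² + w_Q (Σq − Q_tot)²

is a linear least-squares problem in the charges.  The restraint term is
quadratic; a linear restraint cannot regularize a least-squares problem.
V^MM and **E**^MM are bare Coulomb sums (k_C = 138.935458 kJ mol⁻¹ nm e⁻²);
the field residual uses the full 3-vector norm per SR atom.  All snapshots
are weighted equally and SR atoms enter per snapshot without normalization
by SR count.

Two constraints are imposed by exact variable elimination rather than
penalties: (i) chemically equivalent atoms share one free variable (so
intra-group charge spread is exactly zero, not post-hoc averaged), and
(ii) the group populations are projected so Σq = Q_tot holds identically.
The w_Q penalty term is still evaluated and reported so that user grids
over w_Q keep their meaning, and a hard conservation check
(|Σq − Q_tot| ≤ 1e-8 e) runs after every solve regardless; violation is a
hard error.  Rank-deficient systems are solved in the minimum-norm sense
with a logged warning.  Weight grids evaluate the full Cartesian product
in row-major order (w_V outermost); the score of a grid point is
MSD(V) + MSD(E) per data point computed with its optimized charges, and
ties break to the first point encountered.

Atom equivalence is auto-detected: two QM atoms are equivalent iff they
have the same atom type and automorphic positions in the intra-QM bond
graph, found by iterative neighborhood color refinement seeded with atom
types (a user-supplied partition can override the detection).  The test
suite cross-checks the refinement against brute-force typed-graph
automorphism enumeration on ≤10-atom molecules.

**Boundary charges.**  When QM atoms are covalently bonded to MM atoms,
charges on all QM atoms within n_neighbor_shells bond-graph steps of a
boundary atom (the boundary atom itself is shell 0) are reset to their
original force-field values, and the excess charge is spread uniformly
over the remaining QM atoms, restoring Σq = Q_tot exactly.  The uniform
shift preserves equivalence among the non-reset atoms.

**Stage 2 — bonded parameters.**  Reference bonded forces are
**F**^QM − **F**^MM,nb per snapshot and QM atom, where the nonbonded model
forces use the stage-1 charges and the reference Lennard-Jones
parameters.  The objective adds an optional L2 term
λ Σ_n ((τ_n − τ_n^orig)/s_n)² with s_n = |τ_n^orig| when nonzero (else 1),
making λ unitless across parameter kinds.

Free slots: force constant *and* equilibrium value for bonds, angles and
impropers; only the force constant for periodic dihedrals (multiplicity is
integer-valued and phase fitting is ill-conditioned under short sampling);
all six Ryckaert-Bellemans coefficients.  Terms with identical
(kind, function type, atom-type signature) are tied to one parameter set,
mirroring the equivalent-atom charge tying; tying can be disabled.
Dihedrals are excluded from fitting by default — short reference
trajectories rarely sample torsional space well enough for transferable
dihedral parameters.

Minimization uses scipy's trust-region-reflective least squares
(ftol = xtol = gtol = 1e-10, ≤1000 iterations per parameter per stage)
starting from the original force-field values — never random, so results
need no seed.  Bounds keep force constants and b₀ nonnegative and θ₀ in
(0°, 180°).  The "simultaneous" strategy fits all included kinds at once.
The "hierarchical" strategy fits kinds in stages (bonds, angles,
impropers, dihedrals), each stage freezing the others; because the stages
only decouple exactly for independent coordinates, the stage sequence is
swept repeatedly until the objective improvement over a full sweep falls
below ftol (at most 50 sweeps).  Each stage can only decrease σ², so the
trajectory is monotone.  Non-convergence is flagged in the result and the
output files, never silent.

## Force engine

Analytical bonded forces follow the GROMACS functional forms and
conventions: harmonic bonds and angles, periodic dihedrals
k(1 + cos(nφ − φ_s)), Ryckaert-Bellemans Σ C_m cos^m ψ with ψ = φ − 180°
(sign conventions differ between MD codes; this is the GROMACS one), and
harmonic impropers with the deviation wrapped to (−180°, 180°].  Angle
parameters are stored in degrees and converted to radians in the kernels.
Every kernel is validated against central-difference energy gradients and
satisfies per-term force sums ≤ 1e-10, translational invariance and
rotational equivariance.  Collinear angle/dihedral geometries
(sin θ < 1e-9) raise a hard error identifying the term — no silent
clamping.  Atom pairs closer than 1e-5 nm are treated as overlapping and
rejected.

The nonbonded engine computes Coulomb + Lennard-Jones forces on QM atoms
from other QM atoms (exclusions generated from the bond graph to nrexcl
plus explicit [exclusions]; [pairs] scaled by fudge_QQ/fudge_LJ, defaults
0.8333/0.5) and from SR atoms within an optional cutoff (minimum-image
for orthorhombic boxes).  Combination rules 2 (Lorentz-Berthelot) and 3
(geometric) are supported, read from [defaults], defaulting to
Lorentz-Berthelot.  Electrostatics are plain cutoff sums with an optional
reaction-field correction (applied on the QM-SR path) — no mesh Ewald.
For exact parity with a mesh-Ewald rerun of an MD engine, externally
computed nonbonded force trajectories can be imported (JSON frame format
or TRR); full-system frames are sliced to the QM atoms by global index.
SR indices that do not resolve to a topology atom are treated as inert
probe points with zero charge and no LJ type.

## Units and containers

Internal units are nm, kJ/mol, e.  Reference-data files declare their
unit system in metadata and default to Hartree atomic units (the natural
output of a QM engine); conversion uses CODATA constants and happens once
at the I/O boundary.  The JSON container is a top-level array (header
object with units and QM ids, then one object per snapshot); concatenated
one-object-per-line input is also accepted.  The exact field names of any
particular producer's stream are not standardized; this schema is the
package's documented dialect.  The HDF5 container stores one group per
snapshot with root attributes for units and QM ids; snapshot access is
lazy, so peak memory is independent of the number of snapshots.  Snapshot
order in the file is authoritative; the stored step index is informative.
A missing box means non-periodic (no minimum image).

## Topology handling

The GROMACS-dialect parser resolves #include against the including file's
directory plus a search path, performs simple #define token substitution
and honors #ifdef/#ifndef/#else/#endif with user-supplied defines.
Missing inline bonded parameters are resolved from
[bondtypes]/[angletypes]/[dihedraltypes] (inline values win; dihedral
lookups try exact, reversed and X-wildcard patterns; multi-line type-9
entries expand to one term per multiplicity).  Unknown sections are
preserved verbatim and re-emitted.  Writing flattens the include graph
into one file and is a fixed point after one parse/write cycle; charges
are written with 10 decimals and parameters with 12 significant digits.
Supported fittable function types: bonds 1, angles 1, dihedrals 1/9/3,
impropers 2; other types parse and round-trip but are not fittable.
Files are 1-based, internal arrays 0-based; the QM region's index-map
object is the only place conversions happen.  Modifications
(zero_qm_bonded, update_topology) act at the molecule-type level and
refuse QM regions that touch only some copies of a multi-instance
molecule type — such topologies must be split first.

The selection grammar is a documented subset: resname / resid / name /
type / index with and / or / not, parentheses and ranges ("1 to 6" or
"1-6").  Boundary atoms are QM atoms with at least one bond term crossing
into the MM region.

## Synthetic reference data

The generator emulates the producer side of the pipeline: configurations
are sampled by i.i.d. Gaussian displacement (default σ = 0.005 nm per
coordinate) around an equilibrium geometry that satisfies every b₀/θ₀
exactly (equilibrium values are measured from the constructed geometry,
so consistency is by construction); probe points are drawn uniformly in a
spherical shell (default 0.5–1.0 nm) whose inner radius must exceed the
molecular extent.  Reference forces are bonded(true τ) + nonbonded(true
q) computed with the package's own engine, and probe potentials/fields
come from the same Coulomb kernel the charge fit uses — so with zero
noise every stored quantity is exactly reproducible by the pipeline, and
fits are validated by parameter recovery.  Noise is independent
multiplicative Gaussian per component, the simplest model that exposes
estimator bias and variance.  Snapshots with interatomic distances below
0.03 nm are resampled with a cap.

The standard fixtures are a 5-atom distinct-type chain for charge fitting
(20 snapshots, 50 probes) and a butane-like 4-site chain for bonded
fitting (200 snapshots); displacement amplitudes keep angles far from
collinearity and the quadratic basins well sampled.  What passing these
tests does *not* show: performance on real QM densities (point charges
only), conformational diversity beyond one basin, solvent boxes, periodic
electrostatics, or link-atom chemistry at real covalent boundaries.

## Workflow and reproducibility

The single-command workflow runs QM-region construction → D-RESP (single
set or grid, CSV export) → boundary redistribution (only when boundary
atoms exist) → nonbonded forces (internal engine or imported rerun) →
bonded fit → topology update, logging each stage with timestamps to
fm.log and finishing with the σ_V/σ_E/σ_F summary.  σ_X =
sqrt(Σ|X^fit − X^ref|² / Σ|X^ref|²) over all data points of quantity X
(vector norms for **E** and **F**); σ_F is reported against the isolated
bonded reference.  Other normalizations of these σ metrics exist in the
literature; this one is the package's documented choice, and an all-zero
reference makes the metric undefined (error).  optimization_results.txt
and opt_topology.itp contain no timestamps and are byte-reproducible
across reruns; χ²/σ² assembly uses fixed summation order, so the worker
count (n_processes) can never change results.  The mdp/ndx/gmx options
exist for command-line parity with an external MD-engine rerun and are
used only on the imported-forces path.

## Known limitations

- No mesh-Ewald electrostatics in the internal engine; use the import
  path when long-range accuracy matters.
- Combination rule 1 (C6/C12) and virtual sites/constraints are not
  supported beyond passthrough.
- Dihedral phase and multiplicity are never fitted.
- The grid-search score averages per data point; per-snapshot averaging
  would weight uneven SR counts differently.
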