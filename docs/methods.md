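# Methods

`ectodyn` analyses conformational ensembles of receptor ectodomains composed
of several Ig-like domains joined by a short flexible linker — the
architecture of the IL-1 receptor family, where two rigid N-terminal domains
(D1, D2) are followed by a mobile third domain (D3) whose position is
governed entirely by the backbone torsions of a six-residue linker.  This
note records the models, conventions, defaults and known limitations; every
empirical statement here is one the test suite or `scripts/acceptance.py`
computes.

## Data model and units

Structures are fixed-column PDB; trajectories are multi-model PDB sharing
one topology (binary formats can be adapted behind the same `Trajectory`
contract).  Internal units are Angstrom and picoseconds everywhere;
reporting layers convert Rg to nm and SASA to nm² where those units are
conventional.  Alternate locations resolve to the highest-occupancy
conformer (ties by altloc letter); insertion-coded residues are kept as
distinct residues; hydrogens are retained when present but never built.
Atomic masses come from the element column; an unknown element is an error,
never a guessed mass.

Domain definitions (`DomainMap`) are mandatory configuration: the linker
position fixes the D2/D3 split, but no structural fact pins the D1/D2
boundary, so the shipped toy layout (D1 = 1–100, D2 = 101–200, linker =
201–206, D3 = 207–319, mirroring a 319-residue ectodomain) is an explicit
config choice, enforced disjoint at construction.

## Superposition-based metrics

Superposition is the Kabsch least-squares fit (SVD with reflection
correction), unweighted and on Cα atoms by default, matching the common
Cα-alignment convention; centres of mass and the radius of gyration are
mass-weighted.  RMSD against a different crystal form matches atoms by
(residue number, atom name) after an optional chain mapping and drops
unmatched residues with a reported count, since crystals differ in resolved
residues.  RMSF uses one fit-to-frame-1 pass followed by a single refit to
the resulting mean — at the trajectory lengths used here a second iteration
changes nothing measurable.  Crystallographic B-factors convert through
RMSF = √(3B/8π²), exactly invertible.

### Hinge angles

The interdomain hinge is reported as the angle at a vertex — the linker
centre of mass — between the vectors to the centres of mass of the two
domains (D1–D3 and D2–D3 pairs).  The vertex choice is a design decision:
it produces a bounded [0°, 180°] angle whose open/closed ranges match the
convention of small = closed (≈110–125°), large = open (≈150–180°).  An
optional projection plane (e.g. XY for a membrane-anchored system) is
available by flag and recorded in report metadata; the default is the full
3-D angle.  Degenerate projected vectors yield NaN for that frame, never a
silent zero.

### Domain rotation

The rigid-body rotation of D3 between two structures is measured by first
superposing on D1+D2, then superposing the two D3 copies onto each other
and reporting θ = arccos((tr R − 1)/2) of that second fit.  The measure is
symmetric in its two arguments to numerical precision.

## SASA and hydrogen bonds

SASA is Shrake–Rupley with a deterministic golden-spiral sphere lattice
(default 960 points, probe 1.4 Å) over Bondi van der Waals radii, so
results are bit-reproducible; for an isolated atom the lattice is exact at
any density.  Doubling the point count moves a protein-sized total by well
under 0.5%.

Hydrogen bonds are geometric.  With explicit hydrogens: donor–acceptor
distance ≤ 3.5 Å and H–D–A angle ≤ 30°.  For hydrogen-free inputs a
heavy-atom-only mode counts N/O···N/O contacts by distance alone, with a
2.4 Å minimum so covalent peptide geometry (e.g. O(i)···N(i+1) at ≈2.25 Å)
is not miscounted.  Absolute counts depend strongly on protonation and
criteria conventions, so crystal-structure H-bond counts are reported with
the mode declared in metadata and are not treated as reference values.

## Essential dynamics

Every frame is RMS-fitted to a fixed reference (by default the starting
snapshot) on the analysis selection; the covariance of the 3N flattened
coordinates about their grand mean (population normalisation, unweighted —
no mass weighting, matching backbone-coordinate practice) is diagonalised
with a dense symmetric solver.  Eigenvector signs are canonicalised
(largest-magnitude component positive).  When several replicas are
analysed jointly the grand mean over the pooled frames defines the centre;
per-replica fits are also available.  External structures project into the
subspace after matching the selection atoms by residue number and atom
name, with missing atoms reported explicitly.

## Linker dihedral clustering

Each linker torsion θ enters the feature matrix as (sin θ, cos θ), making
the representation continuous across ±180°.  Features are unscaled by
default — sine and cosine are already bounded and commensurate — with a
z-scored mode available; the choice is recorded in report metadata.
Prolines are excluded (ring-locked φ), as the final linker residue is in
the toy system.

Clustering is PAM (k-medoids): greedy BUILD initialisation, then
best-improvement SWAP steps, each strictly decreasing the total
point-to-medoid distance (asserted), until convergence or an iteration
cap.  The exact path is RNG-free and deterministic; for more than 20,000
points a CLARA-style strategy (5 subsamples of 10,000, best full-data
objective kept) takes over, controlled by a single seed.  Cluster labels
are canonicalised by descending size.  k is chosen by maximising the mean
silhouette width over k = 2..10 (ties to the smaller k); silhouette values
come from scikit-learn's implementation and are cross-checked against a
hand computation in the tests.  Cluster representatives are medoid frames;
populations below a 5% floor are flagged but retained in the table.

Ramachandran assignment uses a coarse rectilinear approximation of the
general-case map (β/extended and right-handed α as favored, broader
margins plus the left-handed α region as allowed); boundaries resolve to
the more permissive region.  It is a qualitative plausibility check, not a
validation-grade map.

## Synthetic data generator

The generator replaces a molecular-dynamics engine as the testbed: it
emulates a three-domain ectodomain switching between discrete open
(hinge 165°), closed (115°) and twisted (extra 110° D3 rotation about the
linker axis; 85° and 170° are the other typical choices) states, with the
closed/open hinge defaults placed centrally in the 110–125° and 150–180°
bands that characterise such systems.

The toy receptor is a single 319-residue chain of backbone atoms
(N, CA, C, O).  Domains are rigid pseudo-globular blobs: CA atoms laid
along a pole-to-pole spherical spiral at 3.8 Å spacing with ≈5.5 Å between
windings (giving Ig-domain-like ≈13 Å radii and a ≈2.8 nm whole-receptor
Rg), with N/C/O synthesised from local tangent frames at ideal bond
lengths.  The linker is fully parameterised: per-frame φ/ψ are drawn from
per-state von Mises distributions (default κ = 50, ≈8° circular sd; state
means in the α, β and left-handed-α regions for closed, open and twisted
respectively) and the linker is rebuilt atom by atom by natural-extension
forward kinematics, so dihedral truth and Cartesian truth agree exactly
for the clustered residues.  D3 rides rigidly on the rebuilt linker end;
an exact rigid rotation about the linker centre of mass then sets the
D1–D3 hinge to the state mean (so the noise-free hinge is exact, not
approximate), and a second rotation about the linker-COM→D3-COM axis
applies the twist without disturbing the hinge.  The junction bond at the
linker/D3 seam and ψ of the final (proline) linker residue are idealised
rather than re-derived; neither enters the clustered feature set.
Isotropic Gaussian noise (default σ = 0.3 Å per axis) is added last, and
topology B-factors are written from the realised per-atom fluctuation
(state motion plus noise) through the B↔RMSF relation.

State sequences are block-ordered with largest-remainder apportionment
(exact occupancies) or first-order Markov switching at a configurable
rate.  A `freeze_linker` mode pins torsions to the state means — the
noise-only control in which measured RMSF must equal σ√3.  Frame-to-frame
D3/D1–D2 CA overlaps closer than 1.5 Å are counted and warned about, not
repaired: some seed layouts allow the closed state to graze D1.

What the generator does *not* emulate: side chains, secondary-structure
detail inside domains, solvent, membranes, force-field energetics,
continuous diffusive transitions, or state-dependent within-state hinge
dispersion (the noise is isotropic and stateless).  Tests passing on this
generator therefore demonstrate that the analysis stack recovers known
rigid-body/torsional ground truth at realistic geometry and noise — not
that it reproduces any particular empirical system.

## Pipeline and problem sizes

`run_analysis` executes metrics → hinge → PCA → clustering from one
config; optional-stage failures are logged into the bundle and metadata
rather than aborting the run, and every convention above is echoed into
`metadata.json` so a report is self-describing.  Summary tables use the
sample standard deviation (n−1).  Expensive per-frame properties (SASA,
H-bonds) are evaluated on a configurable frame stride (default every 50th
frame) and averaged.

Default analysis sizes are chosen so a full synthetic study runs on one
CPU in minutes: 2000 frames per replica (1 frame / 60 ps over 120 ns
equivalent), three replicas pooled for PCA, clustering on one pooled
dihedral table with k = 2..10.  At these sizes the two-state PC1+PC2
variance fraction computed by `scripts/acceptance.py` lands near 90%, the
three-state linker clustering recovers k = 3 with ARI ≥ 0.9, and hinge
state means are recovered to well under 2°.

## Known limitations

- PAM is O(k·n²) per SWAP sweep with an n×n distance matrix; beyond the
  20,000-point exact cap the CLARA path trades optimality for memory.
- The heavy-atom H-bond count is a contact count, not a protonation-aware
  bond assignment; compare counts only within one convention.
- The Ramachandran map is rectilinear and coarse by design.
- Crystal-to-crystal RMSD depends on the matched-residue set; the matcher
  reports how many residues were dropped, and that number should accompany
  any quoted value.
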