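# ectodyn

Conformational-dynamics analysis of multi-domain receptor ectodomains.

Many cytokine receptors expose an extracellular region built from several
Ig-like domains joined by short flexible linkers — the IL-1 receptor family
being the canonical case, with two rigidly coupled domains (D1, D2)
followed by a mobile third domain (D3) hinged on a six-residue linker.
The biology of such receptors turns on rigid-body questions: how far does
D3 swing between *open* and *closed* arrangements, does it *twist* about
the linker axis, and which linker backbone torsions drive the transitions?
`ectodyn` is a toolkit for answering those questions from conformational
ensembles (multi-model PDB trajectories), aimed at structural
bioinformaticians who have ensembles in hand and want reproducible,
scriptable analysis rather than a simulation engine.

## What it computes

- **Per-frame metrics** — Kabsch-superposed Cα RMSD against a reference
  crystal, per-atom RMSF and the B-factor relation RMSF = √(3B/8π²),
  mass-weighted radius of gyration, Shrake–Rupley SASA (deterministic
  golden-spiral lattice, Bondi radii) and geometric hydrogen-bond counts.
- **Interdomain geometry** — hinge angles φ measured at the linker centre
  of mass between domain centres of mass (small φ = closed, large φ =
  open), and the rigid-body rotation angle of one domain between two
  structures after fitting on the others, θ = arccos((tr R − 1)/2).
- **Essential dynamics** — PCA of the fitted backbone coordinate
  covariance C = ⟨(x − ⟨x⟩)(x − ⟨x⟩)ᵀ⟩; leading eigenvectors are the
  collective open/close and twist modes, and external crystal structures
  project into the same PC subspace as reference points.
- **Linker clustering** — backbone (φ, ψ) of the linker residues, mapped
  to (sin θ, cos θ) features and clustered with PAM (k-medoids,
  BUILD + SWAP, written here from scratch), with k chosen by maximising
  the mean silhouette width and clusters represented by medoid frames.
- **Synthetic testbed** — a generator that builds a toy three-domain
  receptor and emits state-switching trajectories (open/closed/twisted)
  with exact ground truth for hinge angles, linker torsions, state labels
  and per-atom RMSF, so every stage of the stack is validated against
  known truth.

Estimator-style classes (`EssentialDynamics`, `PAM`) follow scikit-learn
conventions (`fit`/`transform`/`predict`, trailing-underscore attributes)
and compose with sklearn tooling; module functions are thin wrappers.

## Worked example

Generate three synthetic replicas of a two-state (closed ⇌ open) receptor
and run the core analyses:

```python
import ectodyn as ed
from ectodyn.io import select_atoms
from ectodyn.metrics import hinge_series
from ectodyn.synthetic import toy_domain_map

topo = ed.build_toy_receptor(seed=0)
states = ed.default_states(["closed", "open"], [0.5, 0.5])
trajs, truths = [], []
for rep in range(3):
    traj, truth = ed.generate_trajectory(topo, states, n_frames=2000,
                                         noise_sigma=0.3, seed=1000 + rep)
    trajs.append(traj); truths.append(truth)

backbone = select_atoms(trajs[0], atom_names=("N", "CA", "C"))
model = ed.fit_pca(trajs, selection=backbone)
print(f"PC1+PC2 variance fraction: {model.variance_fraction(2):.3f}")

dm = toy_domain_map()
hs = hinge_series(trajs[0], dm, "D1", "D3")
labels = truths[0].state_labels()
print(f"mean hinge (closed frames): {hs.angles[labels == 'closed'].mean():.1f} deg")
print(f"mean hinge (open frames):   {hs.angles[labels == 'open'].mean():.1f} deg")

dih = ed.backbone_dihedrals(trajs[0], dm["linker"])
feats = ed.circular_features(dih)          # proline excluded automatically
result = ed.select_k(feats, range(2, 7))
print(f"best k by mean silhouette: {result.best_k}")
```

Output:

```
PC1+PC2 variance fraction: 0.907
mean hinge (closed frames): 115.0 deg
mean hinge (open frames):   165.0 deg
best k by mean silhouette: 2
```

Reading: the first two principal components carry ~91% of the positional
variance — the single open/close hinge mode dominates, as it should for a
two-state system; the hinge-angle means recover the generator's configured
115° (closed) and 165° (open) states; and silhouette-based model selection
finds exactly the two linker-torsion states that were simulated.

## Command line

```bash
ectodyn simulate --states closed,open --n-frames 2000 --seed 1 --out runs/S1
ectodyn analyze --config analysis.yaml --seed 1 --out report/
ectodyn compare-structures open.pdb closed.pdb --domains domains.yaml
```

`analyze` writes every result as TSV (summary table in the conventional
mean ± sd schema: RMSD in Å, Rg in nm, H-bond count, SASA in nm²; hinge
series; PC projections; silhouette-vs-k; cluster populations; medoid PDBs)
plus a `metadata.json` recording the seed, versions and every analysis
convention in effect.  Crystal-structure comparisons (`compare-structures`)
additionally report the interdomain rotation angle when a domain map is
supplied.

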