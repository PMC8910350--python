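"""Essential dynamics: PCA of the coordinate covariance of fitted frames.

Every frame is least-squares fitted to a fixed reference (by default the
first frame of the first trajectory, i.e. the starting snapshot) on the
analysis selection; the covariance matrix of the 3N flattened coordinates
about their grand mean is then diagonalised with a dense symmetric solver.
Leading eigenvectors describe the dominant collective motions (for a
two-domain hinge system, typically the open/close mode first, then
twisting).  External reference structures (e.g. crystal forms) can be
projected into the same subspace for comparison.

The covariance is unweighted (no mass weighting), matching the common
backbone-coordinate usage; this is recorded in the model metadata.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ectodyn._geometry import apply_transform, kabsch
from ectodyn.io import Structure, Trajectory
from ectodyn.metrics import match_atoms

__all__ = ["EssentialDynamics", "fit_pca", "project", "variance_fraction"]


def _as_traj_list(trajs) -> list[Trajectory]:
    if isinstance(trajs, Trajectory):
        return [trajs]
    return list(trajs)


class EssentialDynamics(BaseEstimator):
    """Covariance-based PCA of fitted coordinates (scikit-learn style).

    Parameters
    ----------
    selection:
        Topology atom indices to analyse (e.g. backbone N/CA/C).  ``None``
        uses all atoms.
    n_components:
        Number of leading eigenpairs kept on ``transform``; all eigenpairs
        are always computed and stored.

    Attributes (after :meth:`fit`)
    ------------------------------
    mean_coords_ : (N, 3) grand-mean fitted coordinates, Angstrom.
    eigenvectors_ : (3N, 3N) orthonormal columns, descending eigenvalue order.
    eigenvalues_ : (3N,) non-negative, Angstrom^2, descending.
    reference_coords_ : (N, 3) fit-reference coordinates.
    selection_ : resolved atom index array.
    selection_topology_ : Structure of the selected atoms (for matching
        external structures by residue number and atom name).
    """

    def __init__(self, selection: np.ndarray | None = None,
                 n_components: int = 4):
        self.selection = selection
        self.n_components = n_components

    # -- fitting ----------------------------------------------------------

    def fit(self, trajs: Trajectory | Iterable[Trajectory],
            fit_reference: Structure | None = None) -> "EssentialDynamics":
        trajs = _as_traj_list(trajs)
        if not trajs:
            raise ValueError("need at least one trajectory")
        topo0 = trajs[0].topology
        sel = (np.arange(topo0.n_atoms) if self.selection is None
               else np.asarray(self.selection, dtype=int))
        for t in trajs:
            if t.topology.n_atoms != topo0.n_atoms:
                raise ValueError("trajectories do not share the selection's atoms")
        total_frames = sum(t.n_frames for t in trajs)
        if total_frames < 2:
            raise ValueError("PCA needs at least 2 frames in total")
        if fit_reference is None:
            ref = trajs[0].frames[0][sel]
            ref_label = f"{trajs[0].label or 'traj0'}:frame0"
        else:
            ref = self._resolve_external(fit_reference, topo0, sel)
            ref_label = fit_reference.identifier
        X = np.concatenate([t.frames[:, sel] for t in trajs], axis=0)
        for f in range(X.shape[0]):
            R, t_, _ = kabsch(X[f], ref)
            X[f] = apply_transform(X[f], R, t_)
        mean = X.mean(axis=0)
        Xc = (X - mean).reshape(X.shape[0], -1)
        cov = (Xc.T @ Xc) / X.shape[0]
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1]
        evals = np.clip(evals[order], 0.0, None)
        evecs = evecs[:, order]
        # canonical signs: largest-magnitude component positive
        peaks = np.argmax(np.abs(evecs), axis=0)
        signs = np.sign(evecs[peaks, np.arange(evecs.shape[1])])
        signs[signs == 0] = 1.0
        evecs = evecs * signs
        self.selection_ = sel
        self.mean_coords_ = mean
        self.eigenvectors_ = evecs
        self.eigenvalues_ = evals
        self.reference_coords_ = np.asarray(ref, dtype=float)
        self.reference_label_ = ref_label
        self.selection_topology_ = topo0.subset(sel)
        self.n_frames_ = X.shape[0]
        self.metadata_ = {
            "mass_weighted": False,
            "fit_reference": ref_label,
            "n_frames": int(X.shape[0]),
            "n_atoms": int(sel.size),
        }
        return self

    @staticmethod
    def _resolve_external(structure: Structure, topo: Structure,
                          sel: np.ndarray) -> np.ndarray:
        """Coordinates of ``structure`` matched to the selected topology atoms."""
        if structure.n_atoms == topo.n_atoms:
            return structure.coords[sel]
        return EssentialDynamics._match_to_subset(structure, topo.subset(sel))

    @staticmethod
    def _match_to_subset(structure: Structure, sub: Structure) -> np.ndarray:
        """Match an external structure to a subset topology by residue/name."""
        if structure.n_atoms == sub.n_atoms and \
                np.array_equal(structure.res_id, sub.res_id) and \
                np.array_equal(np.char.strip(structure.name.astype(str)),
                               np.char.strip(sub.name.astype(str))):
            return structure.coords
        i_ext, i_sub, _ = match_atoms(structure, sub, atom_names=None)
        if i_sub.size < sub.n_atoms:
            matched = set(i_sub.tolist())
            missing = [
                f"{sub.chain_id[i]}/{sub.res_id[i]}/{str(sub.name[i]).strip()}"
                for i in range(sub.n_atoms) if i not in matched
            ]
            raise ValueError(f"structure is missing selection atoms: {missing[:10]}"
                             + (" ..." if len(missing) > 10 else ""))
        coords = np.empty((sub.n_atoms, 3))
        coords[i_sub] = structure.coords[i_ext]
        return coords

    # -- projection -------------------------------------------------------

    def _fitted_coords(self, source: Structure | Trajectory) -> np.ndarray:
        if isinstance(source, Trajectory):
            frames = source.frames[:, self.selection_]
        else:
            frames = self._match_to_subset(source, self.selection_topology_)[None]
        out = np.empty_like(frames)
        for f in range(frames.shape[0]):
            R, t, _ = kabsch(frames[f], self.reference_coords_)
            out[f] = apply_transform(frames[f], R, t)
        return out

    def transform(self, source: Structure | Trajectory,
                  components: Sequence[int] | None = None) -> np.ndarray:
        """Project frames (or one structure) onto principal components.

        Returns an (n_frames, k) array of PC coordinates in Angstrom.
        ``components`` are 0-based indices; default the first
        ``n_components``.
        """
        comps = (list(range(self.n_components)) if components is None
                 else list(components))
        fitted = self._fitted_coords(source)
        Xc = (fitted - self.mean_coords_).reshape(fitted.shape[0], -1)
        return Xc @ self.eigenvectors_[:, comps]

    def fit_transform(self, trajs, fit_reference: Structure | None = None,
                      components: Sequence[int] | None = None) -> np.ndarray:
        self.fit(trajs, fit_reference=fit_reference)
        tl = _as_traj_list(trajs)
        return np.concatenate([self.transform(t, components) for t in tl], axis=0)

    def reconstruct(self, projections: np.ndarray,
                    components: Sequence[int] | None = None) -> np.ndarray:
        """Rebuild fitted coordinates from PC coordinates (inverse transform)."""
        comps = (list(range(projections.shape[1])) if components is None
                 else list(components))
        flat = projections @ self.eigenvectors_[:, comps].T
        return flat.reshape(projections.shape[0], -1, 3) + self.mean_coords_

    def variance_fraction(self, k: int) -> float:
        """Fraction of total variance in the first ``k`` eigenvalues."""
        ev = self.eigenvalues_
        if not 1 <= k <= ev.size:
            raise ValueError(f"k must be in 1..{ev.size}")
        total = ev.sum()
        if total == 0:
            return 0.0
        return float(ev[:k].sum() / total)

    def extreme_structures(self, component: int = 0) -> Trajectory:
        """Two-model trajectory at the extreme projections along one PC."""
        ev = self.eigenvectors_[:, [component]]
        lo = self.mean_coords_.reshape(-1) - np.sqrt(self.eigenvalues_[component]) * 2 * ev[:, 0]
        hi = self.mean_coords_.reshape(-1) + np.sqrt(self.eigenvalues_[component]) * 2 * ev[:, 0]
        frames = np.stack([lo.reshape(-1, 3), hi.reshape(-1, 3)])
        return Trajectory(topology=self.selection_topology_, frames=frames,
                          time_stride=1.0, label=f"PC{component + 1}-extremes")


# ---------------------------------------------------------------------------
# Functional wrappers


def fit_pca(trajs, selection: np.ndarray | None = None,
            fit_reference: Structure | None = None,
            n_components: int = 4) -> EssentialDynamics:
    """Fit an :class:`EssentialDynamics` model (functional form)."""
    return EssentialDynamics(selection=selection,
                             n_components=n_components).fit(
        trajs, fit_reference=fit_reference)


def project(model: EssentialDynamics, source: Structure | Trajectory,
            components: Sequence[int] | None = None) -> np.ndarray:
    """Project a trajectory or structure onto the model's components."""
    return model.transform(source, components)


def variance_fraction(model: EssentialDynamics, k: int) -> float:
    """Fraction of total variance captured by the first ``k`` components."""
    return model.variance_fraction(k)
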