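"""Circular dihedral features and partitioning-around-medoids clustering.

The conformational states of a short flexible linker are characterised by
the backbone torsions (phi, psi) of its residues.  Because torsions are
circular, each angle theta contributes the pair (sin theta, cos theta) to
the feature vector, making 179.5 deg and -179.5 deg near-neighbours in
Euclidean feature space.  Frames are then clustered with the classic PAM
(partitioning around medoids) algorithm — BUILD initialisation followed by
strictly-improving SWAP steps — and the number of clusters is chosen by
maximising the mean silhouette width.  Medoids are actual frames, so each
cluster has a concrete representative structure.

For datasets beyond an exact-PAM size cap, a CLARA-style strategy (repeated
subsampling, best objective kept) is used; that path is seed-controlled,
the exact path is RNG-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import silhouette_samples

from ectodyn.io import Structure, Trajectory

__all__ = [
    "CircularFeatures",
    "PAM",
    "circular_features",
    "pam",
    "silhouette",
    "select_k",
    "SelectKResult",
    "cluster_report",
    "ramachandran_region",
    "RAMACHANDRAN_REGIONS",
]


# ---------------------------------------------------------------------------
# Circular features


@dataclass
class CircularFeatures:
    """sin/cos-transformed dihedral feature matrix.

    ``matrix`` is (n_frames, 2m) with columns ordered residue-major, phi
    before psi, (sin, cos) per angle.  With ``scaling="none"`` every
    (sin, cos) pair lies on the unit circle.  Frames containing undefined
    angles are dropped (``n_dropped`` records how many).
    """

    matrix: np.ndarray
    angle_labels: list[tuple[int, str]]
    frame_ids: np.ndarray
    scaling: str = "none"
    n_dropped: int = 0

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = []
        for res, ang in self.angle_labels:
            cols += [f"sin_{ang}_{res}", f"cos_{ang}_{res}"]
        df = pd.DataFrame(self.matrix, columns=cols)
        df.insert(0, "frame", self.frame_ids)
        return df


def circular_features(dihedrals: pd.DataFrame,
                      exclude_residues: Iterable[int] | None = None,
                      exclude_proline: bool = True,
                      scaling: str = "none") -> CircularFeatures:
    """Build the circular feature matrix from a phi/psi table.

    ``dihedrals`` is the long-format table of
    :func:`ectodyn.metrics.backbone_dihedrals` (columns frame, residue,
    res_name, phi, psi).  Proline residues are excluded by default (their
    phi is locked by the pyrrolidine ring), as are any residue numbers in
    ``exclude_residues``.  ``scaling`` is ``"none"`` (default; sin/cos are
    already bounded and commensurate) or ``"standardized"`` (z-scored
    columns).
    """
    if scaling not in ("none", "standardized"):
        raise ValueError(f"unknown scaling {scaling!r}")
    df = dihedrals.copy()
    excl = set(int(r) for r in (exclude_residues or ()))
    if exclude_proline:
        excl |= set(df.loc[df["res_name"].astype(str).str.upper() == "PRO",
                           "residue"].astype(int))
    df = df[~df["residue"].astype(int).isin(excl)]
    if df.empty:
        raise ValueError("no residues left after exclusions")
    residues = sorted(df["residue"].astype(int).unique())
    wide_phi = df.pivot_table(index="frame", columns="residue", values="phi",
                              dropna=False)
    wide_psi = df.pivot_table(index="frame", columns="residue", values="psi",
                              dropna=False)
    labels: list[tuple[int, str]] = []
    cols: list[np.ndarray] = []
    for res in residues:
        for ang, wide in (("phi", wide_phi), ("psi", wide_psi)):
            series = wide[res].to_numpy(dtype=float)
            if np.all(np.isnan(series)):
                continue  # e.g. terminal angle undefined in every frame
            rad = np.deg2rad(series)
            labels.append((res, ang))
            cols.append(np.sin(rad))
            cols.append(np.cos(rad))
    if not labels:
        raise ValueError("no defined dihedral angles to featurise")
    mat = np.column_stack(cols)
    frame_ids = wide_phi.index.to_numpy()
    keep = ~np.isnan(mat).any(axis=1)
    n_dropped = int((~keep).sum())
    mat = mat[keep]
    frame_ids = frame_ids[keep]
    if mat.shape[0] == 0:
        raise ValueError("all frames dropped: missing angles everywhere")
    if scaling == "standardized":
        sd = mat.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        mat = (mat - mat.mean(axis=0)) / sd
    return CircularFeatures(matrix=mat, angle_labels=labels,
                            frame_ids=frame_ids, scaling=scaling,
                            n_dropped=n_dropped)


# ---------------------------------------------------------------------------
# PAM


class PAM(BaseEstimator, ClusterMixin):
    """Partitioning around medoids (k-medoids), scikit-learn style.

    Exact BUILD + SWAP for up to ``max_exact_n`` points; above that a
    CLARA-style strategy fits exact PAM on ``clara_samples`` random subsets
    of size ``clara_sample_size`` and keeps the medoid set with the best
    full-data objective.  Distances are Euclidean.

    Attributes (after :meth:`fit`)
    ------------------------------
    medoid_indices_ : (k,) indices into X, ordered by descending cluster size.
    labels_ : (n,) cluster ids in ``0..k-1`` (0 = largest cluster).
    inertia_ : total distance of points to their medoids (the PAM objective).
    objective_trace_ : objective after BUILD and after each SWAP step
        (strictly decreasing).
    """

    def __init__(self, n_clusters: int = 8, max_swap_iter: int = 200,
                 max_exact_n: int = 20000, clara_samples: int = 5,
                 clara_sample_size: int = 10000, random_state: int = 0):
        self.n_clusters = n_clusters
        self.max_swap_iter = max_swap_iter
        self.max_exact_n = max_exact_n
        self.clara_samples = clara_samples
        self.clara_sample_size = clara_sample_size
        self.random_state = random_state

    # -- exact PAM --------------------------------------------------------

    @staticmethod
    def _build(D: np.ndarray, k: int) -> list[int]:
        n = D.shape[0]
        first = int(np.argmin(D.sum(axis=1)))
        medoids = [first]
        dnear = D[:, first].copy()
        while len(medoids) < k:
            gains = np.maximum(dnear[:, None] - D, 0.0).sum(axis=0)
            gains[medoids] = -np.inf
            nxt = int(np.argmax(gains))
            medoids.append(nxt)
            dnear = np.minimum(dnear, D[:, nxt])
        return medoids

    def _swap(self, D: np.ndarray, medoids: list[int]) -> tuple[list[int], list[float]]:
        n = D.shape[0]
        medoids = list(medoids)
        trace: list[float] = []

        def nearest_info(meds):
            sub = D[:, meds]
            order = np.argsort(sub, axis=1, kind="stable")
            n1 = order[:, 0]
            d1 = sub[np.arange(n), n1]
            d2 = sub[np.arange(n), order[:, 1]] if len(meds) > 1 else np.full(n, np.inf)
            return n1, d1, d2

        obj = None
        for _ in range(self.max_swap_iter):
            n1, d1, d2 = nearest_info(medoids)
            cur = float(d1.sum())
            if obj is not None and cur > obj + 1e-9:  # pragma: no cover
                raise AssertionError("PAM objective increased")
            obj = cur
            trace.append(cur)
            best_delta = -1e-9
            best_swap = None
            chunk = max(256, int(2e7 // max(n, 1)))
            for mi, m in enumerate(medoids):
                mine = n1 == mi
                # candidate columns: every non-medoid h (chunked to bound memory)
                deltas = np.empty(n)
                for s0 in range(0, n, chunk):
                    Dc = D[:, s0:s0 + chunk]
                    contrib = np.where(
                        mine[:, None],
                        np.minimum(Dc, d2[:, None]) - d1[:, None],
                        np.minimum(Dc - d1[:, None], 0.0),
                    )
                    deltas[s0:s0 + chunk] = contrib.sum(axis=0)
                deltas[medoids] = np.inf
                h = int(np.argmin(deltas))
                if deltas[h] < best_delta:
                    best_delta = float(deltas[h])
                    best_swap = (mi, h)
            if best_swap is None:
                break
            medoids[best_swap[0]] = best_swap[1]
        n1, d1, _ = nearest_info(medoids)
        trace.append(float(d1.sum()))
        return medoids, trace

    def _fit_exact(self, X: np.ndarray) -> tuple[np.ndarray, float, list[float]]:
        D = cdist(X, X)
        medoids = self._build(D, self.n_clusters)
        medoids, trace = self._swap(D, medoids)
        labels = np.argmin(D[:, medoids], axis=1)
        obj = float(D[np.arange(len(X)), np.asarray(medoids)[labels]].sum())
        return np.asarray(medoids), obj, trace

    # -- public API -------------------------------------------------------

    def fit(self, X: np.ndarray, y=None) -> "PAM":
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        k = self.n_clusters
        if not 2 <= k < n:
            raise ValueError(f"n_clusters must satisfy 2 <= k < n_frames ({n})")
        if n <= self.max_exact_n:
            medoids, obj, trace = self._fit_exact(X)
        else:
            rng = np.random.default_rng(self.random_state)
            best: tuple[float, np.ndarray] | None = None
            trace = []
            for _ in range(self.clara_samples):
                sample = rng.choice(n, size=min(self.clara_sample_size, n),
                                    replace=False)
                sample.sort()
                sub_meds, _, sub_trace = self._fit_exact(X[sample])
                cand = sample[sub_meds]
                dist = cdist(X, X[cand])
                obj = float(dist.min(axis=1).sum())
                if best is None or obj < best[0]:
                    best = (obj, cand)
                    trace = sub_trace
            obj, medoids = best  # type: ignore[misc]
        dist = cdist(X, X[medoids])
        labels = np.argmin(dist, axis=1)
        # canonical ordering: clusters numbered by descending size
        sizes = np.bincount(labels, minlength=len(medoids))
        order = np.lexsort((np.asarray(medoids), -sizes))
        medoids = np.asarray(medoids)[order]
        remap = np.empty(len(order), dtype=int)
        remap[order] = np.arange(len(order))
        self.labels_ = remap[labels]
        self.medoid_indices_ = medoids
        self.inertia_ = obj
        self.objective_trace_ = trace
        self.cluster_sizes_ = np.bincount(self.labels_, minlength=len(medoids))
        self.n_samples_ = n
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not hasattr(self, "medoid_coords_"):
            raise AttributeError("call fit_with_coords or fit first")
        return np.argmin(cdist(np.asarray(X, float), self.medoid_coords_), axis=1)

    def fit_predict(self, X: np.ndarray, y=None) -> np.ndarray:
        self.fit(X)
        self.medoid_coords_ = np.asarray(X, float)[self.medoid_indices_]
        return self.labels_


def pam(features: CircularFeatures | np.ndarray, k: int,
        max_swap_iters: int = 200, random_state: int = 0) -> PAM:
    """Fit PAM with ``k`` clusters on a feature matrix (functional form)."""
    X = features.matrix if isinstance(features, CircularFeatures) else features
    model = PAM(n_clusters=k, max_swap_iter=max_swap_iters,
                random_state=random_state)
    model.fit(X)
    model.medoid_coords_ = np.asarray(X, float)[model.medoid_indices_]
    return model


# ---------------------------------------------------------------------------
# Silhouette and k selection


def silhouette(features: CircularFeatures | np.ndarray,
               labels: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-point silhouette values and their mean.

    s(i) = (b - a) / max(a, b) with a the mean intra-cluster distance and b
    the smallest mean distance to another cluster; singletons score 0.
    """
    X = features.matrix if isinstance(features, CircularFeatures) else features
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    vals = silhouette_samples(np.asarray(X, float), labels)
    return vals, float(vals.mean())


@dataclass
class SelectKResult:
    best_k: int
    model: PAM
    table: pd.DataFrame  # columns: k, mean_silhouette


def select_k(features: CircularFeatures | np.ndarray,
             k_range: Sequence[int] | range = range(2, 11),
             random_state: int = 0, **pam_kwargs) -> SelectKResult:
    """Choose the cluster count maximising mean silhouette width.

    Fits PAM for every k in ``k_range`` and returns the argmax (ties go to
    the smaller k) together with the winning model and the full
    silhouette-vs-k table.
    """
    X = features.matrix if isinstance(features, CircularFeatures) else features
    X = np.asarray(X, float)
    rows = []
    best: tuple[float, int, PAM] | None = None
    for k in k_range:
        model = PAM(n_clusters=int(k), random_state=random_state, **pam_kwargs)
        model.fit(X)
        model.medoid_coords_ = X[model.medoid_indices_]
        _, mean_sil = silhouette(X, model.labels_)
        rows.append((int(k), mean_sil))
        if best is None or mean_sil > best[0] + 1e-12:
            best = (mean_sil, int(k), model)
    assert best is not None
    table = pd.DataFrame(rows, columns=["k", "mean_silhouette"])
    return SelectKResult(best_k=best[1], model=best[2], table=table)


# ---------------------------------------------------------------------------
# Reporting


def cluster_report(model: PAM, features: CircularFeatures | None = None,
                   traj: Trajectory | None = None,
                   min_fraction: float = 0.05
                   ) -> tuple[pd.DataFrame, list[Structure]]:
    """Population table and medoid structures, clusters ranked by size.

    Clusters below ``min_fraction`` of the population are flagged but kept
    in the table.  If a trajectory is given, medoid frames are exported as
    Structures (``frame_ids`` of the features map medoids back to frames).
    """
    labels = model.labels_
    n = labels.size
    sizes = np.bincount(labels, minlength=model.medoid_indices_.size)
    fractions = sizes / n
    frame_ids = (features.frame_ids if features is not None
                 else np.arange(n))
    medoid_frames = frame_ids[model.medoid_indices_]
    table = pd.DataFrame({
        "cluster": np.arange(1, sizes.size + 1),
        "n_frames": sizes,
        "fraction": fractions,
        "medoid_frame": medoid_frames,
        "below_min_fraction": fractions < min_fraction,
    })
    medoid_structures: list[Structure] = []
    if traj is not None:
        for mf in medoid_frames:
            s = traj.frame(int(mf))
            s.identifier = f"{traj.label or 'traj'}:frame{int(mf)}"
            medoid_structures.append(s)
    return table, medoid_structures


# ---------------------------------------------------------------------------
# Ramachandran regions

#: Coarse rectilinear approximation of the general-case Ramachandran map
#: (beta/extended, right-handed alpha, and the additionally-allowed
#: left-handed alpha region), in degrees.  Each entry is
#: (phi_min, phi_max, psi_min, psi_max), boundaries inclusive; a point on an
#: edge takes the more permissive assignment by checking "favored" first.
RAMACHANDRAN_REGIONS: dict[str, list[tuple[float, float, float, float]]] = {
    "favored": [
        (-180.0, -45.0, 90.0, 180.0),   # beta / extended
        (-180.0, -45.0, -180.0, -150.0),  # beta (periodic tail)
        (-160.0, -20.0, -80.0, -5.0),   # right-handed alpha
    ],
    "allowed": [
        (-180.0, -20.0, 45.0, 180.0),
        (-180.0, -20.0, -180.0, -140.0),
        (-180.0, -20.0, -120.0, 45.0),
        (20.0, 100.0, -30.0, 90.0),     # left-handed alpha
    ],
}


def _wrap_angle(a: float) -> float:
    """Wrap to (-180, 180]."""
    a = (float(a) + 180.0) % 360.0 - 180.0
    return 180.0 if a == -180.0 else a


def ramachandran_region(phi: float, psi: float) -> str:
    """Classify a (phi, psi) pair as ``favored``, ``allowed`` or ``outlier``."""
    if not (np.isfinite(phi) and np.isfinite(psi)):
        raise ValueError("both angles must be defined")
    p, s = _wrap_angle(phi), _wrap_angle(psi)
    for region in ("favored", "allowed"):
        for lo_p, hi_p, lo_s, hi_s in RAMACHANDRAN_REGIONS[region]:
            if lo_p <= p <= hi_p and lo_s <= s <= hi_s:
                return region
    return "outlier"
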