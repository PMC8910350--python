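"""Superposition-based deviation/fluctuation metrics and interdomain geometry.

Covers the per-frame observables used to characterise multi-domain ectodomain
ensembles: least-squares (Kabsch) superposition and RMSD against a crystal
reference, per-atom RMSF and its relation to crystallographic B-factors
(RMSF = sqrt(3B / 8 pi^2)), mass-weighted radius of gyration, interdomain
hinge angles measured at the linker centre of mass, backbone phi/psi
dihedrals, and the rigid-body rotation of one domain between two structures
after fitting on the others.

Public interfaces use degrees and Angstrom; internals use radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ectodyn._geometry import (
    angle_between,
    apply_transform,
    dihedral,
    kabsch,
)
from ectodyn.io import DomainMap, ResidueRange, Structure, Trajectory, select_atoms

__all__ = [
    "SuperpositionResult",
    "HingeSeries",
    "kabsch_superpose",
    "rmsd_series",
    "rmsf",
    "bfactor_to_rmsf",
    "rmsf_to_bfactor",
    "radius_of_gyration",
    "center_of_mass",
    "hinge_angle",
    "hinge_series",
    "backbone_dihedrals",
    "domain_rotation_angle",
    "match_atoms",
]


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid-body fit: ``mobile @ rotation.T + translation``."""

    rotation: np.ndarray  # (3, 3), proper orthogonal
    translation: np.ndarray  # (3,), Angstrom
    rmsd: float  # Angstrom

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return apply_transform(coords, self.rotation, self.translation)


@dataclass
class HingeSeries:
    """Per-frame hinge angle at a vertex between two domain COM vectors."""

    times: np.ndarray  # ps
    angles: np.ndarray  # degrees in [0, 180]; NaN where degenerate
    domain_pair: tuple[str, str]
    vertex: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ps": self.times, "angle_deg": self.angles})


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     weights: np.ndarray | None = None) -> SuperpositionResult:
    """Least-squares superposition of ``mobile`` onto ``reference``.

    Minimises the (optionally weighted) RMSD over corresponding points and
    enforces a proper rotation (reflections corrected).  Requires >= 3
    non-collinear points.
    """
    R, t, rmsd = kabsch(mobile, reference, weights)
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def match_atoms(a: Structure, b: Structure,
                atom_names: Iterable[str] | None = ("CA",),
                chain_map: dict[str, str] | None = None
                ) -> tuple[np.ndarray, np.ndarray, int]:
    """Pair atoms of two structures by (residue_number, atom name).

    Chains of ``a`` are first renamed through ``chain_map`` (identity by
    default).  Residues resolved in only one structure are dropped; the
    number of unmatched residues is returned so callers can log it.  This is
    the correspondence rule used when comparing different crystal forms.
    """
    def keys(s: Structure, cmap: dict[str, str] | None):
        out = {}
        for i in range(s.n_atoms):
            nm = str(s.name[i]).strip()
            if atom_names is not None and nm not in atom_names:
                continue
            ch = str(s.chain_id[i])
            if cmap:
                ch = cmap.get(ch, ch)
            out[(int(s.res_id[i]), nm)] = i
        return out

    ka = keys(a, chain_map)
    kb = keys(b, None)
    common = sorted(set(ka) & set(kb))
    if not common:
        raise ValueError("no common atoms between structures")
    dropped = len({k[0] for k in set(ka) ^ set(kb)})
    ia = np.array([ka[k] for k in common])
    ib = np.array([kb[k] for k in common])
    return ia, ib, dropped


def rmsd_series(traj: Trajectory, reference: Structure,
                selection: np.ndarray | None = None,
                atom_names: Iterable[str] | None = ("CA",)) -> np.ndarray:
    """Per-frame RMSD (Angstrom) after independent fit of each frame.

    Atom correspondence between trajectory topology and reference is by
    (residue_number, atom name).  ``selection`` optionally restricts the
    trajectory atoms considered before matching.
    """
    topo = traj.topology
    if selection is not None:
        topo = topo.subset(selection)
        frames = traj.frames[:, selection]
    else:
        frames = traj.frames
    it, ir, _ = match_atoms(topo, reference, atom_names=atom_names)
    ref = reference.coords[ir]
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        _, _, out[f] = kabsch(frames[f][it], ref)
    return out


def rmsf(traj: Trajectory, selection: np.ndarray | None = None,
         fit: bool = True) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (Angstrom).

    RMSF_i = sqrt(<|x_i - <x_i>|^2>) over frames.  With ``fit=True`` each
    frame is first superposed: one pass fitting to frame 1, then a refit of
    every frame to the resulting mean (single iteration).
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    sel = np.arange(traj.n_atoms) if selection is None else np.asarray(selection)
    X = traj.frames[:, sel].copy()
    if fit:
        ref = X[0]
        for f in range(X.shape[0]):
            R, t, _ = kabsch(X[f], ref)
            X[f] = apply_transform(X[f], R, t)
        mean = X.mean(axis=0)
        for f in range(X.shape[0]):
            R, t, _ = kabsch(X[f], mean)
            X[f] = apply_transform(X[f], R, t)
    mean = X.mean(axis=0)
    d2 = np.sum((X - mean) ** 2, axis=2)
    return np.sqrt(d2.mean(axis=0))


_B_TO_RMSF = 3.0 / (8.0 * math.pi ** 2)


def bfactor_to_rmsf(B):
    """Crystallographic B-factor (A^2) to isotropic RMSF (A): sqrt(3B/8pi^2)."""
    B = np.asarray(B, dtype=float)
    if np.any(B < 0):
        raise ValueError("negative B-factor")
    out = np.sqrt(_B_TO_RMSF * B)
    return float(out) if out.ndim == 0 else out


def rmsf_to_bfactor(r):
    """Inverse of :func:`bfactor_to_rmsf`: B = 8 pi^2 RMSF^2 / 3."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("negative RMSF")
    out = r ** 2 / _B_TO_RMSF
    return float(out) if out.ndim == 0 else out


def center_of_mass(coords: np.ndarray, masses: np.ndarray) -> np.ndarray:
    masses = np.asarray(masses, dtype=float)
    if coords.shape[0] == 0:
        raise ValueError("empty selection")
    if np.any(masses <= 0):
        raise ValueError("non-positive mass")
    return (masses[:, None] * coords).sum(axis=0) / masses.sum()


def radius_of_gyration(coords: np.ndarray, masses: np.ndarray) -> float:
    """Mass-weighted radius of gyration (Angstrom)."""
    coords = np.asarray(coords, dtype=float)
    com = center_of_mass(coords, masses)
    masses = np.asarray(masses, dtype=float)
    d2 = np.sum((coords - com) ** 2, axis=1)
    return float(np.sqrt((masses * d2).sum() / masses.sum()))


def hinge_angle(coords: np.ndarray, masses: np.ndarray,
                dom_a: np.ndarray, dom_b: np.ndarray, vertex: np.ndarray,
                plane: tuple[int, int] | None = None) -> float:
    """Hinge angle (degrees, [0, 180]) at the vertex centre of mass.

    The angle between the vectors from the vertex COM (typically the linker)
    to the COMs of domains A and B.  With ``plane`` given as an axis pair
    (e.g. ``(0, 1)`` for XY), both vectors are first projected onto that
    plane — the membrane-plane variant.  Degenerate (zero-length) projected
    vectors yield NaN, never a silent 0.
    """
    coords = np.asarray(coords, dtype=float)
    v = center_of_mass(coords[vertex], masses[vertex])
    u = center_of_mass(coords[dom_a], masses[dom_a]) - v
    w = center_of_mass(coords[dom_b], masses[dom_b]) - v
    if plane is not None:
        keep = list(plane)
        mask = np.zeros(3)
        mask[keep] = 1.0
        u = u * mask
        w = w * mask
    if np.linalg.norm(u) < 1e-12 or np.linalg.norm(w) < 1e-12:
        return float("nan")
    return math.degrees(angle_between(u, w))


def hinge_series(traj: Trajectory, domain_map: DomainMap,
                 dom_a: str, dom_b: str, vertex: str = "linker",
                 plane: tuple[int, int] | None = None) -> HingeSeries:
    """Hinge-angle time series for a trajectory."""
    ia = select_atoms(traj, ranges=domain_map[dom_a])
    ib = select_atoms(traj, ranges=domain_map[dom_b])
    iv = select_atoms(traj, ranges=domain_map[vertex])
    m = traj.topology.mass
    angles = np.array([
        hinge_angle(traj.frames[f], m, ia, ib, iv, plane=plane)
        for f in range(traj.n_frames)
    ])
    return HingeSeries(times=traj.times, angles=angles,
                       domain_pair=(dom_a, dom_b), vertex=vertex)


def _residue_backbone_index(topo: Structure):
    """(chain, res_id) -> {atom_name: index} for backbone atoms."""
    table: dict[tuple[str, int], dict[str, int]] = {}
    for i in range(topo.n_atoms):
        nm = str(topo.name[i]).strip()
        if nm in ("N", "CA", "C"):
            table.setdefault((str(topo.chain_id[i]), int(topo.res_id[i])), {})[nm] = i
    return table


def backbone_dihedrals(obj: Structure | Trajectory,
                       residues: Sequence[tuple[str, int]] | Sequence[ResidueRange],
                       ) -> pd.DataFrame:
    """Phi/psi table for the given residues, long format.

    phi(i) = C(i-1)-N(i)-CA(i)-C(i); psi(i) = N(i)-CA(i)-C(i)-N(i+1);
    IUPAC sign convention, degrees in (-180, 180].  Angles undefined at
    chain termini (or with missing backbone atoms) are NaN.

    Returns a DataFrame with columns
    ``frame, chain, residue, res_name, phi, psi``.
    """
    traj = obj if isinstance(obj, Trajectory) else Trajectory(
        topology=obj, frames=obj.coords[None], time_stride=1.0)
    topo = traj.topology
    # normalise residue spec
    res_list: list[tuple[str, int]] = []
    for r in residues:
        if isinstance(r, ResidueRange):
            res_list.extend((r.chain_id, i) for i in range(r.start, r.stop + 1))
        else:
            res_list.append((str(r[0]), int(r[1])))
    bb = _residue_backbone_index(topo)
    name_of = {(str(c), int(i)): str(n)
               for c, i, n in zip(topo.chain_id, topo.res_id, topo.res_name)}
    rows = []
    for f in range(traj.n_frames):
        X = traj.frames[f]
        for chain, res in res_list:
            cur = bb.get((chain, res), {})
            prev = bb.get((chain, res - 1), {})
            nxt = bb.get((chain, res + 1), {})
            phi = psi = float("nan")
            if {"N", "CA", "C"} <= cur.keys():
                if "C" in prev:
                    phi = math.degrees(dihedral(X[prev["C"]], X[cur["N"]],
                                                X[cur["CA"]], X[cur["C"]]))
                if "N" in nxt:
                    psi = math.degrees(dihedral(X[cur["N"]], X[cur["CA"]],
                                                X[cur["C"]], X[nxt["N"]]))
            rows.append((f, chain, res, name_of.get((chain, res), ""), phi, psi))
    return pd.DataFrame(rows, columns=["frame", "chain", "residue",
                                       "res_name", "phi", "psi"])


def domain_rotation_angle(struct1: Structure, struct2: Structure,
                          fit_ranges: Sequence[ResidueRange],
                          measure_ranges: Sequence[ResidueRange],
                          atom_names: Iterable[str] | None = ("CA",),
                          chain_map: dict[str, str] | None = None) -> float:
    """Rigid-body rotation (degrees) of one domain between two structures.

    ``struct2`` is superposed onto ``struct1`` using the atoms of
    ``fit_ranges`` (e.g. D1+D2); the two copies of ``measure_ranges``
    (e.g. D3) are then superposed onto each other and the rotation angle of
    that second fit, theta = arccos((trace(R) - 1) / 2), is returned.
    """
    def _sub(s: Structure, ranges):
        keep = [i for i in range(s.n_atoms)
                if any((str(s.chain_id[i]), int(s.res_id[i])) in r for r in ranges)]
        if not keep:
            raise ValueError("selection resolves to no atoms")
        return s.subset(np.asarray(keep))

    fit1, fit2 = _sub(struct1, fit_ranges), _sub(struct2, fit_ranges)
    i1, i2, _ = match_atoms(fit2, fit1, atom_names=atom_names, chain_map=chain_map)
    R, t, _ = kabsch(fit2.coords[i1], fit1.coords[i2])
    s2 = struct2.with_coords(apply_transform(struct2.coords, R, t))
    m1, m2s = _sub(struct1, measure_ranges), _sub(s2, measure_ranges)
    j2, j1, _ = match_atoms(m2s, m1, atom_names=atom_names, chain_map=chain_map)
    R2, _, _ = kabsch(m2s.coords[j2], m1.coords[j1])
    c = np.clip((np.trace(R2) - 1.0) / 2.0, -1.0, 1.0)
    return math.degrees(math.acos(c))
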