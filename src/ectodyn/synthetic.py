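"""Synthetic multi-domain receptor topologies and trajectories.

This module is the package's testbed: it emulates the conformational
behaviour of a three-Ig-like-domain receptor ectodomain whose third domain
(D3) moves about a six-residue flexible linker between discrete states —
open (large hinge angle), closed (small hinge angle) and twisted (D3
rotated about the linker axis) — with every generated quantity recorded as
ground truth.

The toy receptor is a single chain built entirely from idealised backbone
internal coordinates (fixed bond lengths and angles, chosen torsions): each
domain is a compact helical bundle, the linker a fully parameterised
six-residue segment.  Trajectory frames are produced by forward kinematics:
per-frame linker torsions are sampled from per-state von Mises
distributions, the linker is rebuilt atom by atom, D3 rides rigidly on the
rebuilt linker end, and an exact rigid correction then sets the hinge angle
(at the linker centre of mass, between the D1 and D3 centres of mass) and
the D3 twist to the state's values.  Isotropic Gaussian noise is added
last.  Dihedral truth and Cartesian truth are therefore mutually consistent
for the clustered linker residues.

B-factors of the emitted topology encode the per-atom positional
fluctuation actually realised (state motion plus noise), via
B = 8 pi^2 RMSF^2 / 3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ectodyn._geometry import (
    angle_between,
    kabsch,
    apply_transform,
    dihedral,
    place_atom_nerf,
    rotation_about_axis,
)
from ectodyn.io import DomainMap, ResidueRange, Structure, Trajectory
from ectodyn.metrics import center_of_mass, rmsf_to_bfactor

__all__ = [
    "StateSpec",
    "GroundTruth",
    "default_states",
    "build_toy_receptor",
    "toy_domain_map",
    "generate_trajectory",
]

# Idealised backbone internal coordinates (Angstrom / degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_N_CA_C = math.radians(111.0)
_A_CA_C_N = math.radians(116.2)
_A_C_N_CA = math.radians(121.7)
_A_CA_C_O = math.radians(120.8)
_OMEGA = math.pi  # trans peptide

#: Linker residue names (201..206 by default); the final proline is excluded
#: from dihedral clustering by default because its phi is ring-locked.
_LINKER_RES_NAMES = ("LEU", "GLU", "GLU", "ASN", "LYS", "PRO")

# Pseudo-globular domain layout: CA atoms on a spherical spiral with
# ~3.8 A spacing between consecutive residues and ~5.5 A between windings.
_CA_SPACING = 3.8
_WINDING_GAP = 5.5


@dataclass
class StateSpec:
    """One discrete conformational state of the toy receptor.

    ``hinge_angle_mean`` is the D1-D3 hinge angle (degrees, vertex at the
    linker COM) realised exactly in every noise-free frame of the state;
    ``d3_twist_mean`` an additional rotation of D3 about the linker-to-D3
    axis (degrees); ``linker_phi_psi_means`` per-linker-residue (phi, psi)
    means (degrees) for the von Mises torsion sampling with concentration
    ``concentration``; ``fraction`` the state's occupancy.
    """

    name: str
    hinge_angle_mean: float
    d3_twist_mean: float = 0.0
    linker_phi_psi_means: tuple[float, float] | dict[int, tuple[float, float]] = (-63.0, -43.0)
    concentration: float = 50.0
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.hinge_angle_mean <= 180.0:
            raise ValueError("hinge_angle_mean must be in (0, 180]")
        if self.concentration <= 0:
            raise ValueError("von Mises concentration must be positive")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")

    def phi_psi_mean(self, residue: int) -> tuple[float, float]:
        if isinstance(self.linker_phi_psi_means, dict):
            return self.linker_phi_psi_means[residue]
        return tuple(self.linker_phi_psi_means)  # type: ignore[return-value]


#: Default state palette: closed hinge in the 110-125 deg band, open in the
#: 150-180 deg band, twisted realised as an extra D3 rotation about the
#: linker axis (default 110 deg, with 85 and 170 the other typical choices).
_PALETTE: dict[str, StateSpec] = {
    "closed": StateSpec(name="closed", hinge_angle_mean=115.0, d3_twist_mean=0.0,
                        linker_phi_psi_means=(-63.0, -43.0)),
    "open": StateSpec(name="open", hinge_angle_mean=165.0, d3_twist_mean=0.0,
                      linker_phi_psi_means=(-120.0, 135.0)),
    "twisted": StateSpec(name="twisted", hinge_angle_mean=160.0,
                         d3_twist_mean=110.0,
                         linker_phi_psi_means=(60.0, 45.0)),
}


def default_states(names: Sequence[str] = ("closed", "open"),
                   fractions: Sequence[float] | None = None) -> list[StateSpec]:
    """Named states from the default palette with normalised fractions."""
    specs = [replace(_PALETTE[n]) for n in names]
    if fractions is None:
        fractions = [1.0 / len(specs)] * len(specs)
    if len(fractions) != len(specs):
        raise ValueError("fractions length mismatch")
    total = float(sum(fractions))
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError("state fractions must sum to 1")
    return [replace(s, fraction=float(f)) for s, f in zip(specs, fractions)]


@dataclass
class GroundTruth:
    """Per-frame and per-atom truth emitted alongside a synthetic trajectory."""

    states: pd.DataFrame       # frame, state, hinge_deg, twist_deg
    dihedrals: pd.DataFrame    # frame, residue, phi, psi (sampled values)
    rmsf_per_atom: np.ndarray  # Angstrom, includes state motion + noise
    state_specs: list[StateSpec]
    clash_count: int = 0

    def state_labels(self) -> np.ndarray:
        return self.states["state"].to_numpy()


# ---------------------------------------------------------------------------
# Chain building


def _spiral_ca(n_res: int, phase: float = 0.0) -> np.ndarray:
    """CA positions of a compact pseudo-globular blob.

    Residues run along a pole-to-pole spherical spiral (axis x) with
    ~3.8 A consecutive spacing and ~5.5 A between windings; the sphere
    radius is solved so the spiral holds exactly ``n_res`` points.  The
    ``phase`` rotates the spiral about its axis (seed-derived jitter).
    """
    def walk(R: float) -> np.ndarray:
        loops = max(1.0, math.pi * R / _WINDING_GAP)
        pts = []
        theta = math.pi - 1e-3
        while theta > 1e-3:
            phi = phase + 2.0 * loops * theta
            pts.append([R * math.cos(theta),
                        R * math.sin(theta) * math.cos(phi),
                        R * math.sin(theta) * math.sin(phi)])
            dtheta = _CA_SPACING / (R * math.sqrt(
                1.0 + 4.0 * loops ** 2 * math.sin(theta) ** 2))
            theta -= dtheta
        return np.asarray(pts)

    lo, hi = 3.0, 60.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if len(walk(mid)) >= n_res:
            hi = mid
        else:
            lo = mid
    pts = walk(hi)[:n_res]
    return pts


def _backbone_from_ca(ca: np.ndarray) -> np.ndarray:
    """Synthesise N, C, O positions from a CA trace.

    Bond lengths are ideal (N-CA 1.458, CA-C 1.525, C=O 1.231) and the
    peptide C(i)-N(i+1) distance comes out near 1.33 A by construction;
    local geometry is only approximately protein-like, which is all the
    rigid domains require.
    """
    n = len(ca)
    coords = np.zeros((n, 4, 3))
    coords[:, 1] = ca
    # tilt of the N-CA / CA-C bonds off the CA-CA virtual bond, solved so
    # that the peptide C(i)...N(i+1) gap closes to ~1.33 A along the chain
    alpha = math.acos((_CA_SPACING - _B_C_N) / (_B_N_CA + _B_CA_C))
    for i in range(n):
        t_prev = ca[i] - ca[i - 1] if i > 0 else ca[i + 1] - ca[i]
        t_next = ca[i + 1] - ca[i] if i + 1 < n else ca[i] - ca[i - 1]
        t_prev = t_prev / np.linalg.norm(t_prev)
        t_next = t_next / np.linalg.norm(t_next)
        # out-of-line direction: away from the local chain plane
        p = np.cross(t_prev, t_next)
        if np.linalg.norm(p) < 1e-6:
            p = np.cross(t_next, [0.0, 0.0, 1.0])
            if np.linalg.norm(p) < 1e-6:
                p = np.cross(t_next, [0.0, 1.0, 0.0])
        p = p / np.linalg.norm(p)
        ca_dir = math.cos(alpha)
        off = math.sin(alpha)
        coords[i, 0] = ca[i] - _B_N_CA * (ca_dir * t_prev - off * p)  # N
        coords[i, 2] = ca[i] + _B_CA_C * (ca_dir * t_next + off * p)  # C
        coords[i, 3] = coords[i, 2] + _B_C_O * p                      # O
    return coords


def toy_domain_map(n_res_per_domain: tuple[int, int, int] = (100, 100, 113),
                   linker_start: int = 201, chain_id: str = "A") -> DomainMap:
    """DomainMap matching :func:`build_toy_receptor` numbering."""
    d1, d2, d3 = n_res_per_domain
    if linker_start != d1 + d2 + 1:
        raise ValueError("linker_start must follow D1+D2 residues")
    return DomainMap({
        "D1": (ResidueRange(chain_id, 1, d1),),
        "D2": (ResidueRange(chain_id, d1 + 1, d1 + d2),),
        "linker": (ResidueRange(chain_id, linker_start, linker_start + 5),),
        "D3": (ResidueRange(chain_id, linker_start + 6,
                            linker_start + 5 + d3),),
    })


def build_toy_receptor(n_res_per_domain: tuple[int, int, int] = (100, 100, 113),
                       linker_start: int = 201,
                       seed: int = 0,
                       chain_id: str = "A") -> Structure:
    """Deterministic toy three-domain receptor (backbone N/CA/C/O atoms).

    Domains are compact helical bundles joined in series; a fully
    parameterised six-residue linker sits between D2 and D3 (residues
    ``linker_start``..``linker_start+5``, 201-206 by default).  Identical
    seeds give bitwise-identical coordinates.  Severe steric overlap in the
    generated layout raises after internal retries.
    """
    d1, d2, d3 = n_res_per_domain
    if min(d1, d2, d3) < 5:
        raise ValueError("domains need at least 5 residues each")
    if linker_start != d1 + d2 + 1:
        raise ValueError("linker_start must equal n(D1) + n(D2) + 1")
    rng = np.random.default_rng(seed)
    linker_open = _PALETTE["open"].linker_phi_psi_means
    for attempt in range(5):
        phases = rng.uniform(0.0, 2.0 * math.pi, size=3)
        ca1 = _spiral_ca(d1, phases[0])
        ca2 = _spiral_ca(d2, phases[1])
        ca3 = _spiral_ca(d3, phases[2])
        r1 = float(np.abs(ca1[:, 0]).max())
        r2 = float(np.abs(ca2[:, 0]).max())
        r3 = float(np.abs(ca3[:, 0]).max())
        ca2 = ca2 + np.array([r1 + r2 + 4.0, 0.0, 0.0])
        bb1 = _backbone_from_ca(ca1)
        bb2 = _backbone_from_ca(ca2)
        # linker by NeRF from the last D2 residue, template torsions = open
        lp, ls = linker_open  # type: ignore[misc]
        a, b, c = bb2[-1, 0], bb2[-1, 1], bb2[-1, 2]
        psi_in = ls
        linker_bb = np.zeros((6, 4, 3))
        for k in range(6):
            nN = place_atom_nerf(a, b, c, _B_C_N, _A_CA_C_N, math.radians(psi_in))
            nCA = place_atom_nerf(b, c, nN, _B_N_CA, _A_C_N_CA, _OMEGA)
            nC = place_atom_nerf(c, nN, nCA, _B_CA_C, _A_N_CA_C, math.radians(lp))
            nO = place_atom_nerf(nN, nCA, nC, _B_C_O, _A_CA_C_O,
                                 math.radians(ls) + math.pi)
            linker_bb[k] = [nN, nCA, nC, nO]
            a, b, c = nN, nCA, nC
            psi_in = ls
        # D3 blob: axis aligned with the outgoing linker direction
        end_ca, end_c = linker_bb[-1, 1], linker_bb[-1, 2]
        d_axis = end_c - end_ca
        d_axis = d_axis / np.linalg.norm(d_axis)
        xhat = np.array([1.0, 0.0, 0.0])
        rot_axis = np.cross(xhat, d_axis)
        if np.linalg.norm(rot_axis) < 1e-9:
            R3rot = np.eye(3) if d_axis[0] > 0 else rotation_about_axis(
                np.array([0.0, 0.0, 1.0]), math.pi)
        else:
            R3rot = rotation_about_axis(
                rot_axis, math.acos(np.clip(d_axis[0], -1.0, 1.0)))
        bb3 = _backbone_from_ca(ca3 @ R3rot.T)
        shift = end_c + 2.5 * d_axis - bb3[0, 0]
        bb3 = bb3 + shift
        bb = np.concatenate([bb1, bb2, linker_bb, bb3], axis=0)
        flat = bb.reshape(-1, 3)
        # inter-domain clash scan on CA atoms
        ca = bb[:, 1]
        d = np.linalg.norm(ca[:, None] - ca[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        sep = np.abs(np.arange(len(ca))[:, None] - np.arange(len(ca))[None, :])
        if np.min(d[sep > 2]) > 2.0:
            break
    else:
        raise RuntimeError("could not place domains without severe overlap")
    n_res = d1 + d2 + 6 + d3
    res_names = ["ALA"] * n_res
    for off, nm in enumerate(_LINKER_RES_NAMES):
        res_names[linker_start - 1 + off] = nm
    names = np.tile(np.array(["N", "CA", "C", "O"]), n_res)
    elements = np.tile(np.array(["N", "C", "C", "O"]), n_res)
    res_ids = np.repeat(np.arange(1, n_res + 1), 4)
    res_name_arr = np.repeat(np.array(res_names), 4)
    n_atoms = n_res * 4
    masses = np.where(elements == "N", 14.007,
                      np.where(elements == "O", 15.999, 12.011))
    return Structure(
        identifier=f"toy-receptor-{d1}-{d2}-{d3}-seed{seed}",
        serial=np.arange(1, n_atoms + 1),
        name=names,
        element=elements,
        res_id=res_ids,
        res_name=res_name_arr,
        chain_id=np.full(n_atoms, chain_id),
        ins_code=np.full(n_atoms, ""),
        coords=flat,
        bfactor=np.zeros(n_atoms),
        occupancy=np.ones(n_atoms),
        mass=masses,
    )


# ---------------------------------------------------------------------------
# Trajectory generation


def _sample_states(rng: np.random.Generator, states: Sequence[StateSpec],
                   n_frames: int, transition: str, markov_rate: float) -> np.ndarray:
    fracs = np.array([s.fraction for s in states])
    if not math.isclose(fracs.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("state fractions must sum to 1")
    if transition == "block":
        # largest-remainder apportionment: exact block sizes
        raw = fracs * n_frames
        counts = np.floor(raw).astype(int)
        rem = n_frames - counts.sum()
        order = np.argsort(-(raw - counts))
        counts[order[:rem]] += 1
        return np.repeat(np.arange(len(states)), counts)
    if transition == "markov":
        labels = np.empty(n_frames, dtype=int)
        labels[0] = rng.choice(len(states), p=fracs)
        for f in range(1, n_frames):
            if rng.random() < markov_rate:
                labels[f] = rng.choice(len(states), p=fracs)
            else:
                labels[f] = labels[f - 1]
        return labels
    raise ValueError(f"unknown transition mode {transition!r}")


def _von_mises_deg(rng: np.random.Generator, mean_deg: float, kappa: float) -> float:
    return math.degrees(rng.vonmises(math.radians(mean_deg), kappa))


def _hinge_correction_axis(u: np.ndarray, w: np.ndarray) -> np.ndarray:
    n = np.cross(u, w)
    if np.linalg.norm(n) < 1e-9:
        # collinear: any axis perpendicular to u
        trial = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(trial, u)) / np.linalg.norm(u) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        n = np.cross(u, trial)
    return n / np.linalg.norm(n)


def generate_trajectory(topology: Structure,
                        states: Sequence[StateSpec] | None = None,
                        n_frames: int = 2000,
                        transition: str = "block",
                        markov_rate: float = 0.02,
                        noise_sigma: float = 0.3,
                        seed: int = 0,
                        time_stride: float = 60.0,
                        domain_map: DomainMap | None = None,
                        label: str = "synthetic",
                        freeze_linker: bool = False,
                        ) -> tuple[Trajectory, GroundTruth]:
    """Generate a state-switching trajectory with known ground truth.

    Per frame: a state is drawn (block or Markov switching), linker phi/psi
    are sampled from the state's von Mises distributions, the linker is
    rebuilt by forward kinematics from the last D2 residue, D3 rides
    rigidly on the rebuilt linker end, and exact rigid corrections set the
    D1-D3 hinge angle (vertex at linker COM) and the D3 twist about the
    linker-to-D3 axis to the state means.  Isotropic Gaussian noise of
    ``noise_sigma`` (Angstrom, per axis) is added to all atoms last.

    With ``freeze_linker=True`` the linker torsions are pinned to the state
    means instead of sampled — the noise-only control in which the only
    frame-to-frame variation within a state is the Gaussian noise.

    Returns the trajectory (topology carries B-factors consistent with the
    realised per-atom RMSF) and the :class:`GroundTruth`.
    """
    if n_frames < 10:
        raise ValueError("n_frames must be >= 10")
    states = list(states) if states is not None else default_states()
    if domain_map is None:
        domain_map = _infer_domain_map(topology)
    rng = np.random.default_rng(seed)
    labels = _sample_states(rng, states, n_frames, transition, markov_rate)

    chain = str(topology.chain_id[0])
    linker_lo = domain_map["linker"][0].start
    linker_hi = domain_map["linker"][0].stop
    idx_of = {(int(r), str(n).strip()): i
              for i, (r, n) in enumerate(zip(topology.res_id, topology.name))}
    bb = lambda res, nm: idx_of[(res, nm)]
    d1_idx = _indices(topology, domain_map, "D1")
    d2_idx = _indices(topology, domain_map, "D2")
    d3_idx = _indices(topology, domain_map, "D3")
    linker_idx = _indices(topology, domain_map, "linker")
    masses = topology.mass
    is_ca = np.char.strip(topology.name.astype(str)) == "CA"
    ca_d3_idx = d3_idx[is_ca[d3_idx]]
    ca_fix_idx = np.concatenate([d1_idx[is_ca[d1_idx]], d2_idx[is_ca[d2_idx]]])

    base = topology.coords.copy()
    frames = np.empty((n_frames, topology.n_atoms, 3))
    truth_rows = []
    dihedral_rows = []
    clash_count = 0

    for f in range(n_frames):
        spec = states[labels[f]]
        X = base.copy()
        # --- sample linker torsions (phi for all 6; psi for first 5) -----
        sampled: dict[int, tuple[float, float]] = {}
        for res in range(linker_lo, linker_hi + 1):
            mp, ms = spec.phi_psi_mean(res) if isinstance(
                spec.linker_phi_psi_means, dict) else spec.linker_phi_psi_means
            if freeze_linker:
                sampled[res] = (mp, ms)
            else:
                sampled[res] = (_von_mises_deg(rng, mp, spec.concentration),
                                _von_mises_deg(rng, ms, spec.concentration))
        # --- rebuild linker by NeRF from the last D2 residue -------------
        prev = linker_lo - 1
        psi_prev = math.degrees(dihedral(
            base[bb(prev, "N")], base[bb(prev, "CA")],
            base[bb(prev, "C")], base[bb(linker_lo, "N")]))
        a, b, c = X[bb(prev, "N")], X[bb(prev, "CA")], X[bb(prev, "C")]
        psi_in = psi_prev  # keep D2's own psi fixed
        for res in range(linker_lo, linker_hi + 1):
            phi, psi = sampled[res]
            nN = place_atom_nerf(a, b, c, _B_C_N, _A_CA_C_N, math.radians(psi_in))
            nCA = place_atom_nerf(b, c, nN, _B_N_CA, _A_C_N_CA, _OMEGA)
            nC = place_atom_nerf(c, nN, nCA, _B_CA_C, _A_N_CA_C, math.radians(phi))
            nO = place_atom_nerf(nN, nCA, nC, _B_C_O, _A_CA_C_O,
                                 math.radians(psi) + math.pi)
            X[bb(res, "N")], X[bb(res, "CA")] = nN, nCA
            X[bb(res, "C")], X[bb(res, "O")] = nC, nO
            a, b, c = nN, nCA, nC
            psi_in = psi
        # --- D3 rides rigidly on the rebuilt last linker residue ---------
        tri_ref = base[[bb(linker_hi, "N"), bb(linker_hi, "CA"), bb(linker_hi, "C")]]
        tri_new = X[[bb(linker_hi, "N"), bb(linker_hi, "CA"), bb(linker_hi, "C")]]
        R, t, _ = kabsch(tri_ref, tri_new)
        X[d3_idx] = apply_transform(base[d3_idx], R, t)
        # --- exact hinge correction (rotation of D3 about linker COM) ----
        v = center_of_mass(X[linker_idx], masses[linker_idx])
        u = center_of_mass(X[d1_idx], masses[d1_idx]) - v
        w = center_of_mass(X[d3_idx], masses[d3_idx]) - v
        theta_cur = angle_between(u, w)
        theta_tgt = math.radians(spec.hinge_angle_mean)
        axis = _hinge_correction_axis(u, w)
        delta = theta_tgt - theta_cur
        Rh = rotation_about_axis(axis, delta)
        if not math.isclose(angle_between(u, Rh @ w), theta_tgt, abs_tol=1e-9):
            Rh = rotation_about_axis(axis, -delta)
        X[d3_idx] = (X[d3_idx] - v) @ Rh.T + v
        # --- twist about the linker-COM -> D3-COM axis --------------------
        if spec.d3_twist_mean != 0.0:
            w_new = center_of_mass(X[d3_idx], masses[d3_idx]) - v
            Rt = rotation_about_axis(w_new, math.radians(spec.d3_twist_mean))
            X[d3_idx] = (X[d3_idx] - v) @ Rt.T + v
        # --- clash accounting (CA-CA between D3 and D1/D2) ----------------
        dmin = np.min(np.linalg.norm(
            X[ca_d3_idx][:, None] - X[ca_fix_idx][None, :], axis=-1))
        if dmin < 1.5:
            clash_count += 1
        frames[f] = X
        truth_rows.append((f, spec.name, spec.hinge_angle_mean, spec.d3_twist_mean))
        for res in range(linker_lo, linker_hi + 1):
            dihedral_rows.append((f, res, sampled[res][0], sampled[res][1]))

    if clash_count:
        warnings.warn(f"{clash_count} frames show D3/D1-D2 CA overlap < 1.5 A")

    # realised per-atom fluctuation before noise, plus the isotropic noise
    mean0 = frames.mean(axis=0)
    var_state = np.mean(np.sum((frames - mean0) ** 2, axis=2), axis=0)
    rmsf_true = np.sqrt(var_state + 3.0 * noise_sigma ** 2)

    if noise_sigma > 0:
        frames = frames + rng.normal(0.0, noise_sigma, size=frames.shape)

    topo_out = replace(topology)
    topo_out.bfactor = rmsf_to_bfactor(rmsf_true)
    traj = Trajectory(topology=topo_out, frames=frames,
                      time_stride=time_stride, label=label)
    truth = GroundTruth(
        states=pd.DataFrame(truth_rows,
                            columns=["frame", "state", "hinge_deg", "twist_deg"]),
        dihedrals=pd.DataFrame(dihedral_rows,
                               columns=["frame", "residue", "phi", "psi"]),
        rmsf_per_atom=rmsf_true,
        state_specs=states,
        clash_count=clash_count,
    )
    return traj, truth


def _indices(topology: Structure, domain_map: DomainMap, name: str) -> np.ndarray:
    from ectodyn.io import select_atoms
    return select_atoms(topology, ranges=domain_map[name])


def _infer_domain_map(topology: Structure) -> DomainMap:
    """Recover the default toy DomainMap from a toy-receptor topology."""
    res = np.unique(topology.res_id)
    names = {int(r): str(n) for r, n in zip(topology.res_id, topology.res_name)}
    # linker = the LEU-GLU-GLU-ASN-LYS-PRO run
    for start in res:
        if all(names.get(int(start) + k) == _LINKER_RES_NAMES[k] for k in range(6)):
            chain = str(topology.chain_id[0])
            d1_end = (int(start) - 1) // 2
            return DomainMap({
                "D1": (ResidueRange(chain, int(res.min()), d1_end),),
                "D2": (ResidueRange(chain, d1_end + 1, int(start) - 1),),
                "linker": (ResidueRange(chain, int(start), int(start) + 5),),
                "D3": (ResidueRange(chain, int(start) + 6, int(res.max())),),
            })
    raise ValueError("cannot infer domain map: linker signature not found; "
                     "pass domain_map explicitly")
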