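"""Solvent-accessible surface area and geometric hydrogen-bond counting.

SASA uses the Shrake-Rupley rolling-probe point lattice with a deterministic
golden-spiral sphere sampling (no RNG), so results are bit-reproducible for
identical inputs.  Van der Waals radii are the Bondi set, keyed by element.

Hydrogen bonds are counted geometrically.  With explicit hydrogens the
criterion is donor-acceptor distance plus the H-D-A angle; for hydrogen-free
inputs (crystal structures, coarse models) a heavy-atom-only mode counts
N/O...N/O contacts by distance alone, with a minimum-distance floor so that
covalent peptide-geometry contacts are not miscounted as hydrogen bonds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ectodyn.io import Structure

__all__ = [
    "BONDI_RADII",
    "SasaResult",
    "HBondCriteria",
    "golden_spiral_points",
    "sasa",
    "count_hbonds",
]

#: Bondi van der Waals radii (Angstrom), element-keyed.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "D": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "SE": 1.90,
    "BR": 1.85,
    "I": 1.98,
}


@dataclass
class SasaResult:
    """Shrake-Rupley result; areas in Angstrom^2 (``total_nm2`` converts)."""

    total: float
    per_atom: np.ndarray
    probe_radius: float
    n_sphere_points: int

    @property
    def total_nm2(self) -> float:
        return self.total / 100.0

    def per_residue(self, structure: Structure) -> pd.DataFrame:
        df = pd.DataFrame({
            "chain": structure.chain_id,
            "residue": structure.res_id,
            "res_name": structure.res_name,
            "sasa_A2": self.per_atom,
        })
        return (df.groupby(["chain", "residue", "res_name"], sort=True)
                  .agg(sasa_A2=("sasa_A2", "sum")).reset_index())


@dataclass
class HBondCriteria:
    """Geometric hydrogen-bond criteria.

    ``mode`` is ``"hydrogen-explicit"`` (D-A distance + H-D-A angle) or
    ``"heavy-atom-only"`` (N/O donor-acceptor pairs by distance alone).
    ``donor_acceptor_min`` excludes covalent-geometry contacts.
    """

    donor_acceptor_max: float = 3.5  # Angstrom
    angle_max: float = 30.0  # degrees, H-D-A
    mode: str = "heavy-atom-only"
    donor_acceptor_min: float = 2.4  # Angstrom

    def __post_init__(self) -> None:
        if not (0 < self.donor_acceptor_min < self.donor_acceptor_max):
            raise ValueError("need 0 < donor_acceptor_min < donor_acceptor_max")
        if not (0 < self.angle_max < 180):
            raise ValueError("angle_max must be in (0, 180)")
        if self.mode not in ("hydrogen-explicit", "heavy-atom-only"):
            raise ValueError(f"unknown mode {self.mode!r}")


def golden_spiral_points(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (golden-spiral lattice).

    Deterministic with a fixed ordering: index k gets latitude
    z = 1 - (2k+1)/n and longitude k * golden angle.
    """
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(structure: Structure | np.ndarray,
         elements: Iterable[str] | None = None,
         radii_set: dict[str, float] | None = None,
         probe_radius: float = 1.4,
         n_sphere_points: int = 960) -> SasaResult:
    """Shrake-Rupley solvent-accessible surface area.

    Accepts a :class:`Structure` (elements taken from it) or a raw (N, 3)
    coordinate array plus ``elements``.  Each atom's sphere of radius
    r_i + probe is sampled on the golden-spiral lattice; the accessible
    fraction of points not buried inside any neighbour's sphere scales
    4 pi (r_i + probe)^2.  Unknown elements raise, listing the offenders.
    """
    if isinstance(structure, Structure):
        coords = structure.coords
        elems = [str(e).upper() for e in structure.element]
    else:
        coords = np.asarray(structure, dtype=float)
        if elements is None:
            raise ValueError("elements required when passing raw coordinates")
        elems = [str(e).upper() for e in elements]
    radii_set = radii_set or BONDI_RADII
    unknown = sorted({e for e in elems if e not in radii_set})
    if unknown:
        raise ValueError(f"no van der Waals radius for elements: {unknown}")
    radii = np.array([radii_set[e] for e in elems])
    n = len(radii)
    ext = radii + probe_radius
    sphere = golden_spiral_points(n_sphere_points)
    tree = cKDTree(coords)
    max_ext = ext.max()
    per_atom = np.empty(n)
    area_unit = 4.0 * np.pi / n_sphere_points
    for i in range(n):
        pts = coords[i] + ext[i] * sphere
        neigh = tree.query_ball_point(coords[i], r=ext[i] + max_ext)
        neigh = [j for j in neigh if j != i]
        accessible = np.ones(n_sphere_points, dtype=bool)
        for j in neigh:
            d2 = np.sum((pts - coords[j]) ** 2, axis=1)
            accessible &= d2 > ext[j] ** 2
            if not accessible.any():
                break
        per_atom[i] = accessible.sum() * area_unit * ext[i] ** 2
    return SasaResult(total=float(per_atom.sum()), per_atom=per_atom,
                      probe_radius=probe_radius, n_sphere_points=n_sphere_points)


_DONOR_ELEMENTS = {"N", "O"}
_ACCEPTOR_ELEMENTS = {"N", "O"}


def _hydrogens_by_heavy(structure: Structure) -> dict[int, list[int]]:
    """Map heavy-atom index -> indices of hydrogens covalently attached.

    Attachment is inferred by distance (< 1.3 A), adequate for idealised or
    force-field geometries.
    """
    hyd = np.flatnonzero(np.isin(structure.element, ["H", "D"]))
    heavy = np.flatnonzero(~np.isin(structure.element, ["H", "D"]))
    out: dict[int, list[int]] = {}
    if hyd.size == 0:
        return out
    tree = cKDTree(structure.coords[heavy])
    d, j = tree.query(structure.coords[hyd], k=1)
    for h, dist, jj in zip(hyd, d, j):
        if dist < 1.3:
            out.setdefault(int(heavy[jj]), []).append(int(h))
    return out


def count_hbonds(structure: Structure,
                 criteria: HBondCriteria | None = None
                 ) -> tuple[int, pd.DataFrame]:
    """Count intramolecular hydrogen bonds; returns (count, pair table).

    Each (donor, acceptor) pair is counted once; pairs within the same
    residue are excluded.  The pair table is sorted deterministically by
    (donor chain, residue, atom, acceptor chain, residue, atom).
    """
    crit = criteria or HBondCriteria()
    el = np.char.upper(structure.element.astype(str))
    is_no = np.isin(el, sorted(_DONOR_ELEMENTS | _ACCEPTOR_ELEMENTS))
    cand = np.flatnonzero(is_no)
    if cand.size == 0:
        return 0, _empty_pairs()
    h_by_heavy = _hydrogens_by_heavy(structure)
    if crit.mode == "hydrogen-explicit" and not h_by_heavy:
        raise ValueError(
            "hydrogen-explicit mode requires explicit hydrogens; "
            "use mode='heavy-atom-only' for hydrogen-free structures"
        )
    coords = structure.coords
    tree = cKDTree(coords[cand])
    pairs = tree.query_pairs(r=crit.donor_acceptor_max, output_type="ndarray")
    rows = []
    reskey = list(zip(structure.chain_id.tolist(), structure.res_id.tolist(),
                      structure.ins_code.tolist()))
    for a, b in pairs:
        i, j = int(cand[a]), int(cand[b])
        if reskey[i] == reskey[j]:
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        if d < crit.donor_acceptor_min:
            continue
        if crit.mode == "heavy-atom-only":
            rows.append(_pair_row(structure, i, j, d, float("nan")))
        else:
            # directional: try i as donor then j as donor; count pair once
            matched = None
            for don, acc in ((i, j), (j, i)):
                best = None
                for h in h_by_heavy.get(don, []):
                    hv = coords[h] - coords[don]
                    av = coords[acc] - coords[don]
                    cosang = np.dot(hv, av) / (np.linalg.norm(hv) * np.linalg.norm(av))
                    ang = float(np.degrees(np.arccos(np.clip(cosang, -1, 1))))
                    if ang <= crit.angle_max and (best is None or ang < best):
                        best = ang
                if best is not None:
                    matched = (don, acc, best)
                    break
            if matched:
                rows.append(_pair_row(structure, matched[0], matched[1], d, matched[2]))
    df = pd.DataFrame(rows, columns=_PAIR_COLUMNS)
    df = df.sort_values(list(_PAIR_COLUMNS[:6])).reset_index(drop=True)
    return len(df), df


_PAIR_COLUMNS = ("donor_chain", "donor_residue", "donor_atom",
                 "acceptor_chain", "acceptor_residue", "acceptor_atom",
                 "distance_A", "angle_deg")


def _pair_row(s: Structure, i: int, j: int, d: float, ang: float):
    return (str(s.chain_id[i]), int(s.res_id[i]), str(s.name[i]).strip(),
            str(s.chain_id[j]), int(s.res_id[j]), str(s.name[j]).strip(),
            d, ang)


def _empty_pairs() -> pd.DataFrame:
    return pd.DataFrame(columns=list(_PAIR_COLUMNS))
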