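"""Structure and trajectory I/O and the shared data model.

Structures are read from fixed-column PDB files (the only canonical input
format); conformational trajectories are multi-model PDB files whose MODEL
blocks share one topology.  Parsing and serialisation are delegated to
:mod:`biotite.structure.io.pdb`; this module wraps the results in small
array-backed containers (:class:`Structure`, :class:`Trajectory`) that the
rest of the package computes on, and adds the residue-range bookkeeping
(:class:`DomainMap`) that drives every interdomain computation.

Units are Angstrom and picoseconds throughout the package; reporting layers
convert to nm / nm**2 where conventional.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import biotite.structure as bts
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "ResidueRange",
    "DomainMap",
    "ATOMIC_MASSES",
    "read_pdb",
    "read_trajectory",
    "select_atoms",
    "write_pdb",
]

#: Standard atomic masses (Da) keyed by upper-case element symbol.  Unknown
#: elements raise rather than receive a guessed mass.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "D": 2.014,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "NA": 22.990,
    "MG": 24.305,
    "P": 30.974,
    "S": 32.06,
    "CL": 35.45,
    "K": 39.098,
    "CA": 40.078,
    "MN": 54.938,
    "FE": 55.845,
    "CO": 58.933,
    "NI": 58.693,
    "CU": 63.546,
    "ZN": 65.38,
    "SE": 78.971,
    "BR": 79.904,
    "I": 126.904,
}


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted."""


def element_mass(element: str) -> float:
    """Return the atomic mass (Da) for an element symbol.

    Raises :class:`KeyError`-derived :class:`PDBParseError` for unknown
    elements instead of guessing.
    """
    try:
        return ATOMIC_MASSES[element.strip().upper()]
    except KeyError:
        raise PDBParseError(
            f"no mass tabulated for element {element!r}; extend ATOMIC_MASSES "
            "or fix the element column"
        ) from None


@dataclass(frozen=True)
class Atom:
    """A single atom record (a read-only view row of a :class:`Structure`)."""

    serial: int
    name: str
    element: str
    residue_number: int
    residue_name: str
    chain_id: str
    coords: np.ndarray  # (3,) Angstrom
    bfactor: float  # Angstrom^2
    occupancy: float
    mass: float  # Da


@dataclass
class Structure:
    """A static set of atoms with coordinates and residue/chain metadata.

    All per-atom fields are parallel numpy arrays of length ``n_atoms``.
    Coordinates are Angstrom, B-factors Angstrom^2, masses Da.
    """

    identifier: str
    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    ins_code: np.ndarray
    coords: np.ndarray
    bfactor: np.ndarray
    occupancy: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.serial)
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        for attr in ("bfactor", "occupancy", "mass"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.mass <= 0):
            raise ValueError("non-positive atomic mass")
        if np.any(self.bfactor < 0):
            raise ValueError("negative B-factor")
        keys = list(
            zip(self.chain_id.tolist(), self.res_id.tolist(),
                self.ins_code.tolist(), self.name.tolist())
        )
        if len(set(keys)) != n:
            dup = sorted({k for k in keys if keys.count(k) > 1})[:5]
            raise ValueError(f"duplicate atom identifiers (after altloc resolution): {dup}")

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    def __len__(self) -> int:
        return self.n_atoms

    def __getitem__(self, i: int) -> Atom:
        return Atom(
            serial=int(self.serial[i]),
            name=str(self.name[i]),
            element=str(self.element[i]),
            residue_number=int(self.res_id[i]),
            residue_name=str(self.res_name[i]),
            chain_id=str(self.chain_id[i]),
            coords=self.coords[i].copy(),
            bfactor=float(self.bfactor[i]),
            occupancy=float(self.occupancy[i]),
            mass=float(self.mass[i]),
        )

    def subset(self, indices: np.ndarray, identifier: str | None = None) -> "Structure":
        """Return a new Structure restricted to ``indices`` (order kept)."""
        indices = np.asarray(indices, dtype=int)
        return Structure(
            identifier=identifier or self.identifier,
            serial=self.serial[indices],
            name=self.name[indices],
            element=self.element[indices],
            res_id=self.res_id[indices],
            res_name=self.res_name[indices],
            chain_id=self.chain_id[indices],
            ins_code=self.ins_code[indices],
            coords=self.coords[indices],
            bfactor=self.bfactor[indices],
            occupancy=self.occupancy[indices],
            mass=self.mass[indices],
        )

    def with_coords(self, coords: np.ndarray, identifier: str | None = None) -> "Structure":
        s = dataclasses.replace(self, coords=np.asarray(coords, dtype=float))
        if identifier is not None:
            s.identifier = identifier
        return s

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Ordered unique (chain_id, res_id, ins_code) keys."""
        seen: dict[tuple[str, int, str], None] = {}
        for c, r, i in zip(self.chain_id, self.res_id, self.ins_code):
            seen.setdefault((str(c), int(r), str(i)), None)
        return list(seen)

    @classmethod
    def from_atom_array(cls, arr: bts.AtomArray, identifier: str = "") -> "Structure":
        n = arr.array_length()
        element = np.array([e.upper() for e in arr.element])
        mass = np.array([element_mass(e) for e in element])
        bfac = (arr.b_factor if "b_factor" in arr.get_annotation_categories()
                else np.zeros(n))
        occ = (arr.occupancy if "occupancy" in arr.get_annotation_categories()
               else np.ones(n))
        serial = (arr.atom_id if "atom_id" in arr.get_annotation_categories()
                  else np.arange(1, n + 1))
        ins = (arr.ins_code if "ins_code" in arr.get_annotation_categories()
               else np.array([""] * n))
        return cls(
            identifier=identifier,
            serial=np.asarray(serial, dtype=int),
            name=np.asarray(arr.atom_name),
            element=element,
            res_id=np.asarray(arr.res_id, dtype=int),
            res_name=np.asarray(arr.res_name),
            chain_id=np.asarray(arr.chain_id),
            ins_code=np.asarray(ins),
            coords=np.asarray(arr.coord, dtype=float),
            bfactor=np.clip(np.asarray(bfac, dtype=float), 0.0, None),
            occupancy=np.asarray(occ, dtype=float),
            mass=mass,
        )

    def to_atom_array(self) -> bts.AtomArray:
        n = self.n_atoms
        arr = bts.AtomArray(n)
        arr.coord = np.asarray(self.coords, dtype=np.float32)
        arr.chain_id = self.chain_id.astype("U4")
        arr.res_id = self.res_id.astype(int)
        arr.ins_code = self.ins_code.astype("U1")
        arr.res_name = self.res_name.astype("U5")
        arr.atom_name = self.name.astype("U6")
        arr.element = self.element.astype("U2")
        arr.hetero = np.zeros(n, dtype=bool)
        arr.set_annotation("b_factor", self.bfactor.astype(float))
        arr.set_annotation("occupancy", self.occupancy.astype(float))
        arr.set_annotation("atom_id", self.serial.astype(int))
        return arr


@dataclass
class Trajectory:
    """An ordered sequence of coordinate frames sharing one topology.

    ``frames`` has shape (n_frames, n_atoms, 3), Angstrom; ``time_stride``
    is the frame spacing in ps.
    """

    topology: Structure
    frames: np.ndarray
    time_stride: float = 60.0
    label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} does not match "
                f"topology ({self.topology.n_atoms})"
            )
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory needs at least one frame")
        if self.time_stride <= 0:
            raise ValueError("time_stride must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in ps (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.time_stride

    def frame(self, i: int) -> Structure:
        """Frame ``i`` as a Structure."""
        return self.topology.with_coords(self.frames[i])


@dataclass(frozen=True)
class ResidueRange:
    """A closed residue-number interval on one chain."""

    chain_id: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.stop < self.start:
            raise ValueError(f"empty interval {self.start}..{self.stop}")

    def __contains__(self, key: tuple[str, int]) -> bool:
        chain, res = key
        return chain == self.chain_id and self.start <= res <= self.stop


@dataclass
class DomainMap:
    """Named residue-range sets (e.g. D1, D2, D3, linker).

    Disjointness between named sets is enforced at construction; all
    interdomain computations take their selections from here.
    """

    domains: dict[str, tuple[ResidueRange, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        expanded: dict[str, set[tuple[str, int]]] = {}
        for name, ranges in self.domains.items():
            if not ranges:
                raise ValueError(f"domain {name!r} has no residue ranges")
            s: set[tuple[str, int]] = set()
            for r in ranges:
                s.update((r.chain_id, i) for i in range(r.start, r.stop + 1))
            expanded[name] = s
        names = list(expanded)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                overlap = expanded[a] & expanded[b]
                if overlap:
                    raise ValueError(
                        f"domains {a!r} and {b!r} overlap on residues "
                        f"{sorted(overlap)[:5]}"
                    )
        self._expanded = expanded

    def __getitem__(self, name: str) -> tuple[ResidueRange, ...]:
        return self.domains[name]

    def __contains__(self, name: str) -> bool:
        return name in self.domains

    def names(self) -> list[str]:
        return list(self.domains)

    def residues(self, name: str) -> set[tuple[str, int]]:
        """All (chain_id, residue_number) pairs of a named set."""
        return set(self._expanded[name])

    @classmethod
    def from_dict(cls, spec: Mapping[str, object]) -> "DomainMap":
        """Build from a config mapping.

        Accepted per-domain forms::

            {"D1": "A:1-100", "linker": ["A:201-206"],
             "D3": {"chain": "A", "start": 207, "stop": 319}}
        """
        domains: dict[str, tuple[ResidueRange, ...]] = {}
        for name, val in spec.items():
            if isinstance(val, str):
                val = [val]
            if isinstance(val, Mapping):
                ranges = [ResidueRange(str(val.get("chain", "A")),
                                       int(val["start"]), int(val["stop"]))]
            else:
                ranges = []
                for item in val:  # type: ignore[union-attr]
                    if isinstance(item, Mapping):
                        ranges.append(ResidueRange(str(item.get("chain", "A")),
                                                   int(item["start"]), int(item["stop"])))
                    else:
                        chain, _, span = str(item).partition(":")
                        if not span:
                            chain, span = "A", chain
                        lo, _, hi = span.partition("-")
                        ranges.append(ResidueRange(chain, int(lo), int(hi or lo)))
            domains[name] = tuple(ranges)
        return cls(domains)

    def to_dict(self) -> dict[str, list[str]]:
        return {
            name: [f"{r.chain_id}:{r.start}-{r.stop}" for r in ranges]
            for name, ranges in self.domains.items()
        }

    def validate_against(self, topology: Structure) -> None:
        """Raise if any declared residue is absent from the topology."""
        present = {(str(c), int(r)) for c, r in zip(topology.chain_id, topology.res_id)}
        for name in self.domains:
            missing = sorted(self.residues(name) - present)
            if missing:
                raise ValueError(
                    f"domain {name!r}: residues missing from topology: {missing[:10]}"
                    + (" ..." if len(missing) > 10 else "")
                )


# ---------------------------------------------------------------------------
# Reading


def _read_pdbfile(path: str | Path) -> PDBFile:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return PDBFile.read(str(path))
    except Exception as exc:  # pragma: no cover - biotite error text varies
        raise PDBParseError(f"cannot parse PDB file {path}: {exc}") from exc


_EXTRA_FIELDS = ["b_factor", "occupancy", "atom_id"]


def _clean(arr: bts.AtomArray, chain_filter: Iterable[str] | None,
           keep_hetero: bool) -> bts.AtomArray:
    mask = np.ones(arr.array_length(), dtype=bool)
    if not keep_hetero:
        # drop waters and hetero groups; keep standard polymer records
        mask &= ~arr.hetero
        mask &= arr.res_name != "HOH"
    if chain_filter is not None:
        wanted = {str(c) for c in chain_filter}
        mask &= np.isin(arr.chain_id, sorted(wanted))
    return arr[mask]


def read_pdb(path: str | Path, chain_filter: Iterable[str] | None = None,
             keep_hetero: bool = False, model: int = 1) -> Structure:
    """Read one model of a PDB file into a :class:`Structure`.

    Waters and hetero groups are excluded by default.  Alternate locations
    are resolved to the highest-occupancy conformer (ties broken by altloc
    letter order).  Masses are assigned from the element column.
    """
    pdb = _read_pdbfile(path)
    try:
        arr = pdb.get_structure(model=model, altloc="occupancy",
                                extra_fields=_EXTRA_FIELDS)
    except Exception as exc:
        raise PDBParseError(f"cannot interpret ATOM records of {path}: {exc}") from exc
    arr = _clean(arr, chain_filter, keep_hetero)
    if arr.array_length() == 0:
        raise PDBParseError(
            f"no atoms left after filtering {path} "
            f"(chain_filter={list(chain_filter) if chain_filter else None})"
        )
    return Structure.from_atom_array(arr, identifier=Path(path).stem)


def read_trajectory(path: str | Path, topology: Structure | None = None,
                    chain_filter: Iterable[str] | None = None,
                    time_stride: float = 60.0, label: str = "") -> Trajectory:
    """Read a multi-model PDB file as a :class:`Trajectory`.

    Frames are ordered by MODEL number; the topology is taken from the first
    model unless supplied.  Inconsistent atom counts between models raise an
    error naming the offending model.
    """
    pdb = _read_pdbfile(path)
    n_models = pdb.get_model_count()
    try:
        stack = pdb.get_structure(model=None, altloc="occupancy",
                                  extra_fields=_EXTRA_FIELDS)
    except Exception:
        # diagnose which model breaks the shared-topology contract
        counts = [pdb.get_structure(model=m + 1).array_length()
                  for m in range(n_models)]
        bad = [m + 1 for m, c in enumerate(counts) if c != counts[0]]
        raise PDBParseError(
            f"models {bad} of {path} have atom counts inconsistent with "
            f"model 1 ({counts[0]} atoms)"
        ) from None
    first = _clean(stack[0], chain_filter, keep_hetero=False)
    if first.array_length() == 0:
        raise PDBParseError(f"no atoms left after filtering {path}")
    mask = np.ones(stack.array_length(), dtype=bool)
    mask &= ~stack.hetero
    mask &= stack.res_name != "HOH"
    if chain_filter is not None:
        mask &= np.isin(stack.chain_id, sorted({str(c) for c in chain_filter}))
    stack = stack[:, mask]
    topo = topology if topology is not None else Structure.from_atom_array(
        stack[0], identifier=Path(path).stem)
    if topo.n_atoms != stack.array_length():
        raise PDBParseError(
            f"supplied topology has {topo.n_atoms} atoms but file frames "
            f"have {stack.array_length()}"
        )
    return Trajectory(topology=topo, frames=np.asarray(stack.coord, dtype=float),
                      time_stride=time_stride, label=label or Path(path).stem)


# ---------------------------------------------------------------------------
# Selection


def select_atoms(obj: Structure | Trajectory,
                 ranges: Sequence[ResidueRange] | None = None,
                 atom_names: Iterable[str] | None = None) -> np.ndarray:
    """Resolve a residue-range / atom-name selection to topology indices.

    Indices are strictly increasing and, for trajectories, valid for every
    frame (frames share one topology).  An unresolvable residue interval
    raises, listing the missing residues.
    """
    topo = obj.topology if isinstance(obj, Trajectory) else obj
    mask = np.ones(topo.n_atoms, dtype=bool)
    if ranges is not None:
        ranges = list(ranges)
        rmask = np.zeros(topo.n_atoms, dtype=bool)
        present = set(zip(topo.chain_id.tolist(), topo.res_id.tolist()))
        missing: list[tuple[str, int]] = []
        for r in ranges:
            for res in range(r.start, r.stop + 1):
                if (r.chain_id, res) not in present:
                    missing.append((r.chain_id, res))
            rmask |= (topo.chain_id == r.chain_id) & \
                     (topo.res_id >= r.start) & (topo.res_id <= r.stop)
        if missing:
            raise ValueError(f"selection residues missing from topology: {missing[:10]}"
                             + (" ..." if len(missing) > 10 else ""))
        mask &= rmask
    if atom_names is not None:
        names = sorted({n.strip() for n in atom_names})
        mask &= np.isin(np.char.strip(topo.name.astype(str)), names)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("selection resolves to no atoms")
    return idx


def select_domain(obj: Structure | Trajectory, domain_map: DomainMap,
                  name: str, atom_names: Iterable[str] | None = None) -> np.ndarray:
    """Convenience: resolve a named :class:`DomainMap` entry."""
    return select_atoms(obj, ranges=domain_map[name], atom_names=atom_names)


# ---------------------------------------------------------------------------
# Writing

_PDB_COORD_LIMIT = 9999.999  # %8.3f field width


def write_pdb(obj: Structure | Trajectory, path: str | Path) -> Path:
    """Write a Structure or Trajectory (MODEL/ENDMDL blocks) as PDB.

    Coordinates outside the fixed-column field width raise instead of being
    silently truncated.  The B-factor column is populated from the topology;
    values above the 999.99 field ceiling are clamped to it (the in-memory
    Structure keeps the exact value).
    """
    path = Path(path)
    if isinstance(obj, Trajectory):
        coords = obj.frames
        topo = obj.topology
    else:
        coords = obj.coords[None]
        topo = obj
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates cannot be written")
    if np.any(np.abs(coords) > _PDB_COORD_LIMIT):
        raise ValueError(
            f"coordinate magnitude exceeds PDB field width ({_PDB_COORD_LIMIT} A)"
        )
    arr = topo.to_atom_array()
    arr.set_annotation("b_factor", np.minimum(arr.b_factor, 999.99))
    pdb = PDBFile()
    if coords.shape[0] == 1:
        arr.coord = coords[0].astype(np.float32)
        pdb.set_structure(arr)
    else:
        stack = bts.stack([arr] * coords.shape[0])
        stack.coord = coords.astype(np.float32)
        pdb.set_structure(stack)
    pdb.write(str(path))
    return path
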