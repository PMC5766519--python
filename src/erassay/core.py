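"""Core data model: topology, trajectory, atom selection and LBD region scheme.

The estrogen receptor alpha ligand-binding domain (ERα LBD) is analysed here
as a homodimer (chains A and B), with author residue numbering 303-552 per
monomer.  That numbering is the only residue coordinate system exposed by any
API in this package, because every mechanistic signature of interest
(E380, H377, D351, K529, residue 537 ...) is conventionally quoted in it.

Topologies are read from PDB files (via biotite); trajectories from
multi-model PDB or CHARMM/NAMD-dialect DCD files (via MDAnalysis' libdcd).
DCD carries no trustworthy time axis, so frame times are always synthesised
as ``frame_index * dt_ns`` from a caller-supplied time step.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Topology",
    "Trajectory",
    "RegionScheme",
    "Selection",
    "EmptySelectionError",
    "PDBParseError",
    "default_region_scheme",
    "load_topology",
    "load_trajectory",
    "write_topology_pdb",
    "write_trajectory_pdb",
    "write_trajectory_dcd",
    "split_monomers",
    "CA",
]


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be interpreted as a topology/trajectory."""


class EmptySelectionError(ValueError):
    """Raised when a selection resolves to no atoms (never silently empty)."""


# --------------------------------------------------------------------------
# Topology
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Topology:
    """Atom metadata table for one structure.

    All annotation arrays have length ``n_atoms`` and share one ordering,
    which is the file / constructor ordering and is preserved by every view.
    """

    atom_name: np.ndarray      # str array, e.g. "CA", "OE1"
    element: np.ndarray        # str array, e.g. "C", "O"
    residue_number: np.ndarray  # int array, author numbering
    residue_name: np.ndarray   # str array, e.g. "GLU"
    chain_id: np.ndarray       # str array, e.g. "A"

    def __post_init__(self):
        n = len(self.atom_name)
        for name in ("element", "residue_number", "residue_name", "chain_id"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"annotation '{name}' length != n_atoms")
        if n and any(not str(a) for a in self.atom_name):
            raise ValueError("every atom must have a nonempty name")
        # residue numbers non-decreasing within each chain
        for ch in self.chains:
            rn = self.residue_number[self.chain_id == ch]
            if np.any(np.diff(rn) < 0):
                raise ValueError(f"residue numbers decrease within chain {ch}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    @property
    def chains(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c))
        return tuple(seen)

    def residues(self, chain: str | None = None) -> np.ndarray:
        """Unique residue numbers (in order of first appearance)."""
        mask = np.ones(self.n_atoms, bool) if chain is None else self.chain_id == chain
        _, idx = np.unique(self.residue_number[mask], return_index=True)
        return self.residue_number[mask][np.sort(idx)]

    def subset(self, indices: np.ndarray) -> "Topology":
        return Topology(
            atom_name=self.atom_name[indices],
            element=self.element[indices],
            residue_number=self.residue_number[indices],
            residue_name=self.residue_name[indices],
            chain_id=self.chain_id[indices],
        )


# --------------------------------------------------------------------------
# Trajectory
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """Coordinate frames (Å) with per-frame times (ns)."""

    coordinates: np.ndarray  # (n_frames, n_atoms, 3) float64, Å
    frame_times: np.ndarray  # (n_frames,) ns, strictly increasing

    def __post_init__(self):
        c = np.asarray(self.coordinates, float)
        t = np.asarray(self.frame_times, float)
        object.__setattr__(self, "coordinates", c)
        object.__setattr__(self, "frame_times", t)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if len(t) != c.shape[0]:
            raise ValueError("frame_times length must equal n_frames")
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("frame_times must be strictly increasing")
        if not np.all(np.isfinite(c)):
            raise ValueError("coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def atom_subset(self, indices: np.ndarray) -> "Trajectory":
        return Trajectory(self.coordinates[:, indices, :], self.frame_times)

    def frame_subset(self, frames: np.ndarray | slice) -> "Trajectory":
        return Trajectory(self.coordinates[frames], self.frame_times[frames])


# --------------------------------------------------------------------------
# Region scheme
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionScheme:
    """Ordered partition of a monomer's residue range into named regions."""

    regions: Mapping[str, tuple[int, int]]  # name -> (first, last), inclusive
    chains: tuple[str, ...] = ("A", "B")

    def range(self, name: str) -> tuple[int, int]:
        try:
            return self.regions[name]
        except KeyError:
            raise KeyError(
                f"unknown region {name!r}; known: {', '.join(self.regions)}"
            ) from None

    def residues(self, name: str) -> range:
        first, last = self.range(name)
        return range(first, last + 1)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.regions)

    def region_of(self, residue: int) -> str | None:
        for name, (lo, hi) in self.regions.items():
            if lo <= residue <= hi:
                return name
        return None


#: Secondary-structure regions of the ERα LBD monomer, author numbering.
#: H12 (532-552) is the mobile activation helix; H3 and H5 form the groove it
#: docks into in the antagonist conformation.
_DEFAULT_REGIONS: dict[str, tuple[int, int]] = {
    "H1": (303, 311),
    "H2": (312, 322),
    "C2-3": (323, 338),
    "H3": (339, 363),
    "H4": (364, 371),
    "H5": (372, 382),
    "H6": (383, 396),
    "S1S2": (397, 411),
    "H7": (412, 419),
    "H8": (420, 439),
    "H9": (440, 463),
    "H10": (464, 494),
    "H11": (495, 531),
    "H12": (532, 552),
}


def default_region_scheme() -> RegionScheme:
    """The 14-region LBD scheme (H1 ... H12, loops included in helix labels)."""
    return RegionScheme(regions=dict(_DEFAULT_REGIONS))


# --------------------------------------------------------------------------
# Selection
# --------------------------------------------------------------------------

def _normalise_residues(residues) -> frozenset[int] | None:
    if residues is None:
        return None
    out: set[int] = set()
    for item in residues:
        if isinstance(item, (tuple, list)):
            lo, hi = item
            out.update(range(int(lo), int(hi) + 1))
        else:
            out.add(int(item))
    return frozenset(out)


@dataclass(frozen=True)
class Selection:
    """Atom predicate over (chain set, residue set/ranges, atom-name set).

    ``None`` for a field means "no constraint".  ``resolve`` returns indices
    in topology order, so the same inputs always yield the same ordered list.
    """

    chains: frozenset[str] | None = None
    residues: frozenset[int] | None = None
    names: frozenset[str] | None = None

    @classmethod
    def of(cls, chains=None, residues=None, names=None) -> "Selection":
        return cls(
            chains=None if chains is None else frozenset(str(c) for c in chains),
            residues=_normalise_residues(residues),
            names=None if names is None else frozenset(str(n) for n in names),
        )

    def resolve(self, top: Topology) -> np.ndarray:
        mask = np.ones(top.n_atoms, bool)
        if self.chains is not None:
            mask &= np.isin(top.chain_id, sorted(self.chains))
        if self.residues is not None:
            mask &= np.isin(top.residue_number, sorted(self.residues))
        if self.names is not None:
            mask &= np.isin(top.atom_name, sorted(self.names))
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise EmptySelectionError(f"selection resolves to no atoms: {self}")
        return idx


#: Cα atoms of all chains — the atom set for residue-level analyses.
CA = Selection.of(names=["CA"])


# --------------------------------------------------------------------------
# PDB / DCD I/O (biotite + MDAnalysis libdcd behind the data model)
# --------------------------------------------------------------------------

def _to_atom_array(top: Topology, coords: np.ndarray):
    import biotite.structure as struc

    arr = struc.AtomArray(top.n_atoms)
    arr.coord = np.asarray(coords, float)
    arr.chain_id = top.chain_id.astype("U4")
    arr.res_id = top.residue_number.astype(int)
    arr.res_name = top.residue_name.astype("U5")
    arr.atom_name = top.atom_name.astype("U6")
    arr.element = top.element.astype("U2")
    return arr


def _check_duplicates(top: Topology) -> None:
    seen: set[tuple[str, int, str]] = set()
    for ch, rn, an in zip(top.chain_id, top.residue_number, top.atom_name):
        key = (str(ch), int(rn), str(an))
        if key in seen:
            raise PDBParseError(
                f"duplicate atom {an!r} within residue {ch}:{rn}"
            )
        seen.add(key)


def load_topology(path: str | os.PathLike) -> tuple[Topology, np.ndarray]:
    """Read a PDB file into a Topology plus the coordinates of its first model.

    Author residue numbers and chain IDs are preserved exactly as written.
    """
    from biotite.structure.io.pdb import PDBFile

    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        pdb = PDBFile.read(str(path))
        if pdb.get_model_count() == 0:
            raise PDBParseError(f"no atoms in {path}")
        arr = pdb.get_structure(model=1)
    except PDBParseError:
        raise
    except Exception as exc:  # surface biotite's record/line diagnostics
        raise PDBParseError(f"malformed PDB {path}: {exc}") from exc
    if arr.array_length() == 0:
        raise PDBParseError(f"no atoms in {path}")
    top = Topology(
        atom_name=np.asarray(arr.atom_name, dtype="U6"),
        element=np.asarray(arr.element, dtype="U2"),
        residue_number=np.asarray(arr.res_id, dtype=int),
        residue_name=np.asarray(arr.res_name, dtype="U5"),
        chain_id=np.asarray(arr.chain_id, dtype="U4"),
    )
    _check_duplicates(top)
    return top, np.asarray(arr.coord, float)


def load_trajectory(
    path: str | os.PathLike, top: Topology, dt_ns: float
) -> Trajectory:
    """Read a multi-model PDB or DCD trajectory against a known topology.

    Frame times are synthesised as ``frame_index * dt_ns`` (DCD headers carry
    no trusted time metadata; multi-model PDB carries none at all).
    """
    path = str(path)
    if path.lower().endswith(".dcd"):
        coords = _read_dcd(path)
    else:
        coords = _read_multimodel_pdb(path)
    if coords.shape[0] == 0:
        raise PDBParseError(f"zero frames in {path}")
    if coords.shape[1] != top.n_atoms:
        raise ValueError(
            f"atom-count mismatch in {path}: topology expects {top.n_atoms}, "
            f"trajectory has {coords.shape[1]}"
        )
    times = np.arange(coords.shape[0], dtype=float) * float(dt_ns)
    return Trajectory(coordinates=coords, frame_times=times)


def _read_multimodel_pdb(path: str) -> np.ndarray:
    from biotite.structure.io.pdb import PDBFile

    try:
        pdb = PDBFile.read(path)
        if pdb.get_model_count() == 0:
            raise PDBParseError(f"no atoms in {path}")
        stack = pdb.get_structure()
    except PDBParseError:
        raise
    except Exception as exc:
        raise PDBParseError(f"malformed PDB {path}: {exc}") from exc
    coord = np.asarray(stack.coord, float)
    if coord.ndim == 2:  # single model
        coord = coord[None]
    return coord


def _read_dcd(path: str) -> np.ndarray:
    from MDAnalysis.lib.formats.libdcd import DCDFile

    frames = []
    with DCDFile(path) as f:
        for frame in f:
            frames.append(np.asarray(frame.xyz, float).copy())
    if not frames:
        raise PDBParseError(f"zero frames in {path}")
    return np.stack(frames)


def write_topology_pdb(top: Topology, coords: np.ndarray, path) -> None:
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(top, coords))
    pdb.write(str(path))


def write_trajectory_pdb(top: Topology, traj: Trajectory, path) -> None:
    """Write a multi-model PDB (MODEL/ENDMDL per frame)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    arrays = [_to_atom_array(top, traj.coordinates[i]) for i in range(traj.n_frames)]
    pdb = PDBFile()
    pdb.set_structure(struc.stack(arrays))
    pdb.write(str(path))


_DCD_REMARKS = "erassay synthetic trajectory"


def write_trajectory_dcd(traj: Trajectory, path) -> None:
    """Write a CHARMM-dialect float32 DCD.  Header content is fixed so that
    rewriting the same trajectory is byte-identical."""
    from MDAnalysis.lib.formats.libdcd import DCDFile

    with DCDFile(str(path), "w") as f:
        f.write_header(
            remarks=_DCD_REMARKS,
            natoms=traj.n_atoms,
            istart=0,
            nsavc=1,
            delta=1.0,
            is_periodic=0,
        )
        for i in range(traj.n_frames):
            f.write(np.ascontiguousarray(traj.coordinates[i], dtype=np.float32))


# --------------------------------------------------------------------------
# Monomer split
# --------------------------------------------------------------------------

def split_monomers(
    top: Topology, traj: Trajectory | None = None, chains: Iterable[str] | None = None
) -> dict[str, tuple[Topology, Trajectory | None]]:
    """Per-chain (Topology, Trajectory) views, atom order preserved.

    The two LBD monomers are analysed separately throughout (their
    correlation maps and interaction persistences genuinely differ), so this
    split is the entry point of every per-monomer stage.
    """
    available = top.chains
    if len(available) == 0:
        raise ValueError("topology has no chains")
    wanted = list(available) if chains is None else [str(c) for c in chains]
    out: dict[str, tuple[Topology, Trajectory | None]] = {}
    for ch in wanted:
        if ch not in available:
            raise KeyError(
                f"chain {ch!r} absent; available chains: {', '.join(available)}"
            )
        idx = np.flatnonzero(top.chain_id == ch)
        out[ch] = (
            top.subset(idx),
            None if traj is None else traj.atom_subset(idx),
        )
    return out
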