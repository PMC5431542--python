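"""Topology and trajectory I/O.

Reads a molecular topology from a PDB file and coordinate frames from a
multi-model PDB (or, optionally, a DCD file), producing the lightweight
in-memory containers the analysis kernels operate on.  Coordinates are
always in Å and times in ps.

PDB parsing and writing are delegated to :mod:`biotite`; DCD reading uses
mdtraj's raw reader (DCD stores Å natively, so no unit conversion is
applied).  Trajectories are assumed to be pre-imaged: no periodic-boundary
handling is performed anywhere in this package.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as struc
import biotite.structure.info as struc_info
import biotite.structure.io.pdb as pdbio

__all__ = [
    "Atom",
    "Topology",
    "FrameSeries",
    "AtomSelection",
    "TrajectoryFormatError",
    "UnknownElementError",
    "read_topology",
    "read_frames",
    "write_frames",
    "STANDARD_AMINO_ACIDS",
]


class TrajectoryFormatError(ValueError):
    """A structure/trajectory file violates the expected format."""


class UnknownElementError(ValueError):
    """An atom's element could not be resolved to a known mass."""


#: Three-letter codes treated as polymer residues when writing ATOM records
#: and when interpreting "backbone"/"sidechain" in selections.
STANDARD_AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR "
    "TRP TYR VAL SEC PYL".split()
)

_WATER_RESNAMES = frozenset({"HOH", "WAT", "TIP3", "TIP4", "SPC", "SOL"})
_BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class Atom:
    """One atom of a topology; masses are in amu."""

    name: str
    element: str
    mass: float
    res_name: str
    res_id: int
    chain_id: str


class Topology:
    """Static description of the molecular system: one entry per atom.

    Invariants enforced at construction: every mass is strictly positive
    and (chain_id, res_id, atom_name) triples are unique.
    """

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms = tuple(atoms)
        seen = set()
        for i, a in enumerate(self.atoms):
            if not a.mass > 0:
                raise ValueError(
                    f"atom {i} ({a.chain_id}/{a.res_id}/{a.name}) has "
                    f"non-positive mass {a.mass}"
                )
            key = (a.chain_id, a.res_id, a.name)
            if key in seen:
                raise ValueError(f"duplicate atom identifier {key}")
            seen.add(key)
        # Cached per-atom annotation arrays for vectorised selection.
        self.atom_names = np.array([a.name for a in self.atoms])
        self.elements = np.array([a.element for a in self.atoms])
        self.masses = np.array([a.mass for a in self.atoms])
        self.res_names = np.array([a.res_name for a in self.atoms])
        self.res_ids = np.array([a.res_id for a in self.atoms], dtype=int)
        self.chain_ids = np.array([a.chain_id for a in self.atoms])

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"Topology(n_atoms={self.n_atoms})"

    @property
    def is_water(self) -> np.ndarray:
        return np.isin(self.res_names, sorted(_WATER_RESNAMES))

    @property
    def is_backbone(self) -> np.ndarray:
        """Backbone = N/CA/C/O(+OXT) of polymer residues; water excluded."""
        return np.isin(self.atom_names, sorted(_BACKBONE_NAMES)) & ~self.is_water

    def has_hydrogens(self) -> bool:
        return bool(np.any(self.elements == "H"))


@dataclass
class FrameSeries:
    """Ordered coordinate snapshots with a uniform time step.

    ``coordinates`` has shape (n_frames, n_atoms, 3) in Å; ``dt`` is the
    time per frame in ps and ``t0`` the time of the first frame.
    """

    coordinates: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError(
                f"coordinates must have shape (n_frames, n_atoms, 3), "
                f"got {self.coordinates.shape}"
            )
        if not self.dt > 0:
            raise ValueError(f"dt must be positive, got {self.dt}")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times t0 + i*dt in ps."""
        return self.t0 + self.dt * np.arange(self.n_frames)

    def __getitem__(self, frame: int) -> np.ndarray:
        return self.coordinates[frame]


@dataclass(frozen=True)
class AtomSelection:
    """A resolved, ordered, duplicate-free set of atom indices."""

    label: str
    indices: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("selection indices must be one-dimensional")
        if len(np.unique(idx)) != len(idx):
            raise ValueError(f"selection '{self.label}' contains duplicate indices")
        object.__setattr__(self, "indices", idx)

    @property
    def is_empty(self) -> bool:
        """Empty selections are legal but flagged here."""
        return len(self.indices) == 0

    def __len__(self) -> int:
        return len(self.indices)

    def validate(self, topology: Topology) -> None:
        if self.is_empty:
            return
        if self.indices.min() < 0 or self.indices.max() >= topology.n_atoms:
            raise IndexError(
                f"selection '{self.label}' has indices outside "
                f"[0, {topology.n_atoms})"
            )


def _mass_of(element: str, label: str) -> float:
    mass = struc_info.mass(element)
    if mass is None or not mass > 0:
        raise UnknownElementError(
            f"unknown element '{element}' for atom {label}"
        )
    return float(mass)


def _topology_from_atom_array(array: struc.AtomArray) -> Topology:
    atoms = []
    for i in range(array.array_length()):
        element = str(array.element[i]).strip().capitalize()
        name = str(array.atom_name[i]).strip()
        label = f"{array.chain_id[i]}/{array.res_id[i]}/{name}"
        if not element:
            raise UnknownElementError(f"no element resolvable for atom {label}")
        atoms.append(
            Atom(
                name=name,
                element=element,
                mass=_mass_of(element, label),
                res_name=str(array.res_name[i]).strip(),
                res_id=int(array.res_id[i]),
                chain_id=str(array.chain_id[i]).strip() or " ",
            )
        )
    return Topology(atoms)


def _read_pdb(path: str | os.PathLike) -> pdbio.PDBFile:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pdbio.PDBFile.read(str(path))
    except Exception as exc:  # biotite raises various parse errors
        raise TrajectoryFormatError(f"cannot parse PDB file {path}: {exc}") from exc


def read_topology(path: str | os.PathLike) -> Topology:
    """Read a topology from the first MODEL of a PDB file.

    Elements come from the element column, with biotite's atom-name
    heuristic as fallback; masses are standard atomic weights.  Altloc
    handling keeps the highest-occupancy conformer (ties resolve to the
    first listed, conventionally "A").
    """
    pdb_file = _read_pdb(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # element-guess notice
        try:
            array = pdb_file.get_structure(model=1, altloc="occupancy")
        except Exception as exc:
            raise TrajectoryFormatError(
                f"no ATOM/HETATM records readable from {path}: {exc}"
            ) from exc
    if array.array_length() == 0:
        raise TrajectoryFormatError(f"{path} contains no ATOM/HETATM records")
    return _topology_from_atom_array(array)


def _pdb_model_atom_counts(path: Path) -> list[int]:
    """ATOM/HETATM record count per MODEL block, in file order."""
    counts: list[int] = []
    current = 0
    in_model = False
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec in ("ATOM  ", "HETATM"):
                current += 1
    if not counts:  # single implicit model
        counts.append(current)
    elif in_model:
        counts.append(current)
    return counts


def read_frames(
    path: str | os.PathLike,
    topology: Topology,
    dt: float,
    t0: float = 0.0,
) -> FrameSeries:
    """Read coordinate frames from a multi-model PDB or a DCD file.

    Every frame must contain exactly ``topology.n_atoms`` atoms; a
    mismatch raises an error naming the offending model (1-based, in
    file order).
    """
    path = Path(path)
    if path.suffix.lower() == ".dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path)) as fh:
            xyz, _, _ = fh.read()  # raw DCD coordinates are in Å
        coords = np.asarray(xyz, dtype=np.float64)
        if coords.shape[1] != topology.n_atoms:
            raise TrajectoryFormatError(
                f"DCD frames have {coords.shape[1]} atoms, topology has "
                f"{topology.n_atoms}"
            )
        return FrameSeries(coords, dt=dt, t0=t0)

    pdb_file = _read_pdb(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        try:
            stack = pdb_file.get_structure(altloc="occupancy")
        except Exception:
            # Unequal atom counts across models: locate and name the model.
            counts = _pdb_model_atom_counts(path)
            for model_index, count in enumerate(counts, start=1):
                if count != topology.n_atoms:
                    raise TrajectoryFormatError(
                        f"model {model_index} of {path} has {count} atoms, "
                        f"expected {topology.n_atoms}"
                    ) from None
            raise
    coords = np.asarray(stack.coord, dtype=np.float64)
    if coords.ndim == 2:  # single model
        coords = coords[None, :, :]
    if coords.shape[0] == 0 or coords.shape[1] == 0:
        raise TrajectoryFormatError(f"{path} contains no coordinate frames")
    counts = _pdb_model_atom_counts(path)
    for model_index, count in enumerate(counts, start=1):
        if count != topology.n_atoms:
            raise TrajectoryFormatError(
                f"model {model_index} of {path} has {count} atoms, "
                f"expected {topology.n_atoms}"
            )
    return FrameSeries(coords, dt=dt, t0=t0)


def _atom_array_stack(topology: Topology, frames: FrameSeries) -> struc.AtomArrayStack:
    n = topology.n_atoms
    stack = struc.AtomArrayStack(frames.n_frames, n)
    stack.coord[:] = frames.coordinates
    stack.chain_id = topology.chain_ids
    stack.res_id = topology.res_ids
    stack.res_name = topology.res_names
    stack.atom_name = topology.atom_names
    stack.element = np.char.upper(topology.elements)
    stack.hetero = ~np.isin(topology.res_names, sorted(STANDARD_AMINO_ACIDS))
    return stack


def write_frames(
    topology: Topology, frames: FrameSeries, path: str | os.PathLike
) -> None:
    """Write a FrameSeries as a multi-model PDB (10^-3 Å printed precision)."""
    if frames.n_atoms != topology.n_atoms:
        raise ValueError(
            f"frame atom count {frames.n_atoms} does not match topology "
            f"({topology.n_atoms})"
        )
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(_atom_array_stack(topology, frames))
    pdb_file.write(str(path))
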