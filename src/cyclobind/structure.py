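"""Molecular structures, multi-model trajectories, and cyclodextrin topology.

Structures are ordered collections of atoms with Cartesian coordinates in
Angstrom.  PDB is the canonical on-disk format (read and write, via biotite);
XYZ is supported read-only for convenience.  Cyclodextrin topology -- the
glucopyranose units, the ring of glycosidic oxygens, and the primary- and
secondary-rim hydroxyl oxygens -- is either detected from atom naming plus
covalent-distance connectivity or supplied explicitly as hints.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import yaml

from .errors import (
    StructureParseError,
    TopologyError,
    TrajectoryError,
)

__all__ = [
    "AtomRecord",
    "MolecularStructure",
    "Trajectory",
    "CDTopology",
    "SelectionSpec",
    "atomic_mass",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "detect_cd_topology",
    "load_selection",
]

#: Covalent-distance criterion (A) used to link glycosidic oxygens to ring
#: carbons when explicit bonds are absent.
COVALENT_CUTOFF = 1.8

_PYRAN_NAMES = ("O5", "C1", "C2", "C3", "C4", "C5")


def atomic_mass(element: str) -> float:
    """Standard atomic mass (u) of an element symbol.

    Unknown elements raise ``StructureParseError``; there is deliberately no
    silent unit-mass fallback because descriptor centers of mass would be
    wrong without warning.
    """
    el = gemmi.Element(element.strip())
    if el.atomic_number == 0:
        raise StructureParseError(f"unknown element symbol {element!r}")
    return el.weight


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue membership, and position (A)."""

    serial: int
    name: str
    residue_name: str
    residue_index: int
    element: str
    position: np.ndarray

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise StructureParseError(
                f"atom {self.serial}: position must be a finite 3-vector"
            )
        object.__setattr__(self, "position", pos)


@dataclass
class MolecularStructure:
    """Ordered atom collection with optional bond list."""

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int]] | None = None
    label: str = ""

    def __post_init__(self):
        serials = [a.serial for a in self.atoms]
        if len(set(serials)) != len(serials):
            raise StructureParseError("duplicate atom serials in structure")
        self._index = {s: i for i, s in enumerate(serials)}
        if self.bonds is not None:
            for a, b in self.bonds:
                if a not in self._index or b not in self._index:
                    raise StructureParseError(
                        f"bond ({a}, {b}) references a nonexistent serial"
                    )

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def serials(self) -> np.ndarray:
        return np.array([a.serial for a in self.atoms], dtype=int)

    @property
    def positions(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    @property
    def masses(self) -> np.ndarray:
        return np.array([atomic_mass(a.element) for a in self.atoms])

    def atom(self, serial: int) -> AtomRecord:
        try:
            return self.atoms[self._index[serial]]
        except KeyError:
            raise KeyError(f"no atom with serial {serial}") from None

    def coords(self, serials: Iterable[int]) -> np.ndarray:
        return np.array([self.atom(s).position for s in serials], dtype=float)

    def com(self, serials: Iterable[int] | None = None) -> np.ndarray:
        """Mass-weighted center of mass of the given serials (all atoms if None)."""
        atoms = self.atoms if serials is None else [self.atom(s) for s in serials]
        m = np.array([atomic_mass(a.element) for a in atoms])
        xyz = np.array([a.position for a in atoms])
        return (m[:, None] * xyz).sum(axis=0) / m.sum()

    def centroid(self, serials: Iterable[int]) -> np.ndarray:
        """Unweighted geometric centroid of the given serials."""
        return self.coords(serials).mean(axis=0)

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "MolecularStructure":
        """Copy of the structure under a rigid motion ``x -> R x + t``."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        atoms = [
            AtomRecord(a.serial, a.name, a.residue_name, a.residue_index,
                       a.element, R @ a.position + t)
            for a in self.atoms
        ]
        return MolecularStructure(atoms, bonds=self.bonds, label=self.label)


@dataclass
class Trajectory:
    """Ordered frames with identical atom ordering and strictly increasing times (ps)."""

    frames: list[MolecularStructure]
    times: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.frames) != len(self.times):
            raise TrajectoryError("frames and times have different lengths")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryError("frame times must be strictly increasing")
        if self.frames:
            ref = self.frames[0].serials
            for i, fr in enumerate(self.frames[1:], start=2):
                if fr.n_atoms != len(ref) or not np.array_equal(fr.serials, ref):
                    raise TrajectoryError(
                        f"frame {i} atom ordering differs from frame 1"
                    )

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class CDTopology:
    """Per-unit atom serials of a cyclodextrin ring.

    ``glycosidic_oxygens[k]`` is the bridging O4 owned by unit ``k``;
    ``pyran_rings[k]`` lists the six heavy ring atoms (O5, C1..C5);
    ``prim_rim_oxygens[k]`` the O6 serial(s) and ``sec_rim_oxygens[k]``
    the O2/O3 serials of unit ``k``.
    """

    n_units: int
    glycosidic_oxygens: list[int]
    pyran_rings: list[list[int]]
    prim_rim_oxygens: list[list[int]]
    sec_rim_oxygens: list[list[int]]

    def __post_init__(self):
        n = self.n_units
        if len(self.glycosidic_oxygens) != n:
            raise TopologyError(
                f"expected {n} glycosidic oxygens, got {len(self.glycosidic_oxygens)}"
            )
        if len(self.pyran_rings) != n or any(len(set(r)) != 6 for r in self.pyran_rings):
            raise TopologyError("each of the n_units pyran rings needs 6 distinct atoms")
        prim = {s for unit in self.prim_rim_oxygens for s in unit}
        sec = {s for unit in self.sec_rim_oxygens for s in unit}
        if prim & sec:
            raise TopologyError("primary- and secondary-rim oxygen sets overlap")

    @property
    def prim_serials(self) -> list[int]:
        return [s for unit in self.prim_rim_oxygens for s in unit]

    @property
    def sec_serials(self) -> list[int]:
        return [s for unit in self.sec_rim_oxygens for s in unit]


@dataclass
class SelectionSpec:
    """Host/guest atom selections and the guest orientation vector.

    ``guest_vector`` is an ordered (tail, head) pair of guest serials: the
    tail sits in the guest's B ring, the head in its A ring, so that the
    vector points B -> A.  Which two atoms define it is an explicit user
    choice, not something the package guesses.
    """

    host: set[int]
    guest: set[int]
    guest_vector: tuple[int, int]

    def __post_init__(self):
        self.host = set(self.host)
        self.guest = set(self.guest)
        if self.host & self.guest:
            raise TopologyError("host and guest selections overlap")
        tail, head = self.guest_vector
        if tail not in self.guest or head not in self.guest:
            raise TopologyError("guest_vector atoms must belong to the guest selection")


# ---------------------------------------------------------------------------
# PDB / XYZ input and output
# ---------------------------------------------------------------------------

def _prescan_pdb(path: Path) -> int:
    """Validate coordinate fields of ATOM/HETATM records; return record count.

    Raises StructureParseError naming the offending line number.
    """
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                n += 1
                if len(line.rstrip("\n")) < 54:
                    raise StructureParseError(
                        f"{path}: line {lineno}: truncated ATOM/HETATM record"
                    )
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    try:
                        float(line[lo:hi])
                    except ValueError:
                        raise StructureParseError(
                            f"{path}: line {lineno}: malformed coordinate "
                            f"field {line[lo:hi]!r}"
                        ) from None
    return n


def _atoms_from_array(arr) -> list[AtomRecord]:
    serials = (arr.atom_id if "atom_id" in arr.get_annotation_categories()
               else np.arange(1, arr.array_length() + 1))
    atoms = []
    for i in range(arr.array_length()):
        element = str(arr.element[i]).capitalize() or str(arr.atom_name[i])[0]
        atoms.append(AtomRecord(
            serial=int(serials[i]),
            name=str(arr.atom_name[i]),
            residue_name=str(arr.res_name[i]),
            residue_index=int(arr.res_id[i]),
            element=element,
            position=np.asarray(arr.coord[i], dtype=float),
        ))
    return atoms


def _read_pdb_file(path: Path):
    from biotite.structure.io.pdb import PDBFile

    if _prescan_pdb(path) == 0:
        raise StructureParseError(f"{path}: no ATOM/HETATM records")
    try:
        return PDBFile.read(str(path))
    except Exception as exc:  # pragma: no cover - defensive
        raise StructureParseError(f"{path}: {exc}") from exc


def _read_xyz(path: Path) -> MolecularStructure:
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path), topology_format="XYZ", format="XYZ")
        except Exception as exc:
            raise StructureParseError(f"{path}: not a valid XYZ file ({exc})") from exc
        atoms = [
            AtomRecord(serial=i + 1, name=str(a.name), residue_name="UNK",
                       residue_index=1, element=str(a.name).capitalize(),
                       position=np.asarray(a.position, dtype=float))
            for i, a in enumerate(u.atoms)
        ]
    if not atoms:
        raise StructureParseError(f"{path}: empty XYZ file")
    return MolecularStructure(atoms, label=Path(path).stem)


def read_structure(path, dialect: str = "pdb") -> MolecularStructure:
    """Read a single structure (first MODEL of a PDB, or an XYZ file)."""
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"{path}: no such file")
    if dialect == "xyz":
        return _read_xyz(path)
    if dialect != "pdb":
        raise ValueError(f"unknown dialect {dialect!r}")
    pdb = _read_pdb_file(path)
    arr = pdb.get_structure(model=1, extra_fields=["atom_id"])
    return MolecularStructure(_atoms_from_array(arr), label=path.stem)


def read_trajectory(path, dt_ps: float = 1.0) -> Trajectory:
    """Read a multi-model PDB as a trajectory; times are ``0, dt, 2 dt, ...`` ps.

    Atom counts and ordering (serial, name, residue) must be identical across
    models; any mismatch raises ``TrajectoryError``.
    """
    path = Path(path)
    if not path.exists():
        raise StructureParseError(f"{path}: no such file")
    pdb = _read_pdb_file(path)
    n_models = pdb.get_model_count()
    frames = []
    ref = None
    for m in range(1, n_models + 1):
        try:
            arr = pdb.get_structure(model=m, extra_fields=["atom_id"])
        except Exception as exc:
            raise TrajectoryError(f"{path}: inconsistent models ({exc})") from exc
        key = (tuple(arr.atom_id), tuple(arr.atom_name), tuple(arr.res_id))
        if ref is None:
            ref = key
        elif key != ref:
            raise TrajectoryError(
                f"{path}: model {m} atom ordering differs from model 1"
            )
        frames.append(MolecularStructure(_atoms_from_array(arr),
                                         label=f"{path.stem}/frame{m}"))
    return Trajectory(frames, times=np.arange(n_models) * float(dt_ps))


def _to_atom_array(structure: MolecularStructure):
    import biotite.structure as struc

    n = structure.n_atoms
    if n == 0:
        raise StructureParseError("cannot write an empty structure")
    arr = struc.AtomArray(n)
    names = [a.name for a in structure.atoms]
    for nm in names:
        if len(nm) > 4:
            raise StructureParseError(
                f"atom name {nm!r} exceeds the 4-character PDB field"
            )
    arr.coord = structure.positions.astype(np.float32)
    arr.chain_id = np.array(["A"] * n)
    arr.res_id = np.array([a.residue_index for a in structure.atoms])
    arr.res_name = np.array([a.residue_name for a in structure.atoms])
    arr.atom_name = np.array(names)
    arr.element = np.array([a.element.upper() for a in structure.atoms])
    arr.hetero = np.array([True] * n)
    arr.set_annotation("atom_id", structure.serials)
    return arr


def write_structure(structure: MolecularStructure, path) -> None:
    """Write a structure as fixed-column PDB (coordinates to 3 decimals)."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile()
    pdb.set_structure(_to_atom_array(structure))
    pdb.write(str(path))


def write_trajectory(trajectory: Trajectory, path) -> None:
    """Write a trajectory as a multi-model PDB (one MODEL per frame)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    stack = struc.stack([_to_atom_array(fr) for fr in trajectory.frames])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


# ---------------------------------------------------------------------------
# Cyclodextrin topology detection
# ---------------------------------------------------------------------------

def _topology_from_hints(hints) -> CDTopology:
    if isinstance(hints, CDTopology):
        return hints
    return CDTopology(
        n_units=int(hints["n_units"]),
        glycosidic_oxygens=[int(s) for s in hints["glycosidic_oxygens"]],
        pyran_rings=[[int(s) for s in ring] for ring in hints["pyran_rings"]],
        prim_rim_oxygens=[[int(s) for s in u] for u in hints["prim_rim_oxygens"]],
        sec_rim_oxygens=[[int(s) for s in u] for u in hints["sec_rim_oxygens"]],
    )


def detect_cd_topology(structure: MolecularStructure, hints=None) -> CDTopology:
    """Identify glucopyranose units and rim oxygens of one cyclodextrin.

    Glucose units are residues containing the six pyran-ring atoms
    (O5, C1..C5).  Glycosidic oxygens are O4 atoms that bridge C1 of one
    residue and C4 of the next; with no bond records, bridging uses a
    covalent-distance criterion of ``COVALENT_CUTOFF`` (1.8 A).  Units are
    numbered by traversing the glycosidic linkage cycle from the lowest
    residue index, in the direction of increasing indices.  Explicit
    ``hints`` (a CDTopology or a mapping of the same fields) win verbatim.
    """
    if hints is not None:
        return _topology_from_hints(hints)

    by_res: dict[int, dict[str, AtomRecord]] = {}
    for a in structure.atoms:
        by_res.setdefault(a.residue_index, {})[a.name] = a

    glucose = {
        idx: names for idx, names in by_res.items()
        if all(nm in names for nm in _PYRAN_NAMES)
    }
    n_units = len(glucose)
    if n_units not in (6, 7, 8):
        raise TopologyError(
            f"found {n_units} glucopyranose residues; expected 6, 7, or 8 "
            "(supply explicit hints for non-standard inputs)"
        )

    # Link each bridging O4 to the C1 and C4 atoms within covalent distance.
    links: dict[int, tuple[int, int, int]] = {}  # res owning O4 -> (serial, resC1, resC4)
    for idx, names in glucose.items():
        if "O4" not in names:
            raise TopologyError(f"glucose residue {idx} lacks a bridging O4 atom")
        o4 = names["O4"]
        near_c1, near_c4 = [], []
        for jdx, jnames in glucose.items():
            for cname, bucket in (("C1", near_c1), ("C4", near_c4)):
                d = np.linalg.norm(o4.position - jnames[cname].position)
                if d <= COVALENT_CUTOFF:
                    bucket.append(jdx)
        if len(near_c1) != 1 or len(near_c4) != 1:
            raise TopologyError(
                f"ambiguous glycosidic bridging for O4 of residue {idx} "
                f"(C1 candidates {near_c1}, C4 candidates {near_c4}); "
                "supply explicit hints"
            )
        links[idx] = (o4.serial, near_c1[0], near_c4[0])

    # Each O4 joins residue pair (resC1, resC4); build the linkage cycle.
    neighbors: dict[int, set[int]] = {idx: set() for idx in glucose}
    for idx, (_, r1, r4) in links.items():
        if r1 == r4:
            raise TopologyError(
                f"O4 of residue {idx} bridges within a single residue; "
                "supply explicit hints"
            )
        neighbors[r1].add(r4)
        neighbors[r4].add(r1)
    if any(len(nb) != 2 for nb in neighbors.values()):
        raise TopologyError("glucose residues do not form a single linkage cycle")

    start = min(glucose)
    second = min(neighbors[start])
    order = [start, second]
    while len(order) < n_units:
        nxt = (neighbors[order[-1]] - {order[-2]}).pop()
        order.append(nxt)
    if order[0] not in neighbors[order[-1]]:
        raise TopologyError("glucose residues do not form a closed cycle")

    def rim(idx: int, names: Sequence[str]) -> list[int]:
        out = []
        for nm in names:
            if nm not in glucose[idx]:
                raise TopologyError(f"glucose residue {idx} lacks rim oxygen {nm}")
            out.append(glucose[idx][nm].serial)
        return out

    return CDTopology(
        n_units=n_units,
        glycosidic_oxygens=[links[idx][0] for idx in order],
        pyran_rings=[[glucose[idx][nm].serial for nm in _PYRAN_NAMES]
                     for idx in order],
        prim_rim_oxygens=[rim(idx, ("O6",)) for idx in order],
        sec_rim_oxygens=[rim(idx, ("O2", "O3")) for idx in order],
    )


def load_selection(path) -> SelectionSpec:
    """Load a SelectionSpec from a YAML or JSON config file.

    Expected keys: ``host`` and ``guest`` (serial lists) and ``guest_vector``
    (a [tail, head] pair of guest serials).
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        return SelectionSpec(
            host=set(int(s) for s in data["host"]),
            guest=set(int(s) for s in data["guest"]),
            guest_vector=(int(data["guest_vector"][0]), int(data["guest_vector"][1])),
        )
    except (KeyError, TypeError, IndexError) as exc:
        raise StructureParseError(f"{path}: invalid selection config ({exc})") from exc
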