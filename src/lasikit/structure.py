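"""Molecular structures, bonded topologies and coordinate frames.

The data model is deliberately minimal: atoms (identity + partial charge),
an undirected bond graph over internal 0-based indices, and one or more
labelled coordinate frames (e.g. the stationary points RS, TS1, INT, TS2, PS
of a reaction path).  File I/O speaks PDB (ATOM/HETATM), PSF (!NBOND) and a
native JSON topology that round-trips the whole system.

Internal indexing is 0-based everywhere; serials from source files are
1-based and kept verbatim on each :class:`AtomRecord`.  Conversion between
the two happens only at the file boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "AtomRecord", "BondGraph", "Frame", "MolecularSystem",
    "read_pdb", "read_bonds", "read_psf_bonds", "read_json_topology",
    "assemble_system", "write_json_topology", "write_pdb",
    "load_system", "DEFAULT_FORMAL_CHARGES", "CHARGE_CENTERS",
    "infer_element",
]


class TopologyError(ValueError):
    """Raised on malformed or inconsistent structure/topology input."""


# Residue-template formal charges (elementary charge units).  The table is a
# deterministic stand-in for protonation-state bookkeeping: charged sidechains
# of standard amino acids, common ions, and the nucleotide species relevant to
# phosphate hydrolysis (GTP^4-, GDP^3-).  Users override per residue instance.
DEFAULT_FORMAL_CHARGES: dict[str, int] = {
    "ASP": -1,
    "GLU": -1,
    "LYS": +1,
    "ARG": +1,
    "HIP": +1,   # doubly protonated histidine
    "GTP": -4,
    "GDP": -3,
    "MG": +2,
    "ZN": +2,
    "NA": +1,
    "K": +1,
    "CL": -1,
}

# Designated charge-center atom per charged template.  When a charged group is
# only partially selected, the group counts toward the formal charge of a QM
# region iff its charge center is inside the selection.
CHARGE_CENTERS: dict[str, str] = {
    "ASP": "CG",
    "GLU": "CD",
    "LYS": "NZ",
    "ARG": "CZ",
    "HIP": "NE2",
    "GTP": "PG",
    "GDP": "PB",
    "MG": "MG",
    "ZN": "ZN",
    "NA": "NA",
    "K": "K",
    "CL": "CL",
}

# Atom-name → element heuristics used when a PDB lacks the element column.
# Two-letter ions first, then the leading letter after stripping digits.
_NAME_ELEMENT_TABLE: dict[str, str] = {
    "MG": "Mg", "ZN": "Zn", "NA": "Na", "CL": "Cl", "FE": "Fe",
    "MN": "Mn", "CA2": "Ca", "BR": "Br",
}


def infer_element(name: str, residue_name: str = "") -> str:
    """Infer a chemical element from a PDB/PSF atom name.

    The element column is authoritative when present; this heuristic only
    backs it up.  Ion names are matched whole, otherwise the first alphabetic
    character decides (so ``HB2`` is hydrogen, ``CA`` is carbon unless the
    residue itself is a calcium ion).
    """
    key = name.strip().upper()
    res = residue_name.strip().upper()
    # Whole-name ion match trusted only when the residue agrees (the name CA
    # inside GLY is an alpha carbon, not calcium).
    if key in _NAME_ELEMENT_TABLE and res in (key, ""):
        return _NAME_ELEMENT_TABLE[key]
    stripped = key.lstrip("0123456789")
    if not stripped:
        raise TopologyError(f"cannot infer element from atom name {name!r}")
    first = stripped[0]
    if first == "H":
        return "H"
    if first == "C":
        return "C"
    if first == "N":
        return "N"
    if first == "O":
        return "O"
    if first == "S":
        return "S"
    if first == "P":
        return "P"
    return first.capitalize()


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue membership and partial charge."""

    internal_index: int
    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    segment_id: str = ""
    partial_charge: float | None = None

    @property
    def is_hydrogen(self) -> bool:
        return self.element == "H"

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"


class BondGraph:
    """Undirected covalent-bond graph over internal atom indices."""

    def __init__(self, edges: Iterable[tuple[int, int]], n_atoms: int):
        self.n_atoms = n_atoms
        self._adj: dict[int, list[int]] = {i: [] for i in range(n_atoms)}
        self._edges: set[frozenset[int]] = set()
        for i, j in edges:
            self.add_edge(i, j)

    def add_edge(self, i: int, j: int) -> None:
        if i == j:
            raise TopologyError(f"self-bond on atom {i}")
        if not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
            raise TopologyError(f"bond ({i},{j}) references atom outside 0..{self.n_atoms - 1}")
        key = frozenset((i, j))
        if key in self._edges:
            return
        self._edges.add(key)
        self._adj[i].append(j)
        self._adj[j].append(i)
        self._adj[i].sort()
        self._adj[j].sort()

    @property
    def edges(self) -> set[frozenset[int]]:
        return set(self._edges)

    def neighbors(self, i: int) -> list[int]:
        return list(self._adj[i])

    def has_edge(self, i: int, j: int) -> bool:
        return frozenset((i, j)) in self._edges

    def __len__(self) -> int:
        return len(self._edges)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(tuple(sorted(e)) for e in self._edges)
        return g

    def connected_component(self, seed: int) -> set[int]:
        return set(nx.node_connected_component(self.to_networkx(), seed))

    def ring_bonds(self) -> set[frozenset[int]]:
        """Edges that are members of any cycle of the bond graph."""
        g = self.to_networkx()
        rings: set[frozenset[int]] = set()
        for cycle in nx.cycle_basis(g):
            n = len(cycle)
            for k in range(n):
                rings.add(frozenset((cycle[k], cycle[(k + 1) % n])))
        return rings


@dataclass
class Frame:
    """A labelled coordinate set (Å) covering every atom of the system."""

    label: str
    coordinates: np.ndarray  # (n_atoms, 3)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise TopologyError(f"frame {self.label!r}: coordinates must be (n, 3)")


@dataclass
class MolecularSystem:
    """Atoms + bonds + frames + formal-charge templates, validated."""

    atoms: list[AtomRecord]
    bonds: BondGraph
    frames: list[Frame]
    residue_formal_charges: dict[str, int] = field(default_factory=dict)
    # (segment_id, residue_id) → charge; wins over the template table
    residue_overrides: dict[tuple[str, int], int] = field(default_factory=dict)
    charge_centers: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.atoms)
        for k, a in enumerate(self.atoms):
            if a.internal_index != k:
                raise TopologyError(
                    f"atom {a.serial}: internal_index {a.internal_index} != position {k}")
        if self.bonds.n_atoms != n:
            raise TopologyError("bond graph atom count mismatch")
        labels = [f.label for f in self.frames]
        if len(set(labels)) != len(labels):
            raise TopologyError(f"duplicate frame labels in {labels}")
        for f in self.frames:
            if f.coordinates.shape[0] != n:
                raise TopologyError(
                    f"frame {f.label!r} has {f.coordinates.shape[0]} coordinates for {n} atoms")
        if not self.residue_formal_charges:
            self.residue_formal_charges = dict(DEFAULT_FORMAL_CHARGES)
        if not self.charge_centers:
            self.charge_centers = dict(CHARGE_CENTERS)

    # -- lookups ---------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def frame(self, label: str) -> Frame:
        for f in self.frames:
            if f.label == label:
                return f
        raise KeyError(f"no frame labelled {label!r}; have {[f.label for f in self.frames]}")

    def serial_to_index(self) -> dict[int, int]:
        return {a.serial: a.internal_index for a in self.atoms}

    def resolve_atom(self, ident) -> int:
        """Resolve a serial or (segment, residue_id, name) tuple to an internal index."""
        if isinstance(ident, int):
            table = self.serial_to_index()
            if ident not in table:
                raise KeyError(f"no atom with serial {ident}")
            return table[ident]
        seg, resid, name = ident
        for a in self.atoms:
            if a.segment_id == seg and a.residue_id == int(resid) and a.name == name:
                return a.internal_index
        raise KeyError(f"no atom matching (segment={seg!r}, residue={resid}, name={name!r})")

    def residue_atoms(self, segment_id: str, residue_id: int) -> list[int]:
        return [a.internal_index for a in self.atoms
                if a.segment_id == segment_id and a.residue_id == residue_id]

    def residue_instances(self) -> list[tuple[str, int, str]]:
        """Distinct (segment, residue_id, residue_name) in atom order."""
        seen: list[tuple[str, int, str]] = []
        mark: set[tuple[str, int]] = set()
        for a in self.atoms:
            key = (a.segment_id, a.residue_id)
            if key not in mark:
                mark.add(key)
                seen.append((a.segment_id, a.residue_id, a.residue_name))
        return seen

    def formal_charge_of_residue(self, segment_id: str, residue_id: int,
                                 residue_name: str) -> int:
        if (segment_id, residue_id) in self.residue_overrides:
            return self.residue_overrides[(segment_id, residue_id)]
        return self.residue_formal_charges.get(residue_name, 0)

    def total_formal_charge(self) -> int:
        return sum(self.formal_charge_of_residue(s, r, n)
                   for s, r, n in self.residue_instances())


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_pdb(path: str | Path) -> list[tuple[AtomRecord, np.ndarray]]:
    """Parse ATOM/HETATM records of a PDB file.

    Returns atoms in file order paired with their coordinates (Å).  The
    element column (77–78) is used when present, otherwise the atom-name
    heuristic of :func:`infer_element` applies.
    """
    out: list[tuple[AtomRecord, np.ndarray]] = []
    seen_serials: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec not in ("ATOM", "HETATM"):
                continue
            try:
                serial = int(line[6:11])
                name = line[12:16].strip()
                resname = line[17:21].strip()
                # columns 21:22 chain, 22:26 resSeq
                resid = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except (ValueError, IndexError) as exc:
                raise TopologyError(f"{path}: malformed record on line {lineno}: {line.rstrip()!r}") from exc
            if serial in seen_serials:
                raise TopologyError(f"{path}: duplicate serial {serial} on line {lineno}")
            seen_serials.add(serial)
            segment = line[72:76].strip() if len(line) >= 76 else ""
            if not segment:
                segment = line[21:22].strip()
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                element = infer_element(name, resname)
            else:
                element = element.capitalize()
            atom = AtomRecord(
                internal_index=len(out), serial=serial, name=name,
                element=element, residue_name=resname, residue_id=resid,
                segment_id=segment)
            out.append((atom, np.array([x, y, z])))
    return out


def read_psf_bonds(path: str | Path, atoms: Sequence[AtomRecord]) -> BondGraph:
    """Read the !NBOND section of an (X-)PSF file into a bond graph."""
    serial_map = {a.serial: a.internal_index for a in atoms}
    edges: list[tuple[int, int]] = []
    with open(path) as fh:
        lines = fh.readlines()
    nbond = None
    start = None
    for k, line in enumerate(lines):
        if "!NBOND" in line:
            nbond = int(line.split()[0])
            start = k + 1
            break
    if nbond is None:
        raise TopologyError(f"{path}: no !NBOND section found")
    serials: list[int] = []
    k = start
    while len(serials) < 2 * nbond and k < len(lines):
        serials.extend(int(tok) for tok in lines[k].split())
        k += 1
    if len(serials) < 2 * nbond:
        raise TopologyError(f"{path}: !NBOND promises {nbond} bonds, found {len(serials) // 2}")
    for a, b in zip(serials[0::2], serials[1::2]):
        if a not in serial_map or b not in serial_map:
            raise TopologyError(f"{path}: bond ({a},{b}) references unknown serial")
        edges.append((serial_map[a], serial_map[b]))
    return BondGraph(edges, n_atoms=len(atoms))


def _read_json_bonds(payload: Mapping, atoms: Sequence[AtomRecord]) -> BondGraph:
    serial_map = {a.serial: a.internal_index for a in atoms}
    edges = []
    for a, b in payload.get("bonds", []):
        if a not in serial_map or b not in serial_map:
            raise TopologyError(f"bond ({a},{b}) references unknown serial")
        edges.append((serial_map[a], serial_map[b]))
    return BondGraph(edges, n_atoms=len(atoms))


def read_bonds(path: str | Path, atoms: Sequence[AtomRecord]) -> BondGraph:
    """Read a bond list (PSF ``!NBOND`` or native JSON) against known atoms."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        return _read_json_bonds(payload, atoms)
    return read_psf_bonds(path, atoms)


def assemble_system(atoms: Sequence[AtomRecord], bonds: BondGraph,
                    frames: Sequence[Frame],
                    charge_table: Mapping[str, int] | None = None,
                    residue_overrides: Mapping[tuple[str, int], int] | None = None,
                    charge_centers: Mapping[str, str] | None = None) -> MolecularSystem:
    """Validate and assemble a :class:`MolecularSystem`."""
    return MolecularSystem(
        atoms=list(atoms),
        bonds=bonds,
        frames=list(frames),
        residue_formal_charges=dict(charge_table) if charge_table else {},
        residue_overrides=dict(residue_overrides) if residue_overrides else {},
        charge_centers=dict(charge_centers) if charge_centers else {},
    )


# ---------------------------------------------------------------------------
# Native JSON topology round trip
# ---------------------------------------------------------------------------

def write_json_topology(system: MolecularSystem, path: str | Path) -> None:
    payload = {
        "atoms": [
            {
                "serial": a.serial, "name": a.name, "element": a.element,
                "residue_name": a.residue_name, "residue_id": a.residue_id,
                "segment_id": a.segment_id, "partial_charge": a.partial_charge,
            }
            for a in system.atoms
        ],
        "bonds": sorted(
            sorted((system.atoms[i].serial, system.atoms[j].serial))
            for i, j in (tuple(e) for e in system.bonds.edges)
        ),
        "frames": {f.label: f.coordinates.tolist() for f in system.frames},
        "frame_order": [f.label for f in system.frames],
        "formal_charges": system.residue_formal_charges,
        "residue_overrides": {f"{seg}:{rid}": q
                              for (seg, rid), q in system.residue_overrides.items()},
        "charge_centers": system.charge_centers,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def read_json_topology(path: str | Path) -> MolecularSystem:
    with open(path) as fh:
        payload = json.load(fh)
    atoms = [
        AtomRecord(
            internal_index=k, serial=rec["serial"], name=rec["name"],
            element=rec["element"], residue_name=rec["residue_name"],
            residue_id=rec["residue_id"], segment_id=rec.get("segment_id", ""),
            partial_charge=rec.get("partial_charge"))
        for k, rec in enumerate(payload["atoms"])
    ]
    bonds = _read_json_bonds(payload, atoms)
    order = payload.get("frame_order", sorted(payload.get("frames", {})))
    frames = [Frame(label, np.array(payload["frames"][label])) for label in order]
    overrides = {}
    for key, q in payload.get("residue_overrides", {}).items():
        seg, rid = key.rsplit(":", 1)
        overrides[(seg, int(rid))] = q
    return assemble_system(
        atoms, bonds, frames,
        charge_table=payload.get("formal_charges"),
        residue_overrides=overrides,
        charge_centers=payload.get("charge_centers"))


def write_pdb(system: MolecularSystem, frame_label: str, path: str | Path,
              subset: Iterable[int] | None = None) -> None:
    """Write one frame (optionally a subset of atoms) as a PDB file."""
    frame = system.frame(frame_label)
    indices = sorted(subset) if subset is not None else range(system.n_atoms)
    with open(path, "w") as fh:
        for i in indices:
            a = system.atoms[i]
            x, y, z = frame.coordinates[i]
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            fh.write(
                f"ATOM  {a.serial:5d} {name:<4s} {a.residue_name:<4s}"
                f" {a.residue_id:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}      {a.segment_id:<4s}"
                f"{a.element:>2s}\n")
        fh.write("END\n")


def load_system(pdb_paths: Mapping[str, str | Path], topology_path: str | Path,
                charge_table: Mapping[str, int] | None = None) -> MolecularSystem:
    """Build a system from labelled PDB frames plus a bond-list file.

    ``pdb_paths`` maps frame label → PDB file; all files must list the same
    atoms in the same order (coordinates may differ).
    """
    labels = list(pdb_paths)
    first = read_pdb(pdb_paths[labels[0]])
    atoms = [a for a, _ in first]
    frames = [Frame(labels[0], np.array([xyz for _, xyz in first]))]
    for label in labels[1:]:
        parsed = read_pdb(pdb_paths[label])
        if len(parsed) != len(atoms):
            raise TopologyError(f"frame {label!r}: atom count mismatch")
        frames.append(Frame(label, np.array([xyz for _, xyz in parsed])))
    bonds = read_bonds(topology_path, atoms)
    return assemble_system(atoms, bonds, frames, charge_table=charge_table)
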