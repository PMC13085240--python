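"""Topologically extended, distance-based QM-region selection.

Building a QM/MM model requires choosing which atoms are treated quantum
mechanically.  The selection strategy implemented here starts from a small,
user-declared list of core atoms (the reactive center), adds every heavy atom
within a radius of any core atom — in any of the requested structures along a
preliminary reaction path, taking the union — completes hydrogens, and then
grows the selection outward along covalent bonds.  Growth stops only at
*cutable* bonds: apolar carbon–carbon single bonds named in an extensible
cut-rule table (never amide C–N, never ring bonds, never bonds to non-carbon
heavy atoms).  Each cut bond is capped by a hydrogen link atom placed on the
QM→MM bond vector.

Post-processing keeps the QM/MM interface clean: when two cuts share the same
MM-side atom, that atom is absorbed into the region and growth re-runs
(link-atom deduplication); small aliphatic islands (≤ 2 carbons plus their
hydrogens, disconnected from the core) yielded by the radius cut are pruned;
and the formal charge of the selection is accounted from residue templates.
"""

from __future__ import annotations

import fnmatch
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from lasikit.structure import MolecularSystem, write_pdb

__all__ = [
    "CutRule", "CutEvent", "SelectionSpec", "QMRegion",
    "DEFAULT_CUT_RULES", "radial_core", "topological_extension",
    "merge_shared_mm_links", "prune_small_fragments", "place_link_atoms",
    "formal_charge", "select_region", "nested_series", "exclusion_variant",
    "write_region_report",
]


class SelectionError(ValueError):
    """Raised on unresolvable core atoms or degenerate selection specs."""


@dataclass(frozen=True)
class CutRule:
    """An atom-name pair at which the bond graph may be severed.

    ``qm_name``/``mm_name`` are fnmatch-style patterns; ``residue`` optionally
    restricts the rule to residues whose name matches.  Rules are
    direction-agnostic: both orientations of a bond are tried.
    """

    qm_name: str
    mm_name: str
    residue: str | None = None
    description: str = ""

    def __post_init__(self):
        if not self.qm_name or not self.mm_name:
            raise ValueError("cut-rule patterns must be non-empty")

    def _match_oriented(self, qm_atom, mm_atom) -> bool:
        if self.residue is not None and not (
                fnmatch.fnmatch(qm_atom.residue_name, self.residue)
                or fnmatch.fnmatch(mm_atom.residue_name, self.residue)):
            return False
        return (fnmatch.fnmatch(qm_atom.name, self.qm_name)
                and fnmatch.fnmatch(mm_atom.name, self.mm_name))

    def matches(self, atom_a, atom_b) -> bool:
        return self._match_oriented(atom_a, atom_b) or self._match_oriented(atom_b, atom_a)


# Conservative default table for standard amino acids: apolar sidechain C–C
# single bonds only.  Amide C–N, bonds to non-carbon heavy atoms and ring
# bonds are never cut (the ring guard is enforced from the bond graph at
# match time, so e.g. a PRO CA–CB bond is protected even though it matches).
DEFAULT_CUT_RULES: tuple[CutRule, ...] = (
    CutRule("CA", "CB", None, "alpha/beta carbon"),
    CutRule("CB", "CG", "LYS", "lysine beta/gamma"),
    CutRule("CB", "CG", "ARG", "arginine beta/gamma"),
    CutRule("CB", "CG", "GLU", "glutamate beta/gamma"),
    CutRule("CB", "CG", "GLN", "glutamine beta/gamma"),
    CutRule("CB", "CG", "MET", "methionine beta/gamma"),
    CutRule("CB", "CG1", "ILE", "isoleucine beta/gamma1"),
    CutRule("CB", "CG2", None, "beta/gamma2 methyl (VAL, ILE, THR)"),
    CutRule("CG", "CD", "LYS", "lysine gamma/delta"),
    CutRule("CG", "CD", "ARG", "arginine gamma/delta"),
    CutRule("CG1", "CD1", "ILE", "isoleucine gamma1/delta1"),
    CutRule("CD", "CE", "LYS", "lysine delta/epsilon"),
)

# Sentinel rule recorded on cut events created by explicit residue exclusion
# rather than by the cut-rule table.
EXCLUSION_RULE = CutRule("*", "*", None, "explicit moiety exclusion")


@dataclass(frozen=True)
class CutEvent:
    """A severed bond: QM-side atom, MM-side atom, and the rule that matched."""

    qm_atom: int
    mm_atom: int
    matched_rule: CutRule


@dataclass
class SelectionSpec:
    """Parameters of one QM-region selection."""

    core_atoms: list  # serials or (segment, residue_id, name) tuples
    radius: float
    frame_labels: list[str]
    cut_rules: Sequence[CutRule] = DEFAULT_CUT_RULES
    prune_fragment_max_carbons: int = 2
    merge_shared_mm_atoms: bool = True
    d_link: float = 1.09  # Å, C–H cap distance

    def __post_init__(self):
        if self.radius < 0:
            raise SelectionError("radius must be >= 0")
        if not self.core_atoms:
            raise SelectionError("core_atoms must be non-empty")
        if not self.frame_labels:
            raise SelectionError("frame_labels must be non-empty")


@dataclass
class QMRegion:
    """A finished QM selection with its interface bookkeeping."""

    atom_indices: frozenset[int]
    cut_events: list[CutEvent]
    link_atoms: dict[str, list[tuple[int, int, np.ndarray]]]
    formal_charge: int
    provenance: list[str] = field(default_factory=list)
    core_indices: frozenset[int] = frozenset()

    @property
    def n_atoms(self) -> int:
        return len(self.atom_indices)

    @property
    def n_links(self) -> int:
        return len(self.cut_events)

    def serials(self, system: MolecularSystem) -> list[int]:
        return sorted(system.atoms[i].serial for i in self.atom_indices)


# ---------------------------------------------------------------------------
# Stage 1: radial seeding
# ---------------------------------------------------------------------------

def _resolve_core(system: MolecularSystem, core_atoms: Iterable) -> list[int]:
    resolved = []
    for ident in core_atoms:
        try:
            resolved.append(system.resolve_atom(ident))
        except KeyError as exc:
            raise SelectionError(f"unresolvable core atom {ident!r}") from exc
    return resolved


def radial_core(system: MolecularSystem, spec: SelectionSpec) -> set[int]:
    """Heavy atoms within ``spec.radius`` of any core atom in ANY requested
    frame (union over frames), plus hydrogen completion.

    Only heavy atoms are seeded by distance; hydrogens enter by bonding to a
    selected heavy atom.  Symmetrically, a selected hydrogen (a core atom may
    be one) pulls in its bonded heavy atom.
    """
    core = _resolve_core(system, spec.core_atoms)
    heavy = np.array([a.is_heavy for a in system.atoms])
    selected: set[int] = set(core)
    for label in spec.frame_labels:
        coords = system.frame(label).coordinates
        core_xyz = coords[core]  # (n_core, 3)
        d = np.linalg.norm(coords[:, None, :] - core_xyz[None, :, :], axis=2)
        within = (d.min(axis=1) <= spec.radius) & heavy
        selected.update(np.nonzero(within)[0].tolist())
    # hydrogen completion to a fixed point
    changed = True
    while changed:
        changed = False
        for i in sorted(selected):
            for j in system.bonds.neighbors(i):
                if j in selected:
                    continue
                if system.atoms[i].is_heavy and system.atoms[j].is_hydrogen:
                    selected.add(j)
                    changed = True
                elif system.atoms[i].is_hydrogen and system.atoms[j].is_heavy:
                    selected.add(j)
                    changed = True
    return selected


# ---------------------------------------------------------------------------
# Stage 2: topological extension with cut rules
# ---------------------------------------------------------------------------

def _is_cutable(system: MolecularSystem, i: int, j: int,
                cut_rules: Sequence[CutRule],
                ring_bonds: set[frozenset[int]]) -> CutRule | None:
    """Return the first matching rule if bond (i, j) may be cut, else None."""
    if frozenset((i, j)) in ring_bonds:
        return None
    a, b = system.atoms[i], system.atoms[j]
    for rule in cut_rules:
        if rule.matches(a, b):
            return rule
    return None


def topological_extension(system: MolecularSystem, seed_set: set[int],
                          cut_rules: Sequence[CutRule],
                          ring_bonds: set[frozenset[int]] | None = None,
                          ) -> tuple[set[int], list[CutEvent]]:
    """Grow ``seed_set`` along bonds until every boundary bond is cutable.

    A boundary bond that matches no cut rule is crossed (the outside atom is
    absorbed); a matching bond halts growth there and is recorded as a
    :class:`CutEvent`.  Traversal is breadth-first in ascending internal
    index, so the result and the event order are deterministic.
    """
    if not seed_set:
        raise SelectionError("topological extension needs a non-empty seed set")
    if ring_bonds is None:
        ring_bonds = system.bonds.ring_bonds()
    region = set(seed_set)
    frontier = sorted(region)
    while frontier:
        new_frontier: set[int] = set()
        for i in frontier:
            for j in system.bonds.neighbors(i):
                if j in region:
                    continue
                if _is_cutable(system, i, j, cut_rules, ring_bonds) is None:
                    region.add(j)
                    new_frontier.add(j)
        frontier = sorted(new_frontier)
    events = _boundary_events(system, region, cut_rules, ring_bonds)
    return region, events


def _boundary_events(system: MolecularSystem, region: set[int],
                     cut_rules: Sequence[CutRule],
                     ring_bonds: set[frozenset[int]]) -> list[CutEvent]:
    events = []
    for i in sorted(region):
        for j in system.bonds.neighbors(i):
            if j in region:
                continue
            rule = _is_cutable(system, i, j, cut_rules, ring_bonds)
            if rule is None:
                raise SelectionError(
                    f"closure violated: non-cutable boundary bond ({i},{j})")
            events.append(CutEvent(i, j, rule))
    return events


# ---------------------------------------------------------------------------
# Stage 3: link-atom deduplication
# ---------------------------------------------------------------------------

def merge_shared_mm_links(system: MolecularSystem, region: set[int],
                          events: list[CutEvent],
                          cut_rules: Sequence[CutRule],
                          ring_bonds: set[frozenset[int]] | None = None,
                          ) -> tuple[set[int], list[CutEvent], list[int]]:
    """Absorb MM-side atoms shared by two or more cut events.

    Two link atoms landing on the same MM atom would sit almost on top of
    each other; instead the shared atom joins the QM region and growth
    re-runs from the enlarged set, repeating until no MM atom is shared.
    Returns (region, events, absorbed-atom log).
    """
    if ring_bonds is None:
        ring_bonds = system.bonds.ring_bonds()
    absorbed: list[int] = []
    while True:
        seen: dict[int, int] = {}
        shared: set[int] = set()
        for ev in events:
            seen[ev.mm_atom] = seen.get(ev.mm_atom, 0) + 1
            if seen[ev.mm_atom] > 1:
                shared.add(ev.mm_atom)
        if not shared:
            return region, events, absorbed
        absorbed.extend(sorted(shared))
        region, events = topological_extension(
            system, region | shared, cut_rules, ring_bonds)


# ---------------------------------------------------------------------------
# Stage 4: aliphatic-island pruning
# ---------------------------------------------------------------------------

def prune_small_fragments(system: MolecularSystem, region: set[int],
                          events: list[CutEvent], core_indices: set[int],
                          max_carbons: int = 2,
                          ) -> tuple[set[int], list[CutEvent], list[set[int]]]:
    """Drop small aliphatic islands disconnected from the core.

    A connected component of the selection's induced subgraph is removed when
    it contains no core atom and consists solely of at most ``max_carbons``
    carbon atoms plus their hydrogens.  Cut events rooted in a removed island
    are dropped with it.  Returns (region, events, removed components).
    """
    if not core_indices & region:
        raise SelectionError("selection no longer contains any core atom")
    g = system.bonds.to_networkx().subgraph(region)
    removed: list[set[int]] = []
    keep = set(region)
    for comp in nx.connected_components(g):
        if comp & core_indices:
            continue
        elements = {system.atoms[i].element for i in comp}
        n_carbon = sum(1 for i in comp if system.atoms[i].element == "C")
        if elements <= {"C", "H"} and n_carbon <= max_carbons:
            removed.append(set(comp))
            keep -= comp
    if removed:
        gone = set().union(*removed)
        events = [ev for ev in events if ev.qm_atom not in gone]
    return keep, events, removed


# ---------------------------------------------------------------------------
# Stage 5: link-atom placement and formal charge
# ---------------------------------------------------------------------------

def place_link_atoms(system: MolecularSystem, events: Sequence[CutEvent],
                     frame_label: str, d_link: float = 1.09,
                     ) -> list[tuple[int, int, np.ndarray]]:
    """Hydrogen cap positions for each cut bond in one frame.

    The cap sits on the segment from the QM atom toward the MM atom at a
    fixed distance ``d_link`` (Å).
    """
    coords = system.frame(frame_label).coordinates
    placed = []
    for ev in events:
        q = coords[ev.qm_atom]
        m = coords[ev.mm_atom]
        vec = m - q
        norm = np.linalg.norm(vec)
        if norm < 1e-9:
            raise SelectionError(
                f"coincident coordinates for cut bond ({ev.qm_atom},{ev.mm_atom}) "
                f"in frame {frame_label!r}")
        placed.append((ev.qm_atom, ev.mm_atom, q + d_link * vec / norm))
    return placed


def formal_charge(system: MolecularSystem, region: set[int]) -> int:
    """Formal charge of a selection from residue templates.

    A charged residue counts when wholly inside the region.  A partial
    selection raises a warning and counts only if the template's designated
    charge-center atom is inside.
    """
    total = 0
    for seg, rid, rname in system.residue_instances():
        q = system.formal_charge_of_residue(seg, rid, rname)
        if q == 0:
            continue
        members = set(system.residue_atoms(seg, rid))
        inside = members & region
        if not inside:
            continue
        if inside == members:
            total += q
            continue
        center_name = system.charge_centers.get(rname)
        center_inside = any(system.atoms[i].name == center_name for i in inside)
        warnings.warn(
            f"charged residue {rname} {seg}:{rid} partially selected; "
            f"counting its charge: {center_inside}")
        if center_inside:
            total += q
    return total


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def select_region(system: MolecularSystem, spec: SelectionSpec) -> QMRegion:
    """Full selection pipeline: radial seed → topological extension →
    link-atom deduplication → aliphatic pruning → charge accounting."""
    provenance: list[str] = []
    core = _resolve_core(system, spec.core_atoms)
    ring_bonds = system.bonds.ring_bonds()

    seeds = radial_core(system, spec)
    provenance.append(
        f"radial_core: radius={spec.radius:.3f} A frames={','.join(spec.frame_labels)} "
        f"core={sorted(core)} -> {len(seeds)} atoms")

    region, events = topological_extension(system, seeds, spec.cut_rules, ring_bonds)
    provenance.append(
        f"topological_extension: -> {len(region)} atoms, {len(events)} cut bonds")

    if spec.merge_shared_mm_atoms:
        region, events, absorbed = merge_shared_mm_links(
            system, region, events, spec.cut_rules, ring_bonds)
        provenance.append(
            f"merge_shared_mm_links: absorbed {absorbed} -> {len(region)} atoms, "
            f"{len(events)} cut bonds")

    region, events, removed = prune_small_fragments(
        system, region, events, set(core), spec.prune_fragment_max_carbons)
    provenance.append(
        f"prune_small_fragments: removed {[sorted(c) for c in removed]} "
        f"-> {len(region)} atoms, {len(events)} cut bonds")

    events = sorted(events, key=lambda ev: (ev.qm_atom, ev.mm_atom))
    links = {label: place_link_atoms(system, events, label, spec.d_link)
             for label in spec.frame_labels}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        q = formal_charge(system, region)
    provenance.append(f"formal_charge: {q:+d}")

    return QMRegion(
        atom_indices=frozenset(region), cut_events=events, link_atoms=links,
        formal_charge=q, provenance=provenance, core_indices=frozenset(core))


def nested_series(system: MolecularSystem, spec: SelectionSpec,
                  radii: Sequence[float]) -> list[QMRegion]:
    """One region per radius (strictly increasing), for convergence studies."""
    radii = list(radii)
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise SelectionError(f"radii must be strictly increasing, got {radii}")
    out = []
    for r in radii:
        s = SelectionSpec(
            core_atoms=spec.core_atoms, radius=r, frame_labels=spec.frame_labels,
            cut_rules=spec.cut_rules,
            prune_fragment_max_carbons=spec.prune_fragment_max_carbons,
            merge_shared_mm_atoms=spec.merge_shared_mm_atoms, d_link=spec.d_link)
        out.append(select_region(system, s))
    return out


def exclusion_variant(region: QMRegion, system: MolecularSystem,
                      moiety_atoms: Iterable[int],
                      spec: SelectionSpec) -> QMRegion:
    """Remove a moiety from a finished region, for residue-exclusion scans.

    Bonds from the shrunken region into the excluded moiety become cut events
    regardless of the cut-rule table (recorded with a sentinel exclusion
    rule); the remaining boundary is re-validated, shared-MM-atom merging is
    re-applied to rule-based events, and small fragments are re-pruned.
    """
    moiety = set(moiety_atoms)
    if not moiety:
        return region
    if not moiety <= set(region.atom_indices):
        raise SelectionError("moiety must be a subset of the region")
    if moiety & set(region.core_indices):
        raise SelectionError("moiety contains a core atom")
    ring_bonds = system.bonds.ring_bonds()
    atoms = set(region.atom_indices) - moiety

    def boundary(atoms_in: set[int]) -> list[CutEvent]:
        evs = []
        for i in sorted(atoms_in):
            for j in system.bonds.neighbors(i):
                if j in atoms_in:
                    continue
                if j in moiety:
                    evs.append(CutEvent(i, j, EXCLUSION_RULE))
                    continue
                rule = _is_cutable(system, i, j, spec.cut_rules, ring_bonds)
                if rule is None:
                    raise SelectionError(
                        f"closure violated after exclusion at bond ({i},{j})")
                evs.append(CutEvent(i, j, rule))
        return evs

    events = boundary(atoms)
    if spec.merge_shared_mm_atoms:
        # merging never re-absorbs excluded atoms
        while True:
            counts: dict[int, int] = {}
            for ev in events:
                counts[ev.mm_atom] = counts.get(ev.mm_atom, 0) + 1
            shared = {m for m, c in counts.items() if c > 1 and m not in moiety}
            if not shared:
                break
            grown, _ = topological_extension(
                system, atoms | shared, spec.cut_rules, ring_bonds)
            atoms = grown - moiety
            events = boundary(atoms)
    atoms, events, removed = prune_small_fragments(
        system, atoms, events, set(region.core_indices),
        spec.prune_fragment_max_carbons)
    events = sorted(events, key=lambda ev: (ev.qm_atom, ev.mm_atom))
    links = {label: place_link_atoms(system, events, label, spec.d_link)
             for label in spec.frame_labels}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        q = formal_charge(system, atoms)
    provenance = list(region.provenance) + [
        f"exclusion_variant: removed {sorted(moiety)} -> {len(atoms)} atoms, "
        f"{len(events)} cut bonds, pruned {[sorted(c) for c in removed]}"]
    return QMRegion(
        atom_indices=frozenset(atoms), cut_events=events, link_atoms=links,
        formal_charge=q, provenance=provenance, core_indices=region.core_indices)


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def write_region_report(system: MolecularSystem, region: QMRegion,
                        prefix: str | Path) -> None:
    """Write the selection as serial list, per-frame link-atom PDB and a JSON
    report (counts, cut events, formal charge, provenance)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(f"{prefix}.serials.txt", "w") as fh:
        for s in region.serials(system):
            fh.write(f"{s}\n")
    report = {
        "n_atoms": region.n_atoms,
        "n_cut_bonds": region.n_links,
        "formal_charge": region.formal_charge,
        "cut_events": [
            {
                "qm_serial": system.atoms[ev.qm_atom].serial,
                "mm_serial": system.atoms[ev.mm_atom].serial,
                "rule": ev.matched_rule.description,
            }
            for ev in region.cut_events
        ],
        "provenance": region.provenance,
    }
    with open(f"{prefix}.report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    for label, links in region.link_atoms.items():
        write_pdb(system, label, f"{prefix}.{label}.pdb",
                  subset=region.atom_indices)
        with open(f"{prefix}.{label}.links.pdb", "w") as fh:
            for k, (_, _, xyz) in enumerate(links, start=1):
                fh.write(
                    f"ATOM  {k:5d}  HL  LNK {k:4d}    "
                    f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}           H\n")
            fh.write("END\n")
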