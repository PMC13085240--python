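"""Seeded generators of protein-like test systems.

Real enzyme QM/MM models (thousands of atoms, CHARMM topologies, coupled
cluster energy tables) are far beyond desk scale, so every consumer of this
package is exercised on synthetic stand-ins that reproduce the *features*
that matter to the algorithms:

* :func:`make_topology` — a peptide-like chain with aliphatic and explicitly
  charged sidechains, a divalent metal ion coordinated by waters, crystal-
  water solvation, and five stationary-point frames with small coordinated
  displacements.  Everything a QM-region selector must negotiate: bonds to
  cut, charges to count, hydrogens to complete, islands to prune.
* :func:`make_hamiltonian` — a small symmetric-positive-definite
  electronic-structure problem over a planted 1-D atom arrangement whose
  couplings decay exponentially with distance, so locality-based embedding
  and truncation have real structure to exploit.
* :func:`make_energy_series` — long-format energy tables whose relative
  energies approach a planted asymptotic profile exponentially in QM size,
  with the 1 kcal/mol convergence crossing planted at a known size, plus
  Normal/Tight threshold columns with a planted gap.

All generators are pure functions of their recipe (seed included): repeated
calls are byte-identical.  Scales are capped (≤ a few hundred atoms, ≤ ~16
basis functions) so full test sweeps run in minutes on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from lasikit.energies import (
    HARTREE_TO_KCAL, EnergyKey, EnergyTable,
)
from lasikit.embedding import ModelHamiltonian
from lasikit.structure import (
    AtomRecord, BondGraph, Frame, MolecularSystem, assemble_system,
)

__all__ = [
    "TopologyRecipe", "HamiltonianRecipe", "EnergySeriesRecipe",
    "make_topology", "make_hamiltonian", "make_energy_series",
    "RESIDUE_TEMPLATES",
]

FRAME_LABELS = ("RS", "TS1", "INT", "TS2", "PS")


# ---------------------------------------------------------------------------
# Residue templates
# ---------------------------------------------------------------------------
# Local geometry is schematic (bond lengths ~1.0–1.5 Å, sidechains extended
# along +y); the selector only needs distances and connectivity, not real
# stereochemistry.  Each entry: atom (name, element, offset), bond name pairs.

def _bb(sidechain_atoms, sidechain_bonds):
    atoms = [
        ("N", "N", (0.0, 0.0, 0.0)),
        ("HN", "H", (-0.4, -0.9, 0.0)),
        ("CA", "C", (1.45, 0.3, 0.0)),
        ("HA", "H", (1.5, 0.9, 0.9)),
        ("C", "C", (2.6, -0.7, 0.0)),
        ("O", "O", (2.6, -1.9, 0.2)),
    ] + sidechain_atoms
    bonds = [("N", "HN"), ("N", "CA"), ("CA", "HA"), ("CA", "C"),
             ("C", "O")] + sidechain_bonds
    return {"atoms": atoms, "bonds": bonds}


def _chain_sidechain(names_elements, hydrogens_per=2):
    """Stack sidechain heavy atoms above CA along +y, two H's per carbon."""
    atoms, bonds = [], []
    prev = "CA"
    y = 1.5
    for name, elem in names_elements:
        atoms.append((name, elem, (1.45, 0.3 + y, 0.0)))
        bonds.append((prev, name))
        if elem == "C":
            for k in range(hydrogens_per):
                hname = f"H{name[1:]}{k + 1}"
                atoms.append((hname, "H", (1.45 + (0.95 if k == 0 else -0.95),
                                           0.3 + y, 0.45)))
                bonds.append((name, hname))
        prev = name
        y += 1.5
    return atoms, bonds


def _make_templates():
    t = {}
    t["GLY"] = _bb([("HA2", "H", (1.4, 1.2, -0.8))], [("CA", "HA2")])

    ala_sc = [("CB", "C", (1.45, 1.8, 0.0)),
              ("HB1", "H", (2.35, 1.85, 0.5)), ("HB2", "H", (0.55, 1.85, 0.5)),
              ("HB3", "H", (1.45, 2.7, -0.5))]
    t["ALA"] = _bb(ala_sc, [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "HB3")])

    ser_sc, ser_b = _chain_sidechain([("CB", "C")])
    ser_sc += [("OG", "O", (1.45, 3.3, 0.0)), ("HG1", "H", (1.45, 4.1, 0.4))]
    ser_b += [("CB", "OG"), ("OG", "HG1")]
    t["SER"] = _bb(ser_sc, ser_b)

    asp_sc, asp_b = _chain_sidechain([("CB", "C")])
    asp_sc += [("CG", "C", (1.45, 3.3, 0.0)),
               ("OD1", "O", (2.4, 4.0, 0.0)), ("OD2", "O", (0.5, 4.0, 0.0))]
    asp_b += [("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")]
    t["ASP"] = _bb(asp_sc, asp_b)

    glu_sc, glu_b = _chain_sidechain([("CB", "C"), ("CG", "C")])
    glu_sc += [("CD", "C", (1.45, 4.8, 0.0)),
               ("OE1", "O", (2.4, 5.5, 0.0)), ("OE2", "O", (0.5, 5.5, 0.0))]
    glu_b += [("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")]
    t["GLU"] = _bb(glu_sc, glu_b)

    lys_sc, lys_b = _chain_sidechain(
        [("CB", "C"), ("CG", "C"), ("CD", "C"), ("CE", "C")])
    lys_sc += [("NZ", "N", (1.45, 7.8, 0.0)),
               ("HZ1", "H", (2.3, 8.3, 0.0)), ("HZ2", "H", (0.6, 8.3, 0.0)),
               ("HZ3", "H", (1.45, 8.3, 0.85))]
    lys_b += [("CE", "NZ"), ("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3")]
    t["LYS"] = _bb(lys_sc, lys_b)

    arg_sc, arg_b = _chain_sidechain([("CB", "C"), ("CG", "C"), ("CD", "C")])
    arg_sc += [("NE", "N", (1.45, 6.3, 0.0)), ("HE", "H", (2.3, 6.4, 0.4)),
               ("CZ", "C", (1.45, 7.6, 0.0)),
               ("NH1", "N", (2.5, 8.3, 0.0)), ("HH11", "H", (3.3, 7.9, 0.3)),
               ("HH12", "H", (2.5, 9.3, 0.0)),
               ("NH2", "N", (0.4, 8.3, 0.0)), ("HH21", "H", (-0.45, 7.9, 0.3)),
               ("HH22", "H", (0.4, 9.3, 0.0))]
    arg_b += [("CD", "NE"), ("NE", "HE"), ("NE", "CZ"), ("CZ", "NH1"),
              ("CZ", "NH2"), ("NH1", "HH11"), ("NH1", "HH12"),
              ("NH2", "HH21"), ("NH2", "HH22")]
    t["ARG"] = _bb(arg_sc, arg_b)
    return t


RESIDUE_TEMPLATES: dict[str, dict] = _make_templates()
_CHARGED = ("ASP", "GLU", "LYS", "ARG")
_NEUTRAL = ("GLY", "ALA", "SER")


@dataclass
class TopologyRecipe:
    """Recipe for a protein-like test topology."""

    n_residues: int = 10
    residue_menu: Sequence[str] = _NEUTRAL + _CHARGED
    charged_fraction: float = 0.3
    water_count: int = 6
    include_metal: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.charged_fraction <= 1.0:
            raise ValueError("charged_fraction must lie in [0, 1]")
        if self.n_residues < 1:
            raise ValueError("need at least one residue")
        unknown = [r for r in self.residue_menu if r not in RESIDUE_TEMPLATES]
        if unknown:
            raise ValueError(f"unknown residues in menu: {unknown}")


def make_topology(recipe: TopologyRecipe) -> tuple[MolecularSystem, dict]:
    """Build a peptide chain + metal site + waters with five frames.

    Returns the system and a ground-truth manifest (atom/bond counts, total
    formal charge, residue sequence, and declared core/radius selection cases
    for cross-checking selection pipelines).
    """
    rng = np.random.default_rng(recipe.seed)
    charged_menu = [r for r in recipe.residue_menu if r in _CHARGED]
    neutral_menu = [r for r in recipe.residue_menu if r not in _CHARGED]
    if not neutral_menu:
        neutral_menu = charged_menu

    atoms: list[AtomRecord] = []
    coords: list[np.ndarray] = []
    edges: list[tuple[int, int]] = []
    sequence: list[str] = []

    def add_atom(name, element, xyz, resname, resid, segment):
        idx = len(atoms)
        atoms.append(AtomRecord(
            internal_index=idx, serial=idx + 1, name=name, element=element,
            residue_name=resname, residue_id=resid, segment_id=segment,
            partial_charge=round(float(rng.uniform(-0.5, 0.5)), 3)))
        coords.append(np.asarray(xyz, dtype=float))
        return idx

    prev_c: int | None = None
    for r in range(recipe.n_residues):
        if charged_menu and rng.uniform() < recipe.charged_fraction:
            resname = charged_menu[int(rng.integers(len(charged_menu)))]
        else:
            resname = neutral_menu[int(rng.integers(len(neutral_menu)))]
        sequence.append(resname)
        template = RESIDUE_TEMPLATES[resname]
        origin = np.array([3.8 * r, 0.0, 1.2 * (r % 2)])
        local: dict[str, int] = {}
        for name, element, offset in template["atoms"]:
            jitter = rng.uniform(-0.12, 0.12, size=3)
            local[name] = add_atom(name, element, origin + np.array(offset) + jitter,
                                   resname, r + 1, "PROT")
        for a, b in template["bonds"]:
            edges.append((local[a], local[b]))
        if prev_c is not None:
            edges.append((prev_c, local["N"]))
        prev_c = local["C"]

    resid = recipe.n_residues
    metal_pos = None
    if recipe.include_metal:
        resid += 1
        metal_pos = np.array([3.8 * (recipe.n_residues // 2) + 1.45, 9.5, 0.0])
        add_atom("MG", "Mg", metal_pos, "MG", resid, "ION")

    # waters: up to four coordinate the metal, the rest solvate below the chain
    octahedral = np.array([[2.1, 0, 0], [-2.1, 0, 0], [0, 2.1, 0], [0, 0, 2.1]])
    for w in range(recipe.water_count):
        resid += 1
        if metal_pos is not None and w < 4:
            o_pos = metal_pos + octahedral[w] + rng.uniform(-0.1, 0.1, 3)
        else:
            o_pos = np.array([1.0 + 3.0 * w, -5.5, 1.5]) + rng.uniform(-0.3, 0.3, 3)
        o = add_atom("OH2", "O", o_pos, "HOH", resid, "SOLV")
        h1 = add_atom("H1", "H", o_pos + [0.76, 0.59, 0.0], "HOH", resid, "SOLV")
        h2 = add_atom("H2", "H", o_pos + [-0.76, 0.59, 0.0], "HOH", resid, "SOLV")
        edges.append((o, h1))
        edges.append((o, h2))

    base = np.array(coords)
    # coordinated small displacements along a fixed per-atom direction
    dirs = rng.normal(size=base.shape)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    frames = [Frame(label, base + 0.06 * k * dirs)
              for k, label in enumerate(FRAME_LABELS)]

    system = assemble_system(atoms, BondGraph(edges, len(atoms)), frames)

    # declared selection cases: core = a mid-chain CA (plus the metal when
    # present), scanned over small radii
    mid = recipe.n_residues // 2 + 1
    core = [("PROT", mid, "CA")]
    if recipe.include_metal:
        core.append(("ION", recipe.n_residues + 1, "MG"))
    manifest = {
        "n_atoms": len(atoms),
        "n_bonds": len(set(frozenset(e) for e in edges)),
        "total_formal_charge": system.total_formal_charge(),
        "sequence": sequence,
        "n_waters": recipe.water_count,
        "has_metal": recipe.include_metal,
        "selection_cases": [
            {"core": core, "radius": r, "frames": list(FRAME_LABELS)}
            for r in (0.0, 2.5, 4.0, 6.0)
        ],
    }
    return system, manifest


# ---------------------------------------------------------------------------
# Model Hamiltonians
# ---------------------------------------------------------------------------

@dataclass
class HamiltonianRecipe:
    """Recipe for a toy electronic-structure problem on a 1-D atom chain."""

    n_atoms: int = 4
    basis_per_atom: int = 2
    coupling_decay: float = 1.0
    n_electrons: int | None = None  # default: half filling rounded to even
    seed: int = 0

    def __post_init__(self):
        if self.coupling_decay <= 0:
            raise ValueError("coupling_decay must be > 0")
        n_basis = self.n_atoms * self.basis_per_atom
        if self.n_electrons is None:
            self.n_electrons = 2 * max(1, n_basis // 4)
        if self.n_electrons % 2 or not 0 < self.n_electrons <= 2 * n_basis:
            raise ValueError(f"infeasible electron count {self.n_electrons}")


def make_hamiltonian(recipe: HamiltonianRecipe) -> ModelHamiltonian:
    """SPD overlap + attractive one-electron matrix + PSD separable
    two-electron tensor, all decaying as exp(−distance/coupling_decay) over a
    1-D atom chain with unit spacing."""
    rng = np.random.default_rng(recipe.seed)
    n = recipe.n_atoms * recipe.basis_per_atom
    atom_of = np.repeat(np.arange(recipe.n_atoms), recipe.basis_per_atom)
    dist = np.abs(atom_of[:, None] - atom_of[None, :]).astype(float)
    decay = np.exp(-dist / recipe.coupling_decay)

    # overlap: congruence of a decaying random factor guarantees SPD;
    # renormalized to a unit diagonal
    b = np.eye(n) + 0.15 * rng.normal(size=(n, n)) * decay
    s = b @ b.T
    d_inv = 1.0 / np.sqrt(np.diag(s))
    s = s * d_inv[:, None] * d_inv[None, :]

    # well-separated diagonal levels keep the spectrum gapped at any even
    # filling, so the mean-field problem has a benign, unique minimum
    h_diag = -2.0 + 0.35 * np.arange(n) + 0.05 * rng.uniform(size=n)
    off = -0.2 * decay * (0.5 + 0.5 * rng.uniform(size=(n, n)))
    off = 0.5 * (off + off.T)
    core = np.diag(h_diag) + off - np.diag(np.diag(off))

    # two-electron tensor: a sum of separable PSD terms G⊗G keeps the
    # Coulomb contraction positive and the 8-fold symmetry exact; kept weak
    # relative to the level spacing
    g0 = 0.25 * decay  # Laplacian kernel on the chain: PSD
    eri = np.einsum("mn,ls->mnls", g0, g0)
    for _ in range(2):
        c = 0.08 * rng.normal(size=(n, n)) * decay
        g = c @ c.T
        eri += np.einsum("mn,ls->mnls", g, g)

    return ModelHamiltonian(
        overlap=s, core_h=core, two_electron=eri, atom_of_basis=atom_of,
        n_electrons=int(recipe.n_electrons),
        constant_energy=float(rng.uniform(0.0, 0.5)))


# ---------------------------------------------------------------------------
# Energy-table series with planted convergence
# ---------------------------------------------------------------------------

@dataclass
class EnergySeriesRecipe:
    """Recipe for a QM-size-convergent relative-energy table.

    ``true_profile`` is the asymptotic relative energy per state (kcal/mol,
    reference state 0).  Profiles approach it exponentially in QM size; the
    largest deviation among the tracked barriers and reaction energy crosses
    ``tol_kcal`` exactly between the grid point below ``convergence_size``
    and ``convergence_size`` itself.  Normal/Tight threshold rows carry a
    planted gap of ``laf_delta_kcal`` on the first barrier.
    """

    states: Sequence[str] = FRAME_LABELS
    true_profile: dict[str, float] = field(default_factory=lambda: {
        "RS": 0.0, "TS1": 19.0, "INT": 10.0, "TS2": 14.5, "PS": -6.0})
    size_grid: Sequence[int] = (101, 160, 238, 306, 372, 431, 500)
    convergence_size: int = 431
    noise_sd: float = 0.0
    tol_kcal: float = 1.0
    laf_delta_kcal: float = 0.28
    method: str = "DFT"
    seed: int = 0

    def __post_init__(self):
        if self.convergence_size not in self.size_grid:
            raise ValueError("convergence_size must be on the size grid")
        if list(self.size_grid) != sorted(set(self.size_grid)):
            raise ValueError("size_grid must be strictly increasing")
        missing = [s for s in self.states if s not in self.true_profile]
        if missing:
            raise ValueError(f"true_profile missing states {missing}")


# relative per-state amplitudes of the planted size error; the first barrier
# carries the largest deviation among the tracked quantities
_STATE_AMPLITUDE = {"RS": 0.0, "TS1": 1.0, "INT": 0.2, "TS2": 0.4, "PS": -0.5}


def make_energy_series(recipe: EnergySeriesRecipe) -> tuple[EnergyTable, dict]:
    """Generate the table plus a manifest of the planted ground truth."""
    rng = np.random.default_rng(recipe.seed)
    sizes = list(recipe.size_grid)
    conv = recipe.convergence_size
    k_conv = sizes.index(conv)
    if k_conv == 0:
        # converged from the smallest size on: no crossing to plant
        halflife = max(sizes[1] - sizes[0], 1)
        amp = 0.0
    else:
        halflife = conv - sizes[k_conv - 1]
        g_conv = 1.0
        g_max = 2.0 ** ((conv - sizes[-1]) / halflife)
        amp = 0.95 * recipe.tol_kcal / (g_conv - g_max)

    def g(size: int) -> float:
        return 2.0 ** ((conv - size) / halflife)

    table = EnergyTable()
    reference = recipe.states[0]
    for size in sizes:
        base = -150.0 - 0.002 * size  # absolute offset, cancels in profiles
        for state in recipe.states:
            a = _STATE_AMPLITUDE.get(state, 0.3)
            value_kcal = (recipe.true_profile[state] + amp * a * g(size)
                          + rng.normal(0.0, recipe.noise_sd))
            table.add(
                EnergyKey(state=state, method=recipe.method, basis_cardinal=3,
                          lno_threshold="na", qm_size=size),
                base + value_kcal / HARTREE_TO_KCAL)

    # Normal/Tight threshold rows at the largest size: the Tight values shift
    # the first barrier by laf_delta_kcal
    largest = sizes[-1]
    base = -150.0 - 0.002 * largest
    for state in recipe.states:
        e_n = base + recipe.true_profile[state] / HARTREE_TO_KCAL
        shift = recipe.laf_delta_kcal if state == "TS1" else 0.0
        table.add(EnergyKey(state, "LNO-CC", 3, "Normal", largest), e_n)
        table.add(EnergyKey(state, "LNO-CC", 3, "Tight", largest),
                  e_n + shift / HARTREE_TO_KCAL)

    manifest = {
        "reference_state": reference,
        "true_profile": dict(recipe.true_profile),
        "planted_convergence_size": conv if amp else sizes[0],
        "max_amplitude_kcal": amp,
        "laf_delta_kcal": recipe.laf_delta_kcal,
        "sizes": sizes,
    }
    return table, manifest
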