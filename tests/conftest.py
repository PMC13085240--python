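import numpy as np
import pytest

from lasikit.embedding import LevelSpec
from lasikit.fixtures import (
    HamiltonianRecipe, TopologyRecipe, make_hamiltonian, make_topology,
)


@pytest.fixture(scope="session")
def hl_level():
    return LevelSpec("HL", 1.0)


@pytest.fixture(scope="session")
def ll_level():
    return LevelSpec("LL", 0.25)


@pytest.fixture(scope="session")
def small_hamiltonian():
    """A 4-atom, 8-basis gapped model problem."""
    return make_hamiltonian(HamiltonianRecipe(n_atoms=4, basis_per_atom=2, seed=7))


@pytest.fixture(scope="session")
def peptide_system():
    """A 10-residue chain with charges, metal and waters, plus its manifest."""
    return make_topology(TopologyRecipe(n_residues=10, water_count=6, seed=11))


def build_system(atom_specs, bonds, extra_frames=None, charge_table=None):
    """Hand-built MolecularSystem for micro-fixtures.

    ``atom_specs``: list of (name, element, resname, resid, (x, y, z));
    ``extra_frames``: {label: coordinate array} beyond the base RS frame.
    """
    from lasikit.structure import AtomRecord, BondGraph, Frame, assemble_system

    atoms = [
        AtomRecord(internal_index=k, serial=k + 1, name=name, element=elem,
                   residue_name=res, residue_id=rid, segment_id="X")
        for k, (name, elem, res, rid, _) in enumerate(atom_specs)
    ]
    coords = np.array([xyz for *_, xyz in atom_specs], dtype=float)
    frames = [Frame("RS", coords)]
    for label, c in (extra_frames or {}).items():
        frames.append(Frame(label, np.asarray(c, dtype=float)))
    return assemble_system(atoms, BondGraph(bonds, len(atoms)), frames,
                           charge_table=charge_table)


def write_water_pdb(path):
    """Three-atom water PDB used by the structure-reader tests."""
    lines = [
        "ATOM      1  OH2 HOH     1       0.000   0.000   0.000  1.00  0.00      SOLV O",
        "ATOM      2  H1  HOH     1       0.760   0.590   0.000  1.00  0.00      SOLV H",
        "ATOM      3  H2  HOH     1      -0.760   0.590   0.000  1.00  0.00      SOLV H",
        "END",
    ]
    path.write_text("\n".join(lines) + "\n")
    return path
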