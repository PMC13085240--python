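import numpy as np
import pytest

from lasikit.selector import (
    CutRule, SelectionSpec, SelectionError, exclusion_variant, formal_charge,
    merge_shared_mm_links, nested_series, place_link_atoms,
    prune_small_fragments, radial_core, select_region, topological_extension,
)
from lasikit.fixtures import TopologyRecipe, make_topology

from conftest import build_system
from oracles import brute_force_select


def _methane(center=(0.0, 0.0, 0.0)):
    cx, cy, cz = center
    return [
        ("C1", "C", "LIG", 1, (cx, cy, cz)),
        ("H11", "H", "LIG", 1, (cx + 1.0, cy, cz)),
        ("H12", "H", "LIG", 1, (cx - 1.0, cy, cz)),
    ]


class TestRadialCore:
    def test_zero_radius_pulls_bonded_hydrogens(self):
        system = build_system(_methane(), [(0, 1), (0, 2)])
        spec = SelectionSpec(core_atoms=[1], radius=0.0, frame_labels=["RS"])
        assert radial_core(system, spec) == {0, 1, 2}

    def test_union_over_frames(self):
        # one distant carbon at 3.5 A in RS but 2.5 A in TS1
        atoms = _methane() + [("C2", "C", "LIG", 2, (3.5, 0.0, 0.0))]
        ts1 = np.array([a[-1] for a in atoms], dtype=float)
        ts1[3] = [2.5, 0.0, 0.0]
        system = build_system(atoms, [(0, 1), (0, 2)], extra_frames={"TS1": ts1})
        spec_rs = SelectionSpec(core_atoms=[1], radius=3.0, frame_labels=["RS"])
        spec_both = SelectionSpec(core_atoms=[1], radius=3.0,
                                  frame_labels=["RS", "TS1"])
        assert 3 not in radial_core(system, spec_rs)
        assert 3 in radial_core(system, spec_both)

    def test_hydrogens_never_seed_by_distance(self):
        # hydrogen at 1.5 A from the core, its heavy atom far away
        atoms = _methane() + [
            ("HX", "H", "LIG", 2, (1.5, 0.0, 0.0)),
            ("CX", "C", "LIG", 2, (8.0, 0.0, 0.0)),
        ]
        system = build_system(atoms, [(0, 1), (0, 2), (3, 4)])
        spec = SelectionSpec(core_atoms=[1], radius=2.0, frame_labels=["RS"])
        sel = radial_core(system, spec)
        assert 3 not in sel and 4 not in sel

    def test_unresolvable_core_atom_named(self, peptide_system):
        system, _ = peptide_system
        spec = SelectionSpec(core_atoms=[99999], radius=1.0, frame_labels=["RS"])
        with pytest.raises(SelectionError, match="99999"):
            radial_core(system, spec)

    def test_matches_all_pairs_distance_scan(self, peptide_system):
        system, _ = peptide_system
        core = [system.atoms[10].serial]
        spec = SelectionSpec(core_atoms=core, radius=4.0, frame_labels=["RS"])
        got = radial_core(system, spec)
        # independent exhaustive scan + completion
        xyz = system.frame("RS").coordinates
        c = system.resolve_atom(core[0])
        expect = {c} | {
            i for i in range(system.n_atoms)
            if system.atoms[i].is_heavy and np.linalg.norm(xyz[i] - xyz[c]) <= 4.0}
        while True:
            extra = {
                j for i in expect for j in system.bonds.neighbors(i)
                if j not in expect
                and system.atoms[i].is_hydrogen != system.atoms[j].is_hydrogen}
            if not extra:
                break
            expect |= extra
        assert got == expect


class TestTopologicalExtension:
    def test_whole_component_closure_without_rules(self, peptide_system):
        system, _ = peptide_system
        comp = system.bonds.connected_component(0)
        grown, events = topological_extension(system, {0}, cut_rules=[])
        assert grown == comp
        assert events == []

    def test_seeded_component_is_fixed_point(self, peptide_system):
        system, _ = peptide_system
        comp = system.bonds.connected_component(0)
        grown, events = topological_extension(system, set(comp), cut_rules=[])
        assert grown == comp and events == []

    def test_halts_at_matched_bonds(self):
        # linear C chain CA-CB-CG with hydrogens; rule cuts CA-CB only
        atoms = [
            ("CA", "C", "LIG", 1, (0, 0, 0)),
            ("CB", "C", "LIG", 1, (1.5, 0, 0)),
            ("CG", "C", "LIG", 1, (3.0, 0, 0)),
            ("HB", "H", "LIG", 1, (1.5, 1.0, 0)),
        ]
        system = build_system(atoms, [(0, 1), (1, 2), (1, 3)])
        rules = [CutRule("CA", "CB")]
        grown, events = topological_extension(system, {0}, rules)
        assert grown == {0}
        assert [(e.qm_atom, e.mm_atom) for e in events] == [(0, 1)]
        # from the other side the same rule halts growth toward CA
        grown2, events2 = topological_extension(system, {2}, rules)
        assert grown2 == {1, 2, 3}
        assert [(e.qm_atom, e.mm_atom) for e in events2] == [(1, 0)]

    def test_ring_bonds_never_cut(self):
        # 4-ring of atoms whose names all match the cut rule
        atoms = [(f"CA", "C", "RNG", 1, (np.cos(k * np.pi / 2), np.sin(k * np.pi / 2), 0))
                 for k in range(4)]
        system = build_system(atoms, [(0, 1), (1, 2), (2, 3), (3, 0)])
        grown, events = topological_extension(system, {0}, [CutRule("CA", "CA")])
        assert grown == {0, 1, 2, 3} and events == []


class TestMergeSharedMmLinks:
    def _branched(self):
        # seeds a, b each cut toward shared x; x continues to y (cutable)
        atoms = [
            ("QA", "C", "LIG", 1, (0, 0, 0)),
            ("QB", "C", "LIG", 1, (0, 2, 0)),
            ("CX", "C", "LIG", 1, (1.5, 1, 0)),
            ("CY", "C", "LIG", 1, (3.0, 1, 0)),
        ]
        bonds = [(0, 2), (1, 2), (2, 3)]
        rules = [CutRule("QA", "CX"), CutRule("QB", "CX"), CutRule("CX", "CY")]
        return build_system(atoms, bonds), rules

    def test_shared_mm_atom_absorbed(self):
        system, rules = self._branched()
        region, events = topological_extension(system, {0, 1}, rules)
        assert {e.mm_atom for e in events} == {2}
        region, events, absorbed = merge_shared_mm_links(system, region, events, rules)
        assert absorbed == [2]
        assert region == {0, 1, 2}
        assert [(e.qm_atom, e.mm_atom) for e in events] == [(2, 3)]

    def test_all_distinct_is_fixed_point(self):
        system, rules = self._branched()
        region, events = topological_extension(system, {3}, rules)
        r2, e2, absorbed = merge_shared_mm_links(system, region, events, rules)
        assert absorbed == [] and r2 == region and e2 == events

    def test_cascading_share_converges_in_two_passes(self):
        # absorbing x creates a second event on y, already cut from z
        atoms = [
            ("QA", "C", "LIG", 1, (0, 0, 0)),
            ("QB", "C", "LIG", 1, (0, 2, 0)),
            ("QZ", "C", "LIG", 1, (4, 2, 0)),
            ("CX", "C", "LIG", 1, (1.5, 1, 0)),
            ("CY", "C", "LIG", 1, (3.0, 1, 0)),
            ("CT", "C", "LIG", 1, (4.5, 0, 0)),
        ]
        bonds = [(0, 3), (1, 3), (3, 4), (2, 4), (4, 5)]
        rules = [CutRule("QA", "CX"), CutRule("QB", "CX"),
                 CutRule("CX", "CY"), CutRule("QZ", "CY")]
        system = build_system(atoms, bonds)
        region, events = topological_extension(system, {0, 1, 2}, rules)
        region, events, absorbed = merge_shared_mm_links(system, region, events, rules)
        assert absorbed == [3, 4]        # x first, then y
        assert region == {0, 1, 2, 3, 4, 5}  # y pulls in its terminal neighbor
        assert events == []
        mm = [e.mm_atom for e in events]
        assert len(mm) == len(set(mm))


class TestPruneSmallFragments:
    def _with_island(self, island_atoms, island_bonds):
        base = _methane()
        n0 = len(base)
        atoms = base + island_atoms
        bonds = [(0, 1), (0, 2)] + [(i + n0, j + n0) for i, j in island_bonds]
        return build_system(atoms, bonds), n0

    def test_ethyl_island_removed(self):
        island = [
            ("C1", "C", "ETH", 2, (10, 0, 0)), ("C2", "C", "ETH", 2, (11.5, 0, 0)),
            ("H1", "H", "ETH", 2, (10, 1, 0)), ("H2", "H", "ETH", 2, (11.5, 1, 0)),
        ]
        system, n0 = self._with_island(island, [(0, 1), (0, 2), (1, 3)])
        region = set(range(system.n_atoms))
        kept, events, removed = prune_small_fragments(system, region, [], {0})
        assert kept == set(range(n0))
        assert removed == [set(range(n0, n0 + 4))]

    def test_propyl_island_retained(self):
        island = [
            ("C1", "C", "PRP", 2, (10, 0, 0)), ("C2", "C", "PRP", 2, (11.5, 0, 0)),
            ("C3", "C", "PRP", 2, (13.0, 0, 0)),
        ]
        system, _ = self._with_island(island, [(0, 1), (1, 2)])
        region = set(range(system.n_atoms))
        kept, _, removed = prune_small_fragments(system, region, [], {0})
        assert kept == region and removed == []

    def test_island_with_oxygen_retained(self):
        island = [
            ("C1", "C", "ETO", 2, (10, 0, 0)), ("O1", "O", "ETO", 2, (11.4, 0, 0)),
        ]
        system, _ = self._with_island(island, [(0, 1)])
        region = set(range(system.n_atoms))
        kept, _, removed = prune_small_fragments(system, region, [], {0})
        assert kept == region and removed == []

    def test_missing_core_is_an_error(self):
        system, _ = self._with_island([("C1", "C", "ETH", 2, (10, 0, 0))], [])
        with pytest.raises(SelectionError, match="core"):
            prune_small_fragments(system, {3}, [], {0})


class TestPlaceLinkAtoms:
    def _two_atoms(self, qm_xyz, mm_xyz):
        atoms = [("CQ", "C", "LIG", 1, qm_xyz), ("CM", "C", "LIG", 1, mm_xyz)]
        system = build_system(atoms, [(0, 1)])
        _, events = topological_extension(system, {0}, [CutRule("CQ", "CM")])
        return system, events

    def test_collinear_placement(self):
        system, events = self._two_atoms((0, 0, 0), (2, 0, 0))
        placed = place_link_atoms(system, events, "RS")
        np.testing.assert_allclose(placed[0][2], [1.09, 0, 0], atol=1e-12)

    def test_axis_case(self):
        system, events = self._two_atoms((1, 1, 1), (1, 1, 3))
        placed = place_link_atoms(system, events, "RS")
        np.testing.assert_allclose(placed[0][2], [1, 1, 2.09], atol=1e-12)

    def test_distance_equals_d_link(self, peptide_system):
        system, _ = peptide_system
        spec = SelectionSpec(core_atoms=[system.atoms[20].serial], radius=3.0,
                             frame_labels=["RS", "PS"])
        region = select_region(system, spec)
        xyz = system.frame("PS").coordinates
        for qm, _, pos in region.link_atoms["PS"]:
            assert np.linalg.norm(pos - xyz[qm]) == pytest.approx(1.09, abs=1e-9)

    def test_coincident_atoms_rejected(self):
        system, events = self._two_atoms((0, 0, 0), (0, 0, 0))
        with pytest.raises(SelectionError, match="coincident"):
            place_link_atoms(system, events, "RS")


class TestFormalCharge:
    def test_whole_asp_plus_lys_cancels(self):
        system, _ = make_topology(TopologyRecipe(
            n_residues=2, residue_menu=("ASP", "LYS"), charged_fraction=1.0,
            water_count=0, include_metal=False, seed=0))
        names = [r[2] for r in system.residue_instances()]
        assert sorted(names) == ["ASP", "LYS"]  # seed chosen to draw one of each
        assert formal_charge(system, set(range(system.n_atoms))) == 0

    def test_metal_and_nucleotide_template_sum(self):
        atoms = [
            ("MG", "Mg", "MG", 1, (0, 0, 0)),
            ("PG", "P", "GTP", 2, (3, 0, 0)),
            ("O1G", "O", "GTP", 2, (4, 1, 0)),
        ]
        system = build_system(atoms, [(1, 2)])
        assert formal_charge(system, {0, 1, 2}) == -2

    def test_partial_residue_counts_by_charge_center(self, recwarn):
        system, _ = make_topology(TopologyRecipe(
            n_residues=1, residue_menu=("ASP",), charged_fraction=1.0,
            water_count=0, include_metal=False, seed=0))
        sidechain = {i for i in range(system.n_atoms)
                     if system.atoms[i].name in
                     ("CB", "HB1", "HB2", "CG", "OD1", "OD2")}
        assert formal_charge(system, sidechain) == -1
        assert any("partially selected" in str(w.message) for w in recwarn.list)
        # without the carboxylate carbon the charge is not counted
        no_center = {i for i in sidechain if system.atoms[i].name != "CG"}
        assert formal_charge(system, no_center) == 0


class TestSelectRegion:
    def test_matches_bruteforce_pipeline(self, peptide_system):
        system, manifest = peptide_system
        for case in manifest["selection_cases"]:
            spec = SelectionSpec(core_atoms=case["core"], radius=case["radius"],
                                 frame_labels=case["frames"])
            region = select_region(system, spec)
            atoms, cuts, charge = brute_force_select(system, spec)
            assert set(region.atom_indices) == atoms
            assert {(e.qm_atom, e.mm_atom) for e in region.cut_events} == cuts
            assert region.formal_charge == charge

    def test_region_grows_with_radius(self, peptide_system):
        system, manifest = peptide_system
        core = manifest["selection_cases"][0]["core"]
        prev = frozenset()
        for r in (0.0, 2.0, 4.0, 6.0):
            spec = SelectionSpec(core_atoms=core, radius=r, frame_labels=["RS"])
            sel = select_region(system, spec).atom_indices
            assert prev <= sel
            prev = sel

    def test_multi_frame_region_contains_single_frame_region(self, peptide_system):
        system, manifest = peptide_system
        core = manifest["selection_cases"][0]["core"]
        one = select_region(system, SelectionSpec(
            core_atoms=core, radius=3.0, frame_labels=["RS"]))
        all_ = select_region(system, SelectionSpec(
            core_atoms=core, radius=3.0,
            frame_labels=["RS", "TS1", "INT", "TS2", "PS"]))
        assert one.atom_indices <= all_.atom_indices

    def test_provenance_is_deterministic(self, peptide_system):
        system, manifest = peptide_system
        spec = SelectionSpec(core_atoms=manifest["selection_cases"][1]["core"],
                             radius=2.5, frame_labels=["RS", "TS2"])
        r1 = select_region(system, spec)
        r2 = select_region(system, spec)
        assert r1.provenance == r2.provenance
        assert r1.atom_indices == r2.atom_indices

    def test_no_shared_mm_atoms_and_closure(self, peptide_system):
        system, _ = peptide_system
        spec = SelectionSpec(core_atoms=[system.atoms[30].serial], radius=3.5,
                             frame_labels=["RS"])
        region = select_region(system, spec)
        mm = [e.mm_atom for e in region.cut_events]
        assert len(mm) == len(set(mm))
        boundary = {(i, j) for i in region.atom_indices
                    for j in system.bonds.neighbors(i)
                    if j not in region.atom_indices}
        assert boundary == {(e.qm_atom, e.mm_atom) for e in region.cut_events}


class TestNestedSeriesAndExclusion:
    def test_series_sizes_non_decreasing(self, peptide_system):
        system, manifest = peptide_system
        spec = SelectionSpec(core_atoms=manifest["selection_cases"][0]["core"],
                             radius=1.0, frame_labels=["RS"])
        regions = nested_series(system, spec, (2.0, 4.0, 6.0))
        sizes = [r.n_atoms for r in regions]
        assert sizes == sorted(sizes)

    def test_single_radius_equals_select_region(self, peptide_system):
        system, manifest = peptide_system
        core = manifest["selection_cases"][0]["core"]
        spec = SelectionSpec(core_atoms=core, radius=3.0, frame_labels=["RS"])
        series = nested_series(system, spec, (3.0,))
        assert len(series) == 1
        assert series[0].atom_indices == select_region(system, spec).atom_indices

    def test_bounds_zero_and_huge_radius(self, peptide_system):
        system, manifest = peptide_system
        core = manifest["selection_cases"][0]["core"]
        spec = SelectionSpec(core_atoms=core, radius=0.0, frame_labels=["RS"])
        small, big = nested_series(system, spec, (0.0, 1e6))
        # the huge radius swallows every atom of the system
        assert big.atom_indices == frozenset(range(system.n_atoms))
        assert small.atom_indices <= big.atom_indices

    def test_non_increasing_radii_rejected(self, peptide_system):
        system, manifest = peptide_system
        spec = SelectionSpec(core_atoms=manifest["selection_cases"][0]["core"],
                             radius=1.0, frame_labels=["RS"])
        with pytest.raises(SelectionError, match="increasing"):
            nested_series(system, spec, (3.0, 3.0))

    def test_exclude_disconnected_water(self, peptide_system):
        system, manifest = peptide_system
        core = manifest["selection_cases"][0]["core"]
        spec = SelectionSpec(core_atoms=core, radius=6.0, frame_labels=["RS"])
        region = select_region(system, spec)
        water = next(
            set(system.residue_atoms(seg, rid))
            for seg, rid, rn in system.residue_instances()
            if rn == "HOH" and set(system.residue_atoms(seg, rid)) <= region.atom_indices)
        out = exclusion_variant(region, system, water, spec)
        assert out.atom_indices == region.atom_indices - water
        assert out.cut_events == region.cut_events

    def test_exclude_bonded_sidechain_adds_cut(self):
        system, _ = make_topology(TopologyRecipe(
            n_residues=3, residue_menu=("LYS",), charged_fraction=1.0,
            water_count=0, include_metal=False, seed=2))
        core = [("PROT", 2, "CA")]
        spec = SelectionSpec(core_atoms=core, radius=1e6, frame_labels=["RS"])
        region = select_region(system, spec)
        assert region.cut_events == []
        sidechain_names = ("CG", "HG1", "HG2", "CD", "HD1", "HD2",
                          "CE", "HE1", "HE2", "NZ", "HZ1", "HZ2", "HZ3")
        moiety = {i for i in system.residue_atoms("PROT", 2)
                  if system.atoms[i].name in sidechain_names}
        out = exclusion_variant(region, system, moiety, spec)
        assert out.atom_indices == region.atom_indices - moiety
        pairs = [(system.atoms[e.qm_atom].name, system.atoms[e.mm_atom].name)
                 for e in out.cut_events]
        assert pairs == [("CB", "CG")]

    def test_exclude_empty_set_is_identity(self, peptide_system):
        system, manifest = peptide_system
        spec = SelectionSpec(core_atoms=manifest["selection_cases"][0]["core"],
                             radius=3.0, frame_labels=["RS"])
        region = select_region(system, spec)
        assert exclusion_variant(region, system, set(), spec) is region

    def test_excluding_core_atom_rejected(self, peptide_system):
        system, manifest = peptide_system
        spec = SelectionSpec(core_atoms=manifest["selection_cases"][0]["core"],
                             radius=3.0, frame_labels=["RS"])
        region = select_region(system, spec)
        core_atom = next(iter(region.core_indices))
        with pytest.raises(SelectionError, match="core"):
            exclusion_variant(region, system, {core_atom}, spec)
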