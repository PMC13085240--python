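"""Independent reference implementations used only to cross-check the
package.

Everything here is deliberately written with different algorithms and data
structures than the library: exhaustive all-pairs scans instead of vectorized
seeding, repeat-until-stable set sweeps instead of frontier BFS, bridge-based
ring detection instead of cycle bases, and plain damped fixed-point SCF with
quadruple-loop energy evaluation instead of DIIS + einsum.
"""

from __future__ import annotations

import fnmatch
import math

import networkx as nx
import numpy as np


# ---------------------------------------------------------------------------
# Brute-force QM selection pipeline
# ---------------------------------------------------------------------------

def _ring_bonds_by_bridges(system) -> set[frozenset]:
    """An edge lies on a ring iff it is not a bridge."""
    g = system.bonds.to_networkx()
    bridges = {frozenset(e) for e in nx.bridges(g)}
    return {e for e in system.bonds.edges if e not in bridges}


def _rule_matches(rule, a, b) -> bool:
    def oriented(x, y):
        if rule.residue is not None and not (
                fnmatch.fnmatch(x.residue_name, rule.residue)
                or fnmatch.fnmatch(y.residue_name, rule.residue)):
            return False
        return (fnmatch.fnmatch(x.name, rule.qm_name)
                and fnmatch.fnmatch(y.name, rule.mm_name))
    return oriented(a, b) or oriented(b, a)


def _cutable(system, i, j, rules, ring_bonds) -> bool:
    if frozenset((i, j)) in ring_bonds:
        return False
    return any(_rule_matches(r, system.atoms[i], system.atoms[j]) for r in rules)


def brute_force_select(system, spec):
    """Re-derive a full QM selection: returns (atom set, cut pairs, charge).

    Cut pairs are (qm_atom, mm_atom) tuples.
    """
    ring_bonds = _ring_bonds_by_bridges(system)
    core = [system.resolve_atom(c) for c in spec.core_atoms]

    # radial seeding: exhaustive distance scan per frame, heavy atoms only
    selected = set(core)
    for label in spec.frame_labels:
        xyz = system.frame(label).coordinates
        for i in range(system.n_atoms):
            if system.atoms[i].is_hydrogen:
                continue
            for c in core:
                if math.dist(xyz[i], xyz[c]) <= spec.radius:
                    selected.add(i)
                    break

    # hydrogen completion, repeat until stable
    while True:
        extra = set()
        for i in selected:
            for j in system.bonds.neighbors(i):
                if j in selected:
                    continue
                hi = system.atoms[i].is_hydrogen
                hj = system.atoms[j].is_hydrogen
                if (not hi and hj) or (hi and not hj):
                    extra.add(j)
        if not extra:
            break
        selected |= extra

    def extend(region):
        region = set(region)
        while True:
            grow = set()
            for i in region:
                for j in system.bonds.neighbors(i):
                    if j not in region and not _cutable(system, i, j,
                                                        spec.cut_rules, ring_bonds):
                        grow.add(j)
            if not grow:
                return region
            region |= grow

    def boundary_pairs(region):
        pairs = set()
        for i in region:
            for j in system.bonds.neighbors(i):
                if j not in region:
                    pairs.add((i, j))
        return pairs

    region = extend(selected)
    cuts = boundary_pairs(region)

    # absorb shared MM-side atoms until stable
    if spec.merge_shared_mm_atoms:
        while True:
            mm_counts = {}
            for _, m in cuts:
                mm_counts[m] = mm_counts.get(m, 0) + 1
            shared = {m for m, c in mm_counts.items() if c > 1}
            if not shared:
                break
            region = extend(region | shared)
            cuts = boundary_pairs(region)

    # prune aliphatic islands away from the core
    g = nx.Graph()
    g.add_nodes_from(region)
    for i in region:
        for j in system.bonds.neighbors(i):
            if j in region:
                g.add_edge(i, j)
    for comp in list(nx.connected_components(g)):
        if comp & set(core):
            continue
        carbons = [i for i in comp if system.atoms[i].element == "C"]
        others = [i for i in comp if system.atoms[i].element not in ("C", "H")]
        if not others and len(carbons) <= spec.prune_fragment_max_carbons:
            region -= comp
            cuts = {(q, m) for (q, m) in cuts if q not in comp}

    # formal charge from templates, charge-center rule for partial residues
    charge = 0
    for seg, rid, rname in system.residue_instances():
        q = system.formal_charge_of_residue(seg, rid, rname)
        if q == 0:
            continue
        members = set(system.residue_atoms(seg, rid))
        if members <= region:
            charge += q
        elif members & region:
            center = system.charge_centers.get(rname)
            if any(system.atoms[i].name == center for i in members & region):
                charge += q
    return region, cuts, charge


# ---------------------------------------------------------------------------
# Reference electronic-structure evaluation
# ---------------------------------------------------------------------------

def loop_energy(h, exchange_fraction, d) -> float:
    """Textbook closed-shell energy with explicit quadruple loops."""
    n = h.n_basis
    e = h.constant_energy
    for m in range(n):
        for v in range(n):
            e += d[m, v] * h.core_h[m, v]
    for m in range(n):
        for v in range(n):
            for l in range(n):
                for s in range(n):
                    e += 0.5 * d[m, v] * h.two_electron[m, v, l, s] * d[l, s]
                    e -= exchange_fraction * 0.25 * d[m, v] \
                        * h.two_electron[m, l, v, s] * d[l, s]
    return e


def damped_scf(h, exchange_fraction, mix=0.8, max_iter=20000, tol=1e-11):
    """Plain damped fixed-point SCF; returns (density, energy)."""
    s = h.overlap
    n_occ = h.n_electrons // 2
    import scipy.linalg
    _, c = scipy.linalg.eigh(h.core_h, s)
    d = 2.0 * c[:, :n_occ] @ c[:, :n_occ].T
    for _ in range(max_iter):
        j = np.einsum("mnls,ls->mn", h.two_electron, d)
        k = np.einsum("mlns,ls->mn", h.two_electron, d)
        f = h.core_h + j - exchange_fraction * 0.5 * k
        _, c = scipy.linalg.eigh(f, s)
        d_new = 2.0 * c[:, :n_occ] @ c[:, :n_occ].T
        d_next = (1 - mix) * d_new + mix * d
        if np.abs(d_next - d).max() < tol:
            d = d_new
            break
        d = d_next
    j = np.einsum("mnls,ls->mn", h.two_electron, d)
    k = np.einsum("mlns,ls->mn", h.two_electron, d)
    e = h.constant_energy + np.sum(d * h.core_h) + 0.5 * np.sum(d * j) \
        - exchange_fraction * 0.25 * np.sum(d * k)
    return d, float(e)
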