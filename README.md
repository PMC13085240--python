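# lasikit

Building blocks for multiscale (QM/MM and QM-in-QM) enzyme reaction models:
QM-region selection over bonded topologies, composite reaction-energy
assembly with basis-set and local-correlation extrapolations, and a
desk-scale projection-based (Huzinaga) quantum-embedding engine exercised on
toy model Hamiltonians.

## Who this is for

Computational enzymologists setting up QM/MM models face three coupled
choices: which atoms go into the QM region, which level of theory pays for
itself, and how to stitch cheap and expensive methods into one defensible
energy. `lasikit` implements the bookkeeping and the algorithms behind those
choices:

* **QM-region selection** (`lasikit.selector`) — a topologically extended,
  distance-based algorithm: a radial core around user-declared reactive
  atoms (union over several structures along the reaction path, hydrogens
  completed), grown along covalent bonds until every boundary bond is an
  apolar C–C bond from an extensible cut-rule table. Link atoms are
  deduplicated (two cuts sharing an MM atom force its absorption), small
  aliphatic islands are pruned, and the formal charge of the selection is
  tracked from residue templates (ASP⁻, LYS⁺, GTP⁴⁻, Mg²⁺, ...).
* **Composite energies** (`lasikit.energies`) — relative-energy profiles over
  stationary points (RS, TS1, INT, TS2, PS), two-point CBS extrapolations
  (inverse-cubic correlation, exponential mean-field), the
  local-approximation-free (LAF) limit with its ±0.5·(E_Tight − E_Normal)
  uncertainty, the composite reference

  `E(N-T, CBS) = E(Normal, CBS) + E(N-T, X) − E(Normal, X)`,

  coupled-cluster corrections at reduced QM size, and the free-energy
  assembly

  `ΔG = ΔE_DFT(E) + ΔΔE_CC − T·ΔS_DFT(S)`,

  plus mean-absolute-error scoring and QM-size convergence reports with a
  strict "inside the band from here on" criterion.
* **Quantum embedding** (`lasikit.embedding`) — closed-shell SCF on explicit
  model Hamiltonians at two levels that differ in exact-exchange fraction
  (a stand-in for hybrid vs. GGA DFT), Pipek–Mezey-style localization,
  Mulliken active-orbital selection (threshold 0.3), a frozen-environment
  Huzinaga-projected SCF, the first-order-corrected embedding energy

  `E = E_LL[D] − E_LL[Dᴬ] + E_HL[D̃ᴬ] + Tr{(D̃ᴬ − Dᴬ)·(F_LL[D] − F_LL[Dᴬ])}`,

  LESS-style AO truncation (threshold 1e-4), and a subtractive ONIOM
  comparator with link-atom-capped subsystems.
* **Synthetic fixtures** (`lasikit.fixtures`) — seeded generators of
  protein-like topologies (charged sidechains, a Mg²⁺ site, waters, five
  stationary-point frames), gapped model Hamiltonians with
  distance-decaying couplings, and energy tables with a planted 1 kcal/mol
  convergence crossing.

Real electronic-structure calculations (DFT, coupled cluster) are out of
scope: energies enter as tables, and the embedding engine runs on toy
Hamiltonians small enough to verify against brute force.

## Worked example

```python
from lasikit.fixtures import TopologyRecipe, make_topology
from lasikit.selector import SelectionSpec, select_region
from lasikit.energies import LasiComponents, cc_correction, lasi_assemble

# 1. select a QM region on a synthetic active site, union over two frames
system, manifest = make_topology(TopologyRecipe(n_residues=8, seed=3))
spec = SelectionSpec(core_atoms=manifest["selection_cases"][1]["core"],
                     radius=2.5, frame_labels=["RS", "TS1"])
region = select_region(system, spec)
print(region.n_atoms, region.n_links, region.formal_charge)
# -> 68 4 2    (68 QM atoms, 4 cut bonds, formal charge +2)

# 2. assemble a composite barrier-height difference (kcal/mol):
#    a large-QM DFT value of 3.65 plus a CC correction computed at 238 atoms
dd = cc_correction(4.13, 3.15, qm_size_cc=238, qm_size_dft=238)
print(round(lasi_assemble(LasiComponents(3.65, dd, 0.0)), 2))
# -> 4.63
```

The selection above cut the chain at four Cα–Cβ-class bonds and kept the
Mg²⁺ ion (hence the +2); the composite line shows how a coupled-cluster
correction evaluated at a reduced QM size (0.98 kcal/mol here) refines a
converged-size DFT barrier difference.

A command-line interface mirrors the library:

```bash
lasikit fixtures topology --out demo/
lasikit select --pdb RS=demo/RS.pdb --pdb TS1=demo/TS1.pdb \
    --topology demo/topology.json --config select.json --out region
lasikit energies --table energies.csv --method DFT --report report.json
lasikit embed-demo --model model.json --active-atoms 0,1 --out embed.json
```

## Documentation

See `docs/methods.md` for the models, the numerical choices, what the
synthetic generators do and do not emulate, and known limitations.
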