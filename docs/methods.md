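# Methods

This note documents the models implemented in `lasikit`, the numerical
choices behind them, what the synthetic generators emulate, and the limits
of what the tests demonstrate.

## Scope and data flow

The package covers the *computable* side of multiscale enzyme-model
building. Quantities that require real electronic-structure programs —
absolute DFT or coupled-cluster energies, densities, gradients — enter as
inputs: long-format CSV energy tables keyed by (stationary point, method,
basis cardinal, local-correlation threshold, QM size), and explicit model
Hamiltonians (overlap, one-electron matrix, two-electron tensor, atom
assignment) for the embedding engine. Everything downstream of those inputs
is computed here and is testable against independent oracles at desk scale.

## QM-region selection

The selection algorithm grows a chemically meaningful QM region from a
small declared core:

1. **Radial seeding.** All heavy atoms within a radius of any core atom are
   selected. Distances are evaluated in every requested coordinate frame
   and the union is taken, so a residue that approaches the reactive center
   only in, say, the product state is still captured. Hydrogens never seed
   by distance; they are completed afterwards (every hydrogen bonded to a
   selected heavy atom, and the heavy atom behind any selected hydrogen).
2. **Topological extension.** The seed set grows along covalent bonds until
   every boundary bond matches a *cut rule*. The default rule table names
   apolar sidechain C–C single bonds of standard amino acids (Cα–Cβ and the
   aliphatic continuations in LYS/ARG/GLU/GLN/MET/ILE/VAL/THR). Amide C–N
   bonds and bonds involving non-carbon heavy atoms are simply absent from
   the table; ring bonds are protected structurally, by computing cycle
   membership from the bond graph, so a matching name pair inside a ring is
   still crossed rather than cut. Traversal is breadth-first in ascending
   internal index, making the result and the provenance log deterministic.
3. **Link-atom deduplication.** If two cut events share the same MM-side
   atom, the two hydrogen caps would nearly coincide; the shared atom is
   absorbed into the region and extension re-runs, to a fixed point.
4. **Aliphatic pruning.** Islands of at most two carbons (plus their
   hydrogens) that end up disconnected from the core inside the selection
   are dropped together with their cut events. Pruning runs before link
   placement, so generated caps are never counted as island members.
5. **Accounting.** Hydrogen link atoms are placed on the QM→MM bond vector
   at 1.09 Å (a standard C–H length; configurable). The formal charge of
   the selection is summed from an editable residue-template table (ASP −1,
   GLU −1, LYS +1, ARG +1, GTP −4, Mg²⁺ +2, ...) with per-residue
   overrides; a partially selected charged group raises a warning and
   counts only if its designated charge-center atom (e.g. the ASP
   carboxylate carbon) is inside.

Exclusion variants (`exclusion_variant`) support residue-exclusion scans:
the moiety is removed, bonds into it become explicit cut events regardless
of the rule table, the remaining boundary is re-validated, and merging and
pruning re-run. Merging never re-absorbs an excluded atom, so two exclusion
cuts that share an excluded MM atom are retained as-is — the invariant
"no shared MM atoms" applies to rule-based cuts.

The whole pipeline is validated against an independently coded brute-force
implementation (exhaustive distance scans, repeat-until-stable set growth,
bridge-based ring detection) on ~100 randomized systems per run.

## Composite energies

Internal unit is hartree; every report is kcal/mol (conversion constant
627.5094740631 kcal/mol per hartree).

* **CBS extrapolation.** Correlation energies follow the two-point
  inverse-cubic model E(X) = E_CBS + A·X⁻³; mean-field energies the
  two-point exponential E(X) = E_CBS + A·e^(−αX) with α = 1.63 by default
  (configurable — the exponential form is this package's choice of
  mean-field extrapolant and is deliberately pluggable). Both recover
  planted asymptotes of model-exact series to machine precision.
* **Local-correlation (LAF) limit.** From Normal- and Tight-threshold
  energies, the extrapolant is E_T + c·(E_T − E_N) with c = 0.5 by default;
  the associated uncertainty half-width is fixed at |0.5·(E_T − E_N)|
  independent of c. Only the half-width definition is anchored in published
  usage; the extrapolant coefficient is exposed because variants exist.
* **Composite threshold/basis reference.**
  E(N-T, CBS) = E(Normal, CBS) + E(N-T, X) − E(Normal, X): the
  basis-set limit is taken at the cheap threshold and the threshold
  extrapolation at the finite basis X, exploiting that the two effects are
  nearly additive. When Tight = Normal this collapses to the Normal CBS
  value exactly.
* **Free-energy assembly.** ΔG = ΔE_DFT(E) + ΔΔE_CC − T·ΔS_DFT(S). The
  coupled-cluster correction ΔΔE_CC = ΔE_CC − ΔE_DFT is computed from two
  relative energies at the same *reduced* QM size (mismatched sizes are an
  error); its justification is the faster size-convergence of the
  CC-minus-DFT difference compared to the relative energies themselves.
  The entropic term is an external input (0 for electronic-only profiles).
* **Uncertainty propagation** combines half-widths in quadrature under a
  declared independence assumption; a worst-case linear mode is available.
* **Convergence reports.** For each tracked quantity (both barriers, their
  difference, the reaction energy) the report finds the smallest QM size
  from which the deviation against the largest-size profile stays within
  tolerance (1 kcal/mol default) *for that size and all larger ones* — a
  dip into the band followed by an exit does not count. Non-monotonic
  approach is flagged per quantity. MAE scoring excludes the reference
  state, whose relative energy is identically zero and would only dilute
  the mean.

## Toy embedding engine

The embedding engine runs on explicit model Hamiltonians rather than real
molecules, which keeps every limit checkable by brute force.

* **Levels.** A level is a Hartree–Fock-like functional
  E = E_const + Tr(Dh) + ½Tr(D·J[D]) − f·¼Tr(D·K[D]) parameterized by its
  exact-exchange fraction f. The default pair f = 1.0 (high level) vs
  f = 0.25 (low level) mimics the hybrid-versus-semilocal gap that
  motivates embedding in real enzyme work. Densities carry the
  closed-shell factor 2: Tr(DS) equals the electron count.
* **SCF.** Generalized eigensolves (`scipy.linalg.eigh`) with DIIS,
  convergence at max|FDS − SDF| ≤ 1e-10, and a deterministic fallback
  schedule of level shifting and Fock damping for small-gap cases (the
  shift vanishes on the occupied block, so every attempt targets the same
  fixed point). Two initial guesses are tried — core Hamiltonian and the
  converged exchange-free mean field — and the lowest-energy converged
  solution wins, guarding against landing on a higher self-consistent
  solution in bistable high-exchange cases.
* **Localization and selection.** Occupied orbitals are localized by
  Jacobi 2×2 sweeps maximizing the sum of squared per-atom Mulliken
  populations (the Pipek–Mezey objective); the occupied density is
  invariant and the objective is monotone non-decreasing. Active orbitals
  are those with summed Mulliken population ≥ 0.3 on the active atoms.
* **Huzinaga-projected SCF.** With the environment density D_B frozen, the
  active orbitals are re-optimized at the high level under
  F_eff = F − ½(F·D_B·S + S·D_B·F). The environment span is exactly
  invariant under this operator, so its eigenvectors split into environment
  and S-orthogonal-complement blocks; aufbau filling within the complement
  yields Tr(D̃ᴬ·S·D_B·S) = 0 to machine precision. An empty environment
  reduces to a plain high-level SCF and is routed through the standard
  solver.
* **Embedded energy.** E = E_LL[D] − E_LL[Dᴬ] + E_HL[D̃ᴬ] +
  Tr{(D̃ᴬ − Dᴬ)·V_emb} with V_emb = F_LL[D] − F_LL[Dᴬ], which equals the
  low-level environment-plus-interaction potential exactly (Fock matrices
  are affine in the density). The first-order term is the Taylor expansion
  of the low-level environment terms around the unrelaxed active density;
  because the toy functional is quadratic, that expansion is *exact* here:
  the corrected energy coincides with the embedding energy re-evaluated at
  the relaxed active density. Exact limits hold by construction and are
  enforced at 1e-8: identical levels reproduce the full low-level energy;
  an all-active partition reproduces the full high-level energy.
* **AO truncation.** Basis functions are retained if they sit on an active
  atom or contribute Mulliken weight > 1e-4 to any active orbital; the
  high-level embedded problem is restricted to the retained block, the
  frozen environment quantities are restricted alongside, and the relaxed
  active density is padded back for the energy assembly. On
  distance-decaying fixtures the induced error on relative energies stays
  far below 1e-3 and vanishes as the threshold goes to zero. Auxiliary
  (density-fitting) basis truncation has no analogue in the toy model and
  is not implemented.
* **ONIOM comparator.** E = E_LL(full) − E_LL(capped) + E_HL(capped) on a
  link-atom-capped restriction of the Hamiltonian to the active atoms: one
  cap basis function per severed strong one-electron coupling
  (|h_μν| ≥ 0.05 by default), orthogonal to everything, with a diagonal
  term −cap_strength and a −cap_strength/2 coupling to the severed partner
  — inert at zero strength. The capped electron count defaults to twice
  the number of occupied localized orbitals assigned (by maximum Mulliken
  population) to active atoms. With identical levels the subtractive
  scheme returns the full low-level energy identically.

## Synthetic generators

All generators are pure functions of their recipe, including the seed; one
`numpy` Generator per call, no global state. Scales are capped (topologies
≤ a few hundred atoms, Hamiltonians ≤ 16 basis functions) so the suite runs
in seconds.

* **Topologies** emulate the features a selector must negotiate: a peptide
  chain drawn from templated residues (neutral and explicitly charged, with
  hydrogens and schematic local geometry), a divalent metal ion coordinated
  by up to four waters, bulk waters, and five stationary-point frames
  displaced along fixed per-atom directions (≤ ~0.25 Å). They do **not**
  reproduce real stereochemistry, force-field parameters, secondary
  structure, or any particular enzyme; passing selection tests demonstrates
  graph-and-geometry correctness of the algorithm, not biochemical
  relevance of a particular selection.
* **Model Hamiltonians** place atoms on a unit-spaced 1-D chain; overlap is
  a congruence of a decaying random factor (guaranteed SPD, unit diagonal),
  one-electron couplings decay as exp(−d/λ), and the two-electron tensor is
  a sum of separable PSD terms G⊗G (exact 8-fold symmetry, positive
  Coulomb contraction). The one-electron diagonal ascends along the chain
  so the spectrum is gapped at any even filling — a deliberate
  design choice that keeps the mean-field problem well-posed, as the
  generator's contract requires every seeded instance to converge. The
  ascending diagonal also means low-lying orbitals localize on low-index
  atoms, which tests exploit when constructing genuine environments. These
  models have no geometry, no nuclei, and no basis-set physics; embedding
  results on them validate the algebra of the method, not its accuracy on
  molecules.
* **Energy series** approach a declared asymptotic profile exponentially in
  QM size. The per-state deviation amplitudes are fixed ratios with the
  first barrier largest; the decay half-length equals the gap between the
  planted convergence size and the previous grid point, and the amplitude
  is scaled so the largest tracked deviation is 0.95× tolerance at the
  planted size and ~1.9× at the grid point below — the crossing lands
  exactly where declared, with headroom against floating-point noise.
  Normal/Tight threshold rows carry a planted 0.28 kcal/mol gap on the
  first barrier, which reproduces the ±0.14 kcal/mol uncertainty
  half-width.

## Numerical choices and degenerate inputs

* Tie-breaks everywhere are by ascending internal atom index; provenance
  logs are byte-identical across repeated runs.
* Zero-radius selections are valid (core closure); an empty cut-rule table
  absorbs whole connected components; excluding an empty moiety returns
  the region unchanged; a selection that loses its core atoms is an error.
* Coincident QM/MM coordinates make link-atom placement ill-defined and
  raise an error rather than guessing a direction.
* Energy tables reject duplicate keys, non-finite values and unknown units;
  profiles list the exact missing states on failure.
* The PDB element column wins over atom-name heuristics; the heuristic
  table handles common ions and leading-digit hydrogen names.

## Known limitations

* The embedding engine is closed-shell only and has no density-fitting
  layer, no gradients, and no real-molecule integrals.
* The ONIOM cap model is schematic; it preserves the subtractive identity
  and electron counting but does not model real link-atom chemistry.
* Formal charges come from templates; protonation-state bookkeeping across
  reaction intermediates is the user's responsibility via per-residue
  overrides.
* The cut-rule default table covers standard amino acids; nonstandard
  residues need user rules (the selector then still guarantees closure,
  deduplication and pruning).
* Charge-aware selection strategies (many small cores around charged
  groups) are expressed through multi-core specifications; the package
  does not auto-detect charge sites.
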