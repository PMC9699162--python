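# Methods

This note records the models implemented in `fragsapt`, the numerical and
design choices behind them, what the synthetic generators emulate, and the
known limitations. Energies are in millihartree (mH) throughout
(1 mH ≈ 2.6255 kJ/mol); geometry in Å; temperatures in K.

## Units and the unit graph

Fragmentation operates on *units*: each heavy atom is its own unit unless
it is connected to another heavy atom by a double, triple or aromatic
bond, in which case the transitive closure of such bonds forms one unit;
hydrogens belong to their heavy atom's unit. Aromatic rings are therefore
single 6-carbon units. Kekulé SDF input is aromatized during sanitization
on read, so alternating single/double benzene rings do not split into
three 2-atom units. XYZ input gets single bonds from a distance criterion
(interatomic distance < 1.15 × covalent-radius sum, factor configurable);
distances cannot recover bond orders, so hosts whose unit partition
depends on multiple bonds should be supplied as SDF.

A *pendant-merge* pass absorbs every single-heavy-atom unit whose only
neighbour is a multi-atom (ring) unit into that ring, to a fixed point.
This makes a phenolic OH part of its ring unit — so calix[6]arene becomes
a 12-unit cycle of ring-with-hydroxyl and methylene units — while leaving
tert-butyl groups as genuine 4-unit trees (their methyls hang off a
single-carbon unit, not a ring). The merge rule is this package's
reconstruction: it is the unique simple rule consistent with the capped
fragment inventory that level-3 fragmentation of calix[6]arene must
produce (methylene-bridged diphenols and dimethylphenol, i.e. whole
phenol rings carrying their OH).

## Fragmentation weights

Level n represents the molecule as a signed sum of connected unit subsets
of sizes n and n+1. Three regimes:

* **Chain of m units** (m > n+1): +1 for each of the m−n windows of n+1
  consecutive units, −1 for each of the m−n−1 interior windows of n units.
* **Cycle of N units** (N > n+1): all N windows of each size, +1 and −1.
* **Anything smaller**: the whole molecule, weight +1.
* **Branched graphs**: weights are the minimum-norm solution of the
  linear system

  1. Σ over fragments containing unit u of w = 1, for every u;
  2. Σ over fragments containing a but not b of w = 0, for every directed
     bond (a→b) — i.e. the signed count of fragments capped at any given
     broken bond vanishes;

  over the candidate set of *all* connected subsets of sizes n and n+1.

The constraints are exactly what makes the weighted fragment sum
reproduce a strictly atom-pairwise energy model once the non-overlap term
is added (see below), and they reduce to the chain and cycle rules —
which are the unique solutions on those topologies. On branched graphs the
system is underdetermined; the minimum-norm solution is the natural
symmetric completion, because it commutes with every graph automorphism:
fragments that differ only by the choice among topologically equivalent
branch directions receive equal fractional weights. Weights are kept as
exact rationals (`fractions.Fraction`); they are rationalized from a
floating least-squares solve and *verified exactly* against the
constraints, with a pure-rational elimination fallback if rationalization
fails. An explicit maximal-path recursion was tried first and rejected:
annihilating a methyl leaf of a tert-butyl branch inevitably produces
fragments of n−1 units, breaking the size invariant that the window
algebra guarantees.

On the hexa-*p*-tert-butyl host (12-unit macroring plus six 4-unit
trees) this yields exactly 150 fragments, all with nonzero weight — 90 of
four units and 60 of three — and per-unit net weight exactly 1.

## Non-overlap correction

For a pairwise-additive model, exactness requires each unit *pair* (u, v)
to be covered with net coefficient 1. The constraints force coverage 1
for adjacent pairs; distant pairs on chains/cycles have coverage 0 and on
branched graphs the coverage can be a fraction between (or slightly
outside) 0 and 1. The correction is therefore stored as a weighted list,

    E_nb = Σ_(u,v) (1 − c_uv) · E_int(unit_u, unit_v),

whose pairs with coefficient exactly 1 are the classic "never
co-resident" set. Interaction-energy assembly against an unfragmented
guest needs no such term: unit coverage 1 suffices.

## Hydrogen caps

Broken single bonds are saturated with hydrogens placed along the broken
bond direction at the standard X–H length (C–H 1.09, O–H 0.96, N–H 1.01,
S–H 1.34 Å). Cap atoms carry an `is_cap` flag. The surrogate engines skip
capped atoms by default: the signed cap *count* at every broken bond is
zero by construction, but the cap–atom pair interactions of the +1 and −1
fragments capped at the same bond involve different far atoms and cannot
cancel exactly, so a pairwise engine that saw caps would break the
machine-precision reconstruction identity that the test suite relies on.
Engines representing real electronic-structure methods should set
`include_caps=True`; the residual cap effect is then part of the
fragmentation error, as it is in practice.

## Surrogate engines

`PairwiseEngine` is Coulomb (529.177·q·q′/r mH with per-element charges)
plus Lennard-Jones (geometric-mean ε, arithmetic-mean σ), summed over all
atom pairs except 1–2 bonded pairs (whose exclusion is representable
consistently across fragments because bonded atoms always share coverage
1). It is deterministic, translation/rotation invariant, and *strictly
additive*, which is the property the master reconstruction tests exploit.
An optional Axilrod–Teller-like three-body term (k/(r₁₂r₂₃r₁₃)³ over heavy
atoms) deliberately breaks additivity to demonstrate a controlled nonzero
fragmentation error. Properties: the dipole is Σqᵢrᵢ; the toy
polarizability adds an isotropic per-element term plus a position-dependent
outer-product term so that off-diagonal components are exercised. Energies
produced by these parameters are not calibrated to any real system — only
their algebraic structure matters.

`LookupEngine` injects printed per-fragment interaction energies (by plan
position or canonical fragment key), so tabulated reference data can
drive the assembly without any energy code.

## SAPT0 bookkeeping

`SaptComponents` stores the seven-term decomposition; δE_HF is never
stored redundantly — it is derived from the supermolecular HF interaction
energy when present. Effective induction (ind + exch-ind + δE_HF) and
effective dispersion (disp + exch-disp) sum with electrostatics and
exchange to the SAPT0 total *identically*, which the suite asserts both on
the transcribed 60-row reference table (to its 0.1 mH print rounding) and
as a floating-point invariant. The two-point complete-basis-set
extrapolation E_L = E∞ + A/L³ (L = 2, 3) is implemented in closed form
(E∞ = E₃ − (E₂−E₃)·8/19) and cross-checked against a least-squares fit;
a ×4/3 rescaling rule of thumb for double-zeta correlation energies is
exposed as a separate helper and deliberately not reconciled with any
particular composite estimate. Boltzmann populations use
k_B = 3.1668×10⁻⁶ hartree/K (k_B·298.15 K = 0.944 mH); default
temperature 298.15 K.

## Pair classification

Ratios r_X = |E_X/E_int| of the four effective components feed a fixed
decision list (evaluated on unrounded ratios):

1. E_int > 0 → repulsive; |E_int| < 1 mH → negligible (group partitions
   are noisy at this scale, so ratios are withheld);
2. r_exch ≥ 1.0 ∧ r_elst ≥ 1.0 ∧ r_ind ≥ 0.5 → typical H-bond, suffixed
   "+disp" when r_disp ≥ 0.3;
3. r_disp ≥ 0.5 ∧ r_exch ≥ 0.3 → dispersion-bound;
4. r_exch ≥ 0.3 → H⋯π (ring accepting a partially donated hydrogen);
5. r_elst ≥ 0.3 with all other ratios < 0.3 → electrostatic-bound;
6. otherwise unclassified — patterns outside the calibrated archetypes are
   reported as such rather than guessed.

Rule 3 must precede rule 4 because dispersion-bound ring–ring pairs also
carry exchange ratios above 0.3. The thresholds are calibrated once
against the 18-row reference table (which the suite reproduces 18/18) and
are config-overridable. Strength bands use the IUPAC hydrogen-bond energy
windows with lower edges inclusive: strong ≥ 24 mH, medium 6.5–24 mH,
weak < 6.5 mH (6.5 and 24 mH are 17 and 63 kJ/mol).

Motif detection collects attractive pairs within a fractional similarity
window (default 50 %) of the strongest pair; two or more sharing a group
form a poly-dentate motif, and a maximal set of mutually group-disjoint
pairs forms a poly-site motif.

## Conformer descriptors and hydrogen bonds

Each linker of the macroring carries the dihedral pair φ = C1-C2-C3-C4,
χ = C2-C3-C4-C5 (C2, C3, C4 along the macroring; C1/C5 the
hydroxyl-bearing ring carbons), computed in the signed IUPAC convention.
Pairs are ordered counterclockwise as seen from the *top side* — the face
holding the majority of phenolic oxygens; an even split (as in the
alternate conformer) triggers a warning and requires an explicit
orientation vector. Sign patterns are matched to the pinched-cone
(±∓±±∓±), alternate (∓∓±±∓∓) and winged-cone (∓=∓±=±) templates up to
cyclic rotation and global sign flip ("=" matches both same-sign cases;
the all-negative form is canonical), because ring numbering and chirality
are conventions, not observables.

Hydrogen bonds are emitted when d(H⋯A) ≤ min(2.5 Å, vdW(H)+vdW(A)−0.2 Å)
and the D–H⋯A angle is ≥ 120°, donors/acceptors O, N, S; aromatic-ring
centroids act as π-acceptors under a looser 3.0 Å cutoff. These defaults
are geometric conventions chosen to capture O–H⋯O contacts in the
1.6–2.3 Å range with room to spare; they are parameters, not fitted
values. The donor→acceptor digraph is decomposed into maximal simple
paths and cycles.

## Synthetic generators

`make_toy_macrocycle` builds a stylized calixarene: n phenol-like hexagon
units and CH₂ linkers on a circle (neighbour spacing held constant as n
varies), hydroxyl oxygens on a rim circle with adjacent spacing
0.96 + 1.70 Å so head-to-tail O–H⋯O bonds are exactly 1.70 Å and
collinear. Conformer recipes are per-ring (tilt, twist, lean) rotation
triples, found once by a development-time scan that maximizes the margin
of every dihedral from the 0°/180° sign boundaries (margins: cone 41°,
alternate 21°, winged 13°), and frozen as constants. The cone realizes the
pinched-cone sign pattern and a closed 6-membered hydroxyl hydrogen-bond
cycle; alternate and winged realize their patterns and two 2-bond chains
each. The alternate/winged geometries are *test articles*, not chemical
structures: flipped or flattened rings keep their oxygen on the hydroxyl
rim at the cost of stretched C–O linkages, and no bond-length realism is
claimed anywhere in the generator. Consequently, passing geometry tests
demonstrate correctness of the descriptor and detection algebra — not
that real relaxed conformers are reproduced.

`synthetic_pair_table` draws group-pair component vectors around one
archetype per bond class — the reference-table row whose unrounded ratio
vector lies farthest from the classifier's decision boundaries — with
componentwise noise mean·(1 + N(0, sd)) and the total recomputed as the
sum of the noisy components. Note a structural feature of this noise
model: the total of a typical H-bond row is a near-cancellation of large
components, so at sd = 0.1 the total carries ≈ 24 % relative noise and
the two H-bond variants (dispersion ratios 0.22 vs 0.40) overlap at the
0.3 suffix boundary; recovery of the generating labels sits just above
95 % and is dominated by that confusion, which mirrors the genuine
fuzziness of the "+disp" distinction.

Packaged fixtures (two host structures with embedded 3D coordinates and
the transcribed reference tables) are verified against a SHA-256 manifest
at load time.

## Problem sizes and determinism

The default test suite runs toy macrocycles of 3–8 rings (6–16 units),
the two packaged hosts (24- and 150-fragment plans), the 60-row and
18-row component tables, and 3 000 archetype draws; everything completes
in a few seconds on one core, and every random draw is seeded. Reports
are reproducible bit-for-bit from config + seed; the branched weight
solver's rationalization step makes the plan independent of
floating-point noise.

## Known limitations

* No electronic-structure engines are bundled; all quantitative claims
  about real complexes enter as transcribed reference tables.
* The branched weight algebra is a reconstruction constrained by the
  printed fragment counts; other exact symmetric completions exist in
  principle (the null space is large), and min-norm is a choice.
* XYZ bond perception yields single bonds only; aromatic perception for
  bare coordinates is limited to what sanitized SDF input provides.
* Conformer templates are defined for 6-ring macrocycles; other ring
  counts get descriptors but no pc/al/wc label.
* The weighted-sum reproduction of printed per-fragment tables is limited
  by the 0.1 mH print rounding of 24 summands: the printed conformer sums
  were evidently formed from unrounded values and can differ from the
  recomputed sums by up to ±0.2 mH.
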