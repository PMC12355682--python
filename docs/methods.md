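# Methods

This note documents the models and procedures qmmmkit implements, the
defaults it chooses where the underlying conventions are genuinely
open, and what its synthetic test systems do and do not demonstrate.

## The QM/MM partition and energy bookkeeping

A hybrid QM/MM calculation splits a molecular system into system 1
(the QM region, treated quantum-mechanically) and system 2 (the MM
region, treated with a force field).  Two equivalent-looking
bookkeeping formulations exist for the total energy.  The additive
form is

    E_add = E_QM^1 + E_MM^2 + E_QM/MM^(1-2),

a QM term, an MM term over the surroundings, and an explicit
interaction term.  The subtractive form is

    E_sub = E_QM^1 + E_MM^12 − E_MM^1,

the MM energy of everything minus the double-counted MM energy of the
QM region.  With a strictly pairwise MM energy function and a
consistent choice of QM-region charges the two are algebraically
identical; qmmmkit's test suite verifies this identity to 1e-9 kJ/mol
rather than assuming it, because real implementations break it through
inconsistent exclusion handling or charge sources.

In mechanical embedding (ME) the QM–MM electrostatics are computed at
the MM level using point charges for the QM region — either the force
field's own charges (MEA) or externally supplied ESP-fitted charges
(MEE).  In electrostatic embedding (EE) the MM region enters the QM
Hamiltonian as a set of point charges, so the QM density is polarized
by its surroundings.  The EE-subtractive total implemented here is

    E = E_QM1+ptch2^HL + E_MM12,q1=0^CL − E_MM1,q1=0^HL,

where the QM term is the HL-capped QM region embedded in the external
point-charge model (excluding the model's self-energy), the 12 term is
the classical energy of everything with the real carbon link atoms
(CL) and all QM charges zeroed, and the 1 term is the HL-capped QM
region without electrostatics.  Keeping CL in the 12 term but HL in
the 1 term is what produces the van der Waals link-atom correction:
the difference of the two MM terms carries the LJ interactions of the
real boundary atom rather than those of the fictitious hydrogen.  The
EE-additive total instead keeps all QM–MM electrostatics inside the
QM term and adds cross-region LJ plus (optionally) the cross-boundary
bond and angle/torsion terms, switchable independently
(`link_bond`, `link_angles_torsions`).

No distance cutoff is applied to any term.

## Link atoms and boundary shells

A bond crossing the partition (a junction) is capped by a hydrogen
link atom (HL) placed on the Q1→M1 axis: r_HL = r_Q1 + g (r_M1 −
r_Q1).  The default scale g is derived per junction from standard
equilibrium bond lengths, g = d0(Q1–H)/d0(Q1–M1), giving g ≈
1.090/1.526 ≈ 0.714 for a C–C cut; a fixed-length mode is also
provided.  The numeric constant is a documented package default —
different codes use slightly different values, and only the linear
relation itself is canonical.  Cutting a bond to hydrogen and double
junctions (one MM atom bonded to two QM atoms) are rejected rather
than silently accepted.

Atoms are classified into bond-graph shells around each cut: Q1, its
QM neighbours Q2, their neighbours Q3, and M1, M2, M3 on the MM side.
Shells are made disjoint by priority (M1 > M2 > M3), so a ring closure
never places an atom in two shells and never causes double exclusion.

## Charge-redistribution schemes

The HL atom sits close to the M1 charge, so EE calculations modify
the point-charge model near each junction.  Ten schemes are
implemented:

| scheme | rule |
|---|---|
| Z0 | keep every MM charge, including M1 |
| Z1 / Z2 / Z3 | delete shells M1 / M1+M2 / M1+M2+M3 |
| DZ1–DZ3 | as Zk, then spread the junction residue's deleted charge evenly over its remaining MM atoms |
| ZZ2 | as Z2, then shift the junction residue's remaining charges uniformly so they sum to zero |
| RCD | delete M1; add −q0/n to each of the n M2 charges and a site of +2q0/n at each M1–M2 bond midpoint |
| CS | delete M1; add +q0/n to each M2; restore the displaced dipole with charges ±δ at r_M2 ± d·û, δ = −q0·\|r_M2−r_M1\|/(2nd) |

RCD and CS preserve both the total charge and the local {M1 ∪ M2}
dipole exactly (verified to 1e-10 e·Å about arbitrary origins); their
leading embedding error is quadrupolar, so the potential error decays
as d⁻³ versus d⁻¹ for the monopole-breaking Z1.  The test suite
measures these exponents directly by probing the model potential at
10–80 Å.

Numerical conventions: exclusions are unioned across junctions before
any compensation, and an atom excluded by one junction is never
re-adjusted by another (exclusion wins).  DZk redistribution and the
ZZ2 zero-sum shift act per junction residue (the residue containing
M1); deleted charge in *other* residues is not compensated, so DZk
conserves the total model charge exactly only when the deleted shells
stay within the junction residue — the charge-group geometry these
schemes were designed for, and the geometry the random junction
fixtures produce (CA–CB cuts of long side chains).  The CS shift
distance d defaults to 0.25 Å; the original description of the scheme
is ambiguous on this point, so d is exposed, logged in output
provenance, and rejected when it would place a shift charge past an
M2 neighbour.

## The MM evaluator and the surrogate QM backend

The internal MM evaluator implements harmonic bonds k(r−r0)², harmonic
angles k(θ−θ0)², torsions V(1+cos(nφ−γ)), 12-6 LJ with
Lorentz–Berthelot combining, and Coulomb with k = 1389.35458
kJ·mol⁻¹·Å·e⁻².  1-2 and 1-3 pairs are excluded and 1-4 pairs scaled
by 1/1.2 (electrostatics) and 1/2 (LJ), the AMBER convention;
exclusions are computed on the full-system bond graph even for subset
evaluations so that region sums remain consistent.  It supports the
variants the assembly needs: zeroing the charges of any atom set, and
substituting junction M1 atoms by HL hydrogens (hydrogen LJ
parameters, zero charge, bonded terms re-evaluated at the HL
position with unchanged parameters).  Correctness is established
against an independent naive double-loop oracle (≤1e-10 kJ/mol on
systems of ≤25 atoms).

Real electronic-structure engines plug in through a small contract:
`evaluate(system, qm_atoms, junctions, external_model, charge,
multiplicity) → (energy, esp_charges)`, with energies in kJ/mol and
the external model's self-energy excluded.  The shipped
`SurrogateBackend` is a classical model of that contract: its energy
is the MM internal energy of the HL-capped region plus the analytic
Coulomb interaction of the region's force-field charges with the
external sites, and its ESP charges are the force-field charges.  The
HL cap carries zero charge everywhere.  Because this backend is exact
and linear in the external charges, every bookkeeping identity —
additive ≡ subtractive ME, scheme-difference linearity, the reduction
chain of the big-QM assembly — becomes exactly testable instead of
approximately observable.  The surrogate is a verification instrument,
not a stand-in for the physics of a QM region.

## Big-QM region selection

QM/MM energies converge slowly with QM-region size, so the big-QM
procedure re-evaluates the energy with an enlarged region: (i) every
residue with an atom within a radius r (default use: 6–10 Å) of the
base QM atoms is included whole, and touched waters are completed
even in atom-level selection mode; (ii) backbone atoms (N, H, CA, HA,
C, O) of requested flanking residue spans are added; (iii) buried
charged residues (relative SASA < 0.05 by default) are included
whole; (iv) any peptide-bond cut closer than two residues in sequence
to a base-QM residue is relocated outward by adding whole residues,
and cuts are permitted only at backbone C–N or CA–CB bonds.  Cut
relocation stops at chain termini with a warning.  Whole-residue
completion is the default because the two-residue relocation rule is
only well-posed on a residue-completed region; a raw atom-level mode
is provided for comparison.  The big-QM energy itself is the
EE-subtractive expression with the enlarged region, evaluated by the
identical code path, which guarantees the reduction identities
(region = base ⇒ ordinary EE subtractive; region = everything ⇒ bare
backend energy).

Solvent exposure is classified by an internal Shrake–Rupley SASA
(probe 1.4 Å, 960 golden-spiral points per atom by default,
deterministic).  Relative exposure divides a residue's in-context
SASA by a reference maximum; the default reference is the same
residue's SASA computed in isolation, which makes an unoccluded
residue score exactly 1 for arbitrary (including synthetic) residue
types, and a standard Gly-X-Gly theoretical maximum table is
available for real residue types.  Thresholds — buried < 0.05,
exposed ≥ 0.20 — are package defaults, configurable.

Solvent-exposed charged residues outside the region are neutralized
structurally: arginine loses HH22, lysine loses HZ3, aspartate gains
a proton on OD1 and glutamate on OE2.  The added proton is placed
0.97 Å from the oxygen along the in-plane bisector pointing away from
the carboxylate carbon and the other oxygen.  Residues participating
in an ion pair (opposite formal charges with any inter-residue
heavy-atom contact under 4.0 Å) are exempt, since the pair is already
net neutral.  After each edit the residue's formal charge is zero and
its partial charges are shifted uniformly so their sum matches; the
uniform shift is a bookkeeping choice — no force field is refit.

## Synthetic systems

The fixture generator builds linear peptide-like chains with named
backbone atoms, small side chains carrying the atom names the
neutralization rules key on, optional waters and a matching MM term
table (bond/angle equilibria slightly offset from the generated
geometry so bonded energies are non-zero; element-based LJ; TIP3P-like
water charges).  Partial charges are drawn per residue from a seeded
generator and shifted so each residue sums exactly to its formal
charge.  Geometries use ~1.5 Å backbone spacing and are invented:
they exercise graph topology, charge bookkeeping and distance logic
faithfully, but they are not low-energy conformations, their SASA
values are not those of real proteins, and no force-field realism is
claimed.  Passing tests therefore demonstrate the correctness of the
boundary machinery — shell classification, scheme algebra, energy
bookkeeping, selection rules — not the accuracy of any QM/MM energy
for a real enzyme.  Named junction topologies (single cut, two cuts
sharing a residue, ring-closing side chain, water inside the QM
region) cover the hard graph cases; randomized fixtures cut CA–CB
bonds of long-side-chain residues so that shells M1–M3 stay within
one residue.

## Problem sizes and determinism

The shipped test suite and the acceptance script run on fixtures of
roughly 20–80 atoms, 200 random junction systems for the conservation
suite and 50 for the MM oracle; the full suite completes in seconds.
All randomness flows from explicit integer seeds (NumPy
`default_rng` / `SeedSequence`), and every surrogate-backend pipeline
is bit-for-bit deterministic, including through the CLI.

## Known limitations

* No electronic structure: the only shipped backend is the classical
  surrogate; adapters for real engines must convert units and respect
  the self-energy exclusion.
* Mechanical embedding consumes ESP charges but does not fit them.
* The prmtop reader covers only charges, bonds, residue pointers and
  atom names; angle/torsion/LJ tables must arrive via the JSON
  topology dialect.
* No periodic boundary conditions, Ewald summation, polarizable
  embedding or continuum solvation.
* Exposure classification thresholds are heuristics; no pKa or
  protonation-state prediction is attempted.
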