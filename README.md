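# qmmmkit

Boundary and embedding machinery for hybrid QM/MM calculations on
biomolecules: hydrogen link-atom construction, the ten boundary
charge-redistribution schemes (Z0–Z3, DZ1–DZ3, ZZ2, RCD, CS),
additive and subtractive energy assembly under mechanical and
electrostatic embedding, and big-QM region selection with
neutralization of solvent-exposed charged residues.

## Who this is for

QM/MM energies of enzyme reactions are notoriously sensitive to
implementation details that most packages bury: which MM charges near
a cut bond enter the QM Hamiltonian, whether the total is assembled
additively or subtractively, whether the link atom's van der Waals
terms use the real atom or the capping hydrogen, and how far the QM
region must grow before the answer stops moving.  qmmmkit isolates
exactly this machinery as a tested, backend-agnostic library + CLI so
that each choice can be varied, audited and compared in isolation.
It performs no electronic-structure computation itself: a classical
surrogate backend ships, making every bookkeeping identity exactly
verifiable, and real QM engines plug in through a small documented
contract.

## The core expressions

The additive and subtractive totals for a system split into a QM
region (1) and MM region (2) are

    E_add = E_QM^1 + E_MM^2 + E_QM/MM^(1-2)
    E_sub = E_QM^1 + E_MM^12 − E_MM^1

and the electrostatic-embedding subtractive total with hydrogen link
atoms (HL) capping the cut bonds is

    E = E_QM1+ptch2^HL + E_MM12,q1=0^CL − E_MM1,q1=0^HL

(QM region embedded in the external point-charge model; classical
energy of everything with the real carbon link atoms CL and QM
charges zeroed; minus the HL-capped QM region without
electrostatics).  The big-QM energy is the same expression with a
greatly enlarged QM region — all residues within a radius r of the
minimal region, buried charged residues, flanking backbone spans, and
junctions relocated at least two residues away from the original
region.  See `docs/methods.md` for the scheme definitions and every
numerical convention.

## Worked example

```python
from qmmmkit import (make_junction_case, SurrogateBackend,
                     assemble_ee_subtractive, apply_scheme, model_summary)

# a 3-residue synthetic chain whose middle side chain is cut out of
# the QM region at the CA-CB bond
system, terms, partition, junctions = make_junction_case("single_cut", seed=0)
j = junctions[0]
print(f"junction: Q1={system.atoms[j.q1].name} M1={system.atoms[j.m1].name} "
      f"M2={sorted(system.atoms[i].name for i in j.m2)}")

for scheme in ("Z0", "Z1", "RCD", "CS"):
    model = apply_scheme(system, partition, junctions, scheme)
    n, q, _ = model_summary(model)
    print(f"{scheme:>4s}: {n:2d} sites, total charge {q:+.6f} e")

backend = SurrogateBackend(terms)
for scheme in ("Z1", "RCD"):
    report = assemble_ee_subtractive(system, terms, partition, junctions,
                                     scheme, backend)
    print(f"EE subtractive ({scheme}): total = {report.total:.3f} kJ/mol")
```

prints

```
junction: Q1=CA M1=CB M2=['CG', 'HB2']
  Z0: 10 sites, total charge +0.254394 e
  Z1:  9 sites, total charge +0.439510 e
 RCD: 11 sites, total charge +0.254394 e
  CS: 13 sites, total charge +0.254394 e
EE subtractive (Z1): total = 191645.556 kJ/mol
EE subtractive (RCD): total = 191541.324 kJ/mol
```

Reading it: Z1 deletes the boundary charge M1 (here CB, q = −0.185 e),
so the model's total charge shifts by exactly that amount, while RCD
and CS compensate the deletion (on the M2 atoms plus virtual sites —
bond midpoints for RCD, shifted ± pairs for CS) and conserve both the
total charge and the local bond dipole.  The two EE totals differ by
the Coulomb interaction of the QM charges with the model difference —
about 104 kJ/mol here, a synthetic-scale illustration of why the
scheme choice matters this close to the cut.  (Absolute totals are
dominated by the fixture's arbitrary internal strain; only
differences are meaningful.)

The same pipelines are scriptable from the shell:

```bash
qmmmkit fixtures --kind single_cut --seed 0 --out-dir work
qmmmkit charges  --topology work/fixture.json --qm work/qm_atoms.txt --scheme RCD --out work/rcd
qmmmkit assemble --topology work/fixture.json --qm work/qm_atoms.txt --scheme Z1 --out work/energy.json
qmmmkit bigqm    --topology work/fixture.json --base work/qm_atoms.txt --radius 6 --out-dir work/bq
```

## Layout

```
src/qmmmkit/
  system.py     atoms, bonds, residues, QM/MM partition
  boundary.py   junction detection, shell classification, link atoms
  schemes.py    the ten point-charge redistribution schemes
  mm.py         pairwise MM evaluator (bonded, LJ, Coulomb; no cutoff)
  assembly.py   additive/subtractive ME/EE totals, surrogate backend
  bigqm.py      big-QM selection, SASA exposure, neutralization
  sasa.py       Shrake-Rupley solvent-accessible surface area
  fixtures.py   deterministic synthetic peptide-like systems
  io.py         PDB, AMBER prmtop subset, JSON topology, point charges
  cli.py        qmmmkit {fixtures,junctions,charges,assemble,bigqm}
```
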