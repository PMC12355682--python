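"""Assembly of total QM/MM energies in all embedding variants.

Two bookkeeping formulations exist for the total energy.  The additive
form sums a QM term, an MM term for the surroundings and an explicit
interaction term:

    E_add = E_QM^1 + E_MM^2 + E_QM/MM^(1-2)

The subtractive form instead computes the MM energy of everything and
removes the double-counted MM energy of the QM region:

    E_sub = E_QM^1 + E_MM^12 - E_MM^1

With electrostatic embedding and hydrogen link atoms the subtractive
form becomes

    E = E_QM1+ptch2^HL + E_MM12,q1=0^CL - E_MM1,q1=0^HL

where the QM term is evaluated for the HL-capped region embedded in
the external point-charge model (excluding the model's self-energy),
the 12 term keeps the real carbon link atoms (CL) with all QM charges
zeroed, and the 1 term is the HL-capped QM region without
electrostatics.  Using CL in the 12 term but HL in the 1 term is what
supplies the van der Waals link-atom correction.  The big-QM energy
uses the identical expression with the enlarged region.

A classical surrogate backend ships so every identity is exactly
testable: its "QM" energy is the MM internal energy of the capped
region plus the analytic Coulomb interaction of the region's
force-field charges with the external sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Mapping, Protocol, Sequence

import numpy as np

from .boundary import Junction
from .constants import COULOMB_KJ
from .mm import ForceFieldTerms, MMVariant, mm_energy, qmmm_interaction_mm
from .schemes import DEFAULT_CS_SHIFT, PointChargeModel, apply_scheme
from .system import MolecularSystem, RegionPartition


@dataclass(frozen=True)
class BackendResult:
    """QM backend output: energy in kJ/mol (external-charge self-energy
    excluded) and optionally per-atom ESP charges."""

    energy: float
    esp_charges: Mapping[int, float] | None = None


class QMBackend(Protocol):
    """Contract a QM engine adapter must satisfy.

    ``evaluate`` receives the host system, the QM atom set, the
    junction list (whose HL positions define the capped geometry) and
    the external point-charge model; it returns the energy of the
    capped, embedded region in kJ/mol, excluding the self-energy of
    the external charges, deterministically for fixed inputs.
    """

    def evaluate(
        self,
        system: MolecularSystem,
        qm_atoms: frozenset[int],
        junctions: Sequence[Junction],
        external: PointChargeModel,
        total_charge: int = 0,
        multiplicity: int = 1,
    ) -> BackendResult: ...


class SurrogateBackend:
    """Classical stand-in QM engine.

    The returned energy is the MM internal energy of the HL-capped QM
    geometry (HL atoms carry hydrogen LJ parameters and zero charge)
    plus the exact Coulomb interaction of the region's force-field
    charges with the external sites.  ESP-charge requests return the
    force-field charges.  Bit-for-bit deterministic.
    """

    def __init__(self, terms: ForceFieldTerms) -> None:
        self.terms = terms

    def evaluate(
        self,
        system: MolecularSystem,
        qm_atoms: frozenset[int],
        junctions: Sequence[Junction],
        external: PointChargeModel,
        total_charge: int = 0,
        multiplicity: int = 1,
    ) -> BackendResult:
        subset = sorted(qm_atoms | {j.m1 for j in junctions})
        internal = mm_energy(
            system, self.terms, subset,
            variant=MMVariant(link_substitution="HL"), junctions=junctions,
        )
        e_ext = 0.0
        if external.sites:
            pos = system.positions
            chg = system.charges
            ext_pos = external.positions
            ext_chg = external.charges
            for a in sorted(qm_atoms):
                d = np.linalg.norm(ext_pos - pos[a], axis=1)
                e_ext += COULOMB_KJ * chg[a] * float((ext_chg / d).sum())
        esp = {a: float(system.charges[a]) for a in sorted(qm_atoms)}
        return BackendResult(energy=internal + e_ext, esp_charges=esp)


@dataclass(frozen=True)
class EnergyReport:
    """Labeled energy components (kJ/mol) and the assembled total.

    ``components`` uses the canonical labels e_qm1, e_mm2, e_int12,
    e_mm12, e_mm1, e_qm1_ptch2_hl, e_mm12_q1zero_cl, e_mm1_q1zero_hl;
    ``variant`` records scheme, embedding, formulation and link flags.
    """

    components: dict[str, float]
    total: float
    variant: dict = dc_field(default_factory=dict)

    _EXPRESSIONS = {
        ("ME", "additive"): (("e_qm1", 1), ("e_mm2", 1), ("e_int12", 1)),
        ("ME", "subtractive"): (("e_qm1", 1), ("e_mm12", 1), ("e_mm1", -1)),
        ("EE", "subtractive"): (
            ("e_qm1_ptch2_hl", 1), ("e_mm12_q1zero_cl", 1), ("e_mm1_q1zero_hl", -1),
        ),
        ("EE", "additive"): (
            ("e_qm1_ptch2_hl", 1), ("e_mm2", 1), ("e_cross_lj", 1), ("e_cross_bonded", 1),
        ),
    }

    def audit(self) -> float:
        """Recompute the total from the stored components."""
        key = (self.variant.get("embedding"), self.variant.get("formulation"))
        if key == ("EE", "bigqm"):
            key = ("EE", "subtractive")
        expr = self._EXPRESSIONS[key]
        return sum(sign * self.components[name] for name, sign in expr)


def qm_formal_charge(system: MolecularSystem, partition: RegionPartition) -> int:
    """Formal charge of the QM region: sum of formal charges of
    residues wholly contained in it (partial residues contribute 0;
    override explicitly when the cut severs a charged group)."""
    total = 0
    for res in system.residues:
        atoms = set(res.atom_indices)
        if atoms and atoms <= partition.qm_atoms:
            total += res.formal_charge
    return total


def assemble_me_additive(
    system: MolecularSystem,
    terms: ForceFieldTerms,
    partition: RegionPartition,
    junctions: Sequence[Junction],
    backend: QMBackend,
    charge_source: str = "force_field",
    esp_charges: Mapping[int, float] | None = None,
) -> EnergyReport:
    """Mechanical embedding, additive: E_QM^1 + E_MM^2 + E_QM/MM^(1-2)."""
    empty = PointChargeModel(sites=())
    result = backend.evaluate(system, partition.qm_atoms, junctions, empty,
                              qm_formal_charge(system, partition))
    if charge_source == "supplied_esp" and esp_charges is None:
        esp_charges = result.esp_charges
    e_qm1 = result.energy
    e_mm2 = mm_energy(system, terms, partition.mm_atoms)
    e_int12 = qmmm_interaction_mm(
        system, terms, partition, charge_source=charge_source,
        esp_charges=esp_charges,
    )
    total = e_qm1 + e_mm2 + e_int12
    return EnergyReport(
        components={"e_qm1": e_qm1, "e_mm2": e_mm2, "e_int12": e_int12},
        total=total,
        variant={"embedding": "ME", "formulation": "additive",
                 "charge_source": charge_source},
    )


def assemble_me_subtractive(
    system: MolecularSystem,
    terms: ForceFieldTerms,
    partition: RegionPartition,
    junctions: Sequence[Junction],
    backend: QMBackend,
    charge_source: str = "force_field",
    esp_charges: Mapping[int, float] | None = None,
) -> EnergyReport:
    """Mechanical embedding, subtractive: E_QM^1 + E_MM^12 - E_MM^1.

    Requires MM parameters for the QM-region atoms (the formulation's
    known cost).  With a strictly pairwise MM energy and a consistent
    QM charge source this is algebraically identical to the additive
    assembly.
    """
    empty = PointChargeModel(sites=())
    result = backend.evaluate(system, partition.qm_atoms, junctions, empty,
                              qm_formal_charge(system, partition))
    if charge_source == "supplied_esp" and esp_charges is None:
        esp_charges = result.esp_charges
    e_qm1 = result.energy

    eval_system = system
    if charge_source == "supplied_esp":
        if esp_charges is None:
            raise ValueError("supplied_esp requires esp_charges")
        eval_system = system.with_charges(
            {a: q for a, q in esp_charges.items() if a in partition.qm_atoms}
        )
    e_mm12 = mm_energy(eval_system, terms, None)
    e_mm1 = mm_energy(eval_system, terms, partition.qm_atoms)
    total = e_qm1 + e_mm12 - e_mm1
    return EnergyReport(
        components={"e_qm1": e_qm1, "e_mm12": e_mm12, "e_mm1": e_mm1},
        total=total,
        variant={"embedding": "ME", "formulation": "subtractive",
                 "charge_source": charge_source},
    )


def assemble_ee_subtractive(
    system: MolecularSystem,
    terms: ForceFieldTerms,
    partition: RegionPartition,
    junctions: Sequence[Junction],
    scheme: str,
    backend: QMBackend,
    cs_shift: float = DEFAULT_CS_SHIFT,
    _formulation: str = "subtractive",
) -> EnergyReport:
    """Electrostatic embedding, subtractive:
    E = E_QM1+ptch2^HL + E_MM12,q1=0^CL - E_MM1,q1=0^HL."""
    qm = partition.qm_atoms
    model = apply_scheme(system, partition, junctions, scheme, cs_shift)
    e1 = backend.evaluate(system, qm, junctions, model,
                          qm_formal_charge(system, partition)).energy
    e_mm12 = mm_energy(
        system, terms, None,
        variant=MMVariant(zero_charges_on=qm, link_substitution="CL"),
        junctions=junctions,
    )
    capped = qm | {j.m1 for j in junctions}
    e_mm1 = mm_energy(
        system, terms, capped,
        variant=MMVariant(zero_charges_on=frozenset(capped), link_substitution="HL"),
        junctions=junctions,
    )
    total = e1 + e_mm12 - e_mm1
    return EnergyReport(
        components={
            "e_qm1_ptch2_hl": e1,
            "e_mm12_q1zero_cl": e_mm12,
            "e_mm1_q1zero_hl": e_mm1,
        },
        total=total,
        variant={"embedding": "EE", "formulation": _formulation,
                 "scheme": scheme.upper(), "cs_shift": cs_shift,
                 "n_external_sites": len(model.sites)},
    )


def assemble_ee_additive(
    system: MolecularSystem,
    terms: ForceFieldTerms,
    partition: RegionPartition,
    junctions: Sequence[Junction],
    scheme: str,
    backend: QMBackend,
    link_bond: bool = True,
    link_angles_torsions: bool = True,
    cs_shift: float = DEFAULT_CS_SHIFT,
) -> EnergyReport:
    """Electrostatic embedding, additive: the QM term carries all
    QM–MM electrostatics (via the embedded point charges), so the MM
    interaction term is LJ plus optional cross-boundary bonded terms.
    """
    qm = partition.qm_atoms
    model = apply_scheme(system, partition, junctions, scheme, cs_shift)
    e1 = backend.evaluate(system, qm, junctions, model,
                          qm_formal_charge(system, partition)).energy
    e_mm2 = mm_energy(system, terms, partition.mm_atoms)
    e_cross_lj = qmmm_interaction_mm(
        system, terms, partition, include_coulomb=False,
        variant=MMVariant(link_bond=False, link_angles_torsions=False),
    )
    e_cross_bonded = 0.0
    if link_bond or link_angles_torsions:
        e_cross_bonded = qmmm_interaction_mm(
            system, terms, partition, include_coulomb=False,
            variant=MMVariant(link_bond=link_bond,
                              link_angles_torsions=link_angles_torsions),
        ) - e_cross_lj
    total = e1 + e_mm2 + e_cross_lj + e_cross_bonded
    return EnergyReport(
        components={
            "e_qm1_ptch2_hl": e1,
            "e_mm2": e_mm2,
            "e_cross_lj": e_cross_lj,
            "e_cross_bonded": e_cross_bonded,
        },
        total=total,
        variant={"embedding": "EE", "formulation": "additive",
                 "scheme": scheme.upper(), "cs_shift": cs_shift,
                 "link_bond": link_bond,
                 "link_angles_torsions": link_angles_torsions},
    )


def assemble_bigqm(
    system: MolecularSystem,
    terms: ForceFieldTerms,
    bigqm_partition: RegionPartition,
    junctions: Sequence[Junction],
    scheme: str,
    backend: QMBackend,
    cs_shift: float = DEFAULT_CS_SHIFT,
) -> EnergyReport:
    """Big-QM energy: the EE-subtractive expression with the enlarged
    region as QM (E_bigQM+ptch2^HL + E_MM12,q=0^CL - E_MM,q=0^HL).
    Reduces to the ordinary EE subtractive assembly when the big-QM
    region equals the base QM region, and to the bare backend energy
    when it covers the whole system."""
    return assemble_ee_subtractive(
        system, terms, bigqm_partition, junctions, scheme, backend,
        cs_shift=cs_shift, _formulation="bigqm",
    )
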