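"""Energy-assembly identities: additive vs subtractive bookkeeping,
scheme-difference linearity, degenerate partitions and the surrogate
backend contract."""

import numpy as np
import pytest

from qmmmkit import (
    COULOMB_KJ,
    PointChargeModel,
    RegionPartition,
    SCHEMES,
    SurrogateBackend,
    apply_scheme,
    assemble_bigqm,
    assemble_ee_additive,
    assemble_ee_subtractive,
    assemble_me_additive,
    assemble_me_subtractive,
    make_junction_case,
    random_junction_fixture,
)

EMPTY = PointChargeModel(sites=())


def external_coulomb(system, qm_atoms, model):
    """Independent evaluation of Coulomb(QM ff charges, model sites)."""
    if not model.sites:
        return 0.0
    pos, chg = system.positions, system.charges
    e = 0.0
    for a in sorted(qm_atoms):
        d = np.linalg.norm(model.positions - pos[a], axis=1)
        e += COULOMB_KJ * chg[a] * float((model.charges / d).sum())
    return e


@pytest.fixture(params=["single_cut", "two_cuts_same_residue",
                        "ring_adjacent", "water_in_qm"])
def junction_case(request):
    return make_junction_case(request.param, seed=1)


class TestMechanicalEmbedding:
    def test_additive_equals_subtractive(self, junction_case):
        system, terms, partition, junctions = junction_case
        backend = SurrogateBackend(terms)
        add = assemble_me_additive(system, terms, partition, junctions, backend)
        sub = assemble_me_subtractive(system, terms, partition, junctions, backend)
        assert add.total == pytest.approx(sub.total, abs=1e-9)

    def test_additive_equals_subtractive_with_esp_charges(self, junction_case):
        system, terms, partition, junctions = junction_case
        backend = SurrogateBackend(terms)
        rng = np.random.default_rng(4)
        esp = {a: float(system.charges[a] + rng.normal(0, 0.05))
               for a in partition.qm_atoms}
        add = assemble_me_additive(system, terms, partition, junctions,
                                   backend, "supplied_esp", esp)
        sub = assemble_me_subtractive(system, terms, partition, junctions,
                                      backend, "supplied_esp", esp)
        assert add.total == pytest.approx(sub.total, abs=1e-9)

    def test_mea_vs_mee_differ_by_coulomb_of_charge_delta(self, junction_case):
        system, terms, partition, junctions = junction_case
        backend = SurrogateBackend(terms)
        mea = assemble_me_additive(system, terms, partition, junctions, backend)
        # MEE with ESP charges equal to the force-field charges is MEA
        esp = {a: float(system.charges[a]) for a in partition.qm_atoms}
        mee = assemble_me_additive(system, terms, partition, junctions,
                                   backend, "supplied_esp", esp)
        assert mee.total == pytest.approx(mea.total, abs=1e-9)

    def test_whole_system_qm_reduces_to_backend_energy(self, junction_case):
        system, terms, _, _ = junction_case
        backend = SurrogateBackend(terms)
        full = RegionPartition.from_qm(system, range(len(system)))
        rep = assemble_me_additive(system, terms, full, [], backend)
        assert rep.total == pytest.approx(
            backend.evaluate(system, full.qm_atoms, [], EMPTY).energy, abs=1e-12)
        assert rep.components["e_mm2"] == 0.0
        assert rep.components["e_int12"] == 0.0


class TestElectrostaticEmbedding:
    def test_scheme_difference_linearity(self, junction_case):
        system, terms, partition, junctions = junction_case
        backend = SurrogateBackend(terms)
        totals, models = {}, {}
        for scheme in ("Z0", "Z1", "Z3", "DZ1", "ZZ2", "RCD", "CS"):
            totals[scheme] = assemble_ee_subtractive(
                system, terms, partition, junctions, scheme, backend).total
            models[scheme] = apply_scheme(system, partition, junctions, scheme)
        for a in totals:
            for b in totals:
                expected = (external_coulomb(system, partition.qm_atoms, models[a])
                            - external_coulomb(system, partition.qm_atoms, models[b]))
                assert totals[a] - totals[b] == pytest.approx(expected, abs=1e-9)

    def test_all_schemes_equal_without_junctions(self):
        system, terms, partition, junctions = make_junction_case("water_in_qm")
        water_only = RegionPartition.from_qm(
            system, system.residue(2).atom_indices)
        backend = SurrogateBackend(terms)
        totals = {
            s: assemble_ee_subtractive(system, terms, water_only, [], s, backend).total
            for s in SCHEMES
        }
        assert len(set(totals.values())) == 1

    def test_definition_audit(self, junction_case):
        system, terms, partition, junctions = junction_case
        backend = SurrogateBackend(terms)
        rep = assemble_ee_subtractive(system, terms, partition, junctions,
                                      "Z1", backend)
        assert rep.total == pytest.approx(
            rep.components["e_qm1_ptch2_hl"]
            + rep.components["e_mm12_q1zero_cl"]
            - rep.components["e_mm1_q1zero_hl"], abs=1e-12)
        assert rep.audit() == pytest.approx(rep.total, abs=1e-9)

    def test_link_flags_change_only_named_bonded_terms(self, junction_case):
        system, terms, partition, junctions = junction_case
        backend = SurrogateBackend(terms)
        on = assemble_ee_additive(system, terms, partition, junctions, "Z1",
                                  backend, link_bond=True,
                                  link_angles_torsions=True)
        off = assemble_ee_additive(system, terms, partition, junctions, "Z1",
                                   backend, link_bond=False,
                                   link_angles_torsions=False)
        assert on.total - off.total == pytest.approx(
            on.components["e_cross_bonded"], abs=1e-9)
        assert off.components["e_cross_bonded"] == 0.0
        for key in ("e_qm1_ptch2_hl", "e_mm2", "e_cross_lj"):
            assert on.components[key] == off.components[key]

    def test_additive_equals_subtractive_without_junctions(self):
        system, terms, _, _ = make_junction_case("water_in_qm")
        water_only = RegionPartition.from_qm(system, system.residue(2).atom_indices)
        backend = SurrogateBackend(terms)
        sub = assemble_ee_subtractive(system, terms, water_only, [], "Z1", backend)
        add = assemble_ee_additive(system, terms, water_only, [], "Z1", backend)
        assert add.total == pytest.approx(sub.total, abs=1e-9)

    def test_whole_system_qm_returns_backend_energy(self, junction_case):
        system, terms, _, _ = junction_case
        backend = SurrogateBackend(terms)
        full = RegionPartition.from_qm(system, range(len(system)))
        for assemble in (assemble_ee_subtractive, assemble_ee_additive):
            rep = assemble(system, terms, full, [], "Z1", backend)
            assert rep.total == pytest.approx(
                backend.evaluate(system, full.qm_atoms, [], EMPTY).energy,
                abs=1e-9)


class TestBigQMAssembly:
    def test_reduces_to_ee_subtractive_on_base_region(self, junction_case):
        system, terms, partition, junctions = junction_case
        backend = SurrogateBackend(terms)
        big = assemble_bigqm(system, terms, partition, junctions, "Z1", backend)
        ref = assemble_ee_subtractive(system, terms, partition, junctions,
                                      "Z1", backend)
        assert big.total == pytest.approx(ref.total, abs=1e-9)

    def test_whole_system_region_is_pure_backend(self, junction_case):
        system, terms, _, _ = junction_case
        backend = SurrogateBackend(terms)
        full = RegionPartition.from_qm(system, range(len(system)))
        rep = assemble_bigqm(system, terms, full, [], "Z1", backend)
        assert rep.total == pytest.approx(
            backend.evaluate(system, full.qm_atoms, [], EMPTY).energy, abs=1e-9)

    def test_enlarging_region_reduces_external_sites(self):
        system, terms, partition, junctions = make_junction_case("single_cut")
        small = apply_scheme(system, partition, junctions, "Z1")
        bigger_qm = partition.qm_atoms | {sorted(partition.mm_atoms)[0]}
        from qmmmkit import find_junctions
        p2 = RegionPartition.from_qm(system, bigger_qm)
        j2 = find_junctions(system, p2)
        larger = apply_scheme(system, p2, j2, "Z1")
        assert len(larger.sites) < len(small.sites)


class TestSurrogateBackend:
    def test_vacuum_is_internal_energy_only(self, junction_case):
        system, terms, partition, junctions = junction_case
        backend = SurrogateBackend(terms)
        r1 = backend.evaluate(system, partition.qm_atoms, junctions, EMPTY)
        r2 = backend.evaluate(system, partition.qm_atoms, junctions, EMPTY)
        assert r1.energy == r2.energy  # deterministic, bit for bit

    def test_single_external_site_analytic(self):
        from qmmmkit import ChargeSite
        system, terms, partition, junctions = make_junction_case("single_cut")
        backend = SurrogateBackend(terms)
        site = ChargeSite((50.0, 0.0, 0.0), -1.0)
        model = PointChargeModel(sites=(site,))
        vac = backend.evaluate(system, partition.qm_atoms, junctions, EMPTY)
        emb = backend.evaluate(system, partition.qm_atoms, junctions, model)
        assert emb.energy - vac.energy == pytest.approx(
            external_coulomb(system, partition.qm_atoms, model), abs=1e-9)

    def test_esp_request_returns_force_field_charges(self, junction_case):
        system, terms, partition, junctions = junction_case
        backend = SurrogateBackend(terms)
        esp = backend.evaluate(system, partition.qm_atoms, junctions, EMPTY).esp_charges
        for a in partition.qm_atoms:
            assert esp[a] == float(system.charges[a])
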