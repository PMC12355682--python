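"""Big-QM region selection, SASA exposure classification and
charged-residue neutralization."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from qmmmkit import (
    AtomRecord,
    BigQMSpec,
    FixtureSpec,
    MolecularSystem,
    Residue,
    classify_exposure,
    find_ion_pairs,
    generate,
    neutralize_exposed_charges,
    region_report,
    select_bigqm,
)
from qmmmkit.bigqm import RegionError


def rule_i_oracle(system, base_qm, radius):
    """Independent all-pairs distance scan for the whole-residue
    distance rule."""
    pos = system.positions
    base = sorted(base_qm)
    rids = set()
    for res in system.residues:
        for i in res.atom_indices:
            if any(np.linalg.norm(pos[i] - pos[b]) <= radius for b in base):
                rids.add(res.residue_id)
                break
    return rids


@pytest.fixture(scope="module")
def chain9():
    return generate(FixtureSpec(9, ("ALA",), seed=1))


class TestSelection:
    def test_tiny_radius_keeps_base_residues_only(self, chain9):
        system, _ = chain9
        base = frozenset(system.residue(4).atom_indices)
        region, _ = select_bigqm(system, BigQMSpec(radius=1e-9, base_qm=base))
        # relocation still extends along the backbone; check that rule (i)
        # alone selected only the base residue before relocation
        assert rule_i_oracle(system, base, 1e-9) == {4}

    def test_radius_larger_than_system_selects_everything(self, chain9):
        system, _ = chain9
        base = frozenset(system.residue(4).atom_indices)
        region, _ = select_bigqm(system, BigQMSpec(radius=500.0, base_qm=base))
        assert region == frozenset(range(len(system)))

    def test_nine_residue_relocation_hand_trace(self, chain9):
        # base = middle residue; r touches only the flanking residues;
        # peptide cuts must end up >= 2 residues from the base, giving
        # a symmetric 5-residue window
        system, _ = chain9
        base = frozenset(system.residue(4).atom_indices)
        assert rule_i_oracle(system, base, 2.0) == {3, 4, 5}
        region, report = select_bigqm(system, BigQMSpec(radius=2.0, base_qm=base))
        assert set(report["whole_residues"]) == {2, 3, 4, 5, 6}
        cut_rids = {
            tuple(sorted((system.residue_of(a).residue_id,
                          system.residue_of(b).residue_id)))
            for a, b in report["cuts"]
        }
        assert cut_rids == {(1, 2), (6, 7)}

    def test_rule_i_matches_brute_force_oracle(self):
        for seed in range(5):
            system, _ = generate(FixtureSpec(
                6, ("ALA", "ARG", "ALA", "ASP", "ALA", "LYS"),
                n_waters=4, seed=seed))
            base = frozenset(system.residue(2).atom_indices)
            for radius in (3.0, 6.0):
                spec = BigQMSpec(radius=radius, base_qm=base,
                                 include_buried_charges=False,
                                 whole_residues=False)
                region, _ = select_bigqm(system, spec)
                oracle_atoms = {
                    i for i in range(len(system))
                    if min(np.linalg.norm(system.positions[i]
                                          - system.positions[b])
                           for b in base) <= radius
                } | set(base)
                # touched waters are completed even in atom-level mode
                for res in system.residues:
                    if res.name == "HOH" and set(res.atom_indices) & oracle_atoms:
                        oracle_atoms |= set(res.atom_indices)
                assert region == oracle_atoms

    def test_monotone_in_radius(self):
        system, _ = generate(FixtureSpec(7, ("ALA", "ASP"), n_waters=5, seed=3))
        base = frozenset(system.residue(3).atom_indices)
        prev = frozenset()
        for radius in (2.0, 4.0, 8.0, 16.0):
            region, _ = select_bigqm(system, BigQMSpec(radius=radius, base_qm=base))
            assert prev <= region
            prev = region

    def test_backbone_spans_contribute_backbone_atoms(self, chain9):
        system, _ = chain9
        base = frozenset(system.residue(4).atom_indices)
        spec = BigQMSpec(radius=2.0, base_qm=base, backbone_spans=((0, 1),))
        region, _ = select_bigqm(system, spec)
        res0 = system.residue(0)
        names = {system.atoms[i].name for i in res0.atom_indices if i in region}
        assert names == {"N", "H", "CA", "HA", "C", "O"}

    def test_unknown_span_residue_rejected(self, chain9):
        system, _ = chain9
        base = frozenset(system.residue(4).atom_indices)
        with pytest.raises(RegionError, match="unknown residue"):
            select_bigqm(system, BigQMSpec(radius=2.0, base_qm=base,
                                           backbone_spans=((90, 95),)))


class TestRegionReport:
    def test_empty_region(self, chain9):
        system, _ = chain9
        rep = region_report(system, frozenset())
        assert rep == {"atoms": 0, "residues": 0, "waters": 0,
                       "junctions": 0, "net_formal_charge": 0}

    def test_whole_system(self):
        system, _ = generate(FixtureSpec(3, ("ALA", "ARG", "ASP"),
                                         n_waters=2, seed=0))
        rep = region_report(system, frozenset(range(len(system))))
        assert rep["atoms"] == len(system)
        assert rep["residues"] == 5
        assert rep["waters"] == 2
        assert rep["junctions"] == 0
        assert rep["net_formal_charge"] == 0

    def test_counts_monotone_in_radius(self):
        system, _ = generate(FixtureSpec(6, ("ALA", "GLU"), n_waters=3, seed=2))
        base = frozenset(system.residue(2).atom_indices)
        r1, _ = select_bigqm(system, BigQMSpec(radius=3.0, base_qm=base))
        r2, _ = select_bigqm(system, BigQMSpec(radius=9.0, base_qm=base))
        a, b = region_report(system, r1), region_report(system, r2)
        for key in ("atoms", "residues", "waters"):
            assert a[key] <= b[key]


class TestExposure:
    def test_isolated_residue_fully_exposed(self):
        system, _ = generate(FixtureSpec(1, ("ALA",), seed=0))
        exposure = classify_exposure(system, n_sphere_points=240)
        assert exposure[0] == pytest.approx(1.0, abs=0.05)

    def test_enclosed_residue_is_buried(self):
        system, _ = generate(FixtureSpec(1, ("ALA",), seed=0))
        center = system.positions.mean(axis=0)
        # cage of dummy carbons on a tight sphere, dense enough that the
        # probe-inflated cage spheres cover the whole residue surface
        from qmmmkit.sasa import golden_spiral_points
        shell = center + 4.0 * golden_spiral_points(350)
        atoms = list(system.atoms)
        start = len(atoms)
        for k, p in enumerate(shell):
            atoms.append(AtomRecord(start + k, "XC", "C", 1, "CAG", tuple(p)))
        residues = [system.residues[0],
                    Residue(1, "CAG", tuple(range(start, start + len(shell))))]
        caged = MolecularSystem(atoms, system.bonds, residues)
        exposure = classify_exposure(caged, n_sphere_points=120)
        assert exposure[0] < 0.05

    def test_point_count_convergence(self):
        system, _ = generate(FixtureSpec(2, ("ALA", "ASP"), seed=4))
        lo = classify_exposure(system, n_sphere_points=480)
        hi = classify_exposure(system, n_sphere_points=960)
        for rid in lo:
            assert abs(lo[rid] - hi[rid]) < 0.02

    def test_rotation_translation_invariance(self):
        from .conftest import rotate_translate
        system, _ = generate(FixtureSpec(2, ("ALA", "GLU"), seed=6))
        ref = classify_exposure(system, n_sphere_points=480)
        moved_pos = rotate_translate(system.positions, seed=8)
        atoms = [
            AtomRecord(a.index, a.name, a.element, a.residue_id,
                       a.residue_name, tuple(moved_pos[i]), a.charge)
            for i, a in enumerate(system.atoms)
        ]
        moved = MolecularSystem(atoms, system.bonds, system.residues)
        out = classify_exposure(moved, n_sphere_points=480)
        for rid in ref:
            assert out[rid] == pytest.approx(ref[rid], abs=0.03)


@pytest.fixture(scope="module")
def charged_chain():
    return generate(FixtureSpec(
        6, ("ALA", "ARG", "ALA", "ASP", "LYS", "GLU"), seed=2))[0]


class TestNeutralization:
    def test_edits_zero_every_formal_charge(self, charged_chain):
        new, edits = neutralize_exposed_charges(
            charged_chain, [1, 3, 4, 5], pairing_rule=False)
        assert {e.residue_id for e in edits} == {1, 3, 4, 5}
        for rid in (1, 3, 4, 5):
            res = new.residue(rid)
            assert res.formal_charge == 0
            total = float(new.charges[list(res.atom_indices)].sum())
            assert total == pytest.approx(0.0, abs=1e-12)

    def test_specified_atoms_edited(self, charged_chain):
        new, edits = neutralize_exposed_charges(
            charged_chain, [1, 3, 4, 5], pairing_rule=False)
        by_rid = {e.residue_id: e for e in edits}
        assert (by_rid[1].action, by_rid[1].atom_name) == ("delete_atom", "HH22")
        assert (by_rid[4].action, by_rid[4].atom_name) == ("delete_atom", "HZ3")
        assert (by_rid[3].action, by_rid[3].atom_name) == ("add_proton", "OD1")
        assert (by_rid[5].action, by_rid[5].atom_name) == ("add_proton", "OE2")
        names1 = {new.atoms[i].name for i in new.residue(1).atom_indices}
        assert "HH22" not in names1

    def test_added_proton_geometry(self, charged_chain):
        new, _ = neutralize_exposed_charges(charged_chain, [3],
                                            pairing_rule=False)
        res = new.residue(3)
        names = {new.atoms[i].name: i for i in res.atom_indices}
        d = np.linalg.norm(
            np.array(new.atoms[names["HD1"]].position)
            - np.array(new.atoms[names["OD1"]].position))
        assert d == pytest.approx(0.97, abs=1e-6)
        # bonded to OD1 in the new topology
        assert names["HD1"] in new.neighbors(names["OD1"])

    def test_formal_charge_delta_bookkeeping(self, charged_chain):
        before = charged_chain.total_formal_charge()
        new, edits = neutralize_exposed_charges(
            charged_chain, [1, 3], pairing_rule=False)
        after = new.total_formal_charge()
        assert after - before == sum(e.formal_charge_delta for e in edits)

    def test_ion_paired_residues_untouched(self, charged_chain):
        pairs = find_ion_pairs(charged_chain)
        assert pairs  # the fixture has adjacent opposite charges
        protected = set().union(*pairs)
        rid = sorted(protected)[0]
        new, edits = neutralize_exposed_charges(charged_chain, [rid],
                                                pairing_rule=True)
        assert edits == []
        assert new.residue(rid).formal_charge == \
            charged_chain.residue(rid).formal_charge

    def test_wrong_residue_type_rejected(self, charged_chain):
        with pytest.raises(RegionError, match="not ARG/LYS/ASP/GLU"):
            neutralize_exposed_charges(charged_chain, [0], pairing_rule=False)
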