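"""Big-QM region construction and charged-residue neutralization.

QM/MM energies converge slowly with the size of the QM region, so the
big-QM approach re-evaluates the energy with a greatly enlarged region:
every residue with an atom within a radius r of the minimal QM region,
plus buried charged residues, plus the backbone of flanking residues,
with junctions relocated at least two residues away from the original
region and cuts restricted to backbone C–N or CA–CB bonds.

Solvent-exposed charged residues left outside the region dominate the
residual error; they can be neutralized structurally — arginine by
deleting HH22, lysine by deleting HZ3, aspartate/glutamate by
protonating OD1/OE2 — unless they sit in an ion pair, which is already
net neutral.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.spatial import cKDTree

from .constants import MAX_ASA_GXG
from .sasa import DEFAULT_N_POINTS, DEFAULT_PROBE_RADIUS, shrake_rupley
from .system import AtomRecord, MolecularSystem, Residue

BACKBONE_NAMES = ("N", "H", "CA", "HA", "C", "O")
NEUTRALIZABLE = {"ARG": "HH22", "LYS": "HZ3", "ASP": "OD1", "GLU": "OE2"}


class RegionError(ValueError):
    """Invalid big-QM specification."""


@dataclass(frozen=True)
class BigQMSpec:
    """Parameters of a big-QM region selection.

    ``radius`` in Å from the base QM atoms; ``backbone_spans`` are
    inclusive residue-id ranges whose backbone atoms are added;
    ``whole_residues`` switches between whole-residue completion
    (default, required for the junction-relocation rule) and raw
    atom-level selection.
    """

    radius: float
    base_qm: frozenset[int]
    backbone_spans: tuple[tuple[int, int], ...] = ()
    include_buried_charges: bool = True
    neutralize_exposed: bool = False
    sasa_buried_threshold: float = 0.05
    sasa_exposed_threshold: float = 0.20
    whole_residues: bool = True

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise RegionError("big-QM radius must be positive")
        if not self.base_qm:
            raise RegionError("base QM region must be non-empty")


@dataclass(frozen=True)
class NeutralizationEdit:
    """One structural neutralization: a deleted proton (ARG/LYS) or an
    added carboxylate proton (ASP/GLU)."""

    residue_id: int
    action: str  # "delete_atom" | "add_proton"
    atom_name: str
    formal_charge_delta: int


def _is_water(res: Residue) -> bool:
    return res.name.upper() in ("HOH", "WAT", "TIP3", "SOL")


def _is_polymer(res: Residue, system: MolecularSystem) -> bool:
    names = {system.atoms[i].name for i in res.atom_indices}
    return {"N", "CA", "C"} <= names


def classify_exposure(
    system: MolecularSystem,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_POINTS,
    reference: str = "isolated",
) -> dict[int, float]:
    """Relative SASA per residue (residue SASA / reference maximum).

    ``reference='isolated'`` (default) recomputes each residue's SASA
    with all other atoms removed, which makes an unoccluded residue
    score exactly 1 regardless of its geometry; ``'gxg'`` divides by a
    standard Gly-X-Gly theoretical maximum table instead (real residue
    types only).
    """
    pos = system.positions
    elems = [a.element for a in system.atoms]
    per_atom = shrake_rupley(pos, elems, probe_radius, n_sphere_points)
    out: dict[int, float] = {}
    for res in system.residues:
        idx = list(res.atom_indices)
        sasa = float(per_atom[idx].sum())
        if reference == "isolated":
            ref = float(
                shrake_rupley(pos[idx], [elems[i] for i in idx],
                              probe_radius, n_sphere_points).sum()
            )
        elif reference == "gxg":
            try:
                ref = MAX_ASA_GXG[res.name.upper()]
            except KeyError as exc:
                raise RegionError(
                    f"no Gly-X-Gly reference area for residue type {res.name!r}"
                ) from exc
        else:
            raise RegionError(f"unknown reference mode {reference!r}")
        out[res.residue_id] = sasa / ref if ref > 0 else 0.0
    return out


def _sequence_distance_ok(cut: tuple[int, int], base_rids: set[int]) -> bool:
    """Peptide cut between adjacent residues (j, j+1) must be at least
    two residues (in sequence) from every base-QM residue."""
    lo, hi = cut
    return all(min(abs(lo - b), abs(hi - b)) >= 2 for b in base_rids)


def select_bigqm(
    system: MolecularSystem, spec: BigQMSpec
) -> tuple[frozenset[int], dict]:
    """Select the big-QM atom set and report the resulting cuts.

    Steps: (i) whole-residue inclusion of everything within ``radius``
    of the base QM atoms; (ii) backbone atoms of the requested spans;
    (iii) whole buried charged residues; (iv) relocation of peptide
    cuts to at least two residues from the base region, with cuts
    allowed only at backbone C–N or CA–CB bonds.
    """
    if not spec.base_qm <= set(range(len(system))):
        raise RegionError("base QM region references atoms outside the system")
    pos = system.positions
    tree = cKDTree(pos[sorted(spec.base_qm)])

    region: set[int] = set(spec.base_qm)
    whole_rids: set[int] = set()

    # (i) distance rule
    dmin, _ = tree.query(pos, k=1)
    for res in system.residues:
        if any(dmin[i] <= spec.radius for i in res.atom_indices):
            if spec.whole_residues or _is_water(res):
                region.update(res.atom_indices)
                whole_rids.add(res.residue_id)
            else:
                region.update(i for i in res.atom_indices if dmin[i] <= spec.radius)

    # (ii) backbone spans
    known_rids = {r.residue_id for r in system.residues}
    for lo, hi in spec.backbone_spans:
        for rid in range(lo, hi + 1):
            if rid not in known_rids:
                raise RegionError(f"backbone span references unknown residue {rid}")
            if rid in whole_rids:
                continue
            res = system.residue(rid)
            region.update(
                i for i in res.atom_indices
                if system.atoms[i].name in BACKBONE_NAMES
            )

    # (iii) buried charged residues
    if spec.include_buried_charges:
        charged = [r for r in system.residues
                   if r.formal_charge != 0 and r.residue_id not in whole_rids]
        if charged:
            exposure = classify_exposure(system)
            for res in charged:
                if exposure[res.residue_id] < spec.sasa_buried_threshold:
                    region.update(res.atom_indices)
                    whole_rids.add(res.residue_id)

    # (iv) junction relocation on peptide cuts
    base_rids = {system.residue_of(i).residue_id for i in spec.base_qm}
    relocated: list[tuple[int, int]] = []
    if spec.whole_residues:
        for _ in range(len(system.residues) + 1):
            cut_to_fix = None
            for a, b in system.bonds:
                if (a in region) == (b in region):
                    continue
                inside, outside = (a, b) if a in region else (b, a)
                na, nb = system.atoms[inside].name, system.atoms[outside].name
                ra = system.residue_of(inside)
                rb = system.residue_of(outside)
                if ra.residue_id == rb.residue_id and {na, nb} == {"CA", "CB"}:
                    continue  # backbone-span capping cut: always allowed
                if {na, nb} == {"C", "N"} and abs(ra.residue_id - rb.residue_id) == 1:
                    pair = tuple(sorted((ra.residue_id, rb.residue_id)))
                    if _sequence_distance_ok(pair, base_rids):
                        continue
                # disallowed or too-close cut: pull in the outside residue
                cut_to_fix = rb
                break
            if cut_to_fix is None:
                break
            region.update(cut_to_fix.atom_indices)
            whole_rids.add(cut_to_fix.residue_id)
            relocated.append((cut_to_fix.residue_id, len(region)))
        else:
            warnings.warn("junction relocation hit the chain end; cutting at terminus")

    cuts = sorted(
        (a, b) if a in region else (b, a)
        for a, b in system.bonds
        if (a in region) != (b in region)
    )
    report = {
        "n_atoms": len(region),
        "whole_residues": sorted(whole_rids),
        "cuts": cuts,
        "relocations": relocated,
    }
    return frozenset(region), report


def region_report(system: MolecularSystem, region: frozenset[int]) -> dict:
    """Exact counts for a region: atoms, touched residues, whole
    waters, boundary bonds and the net formal charge of fully
    contained residues."""
    region = frozenset(region)
    touched = [r for r in system.residues if set(r.atom_indices) & region]
    whole = [r for r in touched if set(r.atom_indices) <= region]
    return {
        "atoms": len(region),
        "residues": len(touched),
        "waters": sum(1 for r in whole if _is_water(r)),
        "junctions": sum(1 for a, b in system.bonds if (a in region) != (b in region)),
        "net_formal_charge": sum(r.formal_charge for r in whole),
    }


def find_ion_pairs(
    system: MolecularSystem, contact_cutoff: float = 4.0
) -> set[frozenset[int]]:
    """Residue-id pairs of opposite formal charge with any
    inter-residue heavy-atom contact below the cutoff."""
    charged = [r for r in system.residues if r.formal_charge != 0]
    pos = system.positions
    pairs: set[frozenset[int]] = set()
    for i, ra in enumerate(charged):
        heavy_a = [k for k in ra.atom_indices if system.atoms[k].element.upper() != "H"]
        for rb in charged[i + 1:]:
            if ra.formal_charge * rb.formal_charge >= 0:
                continue
            heavy_b = [k for k in rb.atom_indices
                       if system.atoms[k].element.upper() != "H"]
            d = np.linalg.norm(
                pos[heavy_a][:, None, :] - pos[heavy_b][None, :, :], axis=2
            )
            if float(d.min()) < contact_cutoff:
                pairs.add(frozenset((ra.residue_id, rb.residue_id)))
    return pairs


def _proton_position(system: MolecularSystem, res: Residue) -> np.ndarray:
    """0.97 Å from the target carboxylate O, along the in-plane
    bisector pointing away from the carboxylate carbon and the other
    oxygen."""
    names = {system.atoms[i].name: i for i in res.atom_indices}
    if res.name.upper() == "ASP":
        c, o_t, o_o = names["CG"], names["OD1"], names["OD2"]
    else:
        c, o_t, o_o = names["CD"], names["OE2"], names["OE1"]
    pos = system.positions
    u1 = pos[o_t] - pos[c]
    u1 /= np.linalg.norm(u1)
    u2 = pos[o_t] - pos[o_o]
    u2 /= np.linalg.norm(u2)
    d = u1 + u2
    d /= np.linalg.norm(d)
    return pos[o_t] + 0.97 * d


def neutralize_exposed_charges(
    system: MolecularSystem,
    exposed_residues: list[int],
    pairing_rule: bool = True,
    pairing_cutoff: float = 4.0,
) -> tuple[MolecularSystem, list[NeutralizationEdit]]:
    """Neutralize charged residues structurally.

    ARG loses HH22, LYS loses HZ3, ASP gains a proton on OD1, GLU on
    OE2 (placed 0.97 Å from the O along the in-plane bisector away
    from the carboxylate carbon).  Residues participating in an ion
    pair are left untouched when the pairing rule is on.  After each
    edit the residue's formal charge is 0 and its partial charges are
    shifted uniformly so they sum to the new formal charge.
    """
    paired: set[int] = set()
    if pairing_rule:
        for pair in find_ion_pairs(system, pairing_cutoff):
            paired |= set(pair)

    edits: list[NeutralizationEdit] = []
    delete: set[int] = set()
    protons: list[tuple[int, str, np.ndarray, int]] = []  # (rid, name, pos, bond-to)
    shift_rids: set[int] = set()

    for rid in exposed_residues:
        res = system.residue(rid)
        rname = res.name.upper()
        if rname not in NEUTRALIZABLE:
            raise RegionError(
                f"residue {rid} ({res.name}) is not ARG/LYS/ASP/GLU"
            )
        if rid in paired:
            continue
        if res.formal_charge == 0:
            warnings.warn(f"residue {rid} already neutral; no edit applied")
            continue
        names = {system.atoms[i].name: i for i in res.atom_indices}
        target = NEUTRALIZABLE[rname]
        if rname in ("ARG", "LYS"):
            if target not in names:
                raise RegionError(f"residue {rid}: atom {target} absent")
            delete.add(names[target])
            edits.append(NeutralizationEdit(rid, "delete_atom", target, -1))
        else:
            if target not in names:
                raise RegionError(f"residue {rid}: atom {target} absent")
            hname = "HD1" if rname == "ASP" else "HE2"
            protons.append((rid, hname, _proton_position(system, res), names[target]))
            edits.append(NeutralizationEdit(rid, "add_proton", target, +1))
        shift_rids.add(rid)

    # rebuild atom list with deletions and insertions, remapping indices
    new_atoms: list[AtomRecord] = []
    remap: dict[int, int] = {}
    proton_by_rid = {rid: (hn, p, bond_to) for rid, hn, p, bond_to in protons}
    new_bonds: list[tuple[int, int]] = []
    new_residues: list[Residue] = []
    for res in system.residues:
        indices: list[int] = []
        for old in res.atom_indices:
            if old in delete:
                continue
            a = system.atoms[old]
            idx = len(new_atoms)
            remap[old] = idx
            new_atoms.append(AtomRecord(idx, a.name, a.element, a.residue_id,
                                        a.residue_name, a.position, a.charge,
                                        a.serial))
            indices.append(idx)
        if res.residue_id in proton_by_rid:
            hname, ppos, bond_to = proton_by_rid[res.residue_id]
            idx = len(new_atoms)
            new_atoms.append(AtomRecord(idx, hname, "H", res.residue_id,
                                        res.name, tuple(ppos), 0.0))
            indices.append(idx)
            new_bonds.append((remap[bond_to], idx))
        formal = 0 if res.residue_id in shift_rids else res.formal_charge
        new_residues.append(Residue(res.residue_id, res.name, tuple(indices), formal))
    for a, b in system.bonds:
        if a in delete or b in delete:
            continue
        new_bonds.append((remap[a], remap[b]))

    out = MolecularSystem(new_atoms, new_bonds, new_residues)
    # re-close partial charges onto the new formal charge
    charge_fix: dict[int, float] = {}
    for rid in shift_rids:
        res = out.residue(rid)
        idx = list(res.atom_indices)
        excess = float(out.charges[idx].sum()) - res.formal_charge
        for i in idx:
            charge_fix[i] = float(out.charges[i]) - excess / len(idx)
    if charge_fix:
        out = out.with_charges(charge_fix)
    return out, edits
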