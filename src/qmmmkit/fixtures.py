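"""Deterministic generator of synthetic peptide-like systems.

The fixtures are chemically plausible but invented: linear polymer
chains with named backbone atoms (N, H, CA, HA, C, O), small side
chains carrying the atom names the neutralization rules key on (HH22,
HZ3, OD1, OE2), optional waters, and per-residue partial charges that
sum exactly to the residue's formal charge.  Geometries use ~1.5 Å
backbone spacing and make no claim of physical realism — they exist
to exercise graph, charge and distance logic, not to model any real
protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boundary import Junction, LinkAtomRule, find_junctions
from .mm import ForceFieldTerms
from .system import AtomRecord, MolecularSystem, RegionPartition, Residue

# residue templates: atom -> (element, local position); bonds by name
_BB = {
    "N": ("N", (0.0, 0.0, 0.0)),
    "H": ("H", (-0.3, -0.9, 0.3)),
    "CA": ("C", (1.45, 0.35, 0.15)),
    "HA": ("H", (1.45, 0.95, 1.05)),
    "C": ("C", (2.90, 0.00, -0.10)),
    "O": ("O", (3.10, 1.15, -0.55)),
}
_BB_BONDS = [("N", "H"), ("N", "CA"), ("CA", "HA"), ("CA", "C"), ("C", "O")]

_SIDE = {
    "ALA": (
        {"CB": ("C", (1.5, 1.6, -0.6)),
         "HB1": ("H", (0.9, 2.4, -0.2)),
         "HB2": ("H", (2.5, 2.0, -0.7))},
        [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2")],
        0,
    ),
    "ARG": (
        {"CB": ("C", (1.5, 1.8, 0.3)),
         "HB2": ("H", (0.6, 2.2, 0.7)),
         "CG": ("C", (1.7, 2.9, -0.7)),
         "CD": ("C", (1.9, 4.3, -0.2)),
         "NE": ("N", (2.1, 5.3, -1.2)),
         "CZ": ("C", (2.3, 6.7, -1.0)),
         "NH1": ("N", (2.4, 7.2, 0.25)),
         "NH2": ("N", (2.4, 7.5, -2.05)),
         "HH21": ("H", (2.3, 7.05, -2.95)),
         "HH22": ("H", (2.6, 8.5, -2.0))},
        [("CA", "CB"), ("CB", "HB2"), ("CB", "CG"), ("CG", "CD"),
         ("CD", "NE"), ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2"),
         ("NH2", "HH21"), ("NH2", "HH22")],
        +1,
    ),
    "LYS": (
        {"CB": ("C", (1.5, 1.8, 0.3)),
         "HB2": ("H", (0.6, 2.2, 0.7)),
         "CG": ("C", (1.7, 2.9, -0.7)),
         "CD": ("C", (1.9, 4.3, -0.2)),
         "CE": ("C", (2.1, 5.3, -1.2)),
         "NZ": ("N", (2.3, 6.7, -0.8)),
         "HZ1": ("H", (2.4, 7.3, -1.62)),
         "HZ2": ("H", (1.5, 7.05, -0.28)),
         "HZ3": ("H", (3.15, 6.8, -0.24))},
        [("CA", "CB"), ("CB", "HB2"), ("CB", "CG"), ("CG", "CD"),
         ("CD", "CE"), ("CE", "NZ"), ("NZ", "HZ1"), ("NZ", "HZ2"),
         ("NZ", "HZ3")],
        +1,
    ),
    "ASP": (
        {"CB": ("C", (1.5, 1.8, 0.3)),
         "HB2": ("H", (0.6, 2.2, 0.7)),
         "CG": ("C", (1.7, 2.9, -0.7)),
         "OD1": ("O", (1.0, 3.95, -0.55)),
         "OD2": ("O", (2.55, 2.85, -1.65))},
        [("CA", "CB"), ("CB", "HB2"), ("CB", "CG"), ("CG", "OD1"),
         ("CG", "OD2")],
        -1,
    ),
    "GLU": (
        {"CB": ("C", (1.5, 1.8, 0.3)),
         "HB2": ("H", (0.6, 2.2, 0.7)),
         "CG": ("C", (1.7, 2.9, -0.7)),
         "CD": ("C", (1.9, 4.3, -0.2)),
         "OE1": ("O", (1.2, 5.3, -0.05)),
         "OE2": ("O", (3.1, 4.5, 0.05))},
        [("CA", "CB"), ("CB", "HB2"), ("CB", "CG"), ("CG", "CD"),
         ("CD", "OE1"), ("CD", "OE2")],
        -1,
    ),
    # side chain closing a four-membered ring: CB bonded to both CG1
    # and CG2, which share CD — exercises shell disjointing
    "RNG": (
        {"CB": ("C", (1.5, 1.8, 0.3)),
         "CG1": ("C", (0.8, 3.0, -0.2)),
         "CG2": ("C", (2.5, 3.0, 0.1)),
         "CD": ("C", (1.7, 4.1, -0.1)),
         "HD": ("H", (1.7, 5.1, -0.3))},
        [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD"),
         ("CG2", "CD"), ("CD", "HD")],
        0,
    ),
}

_WATER = (
    {"O": ("O", (0.0, 0.0, 0.0)),
     "H1": ("H", (0.76, 0.59, 0.0)),
     "H2": ("H", (-0.76, 0.59, 0.0))},
    [("O", "H1"), ("O", "H2")],
    0,
)

#: TIP3P-style fixed water charges (e)
_WATER_CHARGES = {"O": -0.834, "H1": 0.417, "H2": 0.417}

_LJ_BY_ELEMENT = {
    "H": (0.0657, 2.471),
    "C": (0.3598, 3.400),
    "N": (0.7113, 3.250),
    "O": (0.8803, 3.000),
    "S": (1.0460, 3.564),
}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic system.

    ``palette`` gives the residue type at each chain position (cycled
    if shorter than ``n_residues``); ``n_waters`` appends isolated
    waters behind the chain.  Identical spec + seed gives bit-identical
    output.
    """

    n_residues: int
    palette: tuple[str, ...] = ("ALA",)
    n_waters: int = 0
    seed: int = 0
    charge_spread: float = 0.4

    def residue_name(self, i: int) -> str:
        return self.palette[i % len(self.palette)].upper()


def generate(spec: FixtureSpec) -> tuple[MolecularSystem, ForceFieldTerms]:
    """Build the system and a matching force-field term table.

    Partial charges are drawn per residue and shifted so each
    residue's sum equals its formal charge exactly (waters use fixed
    TIP3P-style charges).  Bond and angle terms are populated for
    every bond/1-3 path with equilibrium values slightly offset from
    the fixture geometry so bonded energies are non-zero; torsions run
    along the backbone.
    """
    rng = np.random.default_rng(spec.seed)
    atoms: list[AtomRecord] = []
    bonds: list[tuple[int, int]] = []
    residues: list[Residue] = []
    prev_c: int | None = None

    for r in range(spec.n_residues):
        rname = spec.residue_name(r)
        if rname not in _SIDE:
            raise ValueError(f"unknown palette entry {rname!r}")
        side_atoms, side_bonds, formal = _SIDE[rname]
        offset = np.array([4.35 * r, 0.55 * (r % 2), 0.3 * ((r // 2) % 2)])
        local: dict[str, int] = {}
        start = len(atoms)
        for name, (elem, lpos) in {**_BB, **side_atoms}.items():
            idx = len(atoms)
            local[name] = idx
            atoms.append(AtomRecord(idx, name, elem, r, rname,
                                    tuple(np.asarray(lpos) + offset)))
        for a, b in _BB_BONDS + side_bonds:
            bonds.append((local[a], local[b]))
        if prev_c is not None:
            bonds.append((prev_c, local["N"]))
        prev_c = local["C"]

        n = len(atoms) - start
        raw = rng.uniform(-spec.charge_spread, spec.charge_spread, n)
        raw += (formal - raw.sum()) / n
        for k in range(n):
            a = atoms[start + k]
            atoms[start + k] = AtomRecord(a.index, a.name, a.element,
                                          a.residue_id, a.residue_name,
                                          a.position, float(raw[k]))
        residues.append(Residue(r, rname, tuple(range(start, len(atoms))), formal))

    for w in range(spec.n_waters):
        wat_atoms, wat_bonds, _ = _WATER
        offset = np.array([1.5 + 3.0 * (w % 5), -4.0 - 3.0 * (w // 5), 4.5])
        local = {}
        start = len(atoms)
        rid = spec.n_residues + w
        for name, (elem, lpos) in wat_atoms.items():
            idx = len(atoms)
            local[name] = idx
            atoms.append(AtomRecord(idx, name, elem, rid, "HOH",
                                    tuple(np.asarray(lpos) + offset),
                                    _WATER_CHARGES[name]))
        for a, b in wat_bonds:
            bonds.append((local[a], local[b]))
        residues.append(Residue(rid, "HOH", tuple(range(start, len(atoms))), 0))

    system = MolecularSystem(atoms, bonds, residues)
    return system, default_terms(system)


def default_terms(system: MolecularSystem) -> ForceFieldTerms:
    """Force-field term table matching a fixture's topology: harmonic
    bonds/angles with equilibria offset from the current geometry,
    backbone torsions, and element-based LJ parameters."""
    pos = system.positions
    bond_terms = {}
    for i, j in sorted(system.bonds):
        r = float(np.linalg.norm(pos[i] - pos[j]))
        bond_terms[(i, j)] = (1000.0, r - 0.02)
    angle_terms = {}
    for j in range(len(system)):
        nbrs = sorted(system.neighbors(j))
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                i, k = nbrs[a], nbrs[b]
                v1, v2 = pos[i] - pos[j], pos[k] - pos[j]
                cos_t = float(np.dot(v1, v2) /
                              (np.linalg.norm(v1) * np.linalg.norm(v2)))
                th = float(np.arccos(np.clip(cos_t, -1.0, 1.0)))
                angle_terms[(i, j, k)] = (300.0, th - 0.05)
    torsion_terms = {}
    name_of = {i: a.name for i, a in enumerate(system.atoms)}
    for i, j in sorted(system.bonds):
        if {name_of[i], name_of[j]} == {"CA", "C"}:
            ca, c = (i, j) if name_of[i] == "CA" else (j, i)
            n_prev = next((x for x in system.neighbors(ca)
                           if name_of[x] == "N"), None)
            n_next = next((x for x in system.neighbors(c)
                           if name_of[x] == "N"), None)
            if n_prev is not None and n_next is not None:
                torsion_terms[(n_prev, ca, c, n_next)] = ((4.0, 2.0, np.pi),)
    lj = {i: _LJ_BY_ELEMENT[a.element.upper()] for i, a in enumerate(system.atoms)}
    return ForceFieldTerms(bonds=bond_terms, angles=angle_terms,
                           torsions=torsion_terms, lj=lj)


def _side_chain_atoms(system: MolecularSystem, rid: int) -> set[int]:
    res = system.residue(rid)
    return {i for i in res.atom_indices
            if system.atoms[i].name not in ("N", "H", "CA", "HA", "C", "O")}


def make_junction_case(
    kind: str, seed: int = 0
) -> tuple[MolecularSystem, ForceFieldTerms, RegionPartition, list[Junction]]:
    """Named boundary topologies for testing the shell logic.

    ``single_cut``: one CA–CB cut with the whole side chain on the MM
    side; ``two_cuts_same_residue``: the middle residue is MM, cut on
    both peptide bonds; ``ring_adjacent``: the cut side chain closes a
    ring inside M2/M3; ``water_in_qm``: a whole water inside the QM
    region (no junction from it).
    """
    if kind == "single_cut":
        system, terms = generate(FixtureSpec(3, ("ALA", "ARG", "ALA"), seed=seed))
        qm = frozenset(range(len(system))) - frozenset(_side_chain_atoms(system, 1))
    elif kind == "two_cuts_same_residue":
        system, terms = generate(FixtureSpec(3, ("ALA", "ARG", "ALA"), seed=seed))
        qm = frozenset(system.residue(0).atom_indices) | frozenset(
            system.residue(2).atom_indices)
    elif kind == "ring_adjacent":
        system, terms = generate(FixtureSpec(3, ("ALA", "RNG", "ALA"), seed=seed))
        qm = frozenset(range(len(system))) - frozenset(_side_chain_atoms(system, 1))
    elif kind == "water_in_qm":
        system, terms = generate(FixtureSpec(2, ("ALA", "ALA"), n_waters=1, seed=seed))
        qm = frozenset(system.residue(0).atom_indices) | frozenset(
            system.residue(2).atom_indices)
    else:
        raise ValueError(f"unknown junction case {kind!r}")
    partition = RegionPartition.from_qm(system, qm)
    junctions = find_junctions(system, partition, LinkAtomRule())
    return system, terms, partition, junctions


def random_junction_fixture(
    seed: int,
) -> tuple[MolecularSystem, ForceFieldTerms, RegionPartition, list[Junction]]:
    """Seeded random system with one CA–CB junction whose M1–M3
    shells all lie inside a single long-side-chain residue (the
    geometry the per-residue redistribution schemes are defined for).
    """
    rng = np.random.default_rng(seed)
    n = int(rng.integers(3, 6))
    cut_pos = int(rng.integers(0, n))
    long_side = str(rng.choice(["ARG", "LYS", "GLU"]))
    palette = tuple(
        long_side if i == cut_pos else str(rng.choice(["ALA", "ASP"]))
        for i in range(n)
    )
    system, terms = generate(
        FixtureSpec(n, palette, n_waters=int(rng.integers(0, 3)),
                    seed=int(rng.integers(0, 2**31 - 1)))
    )
    qm = frozenset(range(len(system))) - frozenset(
        _side_chain_atoms(system, cut_pos))
    partition = RegionPartition.from_qm(system, qm)
    junctions = find_junctions(system, partition, LinkAtomRule())
    return system, terms, partition, junctions
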