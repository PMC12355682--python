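"""Core molecular-system representation and the QM/MM partition.

A :class:`MolecularSystem` bundles atoms (names, elements, coordinates,
partial charges), a covalent bond graph and an exact residue partition.
Everything downstream — junction detection, point-charge models, the
energy assembly, big-QM selection — queries this object.

Units: Å for coordinates, e for charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .constants import COVALENT_RADII, DEFAULT_BOND_TOLERANCE


class SystemError(ValueError):
    """Raised for inconsistent system definitions (dangling bonds,
    overlapping residues, non-finite coordinates)."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, residue membership, position and charge.

    ``index`` is the 0-based internal index; ``serial`` preserves the
    1-based PDB serial when the atom came from a PDB file.
    """

    index: int
    name: str
    element: str
    residue_id: int
    residue_name: str
    position: tuple[float, float, float]
    charge: float = 0.0
    serial: int | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise SystemError(
                f"atom {self.index} ({self.name}): non-finite or malformed position"
            )
        if not self.element:
            raise SystemError(f"atom {self.index}: empty element symbol")


@dataclass(frozen=True)
class Residue:
    """A residue: contiguous group of atoms with a formal charge in e."""

    residue_id: int
    name: str
    atom_indices: tuple[int, ...]
    formal_charge: int = 0


class MolecularSystem:
    """Validated atoms + bond graph + residue partition.

    Parameters
    ----------
    atoms
        Ordered atom records; ``atoms[i].index == i`` is enforced.
    bonds
        Unordered pairs of atom indices.
    residues
        Ordered residues whose ``atom_indices`` partition the atom set.
    """

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        bonds: Iterable[tuple[int, int]],
        residues: Sequence[Residue],
    ) -> None:
        self.atoms: tuple[AtomRecord, ...] = tuple(atoms)
        n = len(self.atoms)
        for i, atom in enumerate(self.atoms):
            if atom.index != i:
                raise SystemError(
                    f"atom at position {i} carries index {atom.index}; "
                    "indices must be 0..n-1 in order"
                )

        normalized: set[tuple[int, int]] = set()
        for a, b in bonds:
            a, b = int(a), int(b)
            if a == b:
                raise SystemError(f"self-bond on atom {a}")
            if not (0 <= a < n and 0 <= b < n):
                raise SystemError(f"dangling bond ({a}, {b}) in {n}-atom system")
            normalized.add((min(a, b), max(a, b)))
        self.bonds: frozenset[tuple[int, int]] = frozenset(normalized)

        self.residues: tuple[Residue, ...] = tuple(residues)
        seen: set[int] = set()
        for res in self.residues:
            for idx in res.atom_indices:
                if not 0 <= idx < n:
                    raise SystemError(
                        f"residue {res.residue_id} references missing atom {idx}"
                    )
                if idx in seen:
                    raise SystemError(
                        f"atom {idx} appears in more than one residue"
                    )
                seen.add(idx)
        if seen != set(range(n)):
            missing = sorted(set(range(n)) - seen)[:5]
            raise SystemError(f"residues do not cover atoms, e.g. {missing}")

        self._graph = nx.Graph()
        self._graph.add_nodes_from(range(n))
        self._graph.add_edges_from(self.bonds)
        self._residue_of = {
            idx: res for res in self.residues for idx in res.atom_indices
        }
        self._residue_by_id = {res.residue_id: res for res in self.residues}

    # -- basic queries -------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def graph(self) -> nx.Graph:
        return self._graph

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) coordinate array in Å."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        """(n,) partial-charge array in e."""
        return np.array([a.charge for a in self.atoms], dtype=float)

    def neighbors(self, index: int) -> frozenset[int]:
        return frozenset(self._graph.neighbors(index))

    def bond_path_length(self, i: int, j: int) -> int:
        """Shortest path length through the bond graph (bonds counted)."""
        return nx.shortest_path_length(self._graph, i, j)

    def residue_of(self, index: int) -> Residue:
        return self._residue_of[index]

    def residue(self, residue_id: int) -> Residue:
        return self._residue_by_id[residue_id]

    def total_formal_charge(self) -> int:
        return sum(r.formal_charge for r in self.residues)

    # -- derived systems ----------------------------------------------

    def with_charges(self, charges: Mapping[int, float] | np.ndarray) -> "MolecularSystem":
        """Copy with some (or all) partial charges replaced."""
        if isinstance(charges, np.ndarray):
            charges = dict(enumerate(charges.tolist()))
        atoms = [
            AtomRecord(
                a.index, a.name, a.element, a.residue_id, a.residue_name,
                a.position, float(charges.get(a.index, a.charge)), a.serial,
            )
            for a in self.atoms
        ]
        return MolecularSystem(atoms, self.bonds, self.residues)


def build_system(
    atoms: Sequence[AtomRecord],
    bonds: Iterable[tuple[int, int]],
    residues: Sequence[Residue],
) -> MolecularSystem:
    """Validate and assemble a :class:`MolecularSystem`."""
    return MolecularSystem(atoms, bonds, residues)


def net_charge(system: MolecularSystem, subset: Iterable[int] | None = None) -> float:
    """Exact sum of partial charges over ``subset`` (default: all atoms)."""
    if subset is None:
        return float(system.charges.sum())
    idx = sorted(set(subset))
    if idx and (idx[0] < 0 or idx[-1] >= len(system)):
        raise SystemError("subset references atoms outside the system")
    if not idx:
        return 0.0
    return float(system.charges[idx].sum())


def infer_bonds_from_distance(
    system: MolecularSystem,
    tolerance: float = DEFAULT_BOND_TOLERANCE,
    radii: Mapping[str, float] | None = None,
) -> frozenset[tuple[int, int]]:
    """Infer covalent bonds from interatomic distances.

    Pair (i, j) is bonded iff ``|r_i - r_j| <= radius_i + radius_j +
    tolerance``.  Hydrogens are restricted to at most one heavy-atom
    bond (closest wins; exact ties go to the smaller atom index).
    Atoms that end up with no bonds (ions, isolated waters read without
    hydrogens) are allowed.
    """
    from scipy.spatial import cKDTree

    radii = dict(radii or COVALENT_RADII)
    pos = system.positions
    elems = [a.element.upper() for a in system.atoms]
    r = np.array([radii.get(e, 0.77) for e in elems])
    max_cut = 2 * r.max() + tolerance

    tree = cKDTree(pos)
    pairs = tree.query_pairs(max_cut, output_type="ndarray")
    bonds: set[tuple[int, int]] = set()
    for i, j in pairs:
        d = float(np.linalg.norm(pos[i] - pos[j]))
        if d <= r[i] + r[j] + tolerance:
            bonds.add((int(min(i, j)), int(max(i, j))))

    # hydrogens: keep only the closest heavy partner (ties -> smaller index)
    for h in range(len(system)):
        if elems[h] != "H":
            continue
        partners = [
            (i if j == h else j)
            for (i, j) in bonds
            if h in (i, j) and elems[i if j == h else j] != "H"
        ]
        if len(partners) <= 1:
            continue
        best = min(
            partners,
            key=lambda p: (round(float(np.linalg.norm(pos[h] - pos[p])), 12), p),
        )
        for p in partners:
            if p != best:
                bonds.discard((min(h, p), max(h, p)))
    return frozenset(bonds)


@dataclass(frozen=True)
class RegionPartition:
    """The QM/MM split: system 1 (QM) and system 2 (MM).

    The QM set must be non-empty; QM and MM together cover every atom
    exactly once.
    """

    qm_atoms: frozenset[int]
    mm_atoms: frozenset[int]

    @classmethod
    def from_qm(cls, system: MolecularSystem, qm_atoms: Iterable[int]) -> "RegionPartition":
        qm = frozenset(int(i) for i in qm_atoms)
        if not qm:
            raise SystemError("QM region must be non-empty")
        all_atoms = frozenset(range(len(system)))
        if not qm <= all_atoms:
            raise SystemError("QM region references atoms outside the system")
        return cls(qm_atoms=qm, mm_atoms=all_atoms - qm)

    def __post_init__(self) -> None:
        if not self.qm_atoms:
            raise SystemError("QM region must be non-empty")
        if self.qm_atoms & self.mm_atoms:
            raise SystemError("QM and MM regions overlap")
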