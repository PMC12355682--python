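"""QM/MM junction detection, boundary-shell classification and
hydrogen link-atom placement.

When a covalent bond crosses the QM/MM boundary (a *junction*), the QM
fragment is capped with a hydrogen link atom (HL) placed on the
Q1–M1 axis; the real MM atom it stands in for is the carbon link
atom (CL = M1).  Atoms are classified into graph shells around the cut
bond: Q1 is the QM atom of the bond, Q2 its other QM neighbours, Q3
their neighbours; M1 is the MM atom, M2 its other neighbours, M3
theirs.  The shells feed the charge-redistribution schemes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import standard_bond_length
from .system import MolecularSystem, RegionPartition


class BoundaryError(ValueError):
    """Unsupported or degenerate QM/MM boundary topology/geometry."""


@dataclass(frozen=True)
class LinkAtomRule:
    """How the HL hydrogen is positioned on the Q1->M1 axis.

    ``scaled``: r_HL = r_Q1 + g (r_M1 - r_Q1) with 0 < g <= 1.  When
    ``scale`` is None, g is taken per junction from standard bond
    lengths as d0(Q1-H)/d0(Q1-M1) (C-H 1.090 / C-C 1.526 ≈ 0.7143 for
    a C-C cut).  ``fixed_length``: HL sits at the stated distance from
    Q1 along the same direction.
    """

    mode: str = "scaled"  # "scaled" | "fixed_length"
    scale: float | None = None
    fixed_length: float = 1.090

    def __post_init__(self) -> None:
        if self.mode not in ("scaled", "fixed_length"):
            raise BoundaryError(f"unknown link-atom mode {self.mode!r}")
        if self.scale is not None and not 0.0 < self.scale <= 1.0:
            raise BoundaryError("link-atom scale must satisfy 0 < g <= 1")
        if self.fixed_length <= 0:
            raise BoundaryError("fixed link-atom length must be positive")


@dataclass(frozen=True)
class Junction:
    """One boundary bond Q1-M1 with its classified shells and HL site.

    Shell sets are disjoint by priority (M1 > M2 > M3 and Q1 > Q2 > Q3)
    so ring closures never put an atom in two shells.
    """

    q1: int
    m1: int
    q2: frozenset[int]
    q3: frozenset[int]
    m2: frozenset[int]
    m3: frozenset[int]
    hl_position: tuple[float, float, float]


def _shells(
    system: MolecularSystem, first: int, anchor: int, region: frozenset[int]
) -> tuple[frozenset[int], frozenset[int]]:
    """Second and third bond-graph shells out from ``first``, staying in
    ``region`` and never re-entering an inner shell."""
    inner = {anchor, first}
    second = frozenset(
        n for n in system.neighbors(first) if n in region and n not in inner
    )
    inner |= second
    third: set[int] = set()
    for s in second:
        third.update(
            n for n in system.neighbors(s) if n in region and n not in inner
        )
    return second, frozenset(third)


def place_link_atom(
    junction_or_pair,
    system: MolecularSystem,
    rule: LinkAtomRule = LinkAtomRule(),
) -> tuple[float, float, float]:
    """Position the HL hydrogen for one junction.

    Accepts either a :class:`Junction` or a raw ``(q1, m1)`` pair.
    """
    if isinstance(junction_or_pair, Junction):
        q1, m1 = junction_or_pair.q1, junction_or_pair.m1
    else:
        q1, m1 = junction_or_pair
    r_q1 = np.asarray(system.atoms[q1].position, dtype=float)
    r_m1 = np.asarray(system.atoms[m1].position, dtype=float)
    delta = r_m1 - r_q1
    dist = float(np.linalg.norm(delta))
    if dist < 0.1:
        raise BoundaryError(
            f"degenerate junction geometry: |Q1-M1| = {dist:.3g} Å < 0.1 Å"
        )
    if rule.mode == "scaled":
        g = rule.scale
        if g is None:
            eq, em = system.atoms[q1].element, system.atoms[m1].element
            g = standard_bond_length(eq, "H") / standard_bond_length(eq, em)
        pos = r_q1 + g * delta
    else:
        pos = r_q1 + rule.fixed_length * delta / dist
    return (float(pos[0]), float(pos[1]), float(pos[2]))


def find_junctions(
    system: MolecularSystem,
    partition: RegionPartition,
    rule: LinkAtomRule = LinkAtomRule(),
) -> list[Junction]:
    """All boundary bonds with classified shells, ordered by (q1, m1).

    Rejects a hydrogen Q1 (cutting an X-H bond leaves no cappable
    valence) and an M1 bonded to two distinct Q1 atoms (a double
    junction, which no single HL can cap).
    """
    qm, mm = partition.qm_atoms, partition.mm_atoms
    crossing = sorted(
        (a, b) if a in qm else (b, a)
        for (a, b) in system.bonds
        if (a in qm) != (b in qm)
    )

    m1_owners: dict[int, int] = {}
    for q1, m1 in crossing:
        if system.atoms[q1].element.upper() == "H":
            raise BoundaryError(
                f"junction cuts a bond to hydrogen (Q1 = atom {q1})"
            )
        if m1 in m1_owners and m1_owners[m1] != q1:
            raise BoundaryError(
                f"unsupported double junction: M1 atom {m1} bonded to "
                f"Q1 atoms {m1_owners[m1]} and {q1}"
            )
        m1_owners[m1] = q1

    junctions = []
    for q1, m1 in crossing:
        q2, q3 = _shells(system, q1, m1, qm)
        m2, m3 = _shells(system, m1, q1, mm)
        hl = place_link_atom((q1, m1), system, rule)
        junctions.append(
            Junction(q1=q1, m1=m1, q2=q2, q3=q3, m2=m2, m3=m3, hl_position=hl)
        )
    return junctions
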