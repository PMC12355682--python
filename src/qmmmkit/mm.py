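"""Minimal pairwise molecular-mechanics evaluator.

Energy terms: harmonic bonds ``k (r - r0)^2``, harmonic angles
``k (θ - θ0)^2``, torsions ``V (1 + cos(nφ - γ))``, Lennard-Jones 12-6
with Lorentz–Berthelot combining, and point-charge Coulomb.  Standard
AMBER-style exclusions apply: 1-2 and 1-3 pairs are excluded, 1-4
pairs scaled (electrostatics by 1/1.2, LJ by 1/2 by default).  No
distance cutoff is ever applied.

The evaluator supports the charge-zeroing and link-atom-substitution
variants the QM/MM energy assembly needs: any atom set can have its
charges zeroed before the Coulomb sum, and junction M1 atoms can be
swapped for hydrogen link atoms (HL) at their link positions with
hydrogen LJ parameters and zero charge.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .boundary import Junction
from .constants import COULOMB_KJ
from .system import MolecularSystem, RegionPartition


class MMParameterError(KeyError):
    """A required force-field parameter is missing."""


@dataclass(frozen=True)
class ForceFieldTerms:
    """Force-field parameter tables keyed by atom indices.

    bonds: (i, j) -> (k [kJ/mol/Å^2], r0 [Å]);
    angles: (i, j, k) -> (k [kJ/mol/rad^2], θ0 [rad]);
    torsions: (i, j, k, l) -> sequence of (V [kJ/mol], periodicity, phase [rad]);
    lj: atom index -> (ε [kJ/mol], σ [Å]).
    ``hl_lj`` is the LJ parameter pair used for substituted hydrogen
    link atoms.
    """

    bonds: Mapping[tuple[int, int], tuple[float, float]] = field(default_factory=dict)
    angles: Mapping[tuple[int, int, int], tuple[float, float]] = field(default_factory=dict)
    torsions: Mapping[tuple[int, int, int, int], tuple[tuple[float, float, float], ...]] = field(default_factory=dict)
    lj: Mapping[int, tuple[float, float]] = field(default_factory=dict)
    hl_lj: tuple[float, float] = (0.0657, 2.471)
    scale_elec_14: float = 1.0 / 1.2
    scale_lj_14: float = 0.5


@dataclass(frozen=True)
class MMVariant:
    """Charge-zeroing / link-substitution switches for one MM evaluation.

    ``link_substitution``: None keeps real atoms; ``"CL"`` keeps the
    real (carbon) M1 atoms explicitly; ``"HL"`` replaces each junction
    M1 by a hydrogen at the link position with zero charge and
    hydrogen LJ parameters.  ``link_bond`` / ``link_angles_torsions``
    control whether cross-boundary bond and angle/torsion terms enter
    additive interaction energies.
    """

    zero_charges_on: frozenset[int] = frozenset()
    link_substitution: str | None = None
    link_bond: bool = True
    link_angles_torsions: bool = True


def _path_lengths(system: MolecularSystem, subset: Sequence[int]) -> dict[tuple[int, int], int]:
    """Shortest bond-path lengths (≤ 3) between subset atoms, computed
    on the full system graph so exclusions are topology-faithful."""
    sub = set(subset)
    out: dict[tuple[int, int], int] = {}
    for src, lengths in nx.all_pairs_shortest_path_length(system.graph, cutoff=3):
        if src not in sub:
            continue
        for dst, length in lengths.items():
            if dst in sub and src < dst and length >= 1:
                out[(src, dst)] = length
    return out


def _effective_arrays(
    system: MolecularSystem,
    terms: ForceFieldTerms,
    subset: Sequence[int],
    variant: MMVariant,
    junctions: Sequence[Junction],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Positions, charges, LJ ε and σ for the subset after variant
    substitutions."""
    pos = system.positions[list(subset)].copy()
    chg = system.charges[list(subset)].copy()
    eps = np.empty(len(subset))
    sig = np.empty(len(subset))
    local = {a: k for k, a in enumerate(subset)}
    for k, a in enumerate(subset):
        try:
            eps[k], sig[k] = terms.lj[a]
        except KeyError as exc:
            raise MMParameterError(f"no LJ parameters for atom {a}") from exc
    if variant.link_substitution == "HL":
        for j in junctions:
            if j.m1 in local:
                k = local[j.m1]
                pos[k] = j.hl_position
                chg[k] = 0.0
                eps[k], sig[k] = terms.hl_lj
    for a in variant.zero_charges_on:
        if a in local:
            chg[local[a]] = 0.0
    return pos, chg, eps, sig


def _bonded_energy(
    terms: ForceFieldTerms,
    subset_set: frozenset[int],
    local: Mapping[int, int],
    pos: np.ndarray,
) -> float:
    e = 0.0
    for (i, j), (k, r0) in terms.bonds.items():
        if i in subset_set and j in subset_set:
            r = float(np.linalg.norm(pos[local[i]] - pos[local[j]]))
            e += k * (r - r0) ** 2
    for (i, j, l), (k, th0) in terms.angles.items():
        if i in subset_set and j in subset_set and l in subset_set:
            v1 = pos[local[i]] - pos[local[j]]
            v2 = pos[local[l]] - pos[local[j]]
            cos_t = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
            theta = math.acos(max(-1.0, min(1.0, cos_t)))
            e += k * (theta - th0) ** 2
    for (i, j, l, m), series in terms.torsions.items():
        if {i, j, l, m} <= subset_set:
            phi = _dihedral(pos[local[i]], pos[local[j]], pos[local[l]], pos[local[m]])
            for v, n, gamma in series:
                e += v * (1.0 + math.cos(n * phi - gamma))
    return e


def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    return math.atan2(float(np.dot(m1, n2)), float(np.dot(n1, n2)))


def mm_energy(
    system: MolecularSystem,
    terms: ForceFieldTerms,
    subset: Iterable[int] | None = None,
    variant: MMVariant = MMVariant(),
    junctions: Sequence[Junction] = (),
    include_coulomb: bool = True,
) -> float:
    """Total MM energy (kJ/mol) of ``subset`` (default: all atoms).

    Bonded terms are included when every member atom is in the subset;
    nonbonded pairs obey 1-2/1-3 exclusions and 1-4 scaling on the
    full-system bond graph.  No cutoff.
    """
    subset = sorted(set(subset)) if subset is not None else list(range(len(system)))
    if not subset:
        return 0.0
    subset_set = frozenset(subset)
    local = {a: k for k, a in enumerate(subset)}
    pos, chg, eps, sig = _effective_arrays(system, terms, subset, variant, junctions)

    e = _bonded_energy(terms, subset_set, local, pos)

    paths = _path_lengths(system, subset)
    for ka, kb in itertools.combinations(range(len(subset)), 2):
        a, b = subset[ka], subset[kb]
        plen = paths.get((min(a, b), max(a, b)), 99)
        if plen <= 2:
            continue
        scale_e, scale_lj = (terms.scale_elec_14, terms.scale_lj_14) if plen == 3 else (1.0, 1.0)
        r = float(np.linalg.norm(pos[ka] - pos[kb]))
        s = 0.5 * (sig[ka] + sig[kb])
        epair = math.sqrt(eps[ka] * eps[kb])
        sr6 = (s / r) ** 6
        e += scale_lj * 4.0 * epair * (sr6 * sr6 - sr6)
        if include_coulomb:
            e += scale_e * COULOMB_KJ * chg[ka] * chg[kb] / r
    return e


def qmmm_interaction_mm(
    system: MolecularSystem,
    terms: ForceFieldTerms,
    partition: RegionPartition,
    charge_source: str = "force_field",
    esp_charges: Mapping[int, float] | None = None,
    variant: MMVariant = MMVariant(),
    include_coulomb: bool = True,
) -> float:
    """Cross-region MM interaction energy (kJ/mol).

    ``charge_source``: ``"force_field"`` uses the system's own partial
    charges for the QM region (mechanical embedding with MM charges);
    ``"supplied_esp"`` substitutes externally fitted ESP charges for
    QM atoms.  Cross-boundary bonded terms are controlled by the
    variant's ``link_bond`` (bonds) and ``link_angles_torsions``
    (angles + torsions) flags.
    """
    qm, mm = partition.qm_atoms, partition.mm_atoms
    if not mm:
        return 0.0
    if charge_source == "supplied_esp":
        if esp_charges is None:
            raise ValueError("charge_source='supplied_esp' requires esp_charges")
        chg_map = dict(esp_charges)
    elif charge_source == "force_field":
        chg_map = {}
    else:
        raise ValueError(f"unknown charge_source {charge_source!r}")

    pos = system.positions
    chg = system.charges.copy()
    for a, q in chg_map.items():
        chg[a] = q
    for a in variant.zero_charges_on:
        chg[a] = 0.0

    all_atoms = sorted(qm | mm)
    paths = _path_lengths(system, all_atoms)

    e = 0.0
    for a in sorted(qm):
        try:
            ea, sa = terms.lj[a]
        except KeyError as exc:
            raise MMParameterError(f"no LJ parameters for atom {a}") from exc
        for b in sorted(mm):
            plen = paths.get((min(a, b), max(a, b)), 99)
            if plen <= 2:
                continue
            scale_e, scale_lj = (terms.scale_elec_14, terms.scale_lj_14) if plen == 3 else (1.0, 1.0)
            eb, sb = terms.lj[b]
            r = float(np.linalg.norm(pos[a] - pos[b]))
            s = 0.5 * (sa + sb)
            sr6 = (s / r) ** 6
            e += scale_lj * 4.0 * math.sqrt(ea * eb) * (sr6 * sr6 - sr6)
            if include_coulomb:
                e += scale_e * COULOMB_KJ * chg[a] * chg[b] / r

    # cross-boundary bonded terms
    def crosses(atoms: tuple[int, ...]) -> bool:
        return any(x in qm for x in atoms) and any(x in mm for x in atoms)

    if variant.link_bond:
        for (i, j), (k, r0) in terms.bonds.items():
            if crosses((i, j)):
                r = float(np.linalg.norm(pos[i] - pos[j]))
                e += k * (r - r0) ** 2
    if variant.link_angles_torsions:
        for (i, j, l), (k, th0) in terms.angles.items():
            if crosses((i, j, l)):
                v1, v2 = pos[i] - pos[j], pos[l] - pos[j]
                cos_t = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
                e += k * (math.acos(max(-1.0, min(1.0, cos_t))) - th0) ** 2
        for (i, j, l, m), series in terms.torsions.items():
            if crosses((i, j, l, m)):
                phi = _dihedral(pos[i], pos[j], pos[l], pos[m])
                for v, n, gamma in series:
                    e += v * (1.0 + math.cos(n * phi - gamma))
    return e
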