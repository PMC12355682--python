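"""Charge-redistribution schemes for the QM point-charge model.

In electrostatic embedding the QM calculation sees the MM region as a
set of point charges.  Charges right at a cut bond over-polarise the
HL cap, so ten schemes decide which MM charges near each junction
enter the model and how deleted charge is compensated:

* ``Z0`` — every MM atom kept, including M1.
* ``Z1`` / ``Z2`` / ``Z3`` — delete shells M1 / M1+M2 / M1+M2+M3.
* ``DZ1`` / ``DZ2`` / ``DZ3`` — as Zk, then redistribute the deleted
  charge of the junction residue evenly over its remaining MM atoms.
* ``ZZ2`` — as Z2, then shift the junction residue's remaining charges
  uniformly so they sum to exactly zero.
* ``RCD`` — redistributed charge and dipole: delete M1, move its
  charge onto the M2 atoms and M1–M2 bond midpoints so both the total
  charge and the local dipole are preserved.
* ``CS`` — charge shift: delete M1, move q0/n onto each M2 and restore
  the displaced dipole with a ± pair straddling each M2 along the
  M1–M2 axis.

Exclusions are unioned across junctions before any compensation; an
atom excluded by one junction is never re-adjusted by another.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .boundary import Junction
from .constants import COULOMB_KJ
from .system import MolecularSystem, RegionPartition

SCHEMES: tuple[str, ...] = (
    "Z0", "Z1", "Z2", "Z3", "DZ1", "DZ2", "DZ3", "ZZ2", "RCD", "CS",
)

#: Default half-separation (Å) of the CS ± pair around each M2.
DEFAULT_CS_SHIFT: float = 0.25


class SchemeError(ValueError):
    """Scheme cannot be applied to this boundary topology."""


@dataclass(frozen=True)
class ChargeSite:
    """One external point charge: a kept MM atom or a virtual site."""

    position: tuple[float, float, float]
    charge: float
    origin_tag: str = "atom"  # "atom" | "midpoint" | "shift_pair"
    source_atom: int | None = None


@dataclass(frozen=True)
class PointChargeModel:
    """The external charge set seen by the QM calculation."""

    sites: tuple[ChargeSite, ...]
    scheme: str = "Z0"

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites], dtype=float).reshape(-1, 3)

    @property
    def charges(self) -> np.ndarray:
        return np.array([s.charge for s in self.sites], dtype=float)

    def total_charge(self) -> float:
        return float(self.charges.sum()) if self.sites else 0.0

    def dipole(self, origin: Sequence[float] = (0.0, 0.0, 0.0)) -> np.ndarray:
        """Dipole moment in e·Å about ``origin``."""
        if not self.sites:
            return np.zeros(3)
        origin = np.asarray(origin, dtype=float)
        return ((self.positions - origin) * self.charges[:, None]).sum(axis=0)


def model_summary(model: PointChargeModel) -> tuple[int, float, np.ndarray]:
    """(site count, total charge in e, dipole about the origin in e·Å)."""
    return len(model.sites), model.total_charge(), model.dipole()


def potential_at(model: PointChargeModel, points: np.ndarray) -> np.ndarray:
    """Electrostatic potential of the model (kJ/mol per unit probe
    charge) at each probe point."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not model.sites:
        return np.zeros(len(points))
    d = np.linalg.norm(points[:, None, :] - model.positions[None, :, :], axis=2)
    return COULOMB_KJ * (model.charges[None, :] / d).sum(axis=1)


def _excluded_shells(junctions: Sequence[Junction], depth: int) -> set[int]:
    out: set[int] = set()
    for j in junctions:
        if depth >= 1:
            out.add(j.m1)
        if depth >= 2:
            out |= j.m2
        if depth >= 3:
            out |= j.m3
    return out


def apply_scheme(
    system: MolecularSystem,
    partition: RegionPartition,
    junctions: Sequence[Junction],
    scheme: str,
    cs_shift: float = DEFAULT_CS_SHIFT,
) -> PointChargeModel:
    """Build the external point-charge model under one scheme.

    With no junctions every scheme degenerates to Z0 (all MM atoms).
    """
    scheme = scheme.upper()
    if scheme not in SCHEMES:
        raise SchemeError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")

    mm = partition.mm_atoms
    depth = {"Z0": 0, "Z1": 1, "DZ1": 1, "RCD": 1, "CS": 1,
             "Z2": 2, "DZ2": 2, "ZZ2": 2, "Z3": 3, "DZ3": 3}[scheme]
    excluded = _excluded_shells(junctions, depth)

    # per-atom charge increments from DZ/ZZ2/RCD/CS compensation
    delta: dict[int, float] = {}
    virtual: list[ChargeSite] = []
    pos = system.positions
    chg = system.charges

    junction_residues = sorted({system.residue_of(j.m1).residue_id for j in junctions})

    if scheme in ("DZ1", "DZ2", "DZ3"):
        for rid in junction_residues:
            res = system.residue(rid)
            members = [i for i in res.atom_indices if i in mm]
            deleted = sum(chg[i] for i in members if i in excluded)
            remaining = [i for i in members if i not in excluded]
            if not remaining:
                raise SchemeError(
                    f"{scheme}: junction residue {rid} has no MM atoms left "
                    "to receive the deleted charge"
                )
            for i in remaining:
                delta[i] = delta.get(i, 0.0) + deleted / len(remaining)

    if scheme == "ZZ2":
        for rid in junction_residues:
            res = system.residue(rid)
            remaining = [i for i in res.atom_indices if i in mm and i not in excluded]
            if not remaining:
                raise SchemeError(
                    f"ZZ2: junction residue {rid} has no MM atoms left to zero"
                )
            incr = -sum(chg[i] for i in remaining) / len(remaining)
            for i in remaining:
                delta[i] = delta.get(i, 0.0) + incr

    if scheme in ("RCD", "CS"):
        for j in junctions:
            q0 = float(chg[j.m1])
            m2 = sorted(j.m2)
            if not m2:
                raise SchemeError(
                    f"{scheme}: junction M1 = atom {j.m1} has no M2 atoms "
                    "to carry the redistributed charge"
                )
            n = len(m2)
            for a in m2:
                if a in excluded:
                    continue  # exclusion (another junction) wins
                if scheme == "RCD":
                    delta[a] = delta.get(a, 0.0) - q0 / n
                    mid = 0.5 * (pos[j.m1] + pos[a])
                    virtual.append(ChargeSite(tuple(mid), 2.0 * q0 / n, "midpoint", a))
                else:  # CS
                    bond_vec = pos[a] - pos[j.m1]
                    length = float(np.linalg.norm(bond_vec))
                    u = bond_vec / length
                    shortest = min(
                        float(np.linalg.norm(pos[a] - pos[nb]))
                        for nb in system.neighbors(a)
                    )
                    if cs_shift >= shortest:
                        raise SchemeError(
                            f"CS: shift pair overlaps neighbor (d = {cs_shift} Å "
                            f">= shortest M2 bond {shortest:.3f} Å)"
                        )
                    delta[a] = delta.get(a, 0.0) + q0 / n
                    d_pair = -q0 * length / (2.0 * n * cs_shift)
                    virtual.append(ChargeSite(
                        tuple(pos[a] + cs_shift * u), d_pair, "shift_pair", a))
                    virtual.append(ChargeSite(
                        tuple(pos[a] - cs_shift * u), -d_pair, "shift_pair", a))

    sites = [
        ChargeSite(tuple(pos[i]), float(chg[i] + delta.get(i, 0.0)), "atom", i)
        for i in sorted(mm)
        if i not in excluded
    ]
    return PointChargeModel(sites=tuple(sites + virtual), scheme=scheme)


def local_replacement_dipole(
    system: MolecularSystem,
    junction: Junction,
    model: PointChargeModel,
    origin: Iterable[float] = (0.0, 0.0, 0.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Dipole of the original {M1 ∪ M2} charges vs. the model sites
    that replaced them (kept M2 atoms plus virtual sites), about
    ``origin``.  RCD and CS preserve this pair exactly.
    """
    origin = np.asarray(tuple(origin), dtype=float)
    pos, chg = system.positions, system.charges
    local = [junction.m1, *sorted(junction.m2)]
    orig = sum(chg[i] * (pos[i] - origin) for i in local)
    repl = np.zeros(3)
    for s in model.sites:
        if s.source_atom in junction.m2 or (
            s.origin_tag == "atom" and s.source_atom == junction.m1
        ):
            repl += s.charge * (np.asarray(s.position) - origin)
    return np.asarray(orig), repl
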