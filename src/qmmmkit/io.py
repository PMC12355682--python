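"""Readers and writers for the formats the toolkit touches.

* PDB structures (ATOM/HETATM/CONECT/TER/END), read through Bio.PDB
  with a raw-line pre-scan for the checks Bio.PDB is permissive about
  (duplicate serials, malformed records) and a CONECT scan (Bio.PDB
  discards connectivity).
* A read-only AMBER prmtop subset: CHARGE (divided by 18.2223 to give
  e), BONDS_INC_HYDROGEN / BONDS_WITHOUT_HYDROGEN (the 3·(i−1) index
  convention), RESIDUE_POINTER and ATOM_NAME.  All other FLAG sections
  are ignored.
* A JSON topology dialect — the canonical fixture format — carrying
  atoms, bonds, charges, residues, formal charges and optionally the
  MM term table.
* Whitespace-delimited point-charge files, one "x y z q" line per
  site (Å, e, ten decimals).
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np

from .constants import PRMTOP_CHARGE_SCALE
from .mm import ForceFieldTerms
from .schemes import PointChargeModel
from .system import AtomRecord, MolecularSystem, Residue

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------- PDB

def read_pdb(path: str | Path) -> MolecularSystem:
    """Parse a PDB file into a system (charges default to 0).

    altLoc handling keeps the highest-occupancy conformer (ties go to
    'A'); CONECT records become bonds when present.  Duplicate serials
    and malformed ATOM/HETATM records raise with the line number.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    lines = path.read_text().splitlines()
    serials_seen: set[int] = set()
    conect: list[tuple[int, int]] = []
    for ln, line in enumerate(lines, start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            try:
                serial = int(line[6:11])
                altloc = line[16]
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path.name}:{ln}: malformed {rec} record") from exc
            if serial in serials_seen and altloc == " ":
                raise FormatError(f"{path.name}:{ln}: duplicate atom serial {serial}")
            serials_seen.add(serial)
        elif rec == "CONECT":
            fields = line[6:].split()
            if fields:
                base = int(fields[0])
                conect.extend((base, int(f)) for f in fields[1:])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("system", str(path))
    model = next(structure.get_models())

    atoms: list[AtomRecord] = []
    residues: list[Residue] = []
    serial_to_index: dict[int, int] = {}
    rid = 0
    for chain in model:
        for residue in chain:
            start = len(atoms)
            for atom in residue:
                if atom.is_disordered():
                    children = sorted(
                        atom.child_dict.values(),
                        key=lambda a: (-a.get_occupancy(), a.get_altloc()),
                    )
                    atom = children[0]
                idx = len(atoms)
                serial_to_index[atom.get_serial_number()] = idx
                elem = (atom.element or atom.get_name()[0]).strip().capitalize()
                atoms.append(AtomRecord(
                    idx, atom.get_name(), elem, rid, residue.get_resname(),
                    tuple(float(x) for x in atom.get_coord()),
                    0.0, int(atom.get_serial_number()),
                ))
            if len(atoms) > start:
                residues.append(Residue(rid, residue.get_resname(),
                                        tuple(range(start, len(atoms))), 0))
                rid += 1

    bonds = {
        (serial_to_index[a], serial_to_index[b])
        for a, b in conect
        if a in serial_to_index and b in serial_to_index
    }
    return MolecularSystem(atoms, bonds, residues)


def write_pdb(system: MolecularSystem, path: str | Path,
              write_conect: bool = True) -> None:
    """Write ATOM/CONECT/TER/END records; serials are written 1-based
    (preserved PDB serials are reused when present and unique)."""
    path = Path(path)
    serials = [a.serial for a in system.atoms]
    if None in serials or len(set(serials)) != len(serials):
        serials = [i + 1 for i in range(len(system))]
    lines = []
    for a, serial in zip(system.atoms, serials):
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        x, y, z = a.position
        lines.append(
            f"ATOM  {serial:>5d} {name:<4s} {a.residue_name:<3s} A"
            f"{(a.residue_id % 10000):>4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"          {a.element.upper():>2s}"
        )
    if write_conect:
        by_atom: dict[int, list[int]] = {}
        for i, j in sorted(system.bonds):
            by_atom.setdefault(i, []).append(j)
            by_atom.setdefault(j, []).append(i)
        for i in sorted(by_atom):
            partners = sorted(by_atom[i])
            for k in range(0, len(partners), 4):
                chunk = partners[k:k + 4]
                lines.append("CONECT" + f"{serials[i]:>5d}"
                             + "".join(f"{serials[j]:>5d}" for j in chunk))
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")


# ------------------------------------------------------------- prmtop

_REQUIRED_FLAGS = ("CHARGE", "BONDS_INC_HYDROGEN", "BONDS_WITHOUT_HYDROGEN",
                   "RESIDUE_POINTER", "ATOM_NAME")


def read_prmtop_subset(
    path: str | Path,
) -> tuple[np.ndarray, frozenset[tuple[int, int]], list[int], list[str]]:
    """Read charges (e), bonds, residue pointers (0-based starts) and
    atom names from an AMBER prmtop.

    Raw CHARGE entries are divided by 18.2223; bond records store
    3·(atom index − 1), decoded here by integer division.
    """
    path = Path(path)
    sections: dict[str, tuple[str, list[str]]] = {}
    flag: str | None = None
    fmt = ""
    for line in path.read_text().splitlines():
        if line.startswith("%FLAG"):
            flag = line.split()[1]
            sections[flag] = (fmt, [])
        elif line.startswith("%FORMAT"):
            if flag is not None:
                fmt = line.strip()[len("%FORMAT("):-1]
                sections[flag] = (fmt, sections[flag][1])
        elif line.startswith("%"):
            continue
        elif flag is not None:
            sections[flag][1].append(line)

    for name in _REQUIRED_FLAGS:
        if name not in sections:
            raise FormatError(f"prmtop missing required FLAG {name}")

    def numbers(name: str) -> list[float]:
        return [float(tok) for line in sections[name][1] for tok in line.split()]

    charges = np.array(numbers("CHARGE")) / PRMTOP_CHARGE_SCALE

    bonds: set[tuple[int, int]] = set()
    for name in ("BONDS_INC_HYDROGEN", "BONDS_WITHOUT_HYDROGEN"):
        vals = [int(v) for v in numbers(name)]
        for k in range(0, len(vals) - 2, 3):
            i, j = vals[k] // 3, vals[k + 1] // 3
            bonds.add((min(i, j), max(i, j)))
    if not bonds:
        warnings.warn(f"{path.name}: no bonds in either bond section")

    pointers = [int(v) - 1 for v in numbers("RESIDUE_POINTER")]

    fmt, body = sections["ATOM_NAME"]
    width = 4
    if "a" in fmt:
        width = int(fmt.split("a")[1].rstrip(")") or 4)
    names = [
        line[k:k + width].strip()
        for line in body
        for k in range(0, len(line.rstrip("\n")), width)
        if line[k:k + width].strip()
    ]
    for extra in sections.keys() - set(_REQUIRED_FLAGS):
        logger.debug("prmtop FLAG %s ignored", extra)
    return charges, frozenset(bonds), pointers, names


# ------------------------------------------------------ JSON topology

def write_json_topology(
    system: MolecularSystem, path: str | Path,
    terms: ForceFieldTerms | None = None, provenance: dict | None = None,
) -> None:
    doc: dict = {
        "format": "qmmmkit-topology-1",
        "atoms": [
            {"name": a.name, "element": a.element, "residue_id": a.residue_id,
             "residue_name": a.residue_name, "position": list(a.position),
             "charge": a.charge, "serial": a.serial}
            for a in system.atoms
        ],
        "bonds": sorted(list(b) for b in system.bonds),
        "residues": [
            {"id": r.residue_id, "name": r.name, "atoms": list(r.atom_indices),
             "formal_charge": r.formal_charge}
            for r in system.residues
        ],
    }
    if provenance:
        doc["provenance"] = provenance
    if terms is not None:
        doc["terms"] = {
            "bonds": [[list(k), list(v)] for k, v in sorted(terms.bonds.items())],
            "angles": [[list(k), list(v)] for k, v in sorted(terms.angles.items())],
            "torsions": [[list(k), [list(t) for t in v]]
                         for k, v in sorted(terms.torsions.items())],
            "lj": [[k, list(v)] for k, v in sorted(terms.lj.items())],
            "hl_lj": list(terms.hl_lj),
            "scale_elec_14": terms.scale_elec_14,
            "scale_lj_14": terms.scale_lj_14,
        }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_json_topology(
    path: str | Path,
) -> tuple[MolecularSystem, ForceFieldTerms | None]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "qmmmkit-topology-1":
        raise FormatError(f"{path}: not a qmmmkit topology file")
    atoms = [
        AtomRecord(i, a["name"], a["element"], a["residue_id"],
                   a["residue_name"], tuple(a["position"]), a["charge"],
                   a.get("serial"))
        for i, a in enumerate(doc["atoms"])
    ]
    residues = [
        Residue(r["id"], r["name"], tuple(r["atoms"]), r["formal_charge"])
        for r in doc["residues"]
    ]
    system = MolecularSystem(atoms, [tuple(b) for b in doc["bonds"]], residues)
    terms = None
    if "terms" in doc:
        t = doc["terms"]
        terms = ForceFieldTerms(
            bonds={tuple(k): tuple(v) for k, v in t["bonds"]},
            angles={tuple(k): tuple(v) for k, v in t["angles"]},
            torsions={tuple(k): tuple(tuple(x) for x in v)
                      for k, v in t["torsions"]},
            lj={int(k): tuple(v) for k, v in t["lj"]},
            hl_lj=tuple(t["hl_lj"]),
            scale_elec_14=t["scale_elec_14"],
            scale_lj_14=t["scale_lj_14"],
        )
    return system, terms


# ------------------------------------------------------ point charges

def write_point_charges(model: PointChargeModel, path: str | Path) -> None:
    """One "x y z q" line per site (virtual sites included), ten
    decimal places, Å and e."""
    lines = [
        f"{s.position[0]:.10f} {s.position[1]:.10f} "
        f"{s.position[2]:.10f} {s.charge:.10f}"
        for s in model.sites
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
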