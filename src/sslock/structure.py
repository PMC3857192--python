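"""PDB coordinate parsing into a queryable two-level structure model.

Deliberately minimal and deterministic: first MODEL block only, ATOM records
of the 20 standard amino acids only, alternate locations resolved to the
highest-occupancy conformer (ties broken by lexicographically smallest altloc
id).  Coordinates are Angstroms throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

#: virtual-Cbeta ideal geometry
CB_BOND_LENGTH = 1.532     # Angstrom, CA-CB
CB_ANGLE_DEG = 110.4       # N-CA-CB


class PDBParseError(ValueError):
    """Raised when the input contains no usable coordinate records."""


class ResidueNotFoundError(LookupError):
    """Raised when a (chain, residue) lookup fails."""


class MissingAtomError(LookupError):
    """Raised when a required atom is absent from a residue."""


@dataclass
class AtomRecord:
    """One atom after altloc resolution."""

    name: str
    element: str
    x: float
    y: float
    z: float
    altloc: str = ""
    occupancy: float = 1.0

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class ResidueRecord:
    chain_id: str
    seq_number: int
    insertion_code: str
    residue_name: str
    atoms: Dict[str, AtomRecord] = field(default_factory=dict)

    @property
    def key(self) -> Tuple[int, str]:
        """Residue identity within its chain: (author number, insertion code)."""
        return (self.seq_number, self.insertion_code)

    @property
    def is_standard(self) -> bool:
        return self.residue_name in STANDARD_RESIDUES

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"ResidueRecord({self.chain_id}/{self.residue_name}"
                f"{self.seq_number}{self.insertion_code}, "
                f"{len(self.atoms)} atoms)")


@dataclass
class StructureModel:
    """One conformational state: ordered chains of ordered residues."""

    label: str
    chains: Dict[str, List[ResidueRecord]] = field(default_factory=dict)
    source: str = ""

    def chain_ids(self) -> List[str]:
        return list(self.chains)

    def residues(self, chain_id: str) -> List[ResidueRecord]:
        if chain_id not in self.chains:
            raise ResidueNotFoundError(
                f"chain {chain_id!r} not in model {self.label!r} "
                f"(have {sorted(self.chains)})")
        return self.chains[chain_id]

    def residue_index(self, chain_id: str) -> Dict[Tuple[int, str], ResidueRecord]:
        return {r.key: r for r in self.residues(chain_id)}

    def get_residue(self, chain_id: str, seq_number: int,
                    insertion_code: str = "") -> ResidueRecord:
        for res in self.residues(chain_id):
            if res.key == (seq_number, insertion_code):
                return res
        raise ResidueNotFoundError(
            f"residue {chain_id}/{seq_number}{insertion_code} "
            f"not found in model {self.label!r}")

    def n_residues(self) -> int:
        return sum(len(v) for v in self.chains.values())

    # -- serialization -----------------------------------------------------

    def to_tsv(self) -> str:
        """Flat atom table for debugging / diffing."""
        lines = ["chain\tresnum\ticode\tresname\tatom\tx\ty\tz"]
        for cid in self.chains:
            for res in self.chains[cid]:
                for name in sorted(res.atoms):
                    a = res.atoms[name]
                    lines.append(
                        f"{cid}\t{res.seq_number}\t{res.insertion_code}\t"
                        f"{res.residue_name}\t{name}\t"
                        f"{a.x:.3f}\t{a.y:.3f}\t{a.z:.3f}")
        return "\n".join(lines) + "\n"

    def to_pdb_text(self) -> str:
        """Re-emit as fixed-column PDB ATOM records (v3.3 layout)."""
        out = []
        serial = 0
        for cid in self.chains:
            for res in self.chains[cid]:
                for name in sorted(res.atoms):
                    a = res.atoms[name]
                    serial += 1
                    out.append(_format_atom_line(serial, a, res))
            out.append(f"TER   {serial + 1:5d}      "
                       f"{res.residue_name:>3s} {cid:1s}"
                       f"{res.seq_number:4d}{res.insertion_code or ' ':1s}")
        out.append("END")
        return "\n".join(out) + "\n"


def _format_atom_line(serial: int, a: AtomRecord, res: ResidueRecord) -> str:
    if len(a.name) >= 4:
        name_field = a.name[:4]
    else:
        # single-letter elements start in column 14
        name_field = f" {a.name:<3s}"
    return (f"ATOM  {serial:5d} {name_field}{a.altloc or ' ':1s}"
            f"{res.residue_name:>3s} {res.chain_id:1s}"
            f"{res.seq_number:4d}{res.insertion_code or ' ':1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}"
            f"{a.occupancy:6.2f}{0.0:6.2f}          "
            f"{a.element:>2s}")


# ---------------------------------------------------------------------------
# parsing


def parse_pdb(text: str, label: str, source: str = "") -> StructureModel:
    """Parse fixed-column PDB content into a :class:`StructureModel`.

    Only ``ATOM`` records of the 20 standard residues in the first MODEL
    block are kept.  Alternate locations are resolved per atom name: highest
    occupancy wins, ties go to the lexicographically smallest altloc id.
    Malformed fixed-column lines are skipped with a warning.

    Raises
    ------
    PDBParseError
        If no usable ATOM record survives filtering.
    """
    if not text or not text.strip():
        raise PDBParseError(f"empty PDB input for {label!r} ({source or 'inline'})")

    n_models = 0
    in_first_model = True
    counts = {"atom": 0, "kept": 0, "nonstandard": 0, "malformed": 0,
              "hetatm": 0, "occupancy_clamped": 0}

    # (chain, resnum, icode) -> residue; per-residue atom candidates by name
    chains: Dict[str, Dict[Tuple[int, str], ResidueRecord]] = {}
    candidates: Dict[Tuple[str, int, str, str], List[AtomRecord]] = {}
    chain_order: List[str] = []

    for line in text.splitlines():
        rec = line[:6]
        if rec == "MODEL ":
            n_models += 1
            if n_models > 1:
                in_first_model = False
            continue
        if rec == "ENDMDL":
            in_first_model = False
            continue
        if not in_first_model:
            continue
        if rec == "HETATM":
            counts["hetatm"] += 1
            continue
        if rec != "ATOM  ":
            continue
        counts["atom"] += 1
        try:
            name = line[12:16].strip()
            altloc = line[16].strip()
            resname = line[17:20].strip()
            chain_id = line[21].strip()
            seq_number = int(line[22:26])
            icode = line[26].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
            occ_field = line[54:60].strip()
            occupancy = float(occ_field) if occ_field else 1.0
            element = line[76:78].strip() or _guess_element(name)
        except (ValueError, IndexError):
            counts["malformed"] += 1
            logger.warning("skipping malformed ATOM line: %r", line)
            continue
        if resname not in STANDARD_RESIDUES:
            counts["nonstandard"] += 1
            continue
        if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(z)):
            counts["malformed"] += 1
            logger.warning("non-finite coordinates, skipping: %r", line)
            continue
        if occupancy < 0.0 or occupancy > 1.0:
            occupancy = min(1.0, max(0.0, occupancy))
            counts["occupancy_clamped"] += 1
            logger.warning("occupancy outside [0,1] clamped: %r", line)

        if chain_id not in chains:
            chains[chain_id] = {}
            chain_order.append(chain_id)
        rkey = (seq_number, icode)
        if rkey not in chains[chain_id]:
            chains[chain_id][rkey] = ResidueRecord(
                chain_id=chain_id, seq_number=seq_number,
                insertion_code=icode, residue_name=resname)
        atom = AtomRecord(name=name, element=element, x=x, y=y, z=z,
                          altloc=altloc, occupancy=occupancy)
        candidates.setdefault((chain_id, seq_number, icode, name), []).append(atom)
        counts["kept"] += 1

    if counts["kept"] == 0:
        raise PDBParseError(
            f"no standard ATOM records in {label!r} ({source or 'inline'}); "
            f"saw {counts['atom']} ATOM and {counts['hetatm']} HETATM lines")

    # altloc resolution: highest occupancy, then smallest altloc id
    for (chain_id, seq_number, icode, name), atoms in candidates.items():
        best = min(atoms, key=lambda a: (-a.occupancy, a.altloc))
        chains[chain_id][(seq_number, icode)].atoms[name] = best

    if n_models > 1:
        logger.warning("%s: %d MODEL blocks present, using the first only",
                       label, n_models)
    logger.info("%s: parsed %d atoms (%d residue-atoms kept, "
                "%d non-standard, %d malformed skipped)",
                label, counts["atom"], counts["kept"],
                counts["nonstandard"], counts["malformed"])

    model = StructureModel(label=label, source=source)
    for cid in chain_order:
        model.chains[cid] = sorted(chains[cid].values(), key=lambda r: r.key)
    return model


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip()
    if stripped[:2] in ("FE", "ZN", "MG", "MN"):  # not expected in practice
        return stripped[:2]
    return stripped[0] if stripped else ""


# ---------------------------------------------------------------------------
# Cbeta access


def virtual_cbeta(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Ideal-geometry Cbeta from backbone N, CA, C.

    Bond length 1.532 A, N-CA-CB angle 110.4 deg, L-amino-acid chirality.
    The placement is exact: |CA-CB| equals the ideal length for any
    non-degenerate backbone.
    """
    n = np.asarray(n, dtype=float)
    ca = np.asarray(ca, dtype=float)
    c = np.asarray(c, dtype=float)
    u = n - ca
    v = c - ca
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("degenerate backbone: coincident atoms")
    u /= nu
    v /= nv
    cross = np.cross(u, v)
    ncross = np.linalg.norm(cross)
    if ncross < 1e-8:
        raise ValueError("degenerate backbone: collinear N, CA, C")
    bis = u + v
    bis /= np.linalg.norm(bis)
    perp = cross / ncross
    half_gamma = math.acos(max(-1.0, min(1.0, float(np.dot(u, v))))) / 2.0
    cos_alpha = -math.cos(math.radians(CB_ANGLE_DEG)) / math.cos(half_gamma)
    cos_alpha = max(-1.0, min(1.0, cos_alpha))
    sin_alpha = math.sqrt(1.0 - cos_alpha * cos_alpha)
    direction = -cos_alpha * bis + sin_alpha * perp
    return ca + CB_BOND_LENGTH * direction


def get_cb(model: StructureModel, chain: str, resnum: int,
           insertion_code: str = "", virtual: bool = False) -> np.ndarray:
    """Cbeta coordinate of a residue; optionally a virtual one for glycine."""
    res = model.get_residue(chain, resnum, insertion_code)
    if "CB" in res.atoms:
        return res.atoms["CB"].coord
    if res.residue_name == "GLY" and virtual:
        try:
            return virtual_cbeta(res.atoms["N"].coord,
                                 res.atoms["CA"].coord,
                                 res.atoms["C"].coord)
        except KeyError as exc:
            raise MissingAtomError(
                f"cannot build virtual CB for {chain}/{resnum}: "
                f"backbone atom {exc} missing") from exc
    raise MissingAtomError(
        f"no CB atom in {res.residue_name} {chain}/{resnum}{insertion_code} "
        f"of model {model.label!r}"
        + ("" if res.residue_name != "GLY" else " (virtual CB disabled)"))


# ---------------------------------------------------------------------------
# numbering


@dataclass
class NumberingMap:
    """Per-chain integer offsets between construct and file (author) numbering.

    ``author = construct + offset``.  The default (no entry) is treated as an
    error so that silent misnumbering cannot occur; use offset 0 explicitly
    to assert identity.
    """

    offsets: Dict[str, int] = field(default_factory=dict)

    def to_author(self, chain: str, construct_number: int) -> int:
        if chain not in self.offsets:
            raise KeyError(f"no numbering offset configured for chain {chain!r}")
        return construct_number + self.offsets[chain]

    def to_construct(self, chain: str, author_number: int) -> int:
        if chain not in self.offsets:
            raise KeyError(f"no numbering offset configured for chain {chain!r}")
        return author_number - self.offsets[chain]


def map_residue(numbering: NumberingMap, chain: str, construct_number: int) -> int:
    """Author sequence number for a construct (mature-protein) number."""
    return numbering.to_author(chain, construct_number)
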