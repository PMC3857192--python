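"""Two-state residue-pair screening for conformation-locking disulfides.

A candidate pair must be close enough to bond in one state (``d_closed <=
closed_max``) and widely separated in the other (``d_open >= open_min``); the
metric is the Cbeta-Cbeta Euclidean distance.  Candidates are ranked by the
open/closed contrast ``delta = d_open - d_closed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from sslock.structure import (
    MissingAtomError,
    StructureModel,
    get_cb,
)

logger = logging.getLogger(__name__)

#: side-chain nitrogen/oxygen atoms are everything N/O that is not backbone
BACKBONE_NO = {"N", "O", "OXT"}
BASIC_RESIDUES = {"LYS", "ARG"}
ACIDIC_RESIDUES = {"ASP", "GLU"}

ResidueRef = Tuple[str, int]  # (chain_id, author resnum); icode via keyword


@dataclass
class ConformerPair:
    """The same complex in two conformational states."""

    closed: StructureModel
    open: StructureModel
    #: chain id in the closed model -> chain id in the open model
    chain_correspondence: Dict[str, str] = field(default_factory=dict)

    def open_chain(self, closed_chain: str) -> str:
        return self.chain_correspondence.get(closed_chain, closed_chain)


@dataclass
class ScreenConfig:
    closed_max: float = 12.0
    open_min: float = 20.0
    #: chain pairs (in closed-model ids) to scan against each other
    chain_pairs: Sequence[Tuple[str, str]] = ()
    use_virtual_cb: bool = False
    include_intrachain: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.closed_max < self.open_min):
            raise ValueError(
                f"need 0 < closed_max < open_min, got "
                f"{self.closed_max} / {self.open_min}")


@dataclass
class PairMetrics:
    residue_i: Tuple[str, int, str]  # (chain, resnum, residue_name)
    residue_j: Tuple[str, int, str]
    d_closed: float
    d_open: float
    delta: float
    candidate: bool

    def sort_key(self):
        return (-self.delta, self.d_closed,
                self.residue_i[0], self.residue_i[1],
                self.residue_j[0], self.residue_j[1])


@dataclass
class PolarContact:
    residue_i: Tuple[str, int, str]
    residue_j: Tuple[str, int, str]
    atom_i: str
    atom_j: str
    distance: float
    contact_type: str  # "salt-bridge" | "h-bond-candidate"


def cb_distance(model: StructureModel, res_i: ResidueRef, res_j: ResidueRef,
                virtual: bool = False) -> float:
    """Cbeta-Cbeta Euclidean distance (Angstrom) within one state.

    Symmetric in its arguments; full precision (round only for display).
    """
    a = get_cb(model, res_i[0], res_i[1], virtual=virtual)
    b = get_cb(model, res_j[0], res_j[1], virtual=virtual)
    return float(np.linalg.norm(a - b))


def _cb_table(model: StructureModel, chain: str,
              virtual: bool) -> Dict[Tuple[int, str], np.ndarray]:
    """All resolvable Cbeta coordinates of one chain, keyed by residue key."""
    table: Dict[Tuple[int, str], np.ndarray] = {}
    for res in model.residues(chain):
        try:
            table[res.key] = get_cb(model, chain, res.seq_number,
                                    res.insertion_code, virtual=virtual)
        except MissingAtomError:
            continue
    return table


def screen_interface_pairs(pair: ConformerPair,
                           config: ScreenConfig) -> List[PairMetrics]:
    """Score every inter-chain residue pair across the two states.

    Only residues present (with a resolvable Cbeta) in BOTH states are
    scanned; others are skipped and counted.  Output is sorted by delta
    descending, ties by d_closed ascending, then lexicographic residue ids.
    """
    if not config.chain_pairs:
        raise ValueError("chain_pairs must be non-empty")

    results: List[PairMetrics] = []
    for chain_i, chain_j in config.chain_pairs:
        if chain_i == chain_j and not config.include_intrachain:
            logger.warning("skipping intra-chain pair %s:%s "
                           "(include_intrachain=False)", chain_i, chain_j)
            continue
        common_i = _common_residues(pair, chain_i, config.use_virtual_cb)
        common_j = _common_residues(pair, chain_j, config.use_virtual_cb)
        if not common_i or not common_j:
            raise ValueError(
                f"no common residues with Cbeta between states for chain "
                f"pair {chain_i}:{chain_j}")
        for key_i, (name_i, cb_ci, cb_oi) in common_i.items():
            for key_j, (name_j, cb_cj, cb_oj) in common_j.items():
                if chain_i == chain_j and key_i >= key_j:
                    continue
                d_closed = float(np.linalg.norm(cb_ci - cb_cj))
                d_open = float(np.linalg.norm(cb_oi - cb_oj))
                results.append(PairMetrics(
                    residue_i=(chain_i, key_i[0], name_i),
                    residue_j=(chain_j, key_j[0], name_j),
                    d_closed=d_closed,
                    d_open=d_open,
                    delta=d_open - d_closed,
                    candidate=(d_closed <= config.closed_max
                               and d_open >= config.open_min),
                ))
    results.sort(key=PairMetrics.sort_key)
    return results


def _common_residues(pair: ConformerPair, closed_chain: str, virtual: bool):
    """Residue keys resolvable to a Cbeta in both states, with coordinates."""
    open_chain = pair.open_chain(closed_chain)
    closed_cb = _cb_table(pair.closed, closed_chain, virtual)
    open_cb = _cb_table(pair.open, open_chain, virtual)
    names = {r.key: r.residue_name for r in pair.closed.residues(closed_chain)}
    common = {}
    skipped = 0
    for key in sorted(closed_cb):
        if key in open_cb:
            common[key] = (names[key], closed_cb[key], open_cb[key])
        else:
            skipped += 1
    skipped += len(open_cb.keys() - closed_cb.keys())
    if skipped:
        logger.info("chain %s: %d residues present in only one state, skipped",
                    closed_chain, skipped)
    return common


def detect_polar_contacts(model: StructureModel,
                          res_i: ResidueRef, res_j: ResidueRef,
                          cutoff: float = 4.0) -> List[PolarContact]:
    """Side-chain N/O atom pairs of two residues within ``cutoff`` Angstrom.

    A contact is typed "salt-bridge" when one residue is Lys/Arg and the
    other Asp/Glu, otherwise "h-bond-candidate".
    """
    ri = model.get_residue(res_i[0], res_i[1])
    rj = model.get_residue(res_j[0], res_j[1])
    pair_names = {ri.residue_name, rj.residue_name}
    is_salt = (bool(pair_names & BASIC_RESIDUES)
               and bool(pair_names & ACIDIC_RESIDUES))
    contacts: List[PolarContact] = []
    for ai in _sidechain_no(ri):
        for aj in _sidechain_no(rj):
            d = float(np.linalg.norm(ai.coord - aj.coord))
            if d <= cutoff:
                contacts.append(PolarContact(
                    residue_i=(res_i[0], res_i[1], ri.residue_name),
                    residue_j=(res_j[0], res_j[1], rj.residue_name),
                    atom_i=ai.name, atom_j=aj.name, distance=d,
                    contact_type="salt-bridge" if is_salt
                    else "h-bond-candidate"))
    contacts.sort(key=lambda c: c.distance)
    return contacts


def _sidechain_no(residue):
    return [a for name, a in sorted(residue.atoms.items())
            if a.element in ("N", "O") and name not in BACKBONE_NO]
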