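"""Synthetic inputs with known ground truth.

Everything downstream is testable offline: toy two-state structure pairs
with an engineered contact that separates on a hinge rotation, wild-type /
cysteine-mutant sequence pairs, log-normal flow-cytometry events, and
rasterized elliptical masks.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple, Union

import numpy as np

from sslock.structure import AtomRecord, ResidueRecord, StructureModel

# geometry of the toy chains (Angstrom); deliberately coarse so that only the
# designed inter-chain pair can pass the default screen thresholds
_SPACING = 8.0          # residue spacing along each chain axis
_CONTACT_GAP = 10.5     # closed-state gap of the engineered pair
_JITTER = 0.2           # per-residue uniform coordinate jitter


@dataclass
class ToyTwoState:
    closed_pdb_text: str
    open_pdb_text: str
    engineered_pair: Tuple[Tuple[str, int], Tuple[str, int]]
    true_d_closed: float
    true_d_open: float
    seed: int
    hinge_angle_deg: float
    n_res_a: int
    n_res_b: int
    hinge_pivot: Tuple[float, float, float]

    def truth_dict(self) -> Dict:
        (ca, ra), (cb, rb) = self.engineered_pair
        return {
            "engineered_pair": {"chain_i": ca, "resnum_i": ra,
                                "chain_j": cb, "resnum_j": rb},
            "true_d_closed": round(self.true_d_closed, 6),
            "true_d_open": round(self.true_d_open, 6),
            "seed": self.seed,
            "hinge_angle_deg": self.hinge_angle_deg,
            "n_res_a": self.n_res_a,
            "n_res_b": self.n_res_b,
            "hinge_pivot": list(self.hinge_pivot),
        }


def _rotation_z(theta_rad: float) -> np.ndarray:
    c, s = math.cos(theta_rad), math.sin(theta_rad)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _residue(chain: str, resnum: int, cb: np.ndarray) -> ResidueRecord:
    """Poly-alanine-like residue: rigid backbone cartoon hanging off the CB."""
    ca = cb + np.array([0.0, 0.0, 1.5])
    n = ca + np.array([-0.7, 1.2, 0.3])
    c = ca + np.array([0.8, 1.1, -0.2])
    res = ResidueRecord(chain_id=chain, seq_number=resnum,
                        insertion_code="", residue_name="ALA")
    for name, xyz, elem in (("N", n, "N"), ("CA", ca, "C"),
                            ("C", c, "C"), ("CB", cb, "C")):
        x, y, z = (round(float(v), 3) for v in xyz)
        res.atoms[name] = AtomRecord(name=name, element=elem, x=x, y=y, z=z)
    return res


def _model_from_cb(label: str, chains_cb: Dict[str, List[np.ndarray]]
                   ) -> StructureModel:
    model = StructureModel(label=label, source="sslock-fixture")
    for chain, cbs in chains_cb.items():
        model.chains[chain] = [_residue(chain, i + 1, cb)
                               for i, cb in enumerate(cbs)]
    return model


def make_two_state_toy(n_res_per_chain: Union[int, Tuple[int, int]] = 8,
                       hinge_angle_deg: float = 60.0,
                       seed: int = 0) -> ToyTwoState:
    """Two chains with one close inter-chain contact; the open state rotates
    chain B rigidly about a hinge through its far end.

    Chain A runs along +x, chain B rises along +y from just beyond A's last
    residue; the engineered pair is (A, last) x (B, first).  For the default
    sizes and hinge angles >= ~45 deg it is the only pair passing the default
    screen thresholds (closed <= 12 A, open >= 20 A).  Deterministic under
    ``seed``; all emitted coordinates are pre-rounded to 3 decimals so PDB
    round-trips are exact.
    """
    if isinstance(n_res_per_chain, int):
        n_a = n_b = n_res_per_chain
    else:
        n_a, n_b = n_res_per_chain
    if n_a < 5 or n_b < 5:
        raise ValueError("need at least 5 residues per chain")
    if not (0.0 <= hinge_angle_deg < 180.0):
        raise ValueError("hinge angle must be in [0, 180) degrees")

    rng = np.random.default_rng(seed)
    x_end = _SPACING * (n_a - 1)

    cb_a = [np.array([_SPACING * i, 0.0, 0.0]) + rng.uniform(-_JITTER, _JITTER, 3)
            for i in range(n_a)]
    cb_b = [np.array([x_end, _CONTACT_GAP + _SPACING * j, 0.0])
            + rng.uniform(-_JITTER, _JITTER, 3)
            for j in range(n_b)]
    # emit at PDB precision so stored truths match re-parsed coordinates
    cb_a = [np.round(v, 3) for v in cb_a]
    cb_b = [np.round(v, 3) for v in cb_b]

    pivot = cb_b[-1].copy()  # hinge through chain B's anchored far end
    rot = _rotation_z(math.radians(hinge_angle_deg))
    cb_b_open = [np.round(pivot + rot @ (v - pivot), 3) for v in cb_b]

    closed = _model_from_cb("closed", {"A": cb_a, "B": cb_b})
    open_ = _model_from_cb("open", {"A": cb_a, "B": cb_b_open})

    d_closed = float(np.linalg.norm(cb_a[-1] - cb_b[0]))
    d_open = float(np.linalg.norm(cb_a[-1] - cb_b_open[0]))

    header = (f"REMARK 250 SSLOCK TOY TWO-STATE FIXTURE\n"
              f"REMARK 250 SEED={seed} HINGE={hinge_angle_deg:g} "
              f"N_A={n_a} N_B={n_b}\n")
    return ToyTwoState(
        closed_pdb_text=header + closed.to_pdb_text(),
        open_pdb_text=header + open_.to_pdb_text(),
        engineered_pair=(("A", n_a), ("B", 1)),
        true_d_closed=d_closed,
        true_d_open=d_open,
        seed=seed,
        hinge_angle_deg=hinge_angle_deg,
        n_res_a=n_a,
        n_res_b=n_b,
        hinge_pivot=tuple(float(v) for v in pivot),
    )


def write_two_state_toy(toy: ToyTwoState, directory) -> Dict[str, str]:
    """Emit closed.pdb, open.pdb and truth.json into a directory."""
    import pathlib

    d = pathlib.Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, text in (("closed.pdb", toy.closed_pdb_text),
                       ("open.pdb", toy.open_pdb_text),
                       ("truth.json", json.dumps(toy.truth_dict(), indent=2) + "\n")):
        p = d / name
        p.write_text(text)
        paths[name] = str(p)
    return paths


# ---------------------------------------------------------------------------
# sequences


_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_ALPHABET_NO_C = _ALPHABET.replace("C", "")


@dataclass
class MutantSequencePair:
    wild_type: str
    mutant: str
    cys_positions: Tuple[int, ...]
    seed: int

    @property
    def wild_type_fasta(self) -> str:
        return f">wt seed={self.seed}\n{self.wild_type}\n"

    @property
    def mutant_fasta(self) -> str:
        pos = ",".join(str(p) for p in self.cys_positions)
        return f">mut seed={self.seed} cys={pos}\n{self.mutant}\n"


def make_mutant_sequences(template_length: int,
                          cys_positions: Sequence[int],
                          seed: int = 0) -> MutantSequencePair:
    """Random wild-type sequence plus a variant with cysteines substituted.

    The wild type is guaranteed to contain internal trypsin (K, not before P)
    and Asp-N (D) sites, and carries no cysteine at the mutated positions
    (collisions are redrawn deterministically), so the mutant differs from
    the wild type exactly at ``cys_positions``.
    """
    if template_length < 8:
        raise ValueError("template_length must be >= 8")
    cys_positions = tuple(sorted(set(int(p) for p in cys_positions)))
    if not cys_positions:
        raise ValueError("need at least one cysteine position")
    if cys_positions[0] < 1 or cys_positions[-1] > template_length:
        raise ValueError("cysteine positions out of range")

    rng = np.random.default_rng(seed)
    chars = [_ALPHABET[i] for i in rng.integers(0, len(_ALPHABET),
                                                template_length)]
    # deterministic redraw of collisions at the future mutation sites
    for p in cys_positions:
        while chars[p - 1] == "C":
            chars[p - 1] = _ALPHABET_NO_C[int(rng.integers(0, len(_ALPHABET_NO_C)))]

    mutable = [i for i in range(1, template_length - 1)
               if (i + 1) not in cys_positions]
    # guarantee an effective internal tryptic site (K not followed by P)
    if not any(chars[i] in "KR" and chars[i + 1] != "P"
               for i in range(template_length - 1)):
        i = mutable[0]
        chars[i] = "K"
        if chars[i + 1] == "P" and (i + 2) not in cys_positions:
            chars[i + 1] = "G"
    # guarantee an internal Asp-N site
    if "D" not in chars[1:]:
        chars[mutable[1]] = "D"

    wild_type = "".join(chars)
    mutant_chars = list(chars)
    for p in cys_positions:
        mutant_chars[p - 1] = "C"
    return MutantSequencePair(wild_type=wild_type,
                              mutant="".join(mutant_chars),
                              cys_positions=cys_positions, seed=seed)


# ---------------------------------------------------------------------------
# flow events & masks


def make_flow_events(n: int, log_mean: float, log_sd: float,
                     seed: int = 0) -> np.ndarray:
    """Log-normal fluorescence events; geometric mean -> exp(log_mean)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if log_sd < 0:
        raise ValueError("log_sd must be >= 0")
    rng = np.random.default_rng(seed)
    return rng.lognormal(mean=log_mean, sigma=log_sd, size=n)


def make_ellipse_mask(a_px: float, b_px: float, angle_deg: float = 0.0,
                      size: Union[int, Tuple[int, int], None] = None
                      ) -> np.ndarray:
    """Rasterized filled ellipse with semi-axes ``a_px`` (minor direction)
    and ``b_px`` (major direction), rotated by ``angle_deg``.

    Returns a boolean matrix; the true axis ratio is max(a,b)/min(a,b).
    """
    if a_px < 3 or b_px < 3:
        raise ValueError("semi-axes must be >= 3 px")
    extent = int(math.ceil(2 * max(a_px, b_px))) + 5
    if size is None:
        size = (extent, extent)
    elif isinstance(size, int):
        size = (size, size)
    h, w = size
    if h < extent or w < extent:
        raise ValueError(f"size {size} too small for ellipse, need >= {extent}")
    rows, cols = np.mgrid[0:h, 0:w]
    y = rows - (h - 1) / 2.0
    x = cols - (w - 1) / 2.0
    theta = math.radians(angle_deg)
    xr = x * math.cos(theta) + y * math.sin(theta)
    yr = -x * math.sin(theta) + y * math.cos(theta)
    return (xr / b_px) ** 2 + (yr / a_px) ** 2 <= 1.0
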