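"""In-silico proteolysis and disulfide-crosslinked peptide m/z prediction.

Applies engineered point mutations to subunit sequences, digests them with
configurable protease rules (single or sequential), and enumerates the
diagnostic crosslinked species a new inter-chain disulfide would produce,
with monoisotopic masses and m/z per charge state.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

# ---------------------------------------------------------------------------
# mass constants

#: monoisotopic residue (amino-acid minus water) masses, Da
MONOISOTOPIC_RESIDUE_MASS: Dict[str, float] = {
    "G": 57.02146, "A": 71.03711, "S": 87.03203, "P": 97.05276,
    "V": 99.06841, "T": 101.04768, "C": 103.00919, "L": 113.08406,
    "I": 113.08406, "N": 114.04293, "D": 115.02694, "Q": 128.05858,
    "K": 128.09496, "E": 129.04259, "M": 131.04049, "H": 137.05891,
    "F": 147.06841, "R": 156.10111, "Y": 163.06333, "W": 186.07931,
}

WATER = 18.0105646        # Da, H2O
HYDROGEN = 1.0078250      # Da, H atom
PROTON = 1.0072765        # Da, H+
DISULFIDE_DELTA = -2 * HYDROGEN  # -2.0156500 Da on S-S formation

VALID_RESIDUES = frozenset(MONOISOTOPIC_RESIDUE_MASS)


@dataclass(frozen=True)
class MassConstants:
    """Monoisotopic mass table plus the small-molecule constants."""

    residue_masses: Tuple[Tuple[str, float], ...] = tuple(
        sorted(MONOISOTOPIC_RESIDUE_MASS.items()))
    water: float = WATER
    hydrogen: float = HYDROGEN
    proton: float = PROTON

    @property
    def disulfide_delta(self) -> float:
        return -2 * self.hydrogen

    def residue_mass(self, residue: str) -> float:
        return dict(self.residue_masses)[residue]


DEFAULT_CONSTANTS = MassConstants()


# ---------------------------------------------------------------------------
# protease rules


@dataclass(frozen=True)
class ProteaseRule:
    """Cleavage specificity: C-terminal (cleave_after) or N-terminal
    (cleave_before) to a residue set, optionally blocked by the next residue
    (Keil rule: trypsin does not cut K/R-P)."""

    name: str
    cleave_after: Optional[FrozenSet[str]] = None
    cleave_before: Optional[FrozenSet[str]] = None
    blocked_by_next: FrozenSet[str] = frozenset()

    def __post_init__(self) -> None:
        if (self.cleave_after is None) == (self.cleave_before is None):
            raise ValueError(
                f"rule {self.name!r}: exactly one of cleave_after / "
                f"cleave_before must be set")

    def boundaries(self, sequence: str) -> List[int]:
        """Cleavage boundaries as indices b (1..len-1): cut between
        sequence[b-1] and sequence[b]."""
        cuts = []
        if self.cleave_after is not None:
            for b in range(1, len(sequence)):
                if (sequence[b - 1] in self.cleave_after
                        and sequence[b] not in self.blocked_by_next):
                    cuts.append(b)
        else:
            for b in range(1, len(sequence)):
                if sequence[b] in self.cleave_before:
                    cuts.append(b)
        return cuts


TRYPSIN = ProteaseRule("trypsin", cleave_after=frozenset("KR"),
                       blocked_by_next=frozenset("P"))
TRYPSIN_NO_P = ProteaseRule("trypsin_nop", cleave_after=frozenset("KR"))
ASPN_D = ProteaseRule("aspn_d", cleave_before=frozenset("D"))
ASPN_DE = ProteaseRule("aspn_de", cleave_before=frozenset("DE"))

PROTEASE_PRESETS: Dict[str, ProteaseRule] = {
    "trypsin": TRYPSIN,
    "trypsin_nop": TRYPSIN_NO_P,
    "aspn": ASPN_D,
    "aspn_d": ASPN_D,
    "aspn_de": ASPN_DE,
}


# ---------------------------------------------------------------------------
# peptides


@dataclass(frozen=True)
class PeptideFragment:
    sequence: str
    span: Tuple[int, int]  # 1-based inclusive on the parent chain
    missed_cleavages: int
    mass: float
    #: engineered-Cys construct positions covered by this fragment
    contains_positions: Tuple[int, ...] = ()

    def covers(self, position: int) -> bool:
        return self.span[0] <= position <= self.span[1]

    @property
    def has_cys(self) -> bool:
        return "C" in self.sequence


def _check_sequence(sequence: str) -> None:
    bad = set(sequence) - VALID_RESIDUES
    if bad:
        raise ValueError(f"non-standard residue(s) {sorted(bad)} in sequence")


def peptide_monoisotopic_mass(sequence: str,
                              constants: MassConstants = DEFAULT_CONSTANTS,
                              fixed_mods: Optional[Dict[str, float]] = None
                              ) -> float:
    """Monoisotopic neutral mass: sum of residue masses plus one water.

    ``fixed_mods`` maps residue letters to additional mass deltas (e.g.
    carbamidomethyl-C +57.02146); none are applied by default because the
    disulfide-verification workflow keeps cysteines unmodified.
    """
    if not sequence:
        raise ValueError("empty sequence")
    _check_sequence(sequence)
    table = dict(constants.residue_masses)
    total = constants.water
    for aa in sequence:
        total += table[aa]
        if fixed_mods and aa in fixed_mods:
            total += fixed_mods[aa]
    return total


# ---------------------------------------------------------------------------
# mutations


@dataclass(frozen=True)
class Mutation:
    chain: str
    position: int  # construct (mature-protein) numbering, 1-based
    from_residue: str
    to_residue: str

    def __post_init__(self) -> None:
        for r in (self.from_residue, self.to_residue):
            if r not in VALID_RESIDUES:
                raise ValueError(f"invalid residue {r!r} in mutation")
        if self.from_residue == self.to_residue:
            raise ValueError(
                f"mutation at {self.position} does not change the residue")
        if self.position < 1:
            raise ValueError("mutation position must be >= 1")

    def __str__(self) -> str:
        return f"{self.chain}:{self.from_residue}{self.position}{self.to_residue}"


_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")


def parse_mutations(spec: str) -> Dict[str, List[Mutation]]:
    """Parse ``"A:K321C,B:E358C"`` into mutations grouped by chain."""
    out: Dict[str, List[Mutation]] = {}
    for token in spec.split(","):
        token = token.strip()
        if not token:
            continue
        if ":" not in token:
            raise ValueError(f"mutation {token!r} lacks a chain prefix "
                             f"(expected CHAIN:K321C)")
        chain, body = token.split(":", 1)
        m = _MUTATION_RE.match(body.strip())
        if not m:
            raise ValueError(f"cannot parse mutation {token!r}")
        mut = Mutation(chain=chain.strip(), position=int(m.group(2)),
                       from_residue=m.group(1).upper(),
                       to_residue=m.group(3).upper())
        out.setdefault(mut.chain, []).append(mut)
    return out


def apply_mutations(sequence: str, mutations: Sequence[Mutation]) -> str:
    """Apply point mutations (1-based positions) to one chain's sequence.

    The stated from_residue must match the sequence; a mismatch raises with
    position, expected and found, which guards against numbering-offset
    mistakes.
    """
    _check_sequence(sequence)
    chars = list(sequence)
    for mut in mutations:
        if mut.position > len(sequence):
            raise ValueError(
                f"mutation {mut} outside sequence of length {len(sequence)}")
        found = chars[mut.position - 1]
        if found != mut.from_residue:
            raise ValueError(
                f"reference mismatch at position {mut.position}: mutation "
                f"{mut} expects {mut.from_residue!r} but sequence has "
                f"{found!r}")
        chars[mut.position - 1] = mut.to_residue
    return "".join(chars)


# ---------------------------------------------------------------------------
# digestion


def _fragments_from_boundaries(sequence: str, cuts: List[int],
                               max_missed: int,
                               constants: MassConstants,
                               fixed_mods: Optional[Dict[str, float]],
                               ) -> List[PeptideFragment]:
    bounds = [0] + sorted(cuts) + [len(sequence)]
    frags: List[PeptideFragment] = []
    for i in range(len(bounds) - 1):
        for m in range(max_missed + 1):
            j = i + m + 1
            if j >= len(bounds):
                break
            start, end = bounds[i], bounds[j]
            seq = sequence[start:end]
            frags.append(PeptideFragment(
                sequence=seq,
                span=(start + 1, end),
                missed_cleavages=m,
                mass=peptide_monoisotopic_mass(seq, constants, fixed_mods),
            ))
    frags.sort(key=lambda f: (f.span, f.missed_cleavages))
    return frags


def digest(sequence: str, rule: ProteaseRule, max_missed: int = 2,
           constants: MassConstants = DEFAULT_CONSTANTS,
           fixed_mods: Optional[Dict[str, float]] = None
           ) -> List[PeptideFragment]:
    """Enumerate proteolytic fragments with 0..max_missed missed cleavages."""
    if not sequence:
        raise ValueError("empty sequence")
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    _check_sequence(sequence)
    return _fragments_from_boundaries(sequence, rule.boundaries(sequence),
                                      max_missed, constants, fixed_mods)


def sequential_digest(sequence: str, rules: Sequence[ProteaseRule],
                      max_missed: int = 2,
                      constants: MassConstants = DEFAULT_CONSTANTS,
                      fixed_mods: Optional[Dict[str, float]] = None
                      ) -> List[PeptideFragment]:
    """Joint digest: the union of all rules' cleavage sites, spans kept on
    the original sequence."""
    if not rules:
        raise ValueError("at least one protease rule required")
    if not sequence:
        raise ValueError("empty sequence")
    _check_sequence(sequence)
    cuts = sorted({b for rule in rules for b in rule.boundaries(sequence)})
    return _fragments_from_boundaries(sequence, cuts, max_missed,
                                      constants, fixed_mods)


# ---------------------------------------------------------------------------
# crosslinks


@dataclass(frozen=True)
class CrosslinkSpecies:
    peptide_a: PeptideFragment
    peptide_b: PeptideFragment
    neutral_mass: float
    mz_by_charge: Tuple[Tuple[int, float], ...]
    diagnostic: bool = False

    def mz(self, z: int) -> float:
        return dict(self.mz_by_charge)[z]


def _as_fragment(pep) -> PeptideFragment:
    if isinstance(pep, PeptideFragment):
        return pep
    seq = str(pep)
    return PeptideFragment(sequence=seq, span=(1, len(seq)),
                           missed_cleavages=0,
                           mass=peptide_monoisotopic_mass(seq))


def disulfide_crosslink_mass(pep_a, pep_b,
                             constants: MassConstants = DEFAULT_CONSTANTS
                             ) -> float:
    """Neutral mass of two peptides joined by one disulfide
    (sum of masses minus two hydrogen atoms)."""
    a, b = _as_fragment(pep_a), _as_fragment(pep_b)
    for frag, tag in ((a, "first"), (b, "second")):
        if not frag.has_cys:
            raise ValueError(
                f"{tag} peptide {frag.sequence!r} contains no cysteine; "
                f"cannot form a disulfide")
    return a.mass + b.mass + constants.disulfide_delta


def mz_for_charge(neutral_mass: float, z: int,
                  constants: MassConstants = DEFAULT_CONSTANTS) -> float:
    """(M + z * proton) / z."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    return (neutral_mass + z * constants.proton) / z


def enumerate_diagnostic_crosslinks(
        digest_a: Sequence[PeptideFragment],
        digest_b: Sequence[PeptideFragment],
        engineered_positions_a: Sequence[int],
        engineered_positions_b: Sequence[int],
        charges: Iterable[int] = (1, 2, 3, 4),
        wildtype_digest_a: Optional[Sequence[PeptideFragment]] = None,
        wildtype_digest_b: Optional[Sequence[PeptideFragment]] = None,
        constants: MassConstants = DEFAULT_CONSTANTS,
) -> List[CrosslinkSpecies]:
    """All crosslink species pairing an engineered-Cys peptide from each
    digest.

    A species is flagged diagnostic when neither constituent peptide occurs
    (by sequence) in the corresponding wild-type digest.  Same-peptide
    (intra-peptide) disulfides are not enumerated.
    """
    if not digest_a or not digest_b:
        return []
    charges = sorted(set(int(z) for z in charges))
    if any(z < 1 for z in charges):
        raise ValueError("charges must all be >= 1")
    wt_a = {f.sequence for f in (wildtype_digest_a or ())}
    wt_b = {f.sequence for f in (wildtype_digest_b or ())}

    def covering(frags, positions):
        out = []
        for f in frags:
            hit = tuple(p for p in positions if f.covers(p))
            if hit and f.has_cys:
                out.append(PeptideFragment(
                    sequence=f.sequence, span=f.span,
                    missed_cleavages=f.missed_cleavages, mass=f.mass,
                    contains_positions=hit))
        return out

    species: List[CrosslinkSpecies] = []
    for fa in covering(digest_a, engineered_positions_a):
        for fb in covering(digest_b, engineered_positions_b):
            neutral = disulfide_crosslink_mass(fa, fb, constants)
            species.append(CrosslinkSpecies(
                peptide_a=fa, peptide_b=fb, neutral_mass=neutral,
                mz_by_charge=tuple(
                    (z, mz_for_charge(neutral, z, constants))
                    for z in charges),
                diagnostic=(fa.sequence not in wt_a
                            and fb.sequence not in wt_b),
            ))
    species.sort(key=lambda s: (s.neutral_mass,
                                s.peptide_a.span, s.peptide_b.span))
    return species


# ---------------------------------------------------------------------------
# peak matching


@dataclass(frozen=True)
class PeakMatch:
    species: CrosslinkSpecies
    charge: int
    mz_predicted: float
    mz_observed: float
    ppm_error: float  # signed, (obs - pred) / pred * 1e6


def match_observed_peaks(species_list: Sequence[CrosslinkSpecies],
                         observed: Sequence[Tuple[float, int]],
                         tol_ppm: float = 10.0) -> List[PeakMatch]:
    """Match observed (m/z, z) peaks to predicted species within a ppm
    tolerance at the same charge."""
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    matches: List[PeakMatch] = []
    for mz_obs, z in observed:
        z = int(z)
        for sp in species_list:
            by_charge = dict(sp.mz_by_charge)
            if z not in by_charge:
                continue
            mz_pred = by_charge[z]
            ppm = (mz_obs - mz_pred) / mz_pred * 1e6
            if abs(ppm) <= tol_ppm:
                matches.append(PeakMatch(
                    species=sp, charge=z, mz_predicted=mz_pred,
                    mz_observed=mz_obs, ppm_error=ppm))
    matches.sort(key=lambda m: (m.mz_observed, abs(m.ppm_error)))
    return matches
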