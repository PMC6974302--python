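"""Domain types for the chirality/RNA-world lattice model.

The model lives on an N x N toroidal grid of "rooms".  Each room holds a
multiset of molecules: achiral-base *precursors* (raw material, one
nucleotide-equivalent each), free *nucleotides* (a base plus a handedness),
free *RNA chains* (sequences of (base, handedness) residues) and *template
complexes* (an RNA chain acting as template with substrates base-paired onto
it).  Only the two mirror forms D and L exist and they never interconvert
directly; precursors alone racemize.

The engine stores precursors and free nucleotides as per-room count arrays
(they carry no further identity), and chains/complexes as objects.  A
length-1 chain *is* a free nucleotide: the count array is its canonical
representation, so no room ever holds both encodings of the same species.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = [
    "Chirality",
    "D",
    "L",
    "BASES",
    "base_index",
    "complement",
    "Precursor",
    "Nucleotide",
    "RNAChain",
    "Attachment",
    "TemplateComplex",
    "PrimerLadder",
    "UNIFORM_LADDER",
    "Params",
    "P_NFR_ACTIVE",
    "P_TLR_ACTIVE",
    "detect_ribozyme",
    "mirror_chain",
    "clamp_probability",
]


class Chirality(enum.IntEnum):
    """Handedness of a chiral molecule; mirror() is an involution."""

    D = 0
    L = 1

    def mirror(self) -> "Chirality":
        return Chirality(1 - self.value)


D = Chirality.D
L = Chirality.L

#: Base alphabet; indices are the internal encoding.  A pairs with U and C
#: with G, so the Watson-Crick complement is ``index ^ 1``.
BASES = "AUCG"


def base_index(symbol: str) -> int:
    try:
        return BASES.index(symbol)
    except ValueError:
        raise ValueError(f"unknown base {symbol!r}; expected one of {BASES}") from None


def complement(base: int) -> int:
    """Watson-Crick partner of an encoded base (A<->U, C<->G)."""
    return base ^ 1


@dataclass(frozen=True)
class Precursor:
    """Nucleotide precursor: chiral raw material without base identity."""

    chirality: Chirality


@dataclass(frozen=True)
class Nucleotide:
    """A free mononucleotide (operationally identical to a 1-mer chain)."""

    base: int
    chirality: Chirality

    def __post_init__(self):
        if not 0 <= self.base <= 3:
            raise ValueError("base must be encoded 0..3 (A,U,C,G)")


class RNAChain:
    """An RNA molecule as an ordered run of (base, chirality) residues.

    Chains are directionless: the model never invokes 3'/5' polarity, so the
    two ends are interchangeable and sequence matching also checks the
    reversed residue order.
    """

    __slots__ = ("bases", "chirs")

    def __init__(self, bases, chirs):
        self.bases = bytearray(bases)
        self.chirs = bytearray(chirs)
        if len(self.bases) != len(self.chirs):
            raise ValueError("bases and chiralities must have equal length")
        if len(self.bases) == 0:
            raise ValueError("an RNA chain has at least one residue")

    @classmethod
    def from_string(cls, seq: str, chirality) -> "RNAChain":
        """Build a chain from a base string.

        ``chirality`` is a single Chirality (homochiral chain) or a sequence
        of Chirality values, one per residue.
        """
        bases = bytes(base_index(s) for s in seq)
        if isinstance(chirality, Chirality):
            chirs = bytes([chirality.value]) * len(bases)
        else:
            chirs = bytes(Chirality(c).value for c in chirality)
        return cls(bases, chirs)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def mass(self) -> int:
        """Relative mass in nucleotide equivalents (= residue count)."""
        return len(self.bases)

    def sequence(self) -> str:
        return "".join(BASES[b] for b in self.bases)

    def residues(self) -> list[tuple[int, Chirality]]:
        return [(b, Chirality(c)) for b, c in zip(self.bases, self.chirs)]

    def is_homochiral(self) -> bool:
        first = self.chirs[0]
        return all(c == first for c in self.chirs)

    def copy(self) -> "RNAChain":
        return RNAChain(self.bases, self.chirs)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        marks = "".join("dl"[c] for c in self.chirs)
        return f"RNAChain({self.sequence()}/{marks})"


def mirror_chain(chain: RNAChain) -> RNAChain:
    """The enantiomeric chain: every residue's handedness flipped."""
    return RNAChain(chain.bases, bytes(1 - c for c in chain.chirs))


class Attachment:
    """A substrate base-paired onto a template at a start position.

    ``false_pairs`` records, per substrate residue, whether the pairing with
    the template base was non-complementary (admitted with probability P_FP).
    Substrates that have been ligated to each other are represented merged
    into a single attachment.
    """

    __slots__ = ("start", "chain", "false_pairs")

    def __init__(self, start: int, chain: RNAChain, false_pairs=None):
        self.start = start
        self.chain = chain
        if false_pairs is None:
            false_pairs = bytes(len(chain))
        self.false_pairs = bytearray(false_pairs)

    @property
    def end(self) -> int:
        """Last template position covered (inclusive)."""
        return self.start + len(self.chain) - 1


class TemplateComplex:
    """A template chain with substrates aligned on it by base pairing.

    Attachments occupy non-overlapping template positions and, because the
    complex hosts a single growing region, they form one contiguous block.
    """

    __slots__ = ("template", "attachments")

    def __init__(self, template: RNAChain, attachments: Optional[list[Attachment]] = None):
        self.template = template
        self.attachments = attachments if attachments is not None else []
        self._check()

    def _check(self) -> None:
        prev_end = -1
        for att in self.attachments:
            if att.start <= prev_end:
                raise ValueError("attachments must occupy increasing, disjoint positions")
            prev_end = att.end
        if self.attachments:
            if self.attachments[0].start < 0 or self.attachments[-1].end >= len(self.template):
                raise ValueError("attachment outside template")

    @property
    def paired_count(self) -> int:
        """r, the number of base pairs in the duplex."""
        return sum(len(a.chain) for a in self.attachments)

    @property
    def mass(self) -> int:
        return len(self.template) + self.paired_count

    def block_span(self) -> tuple[int, int]:
        """(first, last) template positions covered by the substrate block."""
        return self.attachments[0].start, self.attachments[-1].end

    def strands(self) -> Iterator[RNAChain]:
        yield self.template
        for att in self.attachments:
            yield att.chain


@dataclass(frozen=True)
class PrimerLadder:
    """Length-dependent extension-rate multipliers (the primer effect).

    ``rate(n)`` multiplies the base ligation probability when the extending
    polymer currently has n residues: R1 for a monomer, R2 for a dimer, R3
    for a trimer and Rn for anything longer.  Every ladder used in the study
    has Rn = R3, expressing that extension of an established primer is
    uniformly fast.
    """

    R1: float = 1.0
    R2: float = 1.0
    R3: float = 1.0
    Rn: float = 1.0

    def __post_init__(self):
        for r in (self.R1, self.R2, self.R3, self.Rn):
            if r < 0:
                raise ValueError("ladder multipliers must be >= 0")

    def rate(self, extender_length: int) -> float:
        if extender_length <= 1:
            return self.R1
        if extender_length == 2:
            return self.R2
        if extender_length == 3:
            return self.R3
        return self.Rn

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.R1, self.R2, self.R3, self.Rn)


UNIFORM_LADDER = PrimerLadder()

#: Catalytically active rates for the two ribozymes.  The study's parameter
#: table lists these values, but they apply only in scenarios that model the
#: corresponding ribozyme; elsewhere both rates are zero.
P_NFR_ACTIVE = 0.2
P_TLR_ACTIVE = 0.9

_PROB_FIELDS = (
    "P_AT", "P_BB", "P_CIC", "P_FP", "P_MN", "P_MPN", "P_ND",
    "P_NDE", "P_NF", "P_NFR", "P_RL", "P_SP", "P_TL", "P_TLR",
    "F_CSS", "F_CST",
)


@dataclass(frozen=True)
class Params:
    """All model parameters; the single source of truth for rates.

    Probabilities are per-step Bernoulli rates per eligible entity or site.
    P_NFR and P_TLR are zero unless a scenario explicitly models the NSR or
    REP ribozyme (their active values are 0.2 and 0.9 respectively).
    """

    P_AT: float = 0.5       # template attracting a substrate
    P_BB: float = 1e-5      # phosphodiester bond breaking (single-strand site)
    P_CIC: float = 0.5      # precursor racemization
    P_FP: float = 0.001     # false base-pairing during attraction
    P_MN: float = 1e-4      # movement of a nucleotide (chains: P_MN/sqrt(m))
    P_MPN: float = 0.002    # movement of a precursor
    P_ND: float = 0.01      # free nucleotide decaying to precursor
    P_NDE: float = 1e-4     # chain-end residue decaying (single-strand end)
    P_NF: float = 0.001     # nucleotide forming from precursor, non-enzymatic
    P_NFR: float = 0.0      # nucleotide formation catalysed by NSR (active: 0.2)
    P_RL: float = 2e-6      # surface-mediated (random) ligation
    P_SP: float = 0.3       # separation of a single base pair
    P_TL: float = 0.002     # template-directed ligation, non-enzymatic
    P_TLR: float = 0.0      # template-directed ligation by REP (active: 0.9)
    N: int = 20             # grid side
    T_NPB: int = 50000      # total nucleotide precursors introduced at start
    C_T: int = 8            # collision rounds per room per step
    F_CSS: float = 0.5      # chiral selection factor, surface-mediated
    F_CST: float = 0.5      # chiral selection factor, template-directed
    CS_REP: str = "GUUCAG"  # catalytic domain of the replicase ribozyme
    CS_NSR: str = "ACUGGC"  # catalytic domain of the synthetase ribozyme
    R_surface: PrimerLadder = field(default_factory=PrimerLadder)
    R_template: PrimerLadder = field(default_factory=PrimerLadder)
    neighborhood: str = "von_neumann"  # movement: "von_neumann" (4) or "moore" (8)

    def __post_init__(self):
        for name in _PROB_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.N < 1:
            raise ValueError("grid side N must be >= 1")
        if self.T_NPB <= 0:
            raise ValueError("T_NPB must be positive")
        if self.C_T < 0:
            raise ValueError("C_T must be >= 0")
        if self.neighborhood not in ("von_neumann", "moore"):
            raise ValueError("neighborhood must be 'von_neumann' or 'moore'")
        for seq in (self.CS_REP, self.CS_NSR):
            for s in seq:
                base_index(s)

    def replace(self, **kwargs) -> "Params":
        return dataclasses.replace(self, **kwargs)


def clamp_probability(p: float, warn=None) -> float:
    """Clamp an effective rate (probability x multiplier) into [0, 1]."""
    if p > 1.0:
        if warn is not None:
            warn(p)
        return 1.0
    if p < 0.0:
        return 0.0
    return p


def _find_uniform_match(bases, chirs, pattern: bytes) -> Optional[int]:
    """First index where ``pattern`` occurs with uniform chirality, else None."""
    start = bases.find(pattern)
    n = len(pattern)
    while start != -1:
        window = chirs[start:start + n]
        if all(c == window[0] for c in window):
            return start
        start = bases.find(pattern, start + 1)
    return None


def detect_ribozyme(chain: RNAChain, domain: str) -> tuple[bool, Optional[Chirality]]:
    """Does a free chain fold into an active ribozyme with this domain?

    A chain is active iff it is no longer than twice the domain length
    (redundant residues would disrupt folding of the catalytic core), it
    contains the domain as a contiguous base subsequence in either residue
    order (chains are directionless), and the matched residues share one
    handedness.  Returns (active, handedness-of-the-catalytic-core).
    """
    if not domain:
        raise ValueError("domain must be non-empty")
    pattern = bytes(base_index(s) for s in domain)
    if len(chain) > 2 * len(pattern) or len(chain) < len(pattern):
        return False, None
    bases = bytes(chain.bases)
    hit = _find_uniform_match(bases, chain.chirs, pattern)
    if hit is not None:
        return True, Chirality(chain.chirs[hit])
    rev = bases[::-1]
    rev_chirs = chain.chirs[::-1]
    hit = _find_uniform_match(rev, rev_chirs, pattern)
    if hit is not None:
        return True, Chirality(rev_chirs[hit])
    return False, None
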