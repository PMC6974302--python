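"""Rate formulas and single-molecule stochastic events.

Every event is a per-step Bernoulli trial.  The formulas encode the model's
physical assumptions: synergistic double-strand breaking and end decay use
exponent 3/2 instead of 2; duplex separation decays as P_SP^((r+1)/2) with
the base-pair count r (the 1/2 reflecting self-folding of the freed single
strands); and polymer diffusion follows Zimm scaling P_MN / sqrt(m) with the
relative mass m.  Racemization is the only chirality-changing event and
applies to precursors alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    Nucleotide,
    Params,
    Precursor,
    RNAChain,
    TemplateComplex,
)

__all__ = [
    "EventOutcome",
    "racemize",
    "form_nucleotide",
    "decay_nucleotide",
    "end_decay_probability",
    "bond_break_probability",
    "separation_probability",
    "movement_probability",
]


@dataclass(frozen=True)
class EventOutcome:
    """Result of one stochastic event: did it fire, and the products.

    Chemical events conserve nucleotide-equivalent mass: formation and decay
    interconvert precursor and nucleotide one-to-one, breaking partitions
    residues between fragments.
    """

    occurred: bool
    products: tuple


def racemize(p: Precursor, params: Params, rng: np.random.Generator) -> EventOutcome:
    """Precursor handedness flip with probability P_CIC.

    Precursors model glyceraldehyde-like raw material that racemizes
    readily; nucleotides and chain residues never interconvert directly.
    """
    if rng.random() < params.P_CIC:
        return EventOutcome(True, (Precursor(p.chirality.mirror()),))
    return EventOutcome(False, (p,))


def form_nucleotide(
    p: Precursor,
    nsr_credit: int,
    params: Params,
    rng: np.random.Generator,
) -> tuple[EventOutcome, bool]:
    """Precursor -> nucleotide, enzymatically when an NSR credit is available.

    With a same-handed synthetase ribozyme present (``nsr_credit > 0``) the
    transformation fires with P_NFR and, on success, consumes one credit for
    this room and step; otherwise the non-enzymatic rate P_NF applies.  The
    product keeps the precursor's handedness and draws its base uniformly
    from A, U, C, G.
    """
    if nsr_credit < 0:
        raise ValueError("nsr_credit must be >= 0")
    rate = params.P_NFR if nsr_credit > 0 else params.P_NF
    if rng.random() < rate:
        base = int(rng.integers(4))
        return EventOutcome(True, (Nucleotide(base, p.chirality),)), nsr_credit > 0
    return EventOutcome(False, (p,)), False


def decay_nucleotide(n: Nucleotide, params: Params, rng: np.random.Generator) -> EventOutcome:
    """Free nucleotide decays to a same-handed precursor with P_ND."""
    if rng.random() < params.P_ND:
        return EventOutcome(True, (Precursor(n.chirality),))
    return EventOutcome(False, (n,))


def end_decay_probability(end_is_paired: bool, params: Params) -> float:
    """Decay rate of a chain-end residue.

    A single-stranded end decays with P_NDE; a base-paired end loses both
    partnered residues in one synergistic event with P_NDE^(3/2).  Interior
    residues are protected and never decay.
    """
    return params.P_NDE ** 1.5 if end_is_paired else params.P_NDE


def bond_break_probability(site_in_duplex_region: bool, params: Params) -> float:
    """Breaking rate of a phosphodiester bond.

    Within a duplex region the two parallel backbone bonds break together
    with P_BB^(3/2) (synergistic); a single-strand site breaks with P_BB.
    """
    return params.P_BB ** 1.5 if site_in_duplex_region else params.P_BB


def separation_probability(r: int, params: Params) -> float:
    """Probability that a duplex with r base pairs dissociates: P_SP^((r+1)/2)."""
    if r < 1:
        raise ValueError("a duplex has at least one base pair")
    return params.P_SP ** ((r + 1) / 2)


def movement_probability(mol, params: Params) -> float:
    """Per-step probability that a molecule hops to an adjacent room.

    Precursors move with P_MPN; a nucleotide (or 1-mer chain) with P_MN; an
    m-residue chain with P_MN / sqrt(m) (Zimm scaling); a template complex
    moves as one unit with m equal to its total residue count.
    """
    if isinstance(mol, Precursor):
        return params.P_MPN
    if isinstance(mol, Nucleotide):
        return params.P_MN
    if isinstance(mol, RNAChain):
        return params.P_MN / len(mol) ** 0.5
    if isinstance(mol, TemplateComplex):
        return params.P_MN / mol.mass ** 0.5
    raise TypeError(f"unsupported molecule type {type(mol).__name__}")
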