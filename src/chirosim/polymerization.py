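"""Surface-mediated and template-directed RNA synthesis.

Two polymerization routes exist.  *Surface-mediated* (de novo) synthesis
joins free molecules end to end at the low rate P_RL; it knows nothing about
base identity but discriminates handedness through the chiral-selection
factor F_CSS and through the primer-effect ladder (extension of an
established polymer is faster than initiation).  *Template-directed*
synthesis aligns substrates on a template by base pairing (attraction, rate
P_AT, fidelity via P_FP) and ligates adjacent substrates at P_TL (or P_TLR
under replicase catalysis), with chiral selection F_CST.

Cross-inhibition is encoded structurally: incorporating an opposite-handed
residue leaves a heterochiral junction at the chain end, and such an end is
blocked for further extension.  Breaking a chain behind the junction
restores an extendable homochiral end, matching the chemistry of removing
the inhibiting residue.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .core import (
    Attachment,
    Chirality,
    Nucleotide,
    Params,
    PrimerLadder,
    RNAChain,
    TemplateComplex,
    clamp_probability,
    complement,
)

__all__ = [
    "end_blocked",
    "surface_ligation_rate",
    "random_ligation_round",
    "attract_substrate",
    "template_ligation_round",
    "attempt_pair_ligation",
    "attempt_attraction",
]

Draw = Callable[[], float]


def end_blocked(chain: RNAChain, end: int, no_termination: bool = False) -> bool:
    """Is this chain end terminated by cross-inhibition?

    ``end`` selects the terminus: 0 for the residue at index 0, 1 for the
    last residue.  An end is blocked when its terminal residue's handedness
    differs from its neighbour's (the terminal residue was incorporated as
    an opposite-handed monomer).  Length-1 chains have no junction and are
    never blocked.  With ``no_termination`` (a control variant) nothing is
    ever blocked and chimeric chains extend freely.
    """
    if no_termination or len(chain) < 2:
        return False
    if end == 0:
        return chain.chirs[0] != chain.chirs[1]
    return chain.chirs[-1] != chain.chirs[-2]


def surface_ligation_rate(
    extender_end_chirality: Chirality,
    incomer_chirality: Chirality,
    extender_length: int,
    params: Params,
    ladder: PrimerLadder,
) -> float:
    """Effective probability of one surface-mediated ligation attempt.

    rate = P_RL x ladder(extender length) x (1 if same handedness else
    F_CSS), clamped to [0, 1].
    """
    factor = 1.0 if extender_end_chirality == incomer_chirality else params.F_CSS
    return clamp_probability(params.P_RL * ladder.rate(extender_length) * factor)


def _join(extender: RNAChain, ext_end: int, incomer: RNAChain, inc_end: int) -> RNAChain:
    """Concatenate two directionless chains at the chosen ends."""
    inc_b, inc_c = incomer.bases, incomer.chirs
    if ext_end == 1:
        if inc_end == 1:  # incomer joins by its far end: reverse it
            inc_b, inc_c = inc_b[::-1], inc_c[::-1]
        return RNAChain(extender.bases + inc_b, extender.chirs + inc_c)
    if inc_end == 0:
        inc_b, inc_c = inc_b[::-1], inc_c[::-1]
    return RNAChain(inc_b + extender.bases, inc_c + extender.chirs)


def attempt_pair_ligation(
    a: RNAChain,
    b: RNAChain,
    params: Params,
    ladder: PrimerLadder,
    draw: Draw,
    no_termination: bool = False,
) -> Optional[RNAChain]:
    """One collision-driven surface ligation attempt between two molecules.

    The longer partner acts as the extender (ties broken at random): its
    current length selects the primer-ladder multiplier and its joining-end
    residue defines same/opposite handedness.  Joining ends are chosen
    uniformly (chains are directionless).  Returns the merged chain, or
    None when the attempt fails or the extender's end is blocked.
    """
    if len(a) < len(b) or (len(a) == len(b) and draw() < 0.5):
        a, b = b, a
    ext_end = 0 if draw() < 0.5 else 1
    inc_end = 0 if draw() < 0.5 else 1
    if end_blocked(a, ext_end, no_termination):
        return None
    ext_chir = Chirality(a.chirs[0 if ext_end == 0 else -1])
    inc_chir = Chirality(b.chirs[0 if inc_end == 0 else -1])
    rate = surface_ligation_rate(ext_chir, inc_chir, len(a), params, ladder)
    if rate > 0.0 and draw() < rate:
        return _join(a, ext_end, b, inc_end)
    return None


def random_ligation_round(
    room: list,
    params: Params,
    ladder: PrimerLadder,
    rng: np.random.Generator,
    no_termination: bool = False,
) -> list:
    """One collision round of surface-mediated ligation within a room.

    Free chains and nucleotides are grouped pairwise uniformly at random
    (an odd molecule idles); each pair makes one ligation attempt.  Other
    molecule kinds in the room are left untouched.
    """
    participants = [m for m in room if isinstance(m, (RNAChain, Nucleotide))]
    rest = [m for m in room if not isinstance(m, (RNAChain, Nucleotide))]
    if len(participants) < 2:
        return list(room)
    order = list(range(len(participants)))
    rng.shuffle(order)
    out = list(rest)
    draw = rng.random
    for k in range(0, len(order) - 1, 2):
        a = _as_chain(participants[order[k]])
        b = _as_chain(participants[order[k + 1]])
        merged = attempt_pair_ligation(a, b, params, ladder, draw, no_termination)
        if merged is not None:
            out.append(merged)
        else:
            out.append(participants[order[k]])
            out.append(participants[order[k + 1]])
    if len(order) % 2:
        out.append(participants[order[-1]])
    return out


def _as_chain(mol) -> RNAChain:
    if isinstance(mol, Nucleotide):
        return RNAChain(bytes([mol.base]), bytes([mol.chirality.value]))
    return mol


def template_capacity(target, substrate_length: int) -> bool:
    """Can this template (bare chain or complex) accept the substrate?

    A substrate fits when it is no longer than the remaining single-strand
    run adjacent to the growing block (anywhere on a bare template).  A
    template is a chain of length >= 2: a lone nucleotide does not template.
    """
    if isinstance(target, RNAChain):
        return len(target) >= 2 and substrate_length <= len(target)
    if isinstance(target, TemplateComplex):
        first, last = target.block_span()
        left = first
        right = len(target.template) - 1 - last
        return substrate_length <= max(left, right)
    return False


def attempt_attraction(
    target,
    substrate: RNAChain,
    params: Params,
    draw: Draw,
):
    """One attraction attempt of a substrate onto a template.

    Success probability is P_AT times a per-position fidelity factor: 1 for
    a Watson-Crick complementary pairing, P_FP for a false pair.  The first
    substrate lands anywhere on a bare template (uniform start); later
    substrates align contiguously next to the block, on a uniformly chosen
    side with enough free template.  Substrate orientation is chosen at
    random (directionless chains).  Handedness never gates attraction; all
    chiral discrimination happens at ligation.

    Returns the updated TemplateComplex on success (a fresh complex when the
    target was a bare chain; the same object, mutated, when it already was a
    complex) or None on failure.
    """
    m = len(substrate)
    if not template_capacity(target, m):
        return None
    u = draw()
    if u >= params.P_AT:
        return None
    if isinstance(target, RNAChain):
        template = target
        nstarts = len(template) - m + 1
        start = min(int(draw() * nstarts), nstarts - 1)
        side_front = True  # irrelevant for the first substrate
        existing = None
    else:
        existing = target
        template = target.template
        first, last = target.block_span()
        left_fit = m <= first
        right_fit = m <= len(template) - 1 - last
        if left_fit and right_fit:
            side_front = draw() < 0.5
        elif left_fit:
            side_front = True
        else:
            side_front = False
        start = first - m if side_front else last + 1
    sub_b = substrate.bases
    sub_c = substrate.chirs
    if m > 1 and draw() < 0.5:
        sub_b, sub_c = sub_b[::-1], sub_c[::-1]
    mismatches = 0
    t_b = template.bases
    for k in range(m):
        if complement(t_b[start + k]) != sub_b[k]:
            mismatches += 1
    if mismatches and u >= params.P_AT * params.P_FP ** mismatches:
        return None
    placed = RNAChain(sub_b, sub_c)
    false_pairs = bytes(
        1 if complement(t_b[start + k]) != sub_b[k] else 0 for k in range(m)
    )
    att = Attachment(start, placed, false_pairs)
    if existing is None:
        return TemplateComplex(template, [att])
    if side_front:
        existing.attachments.insert(0, att)
    else:
        existing.attachments.append(att)
    return existing


def attract_substrate(
    target,
    substrate,
    params: Params,
    rng: np.random.Generator,
):
    """Public wrapper of :func:`attempt_attraction` drawing from ``rng``."""
    return attempt_attraction(target, _as_chain(substrate), params, rng.random)


def template_ligation_round(
    cx: TemplateComplex,
    rep_credits: dict,
    params: Params,
    ladder: PrimerLadder,
    rng_or_draw,
    no_termination: bool = False,
) -> int:
    """Attempt ligation at every junction between adjacent substrates.

    At each junction the longer attachment is the growing chain (ties broken
    at random) and the shorter is the incomer.  A blocked growing-chain end
    (heterochiral terminal junction) forbids ligation.  When the template,
    both substrates and an available same-handed replicase agree in
    handedness, ligation fires with P_TLR and consumes one REP credit from
    ``rep_credits`` (a mapping Chirality -> remaining count, mutated in
    place).  Otherwise the non-enzymatic rate applies:
    P_TL x ladder(growing-chain length) x (1 if the incomer's junction
    residue matches both the growing chain and the template, else F_CST).
    Ligated substrates are merged into a single attachment.  Returns the
    number of REP credits consumed.
    """
    draw = rng_or_draw.random if isinstance(rng_or_draw, np.random.Generator) else rng_or_draw
    used = 0
    atts = cx.attachments
    i = 0
    while i < len(atts) - 1:
        left, right = atts[i], atts[i + 1]
        if left.end + 1 != right.start:
            i += 1
            continue
        if len(left.chain) > len(right.chain):
            ext, inc, ext_is_left = left, right, True
        elif len(left.chain) < len(right.chain):
            ext, inc, ext_is_left = right, left, False
        elif draw() < 0.5:
            ext, inc, ext_is_left = left, right, True
        else:
            ext, inc, ext_is_left = right, left, False
        # the growing chain extends toward the junction: its junction-side end
        ext_end = 1 if ext_is_left else 0
        if end_blocked(ext.chain, ext_end, no_termination):
            i += 1
            continue
        fired = False
        chir = _uniform_junction_chirality(cx, left, right)
        if chir is not None and rep_credits.get(chir, 0) > 0 and params.P_TLR > 0:
            if draw() < params.P_TLR:
                rep_credits[chir] -= 1
                used += 1
                fired = True
        else:
            inc_chir = Chirality(inc.chain.chirs[0 if ext_is_left else -1])
            ext_chir = Chirality(ext.chain.chirs[-1 if ext_is_left else 0])
            # template residue under the incomer's junction residue
            t_pos = right.start if ext_is_left else left.end
            t_chir = Chirality(cx.template.chirs[t_pos])
            same = inc_chir == ext_chir and inc_chir == t_chir
            rate = clamp_probability(
                params.P_TL * ladder.rate(len(ext.chain)) * (1.0 if same else params.F_CST)
            )
            if rate > 0.0 and draw() < rate:
                fired = True
        if fired:
            merged = Attachment(
                left.start,
                RNAChain(left.chain.bases + right.chain.bases,
                         left.chain.chirs + right.chain.chirs),
                bytes(left.false_pairs) + bytes(right.false_pairs),
            )
            atts[i:i + 2] = [merged]
            # stay at i: the merged block may adjoin the next attachment
        else:
            i += 1
    return used


def _uniform_junction_chirality(cx, left, right):
    """Single handedness shared by both substrates and the covered template.

    Returns that Chirality, or None when any residue disagrees (the
    replicase requires full agreement of template, substrates and itself).
    """
    c = left.chain.chirs[0]
    for att in (left, right):
        if any(x != c for x in att.chain.chirs):
            return None
    t = cx.template.chirs[left.start:right.end + 1]
    if any(x != c for x in t):
        return None
    return Chirality(c)
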