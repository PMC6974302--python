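"""Compiled kernels for the Monte-Carlo step.

Two kernels cover one step: :func:`step_chemistry` (precursor racemization,
nucleotide formation and decay, the C_T collision rounds, template-directed
ligation, chain degradation, and detection of the rare degradation events on
template complexes) and :func:`step_transport` (duplex separation and
movement).  Between the two calls the python layer applies the detected
complex-degradation events; that application draws no random numbers, so a
run remains a single deterministic stream from one seed.

Every event is an independent Bernoulli trial drawn directly from the
``np.random.Generator`` shared with the python-side phases.  The kernels
implement, on the flat array state, exactly the semantics of the
object-level operations in :mod:`chirosim.polymerization`: uniform pairwise
grouping per collision round (odd molecule idles), the two-outcome collision
rule (surface ligation vs template attraction), chirality-blind attraction
with per-position pairing fidelity, chiral selection and primer-effect
ladders at ligation, structural cross-inhibition, and NSR/REP catalysis
credits.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# tops[] indices
TOP_CH = 0        # entries on the chain free-list
TOP_CX = 1        # entries on the complex free-list
ERR = 2           # capacity-error flag
REP_USED = 3      # REP-catalysed ligations this step
NSR_USED = 4      # NSR-catalysed nucleotide formations this step

EV_CAP = 256      # complex degradation events per step (far beyond need)


@njit(cache=True, inline="always")
def _binom_small(n, p, rng):
    """Exact binomial draw for n <= 64, p <= 0.5 by CDF inversion."""
    q = 1.0 - p
    f = q ** n
    u = rng.random()
    k = 0
    c = f
    ratio = p / q
    while u > c and k < n:
        k += 1
        f *= (n - k + 1) / k * ratio
        c += f
    return k


@njit(cache=True, inline="always")
def _binom(n, p, rng):
    """Exact binomial sample; sums draws over <=64-sized chunks so the
    pmf(0) term cannot underflow, mirroring p > 1/2 through the complement.
    Distribution-identical to independent per-trial Bernoulli draws."""
    if n <= 0 or p <= 0.0:
        return 0
    if p >= 1.0:
        return n
    flip = p > 0.5
    pp = 1.0 - p if flip else p
    total = 0
    m = n
    while m > 64:
        total += _binom_small(64, pp, rng)
        m -= 64
    total += _binom_small(m, pp, rng)
    return (n - total) if flip else total


@njit(cache=True, inline="always")
def _ladder(n, R):
    if n <= 1:
        return R[0]
    if n == 2:
        return R[1]
    if n == 3:
        return R[2]
    return R[3]


@njit(cache=True, inline="always")
def _blocked(ch_chir, slot, m, end, no_term):
    if no_term or m < 2:
        return False
    if end == 0:
        return ch_chir[slot, 0] != ch_chir[slot, 1]
    return ch_chir[slot, m - 1] != ch_chir[slot, m - 2]


@njit(cache=True, inline="always")
def _room_remove(room_ids, room_n, r, objid):
    n = room_n[r]
    for i in range(n):
        if room_ids[r, i] == objid:
            room_ids[r, i] = room_ids[r, n - 1]
            room_n[r] = n - 1
            return


@njit(cache=True, inline="always")
def _room_add(room_ids, room_n, r, objid, tops):
    n = room_n[r]
    if n >= room_ids.shape[1]:
        tops[ERR] = 1
        return
    room_ids[r, n] = objid
    room_n[r] = n + 1


@njit(cache=True, inline="always")
def _pop_chain(ch_stack, tops):
    top = tops[TOP_CH]
    if top == 0:
        tops[ERR] = 1
        return -1
    tops[TOP_CH] = top - 1
    return ch_stack[top - 1]


@njit(cache=True, inline="always")
def _push_chain(ch_stack, tops, slot, ch_len, ch_free, ch_room):
    ch_len[slot] = 0
    ch_free[slot] = 0
    ch_room[slot] = -1
    ch_stack[tops[TOP_CH]] = slot
    tops[TOP_CH] = tops[TOP_CH] + 1


@njit(cache=True, inline="always")
def _release(slot, r, nuc, room_ids, room_n,
             ch_len, ch_room, ch_free, ch_base, ch_chir, ch_stack, tops):
    """A strand returns to the room as a free molecule; 1-mers collapse
    into the nucleotide pool (their canonical representation)."""
    m = ch_len[slot]
    if m == 1:
        nuc[r, ch_chir[slot, 0] * 4 + ch_base[slot, 0]] += 1
        _push_chain(ch_stack, tops, slot, ch_len, ch_free, ch_room)
    else:
        ch_free[slot] = 1
        ch_room[slot] = r
        _room_add(room_ids, room_n, r, slot * 2, tops)


@njit(cache=True, inline="always")
def _target_fits(objid, m, ch_len, cx_cap):
    # cx_cap caches each complex's larger free template run
    if objid & 1:
        return m <= cx_cap[objid >> 1]
    slot = objid >> 1
    return ch_len[slot] >= 2 and m <= ch_len[slot]


@njit(cache=True, inline="always")
def _try_ligate_cc(a, b, r, room_ids, room_n,
                   ch_len, ch_room, ch_free, ch_base, ch_chir, ch_stack, tops,
                   P_RL, F_CSS, RS, no_term, maxlen, rng):
    """Surface ligation attempt between two free chains; True on merge.

    The longer partner is the extender (ties broken at random); joining
    ends are chosen uniformly (directionless chains); a blocked extender
    end (cross-inhibition junction) forbids ligation.
    """
    la = ch_len[a]
    lb = ch_len[b]
    if la < lb or (la == lb and rng.random() < 0.5):
        a, b = b, a
        la, lb = lb, la
    ext_end = 0 if rng.random() < 0.5 else 1
    inc_end = 0 if rng.random() < 0.5 else 1
    if _blocked(ch_chir, a, la, ext_end, no_term):
        return False
    ec = ch_chir[a, 0] if ext_end == 0 else ch_chir[a, la - 1]
    ic = ch_chir[b, 0] if inc_end == 0 else ch_chir[b, lb - 1]
    rate = P_RL * _ladder(la, RS) * (1.0 if ec == ic else F_CSS)
    if rate > 1.0:
        rate = 1.0
    if rate <= 0.0 or rng.random() >= rate:
        return False
    if la + lb > maxlen:
        tops[ERR] = 1
        return False
    if ext_end == 1:
        if inc_end == 1:
            for i in range(lb):
                ch_base[a, la + i] = ch_base[b, lb - 1 - i]
                ch_chir[a, la + i] = ch_chir[b, lb - 1 - i]
        else:
            for i in range(lb):
                ch_base[a, la + i] = ch_base[b, i]
                ch_chir[a, la + i] = ch_chir[b, i]
    else:
        for i in range(la - 1, -1, -1):
            ch_base[a, i + lb] = ch_base[a, i]
            ch_chir[a, i + lb] = ch_chir[a, i]
        if inc_end == 0:
            for i in range(lb):
                ch_base[a, i] = ch_base[b, lb - 1 - i]
                ch_chir[a, i] = ch_chir[b, lb - 1 - i]
        else:
            for i in range(lb):
                ch_base[a, i] = ch_base[b, i]
                ch_chir[a, i] = ch_chir[b, i]
    ch_len[a] = la + lb
    _room_remove(room_ids, room_n, r, b * 2)
    _push_chain(ch_stack, tops, b, ch_len, ch_free, ch_room)
    return True


@njit(cache=True, inline="always")
def _try_ligate_cn(a, cat, ch_len, ch_base, ch_chir, tops,
                   P_RL, F_CSS, RS, no_term, maxlen, rng):
    """Surface ligation of a free nucleotide onto a chain; True consumes it."""
    la = ch_len[a]
    ext_end = 0 if rng.random() < 0.5 else 1
    rng.random()  # incomer end choice (monomers are end-symmetric)
    if _blocked(ch_chir, a, la, ext_end, no_term):
        return False
    ec = ch_chir[a, 0] if ext_end == 0 else ch_chir[a, la - 1]
    ic = cat >> 2
    rate = P_RL * _ladder(la, RS) * (1.0 if ec == ic else F_CSS)
    if rate > 1.0:
        rate = 1.0
    if rate <= 0.0 or rng.random() >= rate:
        return False
    if la + 1 > maxlen:
        tops[ERR] = 1
        return False
    if ext_end == 1:
        ch_base[a, la] = cat & 3
        ch_chir[a, la] = ic
    else:
        for i in range(la - 1, -1, -1):
            ch_base[a, i + 1] = ch_base[a, i]
            ch_chir[a, i + 1] = ch_chir[a, i]
        ch_base[a, 0] = cat & 3
        ch_chir[a, 0] = ic
    ch_len[a] = la + 1
    return True


@njit(cache=True, inline="always")
def _try_attract(target, sub_is_nuc, sub, r, room_ids, room_n,
                 ch_len, ch_room, ch_free, ch_base, ch_chir, ch_stack,
                 cx_tmpl, cx_room, cx_nat, cx_r, cx_cap, cx_att, cx_start,
                 cx_stack, tops, P_AT, P_FP, rng):
    """Attraction of a substrate (chain slot, or nucleotide category when
    ``sub_is_nuc``) onto a template (free chain or existing complex).

    Success probability is P_AT times P_FP per false pair.  The first
    substrate lands anywhere on a bare template; later substrates align
    contiguously beside the block on a uniformly chosen fitting side.
    Orientation of an oligomer substrate is random (directionless chains);
    handedness never gates attraction.  Returns True when the substrate was
    absorbed.  Capacity was checked by the caller.
    """
    u = rng.random()
    if u >= P_AT:
        return False
    m = 1 if sub_is_nuc else ch_len[sub]
    if target & 1:
        x = target >> 1
        t = cx_tmpl[x]
        nat = cx_nat[x]
        left = cx_start[x, 0]
        last_end = cx_start[x, nat - 1] + ch_len[cx_att[x, nat - 1]] - 1
        right = ch_len[t] - 1 - last_end
        fit_l = m <= left
        fit_r = m <= right
        if fit_l and fit_r:
            side_front = rng.random() < 0.5
        else:
            side_front = fit_l
        start = left - m if side_front else last_end + 1
    else:
        x = -1
        t = target >> 1
        side_front = False
        nstarts = ch_len[t] - m + 1
        start = int(rng.random() * nstarts)
        if start >= nstarts:
            start = nstarts - 1
    flip = False
    if m > 1 and rng.random() < 0.5:
        flip = True
    mism = 0
    for k in range(m):
        if sub_is_nuc:
            sb = sub & 3
        else:
            sb = ch_base[sub, m - 1 - k] if flip else ch_base[sub, k]
        if (ch_base[t, start + k] ^ 1) != sb:
            mism += 1
    if mism > 0:
        thr = P_AT
        for _ in range(mism):
            thr *= P_FP
        if u >= thr:
            return False
    # capacity checks before any state change
    if x < 0:
        if tops[TOP_CX] == 0:
            tops[ERR] = 1
            return False
    elif cx_nat[x] >= cx_att.shape[1]:
        tops[ERR] = 1
        return False
    if sub_is_nuc:
        s = _pop_chain(ch_stack, tops)
        if s < 0:
            return False
        ch_len[s] = 1
        ch_base[s, 0] = sub & 3
        ch_chir[s, 0] = sub >> 2
    else:
        s = sub
        if flip:
            for i in range(m // 2):
                b0 = ch_base[s, i]
                ch_base[s, i] = ch_base[s, m - 1 - i]
                ch_base[s, m - 1 - i] = b0
                c0 = ch_chir[s, i]
                ch_chir[s, i] = ch_chir[s, m - 1 - i]
                ch_chir[s, m - 1 - i] = c0
        _room_remove(room_ids, room_n, r, s * 2)
        ch_free[s] = 0
        ch_room[s] = -1
    if x < 0:
        top = tops[TOP_CX]
        tops[TOP_CX] = top - 1
        x = cx_stack[top - 1]
        cx_tmpl[x] = t
        cx_room[x] = r
        cx_nat[x] = 1
        cx_r[x] = m
        cx_att[x, 0] = s
        cx_start[x, 0] = start
        right_run = ch_len[t] - start - m
        cx_cap[x] = start if start > right_run else right_run
        ch_free[t] = 0
        ch_room[t] = -1
        _room_remove(room_ids, room_n, r, t * 2)
        _room_add(room_ids, room_n, r, x * 2 + 1, tops)
    else:
        nat = cx_nat[x]
        if side_front:
            for i in range(nat - 1, -1, -1):
                cx_att[x, i + 1] = cx_att[x, i]
                cx_start[x, i + 1] = cx_start[x, i]
            cx_att[x, 0] = s
            cx_start[x, 0] = start
        else:
            cx_att[x, nat] = s
            cx_start[x, nat] = start
        cx_nat[x] = nat + 1
        cx_r[x] = cx_r[x] + m
        if side_front:
            new_left = left - m
            cx_cap[x] = new_left if new_left > right else right
        else:
            new_right = right - m
            cx_cap[x] = left if left > new_right else new_right
    return True


@njit(cache=True, inline="always")
def _take_nucleotide(nuc, r, remk, rng):
    pick = int(rng.random() * remk)
    if pick >= remk:
        pick = remk - 1
    cum = 0
    for c in range(8):
        cum += nuc[r, c]
        if pick < cum:
            nuc[r, c] -= 1
            return c
    return -1


@njit(cache=True)
def _nuc_room_candidates(r, ncand, k, p_up, nuc, room_ids, room_n,
                         ch_len, ch_room, ch_free, ch_base, ch_chir, ch_stack,
                         tops, P_RL, F_CSS, RS, stash, rng):
    """Process ncand monomer-monomer ligation candidates in a room that
    holds only free nucleotides (thinning against the dominating rate
    P_RL*R1; composition revealed without replacement).  A fired
    candidate's dimer skips the remainder of the room-step, an O(p^2)
    truncation of the literal per-round process."""
    remk = k
    for _ in range(ncand):
        if remk < 2:
            break
        c1 = _take_nucleotide(nuc, r, remk, rng)
        remk -= 1
        c2 = _take_nucleotide(nuc, r, remk, rng)
        remk -= 1
        rate = P_RL * RS[0] * (1.0 if (c1 >> 2) == (c2 >> 2) else F_CSS)
        if rate > 1.0:
            rate = 1.0
        if rng.random() * p_up < rate:
            s = _pop_chain(ch_stack, tops)
            if s < 0:
                stash[c1] += 1
                stash[c2] += 1
                continue
            ch_len[s] = 2
            ch_base[s, 0] = c1 & 3
            ch_chir[s, 0] = c1 >> 2
            ch_base[s, 1] = c2 & 3
            ch_chir[s, 1] = c2 >> 2
            ch_free[s] = 1
            ch_room[s] = r
            _room_add(room_ids, room_n, r, s * 2, tops)
        else:
            stash[c1] += 1
            stash[c2] += 1
    for c in range(8):
        if stash[c] > 0:
            nuc[r, c] += stash[c]
            stash[c] = 0


@njit(cache=True)
def _room_rounds(r, C_T, nuc, room_ids, room_n,
                 ch_len, ch_room, ch_free, ch_base, ch_chir, ch_stack,
                 cx_tmpl, cx_room, cx_nat, cx_r, cx_cap, cx_att, cx_start,
                 cx_stack, tops, P_AT, P_FP, P_RL, F_CSS, RS, no_term, maxlen,
                 pool, pa, pb, pk, stash, rng):
    """C_T collision rounds in one room.

    Each round draws a uniform random pairwise grouping of the room's
    molecules (free chains, complexes, free nucleotides; an odd molecule
    idles) and every pair attempts one of the two collision outcomes.
    Nucleotide-nucleotide pairs are thinned against the dominating monomer
    ligation rate P_RL*R1 and their composition revealed on demand, which
    is distribution-exact by exchangeability of the uniform matching.
    """
    p_up = P_RL * RS[0]
    if p_up > 1.0:
        p_up = 1.0
    # feasibility: skip the rounds when no pair in this room could do
    # anything.  Events only remove possibilities within the step (fewer
    # molecules, less capacity), so an infeasible room stays infeasible.
    t0 = room_n[r]
    k0 = 0
    for c in range(8):
        k0 += nuc[r, c]
    if t0 + k0 < 2:
        return
    nch = 0
    min_chain = 1 << 30
    cap_mono = False
    max_cap = 0
    for i in range(t0):
        objid = room_ids[r, i]
        if (objid & 1) == 0:
            nch += 1
            if ch_len[objid >> 1] < min_chain:
                min_chain = ch_len[objid >> 1]
        else:
            cap0 = cx_cap[objid >> 1]
            if cap0 > max_cap:
                max_cap = cap0
            if cap0 >= 1:
                cap_mono = True
    feasible = False
    if P_RL > 0.0 and (k0 + nch) >= 2:
        feasible = True
    elif P_AT > 0.0:
        if nch >= 2:
            feasible = True
        elif nch >= 1 and k0 >= 1:
            feasible = True  # a chain (length >= 2) can template a monomer
        elif k0 >= 1 and cap_mono:
            feasible = True
        elif nch >= 1 and max_cap >= min_chain:
            feasible = True
    if not feasible:
        return
    for _round in range(C_T):
        t = room_n[r]
        k = 0
        for c in range(8):
            k += nuc[r, c]
        if t + k < 2:
            break
        for i in range(t):
            pool[i] = room_ids[r, i]
        npool = t
        remk = k
        phantom = 1 if ((t + k) & 1) == 1 else 0
        npairs = 0
        while npool > 0:
            a = pool[npool - 1]
            npool -= 1
            rem = npool + remk + phantom
            if rem == 0:
                break
            j = int(rng.random() * rem)
            if j >= rem:
                j = rem - 1
            if j < npool:
                pa[npairs] = a
                pb[npairs] = pool[j]
                pk[npairs] = 0
                pool[j] = pool[npool - 1]
                npool -= 1
                npairs += 1
            elif j < npool + remk:
                cat = _take_nucleotide(nuc, r, remk, rng)
                remk -= 1
                pa[npairs] = a
                pb[npairs] = cat
                pk[npairs] = 1
                npairs += 1
            else:
                phantom = 0
        for q in range(npairs):
            a = pa[q]
            if pk[q] == 1:
                cat = pb[q]
                a_chain = (a & 1) == 0
                can_attr = P_AT > 0.0 and _target_fits(a, 1, ch_len, cx_cap)
                can_lig = P_RL > 0.0 and a_chain
                if can_attr and can_lig:
                    if rng.random() < 0.5:
                        can_lig = False
                    else:
                        can_attr = False
                consumed = False
                if can_attr:
                    consumed = _try_attract(
                        a, True, cat, r, room_ids, room_n,
                        ch_len, ch_room, ch_free, ch_base, ch_chir, ch_stack,
                        cx_tmpl, cx_room, cx_nat, cx_r, cx_cap, cx_att,
                        cx_start, cx_stack, tops, P_AT, P_FP, rng)
                elif can_lig:
                    consumed = _try_ligate_cn(
                        a >> 1, cat, ch_len, ch_base, ch_chir, tops,
                        P_RL, F_CSS, RS, no_term, maxlen, rng)
                if not consumed:
                    stash[cat] += 1
            else:
                b = pb[q]
                a_chain = (a & 1) == 0
                b_chain = (b & 1) == 0
                dir_ab = b_chain and _target_fits(a, ch_len[b >> 1], ch_len, cx_cap)
                dir_ba = a_chain and _target_fits(b, ch_len[a >> 1], ch_len, cx_cap)
                can_attr = P_AT > 0.0 and (dir_ab or dir_ba)
                can_lig = P_RL > 0.0 and a_chain and b_chain
                if can_attr and can_lig:
                    if rng.random() < 0.5:
                        can_lig = False
                    else:
                        can_attr = False
                if can_attr:
                    if dir_ab and dir_ba:
                        if rng.random() < 0.5:
                            target, sub = a, b
                        else:
                            target, sub = b, a
                    elif dir_ab:
                        target, sub = a, b
                    else:
                        target, sub = b, a
                    _try_attract(
                        target, False, sub >> 1, r, room_ids, room_n,
                        ch_len, ch_room, ch_free, ch_base, ch_chir, ch_stack,
                        cx_tmpl, cx_room, cx_nat, cx_r, cx_cap, cx_att,
                        cx_start, cx_stack, tops, P_AT, P_FP, rng)
                elif can_lig:
                    _try_ligate_cc(
                        a >> 1, b >> 1, r, room_ids, room_n,
                        ch_len, ch_room, ch_free, ch_base, ch_chir, ch_stack,
                        tops, P_RL, F_CSS, RS, no_term, maxlen, rng)
        if p_up > 0.0 and remk >= 2:
            ncand = _binom(remk // 2, p_up, rng)
            for _ in range(ncand):
                if remk < 2:
                    break
                c1 = _take_nucleotide(nuc, r, remk, rng)
                remk -= 1
                c2 = _take_nucleotide(nuc, r, remk, rng)
                remk -= 1
                rate = P_RL * RS[0] * (1.0 if (c1 >> 2) == (c2 >> 2) else F_CSS)
                if rate > 1.0:
                    rate = 1.0
                if rng.random() * p_up < rate:
                    s = _pop_chain(ch_stack, tops)
                    if s < 0:
                        stash[c1] += 1
                        stash[c2] += 1
                        continue
                    ch_len[s] = 2
                    ch_base[s, 0] = c1 & 3
                    ch_chir[s, 0] = c1 >> 2
                    ch_base[s, 1] = c2 & 3
                    ch_chir[s, 1] = c2 >> 2
                    ch_free[s] = 1
                    ch_room[s] = r
                    _room_add(room_ids, room_n, r, s * 2, tops)
                else:
                    stash[c1] += 1
                    stash[c2] += 1
        for c in range(8):
            if stash[c] > 0:
                nuc[r, c] += stash[c]
                stash[c] = 0


@njit(cache=True, inline="always")
def _junction_chirality(x, i, ch_len, ch_chir, cx_tmpl, cx_att, cx_start):
    """Shared handedness of both junction substrates and the covered
    template region, or -1 when any residue disagrees."""
    left = cx_att[x, i]
    right = cx_att[x, i + 1]
    c = ch_chir[left, 0] + np.int64(0)
    for k in range(ch_len[left]):
        if ch_chir[left, k] != c:
            return np.int64(-1)
    for k in range(ch_len[right]):
        if ch_chir[right, k] != c:
            return np.int64(-1)
    t = cx_tmpl[x]
    for p in range(cx_start[x, i], cx_start[x, i + 1] + ch_len[right]):
        if ch_chir[t, p] != c:
            return np.int64(-1)
    return c


@njit(cache=True)
def _complex_junctions(x, ch_len, ch_base, ch_chir, ch_stack, ch_free, ch_room,
                       cx_tmpl, cx_room, cx_nat, cx_r, cx_att, cx_start,
                       tops, rep_cred, P_TL, P_TLR, F_CST, RT, no_term,
                       maxlen, rng):
    """Ligation attempts at every junction between adjacent substrates of
    one complex.  The longer attachment is the growing chain (ties broken
    at random); a blocked growing end forbids ligation; ligated substrates
    merge into one attachment (they may then adjoin the next junction)."""
    i = 0
    while i < cx_nat[x] - 1:
        left = cx_att[x, i]
        right = cx_att[x, i + 1]
        if cx_start[x, i] + ch_len[left] != cx_start[x, i + 1]:
            i += 1
            continue
        ll = ch_len[left]
        lr = ch_len[right]
        if ll > lr:
            ext_is_left = True
        elif ll < lr:
            ext_is_left = False
        else:
            ext_is_left = rng.random() < 0.5
        ext = left if ext_is_left else right
        lext = ch_len[ext]
        ext_end = 1 if ext_is_left else 0
        if _blocked(ch_chir, ext, lext, ext_end, no_term):
            i += 1
            continue
        fired = False
        room = cx_room[x]
        c = _junction_chirality(x, i, ch_len, ch_chir, cx_tmpl, cx_att, cx_start)
        if P_TLR > 0.0 and c >= 0 and rep_cred[room, c] > 0:
            if rng.random() < P_TLR:
                rep_cred[room, c] -= 1
                tops[REP_USED] += 1
                fired = True
        else:
            inc = right if ext_is_left else left
            linc = ch_len[inc]
            ic = ch_chir[inc, 0] if ext_is_left else ch_chir[inc, linc - 1]
            ec = ch_chir[ext, lext - 1] if ext_is_left else ch_chir[ext, 0]
            t_pos = cx_start[x, i + 1] if ext_is_left else cx_start[x, i] + ll - 1
            tc = ch_chir[cx_tmpl[x], t_pos]
            same = ic == ec and ic == tc
            rate = P_TL * _ladder(lext, RT) * (1.0 if same else F_CST)
            if rate > 1.0:
                rate = 1.0
            if rate > 0.0 and rng.random() < rate:
                fired = True
        if fired:
            if ll + lr > maxlen:
                tops[ERR] = 1
                i += 1
                continue
            for kk in range(lr):
                ch_base[left, ll + kk] = ch_base[right, kk]
                ch_chir[left, ll + kk] = ch_chir[right, kk]
            ch_len[left] = ll + lr
            _push_chain(ch_stack, tops, right, ch_len, ch_free, ch_room)
            nat = cx_nat[x]
            for kk in range(i + 1, nat - 1):
                cx_att[x, kk] = cx_att[x, kk + 1]
                cx_start[x, kk] = cx_start[x, kk + 1]
            cx_nat[x] = nat - 1
            # stay at i: the merged block may adjoin the next substrate
        else:
            i += 1


@njit(cache=True)
def step_chemistry(prec, nuc, nsr_cred, rep_cred,
                   C_T, room_ids, room_n,
                   ch_len, ch_room, ch_free, ch_base, ch_chir, ch_stack,
                   cx_tmpl, cx_room, cx_nat, cx_r, cx_cap, cx_att, cx_start,
                   cx_stack, tops,
                   P_CIC, P_NF, P_NFR, P_ND,
                   P_AT, P_FP, P_RL, F_CSS, RS,
                   P_TL, P_TLR, F_CST, RT,
                   P_NDE, P_BB,
                   no_term, maxlen,
                   pool, pa, pb, pk, stash, sc_chains, sc_cov,
                   ev_x, ev_kind, ev_site,
                   rng):
    """Phases 2-6 of one Monte-Carlo step over the whole grid.

    Returns the number of complex-degradation events detected (recorded in
    ``ev_x`` / ``ev_kind`` / ``ev_site``; kind 0 = end decay with site the
    end index, kind 1 = template bond break with site the bond index).
    Those rare events are applied by the python layer before transport.
    """
    R = prec.shape[0]
    # ---- phase 2: precursor racemization
    for r in range(R):
        if P_CIC > 0.0:
            f0 = _binom(prec[r, 0], P_CIC, rng)
            f1 = _binom(prec[r, 1], P_CIC, rng)
            prec[r, 0] += f1 - f0
            prec[r, 1] += f0 - f1
    # ---- phase 2 (cont.): nucleotide formation
    any_cred = False
    if P_NFR > 0.0:
        for r in range(R):
            if nsr_cred[r, 0] > 0 or nsr_cred[r, 1] > 0:
                any_cred = True
                break
    if any_cred:
        # rooms with synthetase ribozymes: enzymatic channel while the
        # room's same-handed credits last, else the non-enzymatic rate
        for r in range(R):
            for s in range(2):
                n0 = prec[r, s]
                if n0 == 0:
                    continue
                cred = nsr_cred[r, s]
                made = 0
                if cred > 0:
                    for _ in range(n0):
                        if cred > 0:
                            if rng.random() < P_NFR:
                                b = int(rng.random() * 4)
                                if b > 3:
                                    b = 3
                                nuc[r, s * 4 + b] += 1
                                made += 1
                                cred -= 1
                                tops[NSR_USED] += 1
                        elif P_NF > 0.0 and rng.random() < P_NF:
                            b = int(rng.random() * 4)
                            if b > 3:
                                b = 3
                            nuc[r, s * 4 + b] += 1
                            made += 1
                elif P_NF > 0.0:
                    made = _binom(n0, P_NF, rng)
                    for _ in range(made):
                        b = int(rng.random() * 4)
                        if b > 3:
                            b = 3
                        nuc[r, s * 4 + b] += 1
                prec[r, s] -= made
    elif P_NF > 0.0:
        # no ribozymes anywhere: one global draw, then the formed
        # precursors selected without replacement (exact conditional of
        # the independent per-precursor trials)
        total = 0
        for r in range(R):
            total += prec[r, 0] + prec[r, 1]
        kf = _binom(total, P_NF, rng)
        for _ in range(kf):
            pick = int(rng.random() * total)
            if pick >= total:
                pick = total - 1
            cum = 0
            for r in range(R):
                done_cell = False
                for s in range(2):
                    cum += prec[r, s]
                    if pick < cum:
                        prec[r, s] -= 1
                        b = int(rng.random() * 4)
                        if b > 3:
                            b = 3
                        nuc[r, s * 4 + b] += 1
                        done_cell = True
                        break
                if done_cell:
                    break
            total -= 1
    # ---- phase 3: free nucleotide decay (global draw, same construction)
    if P_ND > 0.0:
        total = 0
        for r in range(R):
            for c in range(8):
                total += nuc[r, c]
        kd = _binom(total, P_ND, rng)
        for _ in range(kd):
            pick = int(rng.random() * total)
            if pick >= total:
                pick = total - 1
            cum = 0
            done_cell = False
            for r in range(R):
                for c in range(8):
                    cum += nuc[r, c]
                    if pick < cum:
                        nuc[r, c] -= 1
                        prec[r, c >> 2] += 1
                        done_cell = True
                        break
                if done_cell:
                    break
            total -= 1
    # ---- phase 4: collision rounds
    if P_AT > 0.0 or P_RL > 0.0:
        p_up0 = P_RL * RS[0]
        if p_up0 > 1.0:
            p_up0 = 1.0
        small_rate = p_up0 < 1e-3
        for r in range(R):
            if room_n[r] == 0 and small_rate:
                # nucleotide-only room at a small monomer ligation rate:
                # one aggregate candidate draw for all C_T rounds, so the
                # common no-object room costs a few nanoseconds
                if p_up0 <= 0.0:
                    continue
                k = 0
                for c in range(8):
                    k += nuc[r, c]
                if k < 2:
                    continue
                ncand = _binom(C_T * (k // 2), p_up0, rng)
                if ncand > 0:
                    _nuc_room_candidates(
                        r, ncand, k, p_up0, nuc, room_ids, room_n,
                        ch_len, ch_room, ch_free, ch_base, ch_chir, ch_stack,
                        tops, P_RL, F_CSS, RS, stash, rng)
                continue
            _room_rounds(r, C_T, nuc, room_ids, room_n,
                         ch_len, ch_room, ch_free, ch_base, ch_chir, ch_stack,
                         cx_tmpl, cx_room, cx_nat, cx_r, cx_cap, cx_att,
                         cx_start, cx_stack, tops, P_AT, P_FP, P_RL, F_CSS, RS,
                         no_term, maxlen, pool, pa, pb, pk, stash, rng)
    # ---- phase 5: template-directed ligation
    if P_TL > 0.0 or P_TLR > 0.0:
        for x in range(cx_tmpl.shape[0]):
            if cx_tmpl[x] >= 0 and cx_nat[x] > 1:
                _complex_junctions(x, ch_len, ch_base, ch_chir, ch_stack,
                                   ch_free, ch_room,
                                   cx_tmpl, cx_room, cx_nat, cx_r, cx_att,
                                   cx_start, tops, rep_cred,
                                   P_TL, P_TLR, F_CST, RT, no_term,
                                   maxlen, rng)
    # ---- phase 6a: degradation of free chains (end decay, bond breaking)
    if P_NDE > 0.0 or P_BB > 0.0:
        nfree = 0
        for slot in range(ch_free.shape[0]):
            if ch_free[slot] == 1:
                sc_chains[nfree] = slot
                nfree += 1
        ndefer = 0
        for ii in range(nfree):
            slot = sc_chains[ii]
            m = ch_len[slot]
            r = ch_room[slot]
            e0 = False
            e1 = False
            if P_NDE > 0.0:
                ke = _binom(2, P_NDE, rng)
                if ke == 2:
                    e0 = e1 = True
                elif ke == 1:
                    if rng.random() < 0.5:
                        e0 = True
                    else:
                        e1 = True
            lo = 1 if e0 else 0
            hi = m - 1 if e1 else m
            if e0:
                prec[r, ch_chir[slot, 0]] += 1
            if e1:
                prec[r, ch_chir[slot, m - 1]] += 1
            ncuts = 0
            if P_BB > 0.0 and hi - lo > 1:
                nb = hi - lo - 1
                kb = _binom(nb, P_BB, rng)
                while ncuts < kb:
                    # distinct bond indices (absolute: cut after residue q)
                    q = lo + int(rng.random() * nb)
                    if q >= lo + nb:
                        q = lo + nb - 1
                    dup = False
                    for ci in range(ncuts):
                        if sc_cov[ci] == q:
                            dup = True
                            break
                    if dup:
                        continue
                    # insert sorted
                    pos = ncuts
                    while pos > 0 and sc_cov[pos - 1] > q:
                        sc_cov[pos] = sc_cov[pos - 1]
                        pos -= 1
                    sc_cov[pos] = q
                    ncuts += 1
            if not e0 and not e1 and ncuts == 0:
                continue
            _room_remove(room_ids, room_n, r, slot * 2)
            seg_lo = lo
            for ci in range(ncuts + 1):
                seg_hi = (sc_cov[ci] + 1) if ci < ncuts else hi
                seg = seg_hi - seg_lo
                if seg == 1:
                    nuc[r, ch_chir[slot, seg_lo] * 4 + ch_base[slot, seg_lo]] += 1
                elif seg > 1:
                    s2 = _pop_chain(ch_stack, tops)
                    if s2 < 0:
                        break
                    for kk in range(seg):
                        ch_base[s2, kk] = ch_base[slot, seg_lo + kk]
                        ch_chir[s2, kk] = ch_chir[slot, seg_lo + kk]
                    ch_len[s2] = seg
                    ch_free[s2] = 1
                    ch_room[s2] = r
                    _room_add(room_ids, room_n, r, s2 * 2, tops)
                seg_lo = seg_hi
            # defer freeing the original slot so it cannot be re-scanned
            ch_free[slot] = 2
            sc_chains[nfree + ndefer] = slot
            ndefer += 1
        for ii in range(ndefer):
            _push_chain(ch_stack, tops, sc_chains[nfree + ii],
                        ch_len, ch_free, ch_room)
    # ---- phase 6b: detect degradation events on complexes
    nev = 0
    if P_NDE > 0.0 or P_BB > 0.0:
        p_pe = P_NDE ** 1.5
        p_db = P_BB ** 1.5
        for x in range(cx_tmpl.shape[0]):
            t = cx_tmpl[x]
            if t < 0:
                continue
            L = ch_len[t]
            nat = cx_nat[x]
            last_end = cx_start[x, nat - 1] + ch_len[cx_att[x, nat - 1]] - 1
            if P_NDE > 0.0:
                prob0 = p_pe if cx_start[x, 0] == 0 else P_NDE
                if rng.random() < prob0 and nev < EV_CAP:
                    ev_x[nev] = x
                    ev_kind[nev] = 0
                    ev_site[nev] = 0
                    nev += 1
                if L > 1:
                    prob1 = p_pe if last_end == L - 1 else P_NDE
                    if rng.random() < prob1 and nev < EV_CAP:
                        ev_x[nev] = x
                        ev_kind[nev] = 0
                        ev_site[nev] = 1
                        nev += 1
            if P_BB > 0.0 and L > 1:
                # duplex bonds sit inside a single attachment: there are
                # r - nat of them; the remaining template bonds are
                # single-stranded
                nd = cx_r[x] - nat
                ns = (L - 1) - nd
                kd = _binom(nd, p_db, rng)
                ks = _binom(ns, P_BB, rng)
                if kd > 0 or ks > 0:
                    for p in range(L):
                        sc_cov[p] = 0
                    for i in range(nat):
                        a = cx_att[x, i]
                        s0 = cx_start[x, i]
                        for p in range(s0, s0 + ch_len[a]):
                            sc_cov[p] = i + 1
                    # enumerate and select among sites of each kind
                    for kind_dup in (True, False):
                        want = kd if kind_dup else ks
                        if want == 0:
                            continue
                        nsite = 0
                        for s in range(L - 1):
                            dup = sc_cov[s] != 0 and sc_cov[s] == sc_cov[s + 1]
                            if dup == kind_dup:
                                nsite += 1
                        take = want if want < nsite else nsite
                        # reservoir-free pick: walk sites, keep `take` of them
                        left = nsite
                        need = take
                        for s in range(L - 1):
                            if need == 0:
                                break
                            dup = sc_cov[s] != 0 and sc_cov[s] == sc_cov[s + 1]
                            if dup != kind_dup:
                                continue
                            if rng.random() * left < need:
                                if nev < EV_CAP:
                                    ev_x[nev] = x
                                    ev_kind[nev] = 1
                                    ev_site[nev] = s
                                    nev += 1
                                need -= 1
                            left -= 1
    return nev


@njit(cache=True)
def step_transport(prec, nuc, room_ids, room_n,
                   ch_len, ch_room, ch_free, ch_base, ch_chir, ch_stack,
                   cx_tmpl, cx_room, cx_nat, cx_r, cx_cap, cx_att, cx_start,
                   cx_stack, tops, P_SP, P_MPN, P_MN, psep_tab, pmove_tab,
                   neigh, dp, dn, sc_src, rng):
    """Phases 7-8: duplex separation, then movement.

    Separation dissolves a complex with probability P_SP^((r+1)/2) (r base
    pairs), freeing template and substrates into the room.  Movement is a
    per-molecule Bernoulli hop to a uniformly chosen adjacent room:
    precursors at P_MPN, nucleotides at P_MN, an m-residue chain at
    P_MN/sqrt(m), and a complex as one unit with m its total residue count.
    """
    R = prec.shape[0]
    ndir = neigh.shape[1]
    if P_SP > 0.0:
        for x in range(cx_tmpl.shape[0]):
            if cx_tmpl[x] < 0:
                continue
            if rng.random() < psep_tab[cx_r[x]]:
                r = cx_room[x]
                _room_remove(room_ids, room_n, r, x * 2 + 1)
                _release(cx_tmpl[x], r, nuc, room_ids, room_n,
                         ch_len, ch_room, ch_free, ch_base, ch_chir,
                         ch_stack, tops)
                for i in range(cx_nat[x]):
                    _release(cx_att[x, i], r, nuc, room_ids, room_n,
                             ch_len, ch_room, ch_free, ch_base, ch_chir,
                             ch_stack, tops)
                cx_tmpl[x] = -1
                cx_room[x] = -1
                cx_nat[x] = 0
                cx_r[x] = 0
                cx_stack[tops[TOP_CX]] = x
                tops[TOP_CX] = tops[TOP_CX] + 1
    for r in range(R):
        for s in range(2):
            dp[r, s] = 0
        for c in range(8):
            dn[r, c] = 0
    # Counter movement: one global binomial per species, movers then chosen
    # without replacement (exact conditional of per-molecule Bernoulli
    # trials); destination increments are deferred so the selection walk
    # sees only remaining molecules.
    if P_MPN > 0.0:
        total = 0
        for r in range(R):
            total += prec[r, 0] + prec[r, 1]
        k = _binom(total, P_MPN, rng)
        if k > sc_src.shape[0]:
            k = sc_src.shape[0]
        for i in range(k):
            pick = int(rng.random() * total)
            if pick >= total:
                pick = total - 1
            cum = 0
            done_cell = False
            for r in range(R):
                for s in range(2):
                    cum += prec[r, s] + dp[r, s]
                    if pick < cum:
                        dp[r, s] -= 1
                        sc_src[i] = r * 2 + s
                        done_cell = True
                        break
                if done_cell:
                    break
            total -= 1
        for i in range(k):
            r = sc_src[i] // 2
            s = sc_src[i] % 2
            d = int(rng.random() * ndir)
            if d >= ndir:
                d = ndir - 1
            dp[neigh[r, d], s] += 1
    if P_MN > 0.0:
        total = 0
        for r in range(R):
            for c in range(8):
                total += nuc[r, c]
        k = _binom(total, P_MN, rng)
        if k > sc_src.shape[0]:
            k = sc_src.shape[0]
        for i in range(k):
            pick = int(rng.random() * total)
            if pick >= total:
                pick = total - 1
            cum = 0
            done_cell = False
            for r in range(R):
                for c in range(8):
                    cum += nuc[r, c] + dn[r, c]
                    if pick < cum:
                        dn[r, c] -= 1
                        sc_src[i] = r * 8 + c
                        done_cell = True
                        break
                if done_cell:
                    break
            total -= 1
        for i in range(k):
            r = sc_src[i] // 8
            c = sc_src[i] % 8
            d = int(rng.random() * ndir)
            if d >= ndir:
                d = ndir - 1
            dn[neigh[r, d], c] += 1
    for r in range(R):
        for s in range(2):
            prec[r, s] += dp[r, s]
        for c in range(8):
            nuc[r, c] += dn[r, c]
    if P_MN > 0.0:
        for slot in range(ch_free.shape[0]):
            if ch_free[slot] != 1:
                continue
            if rng.random() < pmove_tab[ch_len[slot]]:
                d = int(rng.random() * ndir)
                if d >= ndir:
                    d = ndir - 1
                r = ch_room[slot]
                dest = neigh[r, d]
                _room_remove(room_ids, room_n, r, slot * 2)
                _room_add(room_ids, room_n, dest, slot * 2, tops)
                ch_room[slot] = dest
        for x in range(cx_tmpl.shape[0]):
            if cx_tmpl[x] < 0:
                continue
            mass = ch_len[cx_tmpl[x]] + cx_r[x]
            if rng.random() < pmove_tab[mass]:
                d = int(rng.random() * ndir)
                if d >= ndir:
                    d = ndir - 1
                r = cx_room[x]
                dest = neigh[r, d]
                _room_remove(room_ids, room_n, r, x * 2 + 1)
                _room_add(room_ids, room_n, dest, x * 2 + 1, tops)
                cx_room[x] = dest


@njit(cache=True)
def run_steps(nsteps, prec, nuc, nsr_cred, rep_cred,
              C_T, room_ids, room_n,
              ch_len, ch_room, ch_free, ch_base, ch_chir, ch_stack,
              cx_tmpl, cx_room, cx_nat, cx_r, cx_cap, cx_att, cx_start,
              cx_stack, tops,
              P_CIC, P_NF, P_NFR, P_ND,
              P_AT, P_FP, P_RL, F_CSS, RS,
              P_TL, P_TLR, F_CST, RT,
              P_NDE, P_BB,
              no_term, maxlen,
              pool, pa, pb, pk, stash, sc_chains, sc_cov,
              ev_x, ev_kind, ev_site,
              P_SP, P_MPN, P_MN, psep_tab, pmove_tab, neigh, dp, dn,
              rng):
    """Drive up to ``nsteps`` whole steps inside the compiled code.

    Returns (completed_steps, pending_events): when a step detects
    complex-degradation events it stops after phase 6 and hands control
    back so the python layer can apply them and finish the step's
    transport; likewise on a capacity error.  Used only when no ribozyme
    census is needed (the census runs in python each step otherwise).
    """
    done = 0
    while done < nsteps:
        nev = step_chemistry(
            prec, nuc, nsr_cred, rep_cred, C_T, room_ids, room_n,
            ch_len, ch_room, ch_free, ch_base, ch_chir, ch_stack,
            cx_tmpl, cx_room, cx_nat, cx_r, cx_cap, cx_att, cx_start,
            cx_stack, tops, P_CIC, P_NF, P_NFR, P_ND, P_AT, P_FP, P_RL,
            F_CSS, RS, P_TL, P_TLR, F_CST, RT, P_NDE, P_BB, no_term, maxlen,
            pool, pa, pb, pk, stash, sc_chains, sc_cov,
            ev_x, ev_kind, ev_site, rng)
        if nev > 0 or tops[ERR] != 0:
            return done, nev
        step_transport(
            prec, nuc, room_ids, room_n,
            ch_len, ch_room, ch_free, ch_base, ch_chir, ch_stack,
            cx_tmpl, cx_room, cx_nat, cx_r, cx_cap, cx_att, cx_start,
            cx_stack, tops, P_SP, P_MPN, P_MN, psep_tab, pmove_tab,
            neigh, dp, dn, pa, rng)
        done += 1
        if tops[ERR] != 0:
            return done, 0
    return done, 0
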