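"""Array-backed simulation state.

The engine keeps the whole system in flat numpy arrays so that the hot
phases (collision rounds, template ligation) can run in compiled kernels:

* precursors and free nucleotides are per-room counters (``prec[r, c]``,
  ``nuc[r, c * 4 + b]`` with ``c`` the chirality slot and ``b`` the base);
* RNA strands live in fixed-width rows of ``ch_base`` / ``ch_chir`` with a
  free-list of slots; a strand row is either a free chain (``ch_free == 1``,
  listed in its room), the template of a complex, or an attachment;
* template complexes reference strand slots through ``cx_tmpl`` /
  ``cx_att`` plus the attachment start positions on the template;
* every room keeps an id list of the objects it contains (chain ids are
  ``2 * slot``, complex ids ``2 * slot + 1``).

Free nucleotides are the canonical representation of 1-mer chains: helper
methods converting strands back to the pool collapse length-1 products into
the count arrays, so the two encodings never coexist.

``labels`` maps the two internal chirality slots to the D/L labels.  The
dynamics never read it — parameters are handedness-symmetric — which makes
a mirrored run (flipped labels, mirrored inoculations) consume the
identical random stream and produce the exactly negated ee trajectory.
"""

from __future__ import annotations

import numpy as np

from .core import Chirality, D, L, Params

__all__ = ["SystemState", "initialize", "ee_statistic", "MAXLEN"]

#: Hard cap on strand length in the engine arrays.  Unreachable in practice:
#: a chain of a few hundred residues carries enough breakable bonds that its
#: expected lifetime is far below the time needed to grow it.  Exceeding the
#: cap raises rather than silently altering the dynamics.
MAXLEN = 512
_MAXATT = 128
_MAXOBJ = 4096
_HEADROOM = 1024

# tops[] indices (shared mutable scalars for the kernels)
TOP_CH = 0      # number of entries on the chain free-list
TOP_CX = 1      # number of entries on the complex free-list
TOP_ERR = 2     # capacity-overflow flag set by kernels
TOP_REP_USED = 3  # REP ligations fired this step


class CapacityError(RuntimeError):
    pass


_NEIGH_OFFSETS = {
    "von_neumann": ((-1, 0), (1, 0), (0, -1), (0, 1)),
    "moore": ((-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1)),
}


class SystemState:
    __slots__ = (
        "params", "N", "R", "prec", "nuc",
        "ch_len", "ch_room", "ch_free", "ch_base", "ch_chir", "ch_stack",
        "cx_tmpl", "cx_room", "cx_nat", "cx_r", "cx_cap", "cx_att", "cx_start", "cx_stack",
        "room_ids", "room_n", "tops",
        "step", "rng", "labels", "injected_mass", "stats",
        "neigh", "zeros2", "dp", "dn",
        "sc_pool", "sc_pa", "sc_pb", "sc_pk", "sc_stash", "sc_chains", "sc_cov",
        "ev_x", "ev_kind", "ev_site",
    )

    def __init__(self, params: Params, rng: np.random.Generator,
                 labels: tuple[Chirality, Chirality] = (D, L)):
        N = params.N
        R = N * N
        self.params = params
        self.N = N
        self.R = R
        self.prec = np.zeros((R, 2), dtype=np.int64)
        self.nuc = np.zeros((R, 8), dtype=np.int64)
        maxc = params.T_NPB + _HEADROOM
        maxx = params.T_NPB // 2 + _HEADROOM
        self.ch_len = np.zeros(maxc, dtype=np.int32)
        self.ch_room = np.full(maxc, -1, dtype=np.int32)
        self.ch_free = np.zeros(maxc, dtype=np.uint8)
        self.ch_base = np.zeros((maxc, MAXLEN), dtype=np.uint8)
        self.ch_chir = np.zeros((maxc, MAXLEN), dtype=np.uint8)
        self.ch_stack = np.arange(maxc - 1, -1, -1, dtype=np.int32)
        self.cx_tmpl = np.full(maxx, -1, dtype=np.int32)
        self.cx_room = np.full(maxx, -1, dtype=np.int32)
        self.cx_nat = np.zeros(maxx, dtype=np.int32)
        self.cx_r = np.zeros(maxx, dtype=np.int32)
        self.cx_cap = np.zeros(maxx, dtype=np.int32)
        self.cx_att = np.zeros((maxx, _MAXATT), dtype=np.int32)
        self.cx_start = np.zeros((maxx, _MAXATT), dtype=np.int32)
        self.cx_stack = np.arange(maxx - 1, -1, -1, dtype=np.int32)
        self.room_ids = np.zeros((R, _MAXOBJ), dtype=np.int32)
        self.room_n = np.zeros(R, dtype=np.int32)
        self.tops = np.zeros(8, dtype=np.int64)
        self.tops[TOP_CH] = maxc
        self.tops[TOP_CX] = maxx
        self.step = 0
        self.rng = rng
        self.labels = labels
        self.injected_mass = 0
        self.stats = {}
        # neighbor table for movement (toroidal wrap)
        offsets = _NEIGH_OFFSETS[params.neighborhood]
        self.neigh = np.empty((R, len(offsets)), dtype=np.int64)
        for r in range(R):
            i, j = divmod(r, N)
            for d, (di, dj) in enumerate(offsets):
                self.neigh[r, d] = ((i + di) % N) * N + (j + dj) % N
        # persistent kernel scratch
        self.zeros2 = np.zeros((R, 2), dtype=np.int64)
        self.dp = np.zeros((R, 2), dtype=np.int64)
        self.dn = np.zeros((R, 8), dtype=np.int64)
        self.sc_pool = np.empty(_MAXOBJ, dtype=np.int64)
        self.sc_pa = np.empty(_MAXOBJ, dtype=np.int64)
        self.sc_pb = np.empty(_MAXOBJ, dtype=np.int64)
        self.sc_pk = np.empty(_MAXOBJ, dtype=np.uint8)
        self.sc_stash = np.zeros(8, dtype=np.int64)
        self.sc_chains = np.empty(maxc, dtype=np.int64)
        self.sc_cov = np.empty(MAXLEN, dtype=np.int64)
        self.ev_x = np.empty(256, dtype=np.int64)
        self.ev_kind = np.empty(256, dtype=np.int64)
        self.ev_site = np.empty(256, dtype=np.int64)

    # ------------------------------------------------------------------
    # chirality label <-> internal slot
    def slot(self, chirality: Chirality) -> int:
        return self.labels.index(chirality)

    def label(self, slot: int) -> Chirality:
        return self.labels[slot]

    # ------------------------------------------------------------------
    # slot allocation
    def _pop_chain_slot(self) -> int:
        top = int(self.tops[TOP_CH])
        if top == 0:
            raise CapacityError("chain slot capacity exhausted")
        self.tops[TOP_CH] = top - 1
        return int(self.ch_stack[top - 1])

    def _push_chain_slot(self, slot: int) -> None:
        self.ch_len[slot] = 0
        self.ch_free[slot] = 0
        self.ch_room[slot] = -1
        top = int(self.tops[TOP_CH])
        self.ch_stack[top] = slot
        self.tops[TOP_CH] = top + 1

    def _pop_complex_slot(self) -> int:
        top = int(self.tops[TOP_CX])
        if top == 0:
            raise CapacityError("complex slot capacity exhausted")
        self.tops[TOP_CX] = top - 1
        return int(self.cx_stack[top - 1])

    def _push_complex_slot(self, x: int) -> None:
        self.cx_tmpl[x] = -1
        self.cx_room[x] = -1
        self.cx_nat[x] = 0
        self.cx_r[x] = 0
        self.cx_cap[x] = 0
        top = int(self.tops[TOP_CX])
        self.cx_stack[top] = x
        self.tops[TOP_CX] = top + 1

    # ------------------------------------------------------------------
    # room object lists
    def room_add(self, r: int, objid: int) -> None:
        n = int(self.room_n[r])
        if n >= _MAXOBJ:
            raise CapacityError("room object capacity exhausted")
        self.room_ids[r, n] = objid
        self.room_n[r] = n + 1

    def room_remove(self, r: int, objid: int) -> None:
        n = int(self.room_n[r])
        row = self.room_ids[r]
        for i in range(n):
            if row[i] == objid:
                row[i] = row[n - 1]
                self.room_n[r] = n - 1
                return
        raise KeyError(f"object {objid} not in room {r}")

    # ------------------------------------------------------------------
    # molecule constructors / destructors
    def alloc_strand(self, bases, chirs) -> int:
        """Write a residue run into a fresh strand slot (not room-listed)."""
        m = len(bases)
        if m > MAXLEN:
            raise CapacityError(f"strand longer than the {MAXLEN}-residue cap")
        slot = self._pop_chain_slot()
        self.ch_len[slot] = m
        self.ch_base[slot, :m] = np.frombuffer(bytes(bases), dtype=np.uint8)
        self.ch_chir[slot, :m] = np.frombuffer(bytes(chirs), dtype=np.uint8)
        return slot

    def add_free_chain(self, bases, chirs, r: int) -> int:
        """Place a molecule in a room: a chain object, or the nucleotide
        pool when it is a 1-mer.  Returns the chain slot or -1."""
        if len(bases) == 1:
            self.nuc[r, int(chirs[0]) * 4 + int(bases[0])] += 1
            return -1
        slot = self.alloc_strand(bases, chirs)
        self.ch_free[slot] = 1
        self.ch_room[slot] = r
        self.room_add(r, slot * 2)
        return slot

    def release_strand(self, slot: int, r: int) -> None:
        """Return a strand slot to the room as a free molecule
        (collapsing 1-mers into the nucleotide pool)."""
        m = int(self.ch_len[slot])
        if m == 1:
            self.nuc[r, int(self.ch_chir[slot, 0]) * 4 + int(self.ch_base[slot, 0])] += 1
            self._push_chain_slot(slot)
        else:
            self.ch_free[slot] = 1
            self.ch_room[slot] = r
            self.room_add(r, slot * 2)

    def remove_free_chain(self, slot: int) -> None:
        r = int(self.ch_room[slot])
        self.room_remove(r, slot * 2)
        self._push_chain_slot(slot)

    def dissolve_complex(self, x: int) -> None:
        """All strands of a complex become free molecules in its room."""
        r = int(self.cx_room[x])
        self.room_remove(r, x * 2 + 1)
        self.release_strand(int(self.cx_tmpl[x]), r)
        for i in range(int(self.cx_nat[x])):
            self.release_strand(int(self.cx_att[x, i]), r)
        self._push_complex_slot(x)

    # ------------------------------------------------------------------
    # aggregate queries
    def free_chain_slots(self) -> np.ndarray:
        return np.flatnonzero(self.ch_free)

    def complex_slots(self) -> np.ndarray:
        return np.flatnonzero(self.cx_tmpl >= 0)

    def complex_mass(self, x: int) -> int:
        return int(self.ch_len[self.cx_tmpl[x]]) + int(self.cx_r[x])

    def total_mass(self) -> int:
        """Nucleotide-equivalent mass across every species (conserved)."""
        strands = int(self.ch_len[self.ch_len > 0].sum())
        return int(self.prec.sum()) + int(self.nuc.sum()) + strands

    def slot_masses(self) -> tuple[int, int]:
        nuc2 = self.nuc.reshape(self.R, 2, 4)
        t0 = int(self.prec[:, 0].sum()) + int(nuc2[:, 0, :].sum())
        t1 = int(self.prec[:, 1].sum()) + int(nuc2[:, 1, :].sum())
        for slot in np.flatnonzero(self.ch_len):
            m = int(self.ch_len[slot])
            ones = int(np.count_nonzero(self.ch_chir[slot, :m]))
            t1 += ones
            t0 += m - ones
        return t0, t1

    def enantiomer_totals(self) -> tuple[int, int]:
        """(D, L) nucleotide-equivalent totals, label-resolved."""
        s0, s1 = self.slot_masses()
        return (s0, s1) if self.labels[0] is D else (s1, s0)

    # ------------------------------------------------------------------
    # rare-event mutations used by the python-side degradation phases
    def chain_end_decay(self, slot: int, decay_first: bool, decay_last: bool) -> None:
        """Terminal residues of a free chain decay into precursors."""
        r = int(self.ch_room[slot])
        m = int(self.ch_len[slot])
        keep_lo = 1 if decay_first else 0
        keep_hi = m - 1 if decay_last else m
        if decay_first:
            self.prec[r, int(self.ch_chir[slot, 0])] += 1
        if decay_last:
            self.prec[r, int(self.ch_chir[slot, m - 1])] += 1
        rest_b = bytes(self.ch_base[slot, keep_lo:keep_hi])
        rest_c = bytes(self.ch_chir[slot, keep_lo:keep_hi])
        self.room_remove(r, slot * 2)
        self._push_chain_slot(slot)
        if rest_b:
            self.add_free_chain(rest_b, rest_c, r)

    def split_chain(self, slot: int, bonds) -> None:
        """Break a free chain at the given bond indices (bond i joins
        residues i and i+1); fragments return to the room."""
        r = int(self.ch_room[slot])
        m = int(self.ch_len[slot])
        cuts = sorted(bonds)
        pieces = []
        lo = 0
        for b in cuts:
            pieces.append((lo, b + 1))
            lo = b + 1
        pieces.append((lo, m))
        base = bytes(self.ch_base[slot, :m])
        chir = bytes(self.ch_chir[slot, :m])
        self.room_remove(r, slot * 2)
        self._push_chain_slot(slot)
        for lo, hi in pieces:
            self.add_free_chain(base[lo:hi], chir[lo:hi], r)

    # ------------------------------------------------------------------
    # complex mutations (rare degradation events; clarity over speed)
    def _complex_data(self, x: int):
        t = int(self.cx_tmpl[x])
        lt = int(self.ch_len[t])
        t_b = bytes(self.ch_base[t, :lt])
        t_c = bytes(self.ch_chir[t, :lt])
        atts = []
        for i in range(int(self.cx_nat[x])):
            a = int(self.cx_att[x, i])
            m = int(self.ch_len[a])
            atts.append((int(self.cx_start[x, i]),
                         bytes(self.ch_base[a, :m]),
                         bytes(self.ch_chir[a, :m])))
        return t_b, t_c, atts

    def _discard_complex(self, x: int) -> int:
        """Free every slot of a complex (data must have been extracted)."""
        r = int(self.cx_room[x])
        self.room_remove(r, x * 2 + 1)
        self._push_chain_slot(int(self.cx_tmpl[x]))
        for i in range(int(self.cx_nat[x])):
            self._push_chain_slot(int(self.cx_att[x, i]))
        self._push_complex_slot(x)
        return r

    def build_complex(self, r: int, t_b, t_c, atts) -> int:
        """Assemble a complex from raw strand data; with no attachments the
        template simply returns to the room as a free molecule."""
        if not atts:
            self.add_free_chain(t_b, t_c, r)
            return -1
        t = self.alloc_strand(t_b, t_c)
        x = self._pop_complex_slot()
        self.cx_tmpl[x] = t
        self.cx_room[x] = r
        self.cx_nat[x] = len(atts)
        self.cx_r[x] = sum(len(b) for _, b, _ in atts)
        for i, (start, b, c) in enumerate(atts):
            self.cx_att[x, i] = self.alloc_strand(b, c)
            self.cx_start[x, i] = start
        first = atts[0][0]
        last_end = atts[-1][0] + len(atts[-1][1]) - 1
        self.cx_cap[x] = max(first, len(t_b) - 1 - last_end)
        self.room_add(r, x * 2 + 1)
        return x

    def complex_end_decay(self, x: int, side: int) -> None:
        """A template end residue decays; when an attachment terminus is
        base-paired to it, both partnered residues decay together."""
        t_b, t_c, atts = self._complex_data(x)
        r = self._discard_complex(x)
        pos = 0 if side == 0 else len(t_b) - 1
        self.prec[r, t_c[pos]] += 1
        paired = False
        if side == 0 and atts and atts[0][0] == 0:
            start, b, c = atts[0]
            self.prec[r, c[0]] += 1
            paired = True
            rest = (start + 1, b[1:], c[1:])
            atts = ([rest] if rest[1] else []) + atts[1:]
        elif side == 1 and atts:
            start, b, c = atts[-1]
            if start + len(b) == len(t_b):
                self.prec[r, c[-1]] += 1
                paired = True
                rest = (start, b[:-1], c[:-1])
                atts = atts[:-1] + ([rest] if rest[1] else [])
        del paired
        if side == 0:
            t_b, t_c = t_b[1:], t_c[1:]
            atts = [(s - 1, b, c) for s, b, c in atts]
        else:
            t_b, t_c = t_b[:-1], t_c[:-1]
        if t_b:
            self.build_complex(r, t_b, t_c, atts)
        else:
            for _, b, c in atts:
                self.add_free_chain(b, c, r)

    def complex_bond_break(self, x: int, s: int) -> None:
        """Break the template bond between positions s and s+1.  At a
        duplex site the covering attachment's parallel bond breaks too
        (the caller draws with the synergistic rate); elsewhere only the
        template strand is cut and the attachments follow their side."""
        t_b, t_c, atts = self._complex_data(x)
        r = self._discard_complex(x)
        left_atts, right_atts = [], []
        for start, b, c in atts:
            end = start + len(b) - 1
            if end <= s:
                left_atts.append((start, b, c))
            elif start >= s + 1:
                right_atts.append((start - (s + 1), b, c))
            else:  # attachment spans the bond: duplex site, cut it as well
                k = s - start + 1
                left_atts.append((start, b[:k], c[:k]))
                right_atts.append((0, b[k:], c[k:]))
        self.build_complex(r, t_b[:s + 1], t_c[:s + 1], left_atts)
        self.build_complex(r, t_b[s + 1:], t_c[s + 1:], right_atts)

    # ------------------------------------------------------------------
    # object-layer views (tests, snapshots)
    def chain_object(self, slot: int):
        from .core import RNAChain
        m = int(self.ch_len[slot])
        return RNAChain(bytes(self.ch_base[slot, :m]), bytes(self.ch_chir[slot, :m]))

    def complex_object(self, x: int):
        from .core import Attachment, TemplateComplex
        cx = TemplateComplex(self.chain_object(int(self.cx_tmpl[x])))
        for i in range(int(self.cx_nat[x])):
            cx.attachments.append(
                Attachment(int(self.cx_start[x, i]),
                           self.chain_object(int(self.cx_att[x, i]))))
        return cx


def initialize(params: Params, seed,
               labels: tuple[Chirality, Chirality] = (D, L)) -> SystemState:
    """Racemic initial state: T_NPB/2 precursors of each handedness, each
    placed in a uniformly random room.  With odd T_NPB the counts differ
    by one (documented rounding)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = SystemState(params, rng, labels)
    n0 = params.T_NPB // 2
    n1 = params.T_NPB - n0
    pvals = np.full(state.R, 1.0 / state.R)
    for s, count in ((0, n0), (1, n1)):
        state.prec[:, s] += rng.multinomial(count, pvals)
    return state


def ee_statistic(state: SystemState) -> float:
    """Enantiomeric excess (D - L) / (D + L) over all chiral material:
    precursors, free nucleotides and every chain residue, including the
    residues inside template complexes."""
    d, l = state.enantiomer_totals()
    if d + l == 0:
        raise ValueError("ee is undefined for an empty system")
    return (d - l) / (d + l)
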