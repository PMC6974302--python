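"""Monte-Carlo scheduler: per-step, per-room orchestration of all events.

Each step applies a fixed phase order to every room:

1. ribozyme census (per-room NSR/REP credits per handedness);
2. precursor events: racemization, then nucleotide formation (consuming
   NSR credits);
3. free-nucleotide decay;
4. C_T collision rounds (pairwise grouping; surface ligation or template
   attraction per the two-outcome collision rule);
5. template-directed ligation on all complexes (consuming REP credits);
6. degradation: chain-end decay, phosphodiester-bond breaking (free chains
   first, then template complexes);
7. duplex separation;
8. movement of precursors, nucleotides, chains and complexes.

Rates are per-step Bernoulli probabilities per eligible entity or site.
The heavy lifting runs in two compiled kernels (chemistry through
degradation, then separation and transport); the rare degradation events on
template complexes are applied between them by this layer without drawing
random numbers, so a run is bit-reproducible from its single seed.  Room
iteration order is fixed (row-major); all per-room randomness comes from
the RNG stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels as K
from .core import Chirality, D, L, Params, base_index
from .observables import Trajectory, record
from .state import MAXLEN, SystemState, initialize

__all__ = ["InoculationEvent", "RunConfig", "mirror_config", "step", "run"]

logger = logging.getLogger("chirosim")


@dataclass(frozen=True)
class InoculationEvent:
    """Scheduled injection of homochiral RNA molecules.

    ``sequence`` is a base string or ``"random"`` (uniform bases drawn at
    injection time).  Molecules are scattered over uniformly random rooms.
    """

    step: int
    count: int
    length: int
    chirality: Chirality = D
    sequence: str = "random"

    def __post_init__(self):
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.sequence != "random":
            for s in self.sequence:
                base_index(s)
            if len(self.sequence) != self.length:
                raise ValueError("length must equal len(sequence)")
        elif self.length < 1:
            raise ValueError("length must be >= 1")


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a run."""

    params: Params
    steps: int
    seed: int = 0
    inoculations: tuple = ()
    no_termination: bool = False
    record_every: int = 1000
    labels: tuple = (D, L)
    check_mass: bool = False

    def __post_init__(self):
        if self.steps < 0:
            raise ValueError("steps must be >= 0")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")
        if set(self.labels) != {D, L}:
            raise ValueError("labels must be a permutation of (D, L)")

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def mirror_config(config: RunConfig) -> RunConfig:
    """The mirrored experiment: every explicit handedness flipped.

    Internally the engine works on two symmetric chirality slots and the
    D/L labels are applied only at inoculation and observation, so the
    mirrored run consumes the identical random stream: its ee series is
    exactly the negation of the original's.
    """
    return config.replace(
        labels=(config.labels[1], config.labels[0]),
        inoculations=tuple(
            replace(ev, chirality=ev.chirality.mirror())
            for ev in config.inoculations
        ),
    )


def _census(state: SystemState, need_nsr: bool, need_rep: bool):
    """Count active ribozymes (free single-stranded chains only) per room
    and handedness slot; these are the per-step catalysis credits."""
    from .core import _find_uniform_match

    p = state.params
    nsr = np.zeros((state.R, 2), dtype=np.int64)
    rep = np.zeros((state.R, 2), dtype=np.int64)
    pats = []
    if need_nsr:
        pats.append((nsr, bytes(base_index(s) for s in p.CS_NSR)))
    if need_rep:
        pats.append((rep, bytes(base_index(s) for s in p.CS_REP)))
    for slot in state.free_chain_slots():
        m = int(state.ch_len[slot])
        b = state.ch_base[slot, :m].tobytes()
        c = state.ch_chir[slot, :m].tobytes()
        rb, rc = b[::-1], c[::-1]
        for out, pat in pats:
            if not len(pat) <= m <= 2 * len(pat):
                continue
            hit = _find_uniform_match(b, c, pat)
            if hit is not None:
                out[state.ch_room[slot], c[hit]] += 1
                continue
            hit = _find_uniform_match(rb, rc, pat)
            if hit is not None:
                out[state.ch_room[slot], rc[hit]] += 1
    return nsr, rep


def _apply_complex_events(state: SystemState, nev: int) -> None:
    """Apply the degradation events detected on complexes.

    At most one event per complex slot per step is honoured (a second event
    would refer to pre-event geometry); site bounds are re-validated.  Draws
    no random numbers.
    """
    touched = set()
    for i in range(nev):
        x = int(state.ev_x[i])
        if x in touched or state.cx_tmpl[x] < 0:
            continue
        L = int(state.ch_len[state.cx_tmpl[x]])
        kind = int(state.ev_kind[i])
        site = int(state.ev_site[i])
        if kind == 0:
            if site == 1 and L < 2:
                continue
            state.complex_end_decay(x, site)
        else:
            if site >= L - 1:
                continue
            state.complex_bond_break(x, site)
        touched.add(x)


def _check_err(state: SystemState) -> None:
    if state.tops[K.ERR]:
        raise RuntimeError(
            "engine capacity exceeded (strand length, attachments or room "
            "occupancy beyond compiled limits)")


def _step_impl(state: SystemState, config: RunConfig, rs_arr, rt_arr) -> None:
    p = state.params
    need_nsr = p.P_NFR > 0.0
    need_rep = p.P_TLR > 0.0
    if need_nsr or need_rep:
        nsr_cred, rep_cred = _census(state, need_nsr, need_rep)
        state.stats["nsr_census"] = int(nsr_cred.sum())
        state.stats["rep_census"] = int(rep_cred.sum())
    else:
        nsr_cred = rep_cred = state.zeros2
    state.tops[K.REP_USED] = 0
    state.tops[K.NSR_USED] = 0
    nev = K.step_chemistry(
        state.prec, state.nuc, nsr_cred, rep_cred,
        p.C_T, state.room_ids, state.room_n,
        state.ch_len, state.ch_room, state.ch_free, state.ch_base,
        state.ch_chir, state.ch_stack,
        state.cx_tmpl, state.cx_room, state.cx_nat, state.cx_r,
        state.cx_cap, state.cx_att, state.cx_start, state.cx_stack,
        state.tops,
        float(p.P_CIC), float(p.P_NF), float(p.P_NFR), float(p.P_ND),
        float(p.P_AT), float(p.P_FP), float(p.P_RL), float(p.F_CSS), rs_arr,
        float(p.P_TL), float(p.P_TLR), float(p.F_CST), rt_arr,
        float(p.P_NDE), float(p.P_BB),
        config.no_termination, MAXLEN,
        state.sc_pool, state.sc_pa, state.sc_pb, state.sc_pk, state.sc_stash,
        state.sc_chains, state.sc_cov,
        state.ev_x, state.ev_kind, state.ev_site,
        state.rng)
    _check_err(state)
    if need_nsr or need_rep:
        state.stats["nsr_used"] = int(state.tops[K.NSR_USED])
        state.stats["rep_used"] = int(state.tops[K.REP_USED])
    if nev:
        _apply_complex_events(state, nev)
    psep_tab, pmove_tab = _rate_tables(p)
    K.step_transport(
        state.prec, state.nuc, state.room_ids, state.room_n,
        state.ch_len, state.ch_room, state.ch_free, state.ch_base,
        state.ch_chir, state.ch_stack,
        state.cx_tmpl, state.cx_room, state.cx_nat, state.cx_r,
        state.cx_cap, state.cx_att, state.cx_start, state.cx_stack,
        state.tops, float(p.P_SP), float(p.P_MPN), float(p.P_MN),
        psep_tab, pmove_tab, state.neigh, state.dp, state.dn,
        state.sc_pa, state.rng)
    _check_err(state)
    state.step += 1


def step(state: SystemState, config: RunConfig) -> SystemState:
    """Advance the state by one Monte-Carlo step in place (and return it)."""
    p = state.params
    rs_arr = np.asarray(p.R_surface.as_tuple(), dtype=np.float64)
    rt_arr = np.asarray(p.R_template.as_tuple(), dtype=np.float64)
    _step_impl(state, config, rs_arr, rt_arr)
    return state


def _inoculate(state: SystemState, ev: InoculationEvent) -> None:
    rng = state.rng
    c = state.slot(ev.chirality)
    chirs = bytes([c]) * ev.length
    for _ in range(ev.count):
        if ev.sequence == "random":
            bases = bytes(int(x) for x in rng.integers(0, 4, size=ev.length))
        else:
            bases = bytes(base_index(s) for s in ev.sequence)
        room = int(rng.integers(0, state.R))
        state.add_free_chain(bases, chirs, room)
    state.injected_mass += ev.count * ev.length
    logger.info("step %d: inoculated %d %s-chains of length %d",
                state.step, ev.count, ev.chirality.name, ev.length)


def _rate_tables(p):
    """Precomputed per-size rates: duplex separation by base-pair count and
    movement by molecular mass (Zimm scaling)."""
    from .state import MAXLEN as _ML
    sizes = np.arange(2 * _ML + 1, dtype=np.float64)
    psep = p.P_SP ** ((sizes + 1.0) / 2.0) if p.P_SP > 0.0 else np.zeros_like(sizes)
    with np.errstate(divide="ignore"):
        pmove = np.where(sizes > 0, p.P_MN / np.sqrt(np.maximum(sizes, 1.0)), 0.0)
    return psep, pmove


def _run_chunk(state: SystemState, config: RunConfig, rs_arr, rt_arr, n: int) -> None:
    """Advance n steps through the compiled driver, returning to python
    only to apply the rare complex-degradation events mid-step."""
    p = state.params
    psep_tab, pmove_tab = _rate_tables(p)
    remaining = n
    while remaining > 0:
        done, nev = K.run_steps(
            remaining, state.prec, state.nuc, state.zeros2, state.zeros2,
            p.C_T, state.room_ids, state.room_n,
            state.ch_len, state.ch_room, state.ch_free, state.ch_base,
            state.ch_chir, state.ch_stack,
            state.cx_tmpl, state.cx_room, state.cx_nat, state.cx_r,
            state.cx_cap, state.cx_att, state.cx_start, state.cx_stack,
            state.tops,
            float(p.P_CIC), float(p.P_NF), float(p.P_NFR), float(p.P_ND),
            float(p.P_AT), float(p.P_FP), float(p.P_RL), float(p.F_CSS), rs_arr,
            float(p.P_TL), float(p.P_TLR), float(p.F_CST), rt_arr,
            float(p.P_NDE), float(p.P_BB),
            config.no_termination, MAXLEN,
            state.sc_pool, state.sc_pa, state.sc_pb, state.sc_pk,
            state.sc_stash, state.sc_chains, state.sc_cov,
            state.ev_x, state.ev_kind, state.ev_site,
            float(p.P_SP), float(p.P_MPN), float(p.P_MN),
            psep_tab, pmove_tab, state.neigh, state.dp, state.dn,
            state.rng)
        state.step += done
        remaining -= done
        _check_err(state)
        if nev > 0:
            _apply_complex_events(state, nev)
            K.step_transport(
                state.prec, state.nuc, state.room_ids, state.room_n,
                state.ch_len, state.ch_room, state.ch_free, state.ch_base,
                state.ch_chir, state.ch_stack,
                state.cx_tmpl, state.cx_room, state.cx_nat, state.cx_r,
                state.cx_cap, state.cx_att, state.cx_start, state.cx_stack,
                state.tops, float(p.P_SP), float(p.P_MPN), float(p.P_MN),
                psep_tab, pmove_tab, state.neigh, state.dp, state.dn,
                state.sc_pa, state.rng)
            _check_err(state)
            state.step += 1
            remaining -= 1


def run(config: RunConfig) -> Trajectory:
    """Execute a full run and return the recorded trajectory.

    Observables are recorded at step 0, every ``record_every`` steps, and at
    the final step.  Inoculations fire at the start of their scheduled step.
    """
    p = config.params
    for base_rate, ladder, name in ((p.P_RL, p.R_surface, "P_RL"),
                                    (p.P_TL, p.R_template, "P_TL")):
        if base_rate * max(ladder.as_tuple()) > 1.0:
            logger.warning("effective %s rate exceeds 1 and will be clamped", name)
    state = initialize(p, config.seed, config.labels)
    rs_arr = np.asarray(p.R_surface.as_tuple(), dtype=np.float64)
    rt_arr = np.asarray(p.R_template.as_tuple(), dtype=np.float64)
    pending = sorted(config.inoculations, key=lambda e: e.step)
    records = [record(state)]
    expected_mass = p.T_NPB
    # the per-step census (ribozymes) and mass audit need python control
    chunked = not (p.P_NFR > 0.0 or p.P_TLR > 0.0) and not config.check_mass
    while state.step < config.steps:
        while pending and pending[0].step == state.step:
            ev = pending.pop(0)
            _inoculate(state, ev)
            expected_mass += ev.count * ev.length
        target = min(config.steps,
                     (state.step // config.record_every + 1) * config.record_every)
        if pending and pending[0].step < target:
            target = pending[0].step
        if chunked:
            _run_chunk(state, config, rs_arr, rt_arr, target - state.step)
        else:
            for _ in range(target - state.step):
                _step_impl(state, config, rs_arr, rt_arr)
                if config.check_mass and state.total_mass() != expected_mass:
                    raise AssertionError(
                        f"mass not conserved at step {state.step}: "
                        f"{state.total_mass()} != {expected_mass}")
        if state.step % config.record_every == 0 or state.step == config.steps:
            records.append(record(state))
            logger.info("step %d: ee=%.4f", state.step, records[-1].ee)
    return Trajectory(records=records, config=config, final_state=state)
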