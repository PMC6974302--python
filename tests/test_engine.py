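"""Engine-level behaviour: scheduling, conservation, reproducibility,
mirror symmetry, collision-round accounting, catalysis credits."""

import numpy as np
import pytest

from chirosim.core import D, L, Params
from chirosim.engine import InoculationEvent, RunConfig, mirror_config, run, step
from chirosim.state import SystemState, initialize


def busy_config(**overrides):
    """Small grid with every event class active at inflated rates."""
    p = Params(N=4, T_NPB=400, P_RL=1e-3, P_TL=0.05, P_AT=0.5,
               P_NDE=1e-3, P_BB=1e-3, **overrides.pop("params", {}))
    defaults = dict(params=p, steps=1500, seed=11, record_every=100,
                    inoculations=(InoculationEvent(step=10, count=10, length=6),),
                    check_mass=True)
    defaults.update(overrides)
    return RunConfig(**defaults)


class TestConservationAndDeterminism:
    def test_mass_conserved_every_step(self):
        # run() audits nucleotide-equivalent mass after every step
        traj = run(busy_config())
        assert traj.final_state.total_mass() == 400 + 60

    def test_bit_identical_replay(self):
        cfg = busy_config(check_mass=False)
        a = run(cfg)
        b = run(cfg)
        assert np.array_equal(a.ee_series(), b.ee_series())
        for ra, rb in zip(a.records, b.records):
            assert ra == rb

    def test_chunked_driver_matches_stepwise(self):
        # the multi-step compiled driver and the python per-step path
        # consume the stream identically
        cfg = busy_config()
        a = run(cfg)                          # stepwise (mass audit on)
        b = run(cfg.replace(check_mass=False))  # chunked
        assert np.array_equal(a.ee_series(), b.ee_series())

    def test_seed_changes_trajectory_not_schedule(self):
        cfg = busy_config(check_mass=False)
        a = run(cfg)
        b = run(cfg.replace(seed=12))
        assert [r.step for r in a.records] == [r.step for r in b.records]
        assert not np.array_equal(a.ee_series(), b.ee_series())

    def test_zero_step_run_records_initial_state_only(self):
        cfg = RunConfig(params=Params(N=2, T_NPB=100), steps=0, seed=0)
        traj = run(cfg)
        assert len(traj.records) == 1 and traj.records[0].step == 0
        assert traj.records[0].ee == 0.0


class TestMirrorSymmetry:
    def test_mirrored_run_negates_ee_exactly(self):
        cfg = busy_config(check_mass=False)
        fwd = run(cfg)
        rev = run(mirror_config(cfg))
        assert np.array_equal(fwd.ee_series(), -rev.ee_series())

    def test_mirror_swaps_histograms(self):
        cfg = busy_config(check_mass=False)
        fwd = run(cfg).records[-1]
        rev = run(mirror_config(cfg)).records[-1]
        assert fwd.length_hist_D == rev.length_hist_L
        assert fwd.length_hist_L == rev.length_hist_D
        assert (fwd.D_total, fwd.L_total) == (rev.L_total, rev.D_total)


class TestCollisionRounds:
    @pytest.mark.parametrize("c_t,expected_len", [(8, 256), (4, 16)])
    def test_round_count_by_doubling_cascade(self, c_t, expected_len):
        """With certain ligation (P_RL=1) every round halves the molecule
        count, so 2^C_T monomers fuse into chains of exactly 2^C_T residues
        in one step: a direct count of the grouping rounds."""
        p = Params(N=1, T_NPB=256, C_T=c_t, P_RL=1.0, P_AT=0.0, F_CSS=1.0,
                   P_CIC=0.0, P_NF=0.0, P_ND=0.0, P_NDE=0.0, P_BB=0.0,
                   P_MN=0.0, P_MPN=0.0)
        state = SystemState(p, np.random.default_rng(5))
        state.nuc[0, 0] = 256  # 256 D-A monomers in the single room
        cfg = RunConfig(params=p, steps=1, seed=5)
        step(state, cfg)
        lens = sorted(int(v) for v in state.ch_len[state.ch_len > 0])
        assert lens == [expected_len] * (256 // expected_len)

    def test_no_events_when_both_routes_disabled(self):
        p = Params(N=2, T_NPB=50, P_RL=0.0, P_AT=0.0, P_CIC=0.0,
                   P_NF=0.0, P_ND=0.0, P_MPN=0.0, P_MN=0.0)
        state = initialize(p, seed=3)
        before = state.prec.copy()
        cfg = RunConfig(params=p, steps=1, seed=3)
        step(state, cfg)
        assert np.array_equal(state.prec, before)


class TestInoculation:
    def test_mass_jump_equals_inoculated_residues(self):
        # frozen dynamics: the only change is the injected 50 x 6 residues
        p = Params(N=5, T_NPB=2000, P_RL=0.0, P_AT=0.0, P_CIC=0.0,
                   P_NF=0.0, P_ND=0.0, P_NDE=0.0, P_BB=0.0,
                   P_MN=0.0, P_MPN=0.0)
        cfg = RunConfig(params=p, steps=4, seed=9, record_every=1,
                        inoculations=(InoculationEvent(step=2, count=50, length=6),))
        traj = run(cfg)
        # inoculation fires at the start of step 3 (the step taking the
        # counter from 2 to 3), so records 0..2 predate it
        diffs = [r.D_total - r.L_total for r in traj.records]
        assert diffs[:3] == [0, 0, 0]
        assert all(d == 300 for d in diffs[3:])
        assert traj.final_state.total_mass() == 2000 + 300

    def test_explicit_sequence_inoculation(self):
        p = Params(N=2, T_NPB=10, P_RL=0.0, P_AT=0.0, P_CIC=0.0,
                   P_NF=0.0, P_ND=0.0, P_NDE=0.0, P_BB=0.0,
                   P_MN=0.0, P_MPN=0.0)
        ev = InoculationEvent(step=0, count=3, length=6, chirality=L,
                              sequence="ACUGGC")
        traj = run(RunConfig(params=p, steps=1, seed=1, inoculations=(ev,)))
        st = traj.final_state
        seqs = [st.chain_object(int(s)).sequence() for s in st.free_chain_slots()]
        assert seqs == ["ACUGGC"] * 3
        assert traj.records[-1].nsr_L == 3  # they are active L synthetases

    def test_sequence_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            InoculationEvent(step=0, count=1, length=5, sequence="ACUGGC")


class TestCatalysisCredits:
    def test_nsr_usage_bounded_by_census(self):
        """Per room and step, catalysed formations never exceed the number
        of active same-handed synthetase ribozymes present."""
        p = Params(N=1, T_NPB=40, P_NFR=1.0, P_NF=0.0, P_CIC=0.0,
                   P_ND=0.0, P_RL=0.0, P_AT=0.0, P_NDE=0.0, P_BB=0.0,
                   P_MN=0.0, P_MPN=0.0)
        state = SystemState(p, np.random.default_rng(2))
        state.prec[0, 0] = 28  # D precursors
        # two active D synthetases (domain ACUGGC = indices 0,2,1,3,3,2)
        for _ in range(2):
            state.add_free_chain(bytes([0, 2, 1, 3, 3, 2]), bytes(6), 0)
        cfg = RunConfig(params=p, steps=1, seed=2)
        step(state, cfg)
        assert state.stats["nsr_census"] == 2
        assert state.stats["nsr_used"] == 2  # P_NFR = 1: both credits spent
        assert int(state.nuc[0, 0:4].sum()) == 2
        assert int(state.prec[0, 0]) == 26

    def test_enzymatic_channel_replaces_nonenzymatic(self):
        # with a synthetase present but P_NFR failing, precursors do NOT
        # fall back to the non-enzymatic rate in that room
        p = Params(N=1, T_NPB=40, P_NFR=1e-9, P_NF=1.0, P_CIC=0.0,
                   P_ND=0.0, P_RL=0.0, P_AT=0.0, P_NDE=0.0, P_BB=0.0,
                   P_MN=0.0, P_MPN=0.0)
        state = SystemState(p, np.random.default_rng(4))
        state.prec[0, 0] = 20
        state.prec[0, 1] = 14
        state.add_free_chain(bytes([0, 2, 1, 3, 3, 2]), bytes(6), 0)  # D NSR
        cfg = RunConfig(params=p, steps=1, seed=4)
        step(state, cfg)
        # D precursors saw only the (failing) enzymatic channel; L precursors
        # all formed nucleotides non-enzymatically
        assert int(state.prec[0, 0]) == 20
        assert int(state.prec[0, 1]) == 0
        assert int(state.nuc[0, 4:8].sum()) == 14

    def test_rep_usage_bounded_by_census(self):
        p = Params(N=1, T_NPB=60, P_TLR=1.0, P_TL=0.0, P_AT=1.0,
                   P_CIC=0.0, P_NF=0.0, P_ND=0.0, P_NDE=0.0, P_BB=0.0,
                   P_MN=0.0, P_MPN=0.0, P_SP=0.0, P_RL=0.0)
        state = SystemState(p, np.random.default_rng(8))
        # one active D replicase (GUUCAG = 3,1,1,2,0,3)
        state.add_free_chain(bytes([3, 1, 1, 2, 0, 3]), bytes(6), 0)
        # three complexes, each with a ligatable all-D junction
        for _ in range(3):
            t = state.alloc_strand(bytes([0] * 6), bytes(6))
            x = state.build_complex(0, bytes(state.ch_base[t, :6]), bytes(6), [
                (0, bytes([1, 1, 1]), bytes(3)),
                (3, bytes([1, 1]), bytes(2)),
            ])
            state._push_chain_slot(t)
        cfg = RunConfig(params=p, steps=1, seed=8)
        step(state, cfg)
        assert state.stats["rep_census"] == 1
        assert state.stats["rep_used"] == 1  # only one credit available
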