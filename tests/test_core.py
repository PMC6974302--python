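"""Domain types: chirality, chains, parameters, ee, ribozyme recognition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chirosim.core import (
    Chirality,
    D,
    L,
    Params,
    P_NFR_ACTIVE,
    P_TLR_ACTIVE,
    PrimerLadder,
    RNAChain,
    complement,
    detect_ribozyme,
    mirror_chain,
)
from chirosim.state import SystemState, ee_statistic, initialize

from conftest import empty_state


class TestChirality:
    def test_two_values_and_mirror_involution(self):
        assert set(Chirality) == {D, L}
        assert D.mirror() is L and L.mirror() is D
        for c in Chirality:
            assert c.mirror().mirror() is c

    def test_complement_pairs(self):
        # A-U and C-G pairing, involutive
        for b in range(4):
            assert complement(complement(b)) == b
        assert complement(0) == 1 and complement(2) == 3


class TestParams:
    def test_printed_defaults(self):
        p = Params()
        assert p.P_AT == 0.5
        assert p.P_BB == 1e-5
        assert p.P_CIC == 0.5
        assert p.P_FP == 0.001
        assert p.P_MN == 1e-4
        assert p.P_MPN == 0.002
        assert p.P_ND == 0.01
        assert p.P_NDE == 1e-4
        assert p.P_NF == 0.001
        assert p.P_RL == 2e-6
        assert p.P_SP == 0.3
        assert p.P_TL == 0.002
        assert (p.N, p.T_NPB, p.C_T) == (20, 50000, 8)
        assert (p.F_CSS, p.F_CST) == (0.5, 0.5)
        assert p.CS_REP == "GUUCAG" and p.CS_NSR == "ACUGGC"

    def test_ribozyme_rates_zero_unless_enabled(self):
        # the catalytic rates apply only in scenarios modelling the ribozyme
        p = Params()
        assert p.P_NFR == 0.0 and p.P_TLR == 0.0
        assert (P_NFR_ACTIVE, P_TLR_ACTIVE) == (0.2, 0.9)

    @pytest.mark.parametrize("bad", [
        dict(P_AT=1.5), dict(P_CIC=-0.1), dict(N=0), dict(T_NPB=0),
        dict(CS_NSR="ACUGGX"), dict(neighborhood="hex"),
    ])
    def test_validation(self, bad):
        with pytest.raises(ValueError):
            Params(**bad)


class TestPrimerLadder:
    def test_length_classes(self):
        lad = PrimerLadder(1, 10, 200, 200)
        assert lad.rate(1) == 1 and lad.rate(2) == 10
        assert lad.rate(3) == 200
        # Rn applies to every length above three
        assert lad.rate(4) == lad.rate(17) == 200

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError):
            PrimerLadder(-1, 1, 1, 1)


class TestRNAChain:
    def test_from_string_and_roundtrip(self):
        ch = RNAChain.from_string("ACUGGC", D)
        assert len(ch) == 6 and ch.sequence() == "ACUGGC"
        assert ch.is_homochiral()

    def test_mirror_involution(self):
        ch = RNAChain.from_string("AUC", [D, L, D])
        assert mirror_chain(mirror_chain(ch)).residues() == ch.residues()
        assert [c for _, c in mirror_chain(ch).residues()] == [L, D, L]

    def test_length_at_least_one(self):
        with pytest.raises(ValueError):
            RNAChain(b"", b"")


class TestInitialize:
    def test_racemic_split(self):
        p = Params(N=5, T_NPB=50000)
        state = initialize(p, seed=1)
        assert int(state.prec[:, 0].sum()) == 25000
        assert int(state.prec[:, 1].sum()) == 25000
        assert ee_statistic(state) == 0.0

    def test_tiny_symmetric(self):
        state = initialize(Params(N=1, T_NPB=2), seed=0)
        assert tuple(state.prec[0]) == (1, 1)
        assert ee_statistic(state) == 0.0

    def test_same_seed_identical(self):
        p = Params(N=4, T_NPB=1000)
        a = initialize(p, seed=7)
        b = initialize(p, seed=7)
        assert np.array_equal(a.prec, b.prec)

    def test_invalid_configuration(self):
        with pytest.raises(ValueError):
            Params(N=-2)


class TestEeStatistic:
    def test_limits_and_formula(self, params):
        p = Params(N=2, T_NPB=100)
        st_ = empty_state(p)
        st_.prec[0, 0] = 30
        st_.prec[1, 1] = 10
        assert ee_statistic(st_) == pytest.approx(0.5)
        st_.prec[1, 1] = 0
        assert ee_statistic(st_) == 1.0

    def test_counts_residues_inside_complexes(self):
        p = Params(N=2, T_NPB=100)
        st_ = empty_state(p)
        t = st_.add_free_chain(b"\x00\x01\x02", b"\x00\x00\x00", 0)  # D 3-mer
        assert t >= 0
        st_.prec[0, 1] = 3
        assert ee_statistic(st_) == 0.0

    def test_empty_system_raises(self):
        st_ = empty_state(Params(N=1, T_NPB=10))
        with pytest.raises(ValueError):
            ee_statistic(st_)

    def test_antisymmetric_under_relabeling(self):
        p = Params(N=2, T_NPB=100)
        st_ = empty_state(p)
        st_.prec[0, 0] = 30
        st_.prec[1, 1] = 10
        mirrored = empty_state(p)
        mirrored.prec[0, 1] = 30
        mirrored.prec[1, 0] = 10
        assert ee_statistic(st_) == -ee_statistic(mirrored)


class TestDetectRibozyme:
    def test_exact_domain_match(self):
        ch = RNAChain.from_string("ACUGGC", D)
        assert detect_ribozyme(ch, "ACUGGC") == (True, D)

    def test_length_bound_is_twice_domain(self):
        # a 13-mer containing the 6-nt replicase domain is inactive (13 > 12)
        ch = RNAChain.from_string("AAAGUUCAGAAAA", D)
        assert len(ch) == 13
        assert detect_ribozyme(ch, "GUUCAG")[0] is False
        ch12 = RNAChain.from_string("AAAGUUCAGAAA", D)
        assert detect_ribozyme(ch12, "GUUCAG")[0] is True

    def test_match_requires_uniform_handedness(self):
        chirs = [D] * 6
        chirs[3] = L
        ch = RNAChain.from_string("ACUGGC", chirs)
        assert detect_ribozyme(ch, "ACUGGC")[0] is False

    def test_directionless_match(self):
        # chains have no polarity: the reversed residue order also counts
        ch = RNAChain.from_string("CGGUCA", L)  # reverse of ACUGGC
        assert detect_ribozyme(ch, "ACUGGC") == (True, L)

    def test_any_uniform_match_activates(self):
        # first occurrence chimeric, second occurrence uniform
        seq = "ACUGGC" + "ACUGGC"
        chirs = [D, D, D, L, D, D] + [L] * 6
        ch = RNAChain.from_string(seq, chirs)
        assert detect_ribozyme(ch, "ACUGGC") == (True, L)

    def test_mirror_equivariance(self):
        ch = RNAChain.from_string("GGUUCAGG", D)
        act, chir = detect_ribozyme(ch, "GUUCAG")
        mact, mchir = detect_ribozyme(mirror_chain(ch), "GUUCAG")
        assert act == mact is True
        assert mchir == chir.mirror()


class TestCanonicalMonomer:
    def test_one_residue_products_join_nucleotide_pool(self):
        # a 1-mer chain is a free nucleotide: the count array is canonical
        p = Params(N=1, T_NPB=10)
        st_ = empty_state(p)
        slot = st_.add_free_chain(b"\x02", b"\x01", 0)
        assert slot == -1
        assert int(st_.nuc[0, 1 * 4 + 2]) == 1
        assert int(st_.room_n[0]) == 0


@settings(max_examples=50, deadline=None)
@given(st.lists(st.tuples(st.integers(0, 3), st.sampled_from([D, L])),
                min_size=1, max_size=15))
def test_detect_ribozyme_mirror_property(residues):
    """Mirroring a chain mirrors the detected handedness, never activity."""
    bases = bytes(b for b, _ in residues)
    chirs = bytes(c.value for _, c in residues)
    ch = RNAChain(bases, chirs)
    for domain in ("ACUGGC", "GUUCAG"):
        act, chir = detect_ribozyme(ch, domain)
        mact, mchir = detect_ribozyme(mirror_chain(ch), domain)
        assert act == mact
        if act:
            assert mchir == chir.mirror()
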