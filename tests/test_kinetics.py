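"""Rate formulas and single-molecule events, checked against closed forms
and empirical Monte-Carlo frequencies (binomial 3-sigma)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chirosim.core import Chirality, D, L, Nucleotide, Params, Precursor
from chirosim import kinetics


def binom_3sigma(n, p):
    return 3 * math.sqrt(n * p * (1 - p))


class TestFormulas:
    @pytest.mark.parametrize("paired,expected", [
        (False, 1e-4),          # single-strand chain end
        (True, 1e-6),           # (1e-4)^(3/2): synergistic paired decay
    ])
    def test_end_decay(self, paired, expected):
        assert kinetics.end_decay_probability(paired, Params()) == pytest.approx(expected)

    def test_end_decay_zero_rate(self):
        p = Params(P_NDE=0.0)
        assert kinetics.end_decay_probability(False, p) == 0.0
        assert kinetics.end_decay_probability(True, p) == 0.0

    @pytest.mark.parametrize("duplex,expected", [
        (False, 1e-5),
        (True, (1e-5) ** 1.5),  # ~3.162e-8
    ])
    def test_bond_break(self, duplex, expected):
        assert kinetics.bond_break_probability(duplex, Params()) == pytest.approx(expected)

    def test_separation_formula(self):
        p = Params()  # P_SP = 0.3
        assert kinetics.separation_probability(1, p) == pytest.approx(0.3)
        assert kinetics.separation_probability(3, p) == pytest.approx(0.09)
        with pytest.raises(ValueError):
            kinetics.separation_probability(0, p)

    def test_separation_monotone_in_r(self):
        p = Params()
        probs = [kinetics.separation_probability(r, p) for r in range(1, 12)]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_movement(self):
        from chirosim.core import RNAChain
        p = Params()
        assert kinetics.movement_probability(Precursor(D), p) == 0.002
        assert kinetics.movement_probability(Nucleotide(0, D), p) == 1e-4
        four = RNAChain.from_string("AUCG", D)
        assert kinetics.movement_probability(four, p) == pytest.approx(5e-5)
        one = RNAChain.from_string("A", D)
        assert kinetics.movement_probability(one, p) == pytest.approx(1e-4)

    @settings(max_examples=100, deadline=None)
    @given(st.floats(0, 1), st.integers(1, 500))
    def test_probabilities_stay_in_unit_interval(self, p_sp, r):
        p = Params(P_SP=p_sp)
        assert 0.0 <= kinetics.separation_probability(r, p) <= 1.0
        assert 0.0 <= kinetics.end_decay_probability(True, p) <= 1.0
        assert 0.0 <= kinetics.bond_break_probability(True, p) <= 1.0


class TestRacemize:
    def test_zero_rate_never_flips(self, rng):
        p = Params(P_CIC=0.0)
        pre = Precursor(D)
        for _ in range(1000):
            out = kinetics.racemize(pre, p, rng)
            assert not out.occurred and out.products == (pre,)

    def test_flip_frequency(self, rng):
        p = Params()  # P_CIC = 0.5
        n = 100_000
        flips = sum(kinetics.racemize(Precursor(D), p, rng).occurred
                    for _ in range(n))
        assert abs(flips - n * 0.5) < binom_3sigma(n, 0.5)

    def test_involution(self, rng):
        p = Params(P_CIC=1.0)
        out1 = kinetics.racemize(Precursor(D), p, rng)
        out2 = kinetics.racemize(out1.products[0], p, rng)
        assert out2.products[0].chirality is D


class TestFormNucleotide:
    def test_nonenzymatic_frequency(self, rng):
        p = Params()  # P_NF = 0.001
        n = 200_000
        hits = sum(
            kinetics.form_nucleotide(Precursor(L), 0, p, rng)[0].occurred
            for _ in range(n))
        assert abs(hits - n * 1e-3) < binom_3sigma(n, 1e-3)

    def test_enzymatic_frequency_and_credit(self, rng):
        p = Params(P_NFR=0.2)
        n = 10_000
        hits = 0
        for _ in range(n):
            out, used = kinetics.form_nucleotide(Precursor(D), 1, p, rng)
            assert used == out.occurred  # credit spent exactly on success
            hits += out.occurred
        assert abs(hits - n * 0.2) < binom_3sigma(n, 0.2)

    def test_product_keeps_handedness(self, rng):
        p = Params(P_NF=1.0)
        out, _ = kinetics.form_nucleotide(Precursor(L), 0, p, rng)
        assert out.occurred and out.products[0].chirality is L

    def test_bases_uniform(self, rng):
        p = Params(P_NF=1.0)
        counts = [0, 0, 0, 0]
        n = 20_000
        for _ in range(n):
            out, _ = kinetics.form_nucleotide(Precursor(D), 0, p, rng)
            counts[out.products[0].base] += 1
        chi2 = stats.chisquare(counts)
        assert chi2.pvalue > 1e-3

    def test_negative_credit_rejected(self, rng):
        with pytest.raises(ValueError):
            kinetics.form_nucleotide(Precursor(D), -1, Params(), rng)


class TestDecayNucleotide:
    def test_zero_rate(self, rng):
        p = Params(P_ND=0.0)
        nt = Nucleotide(2, D)
        for _ in range(1000):
            assert not kinetics.decay_nucleotide(nt, p, rng).occurred

    def test_frequency(self, rng):
        p = Params()  # P_ND = 0.01
        n = 100_000
        hits = sum(kinetics.decay_nucleotide(Nucleotide(1, D), p, rng).occurred
                   for _ in range(n))
        assert abs(hits - n * 0.01) < binom_3sigma(n, 0.01)

    def test_handedness_conserved(self, rng):
        p = Params(P_ND=1.0)
        for chir in (D, L):
            out = kinetics.decay_nucleotide(Nucleotide(3, chir), p, rng)
            assert out.products[0] == Precursor(chir)


class TestMassAndChiralityConservation:
    def test_events_conserve_mass_and_handedness(self, rng):
        """All chemical events are 1:1 interconversions; only racemization
        changes handedness."""
        p = Params(P_NF=0.5, P_ND=0.5, P_CIC=0.5)
        for _ in range(200):
            out, _ = kinetics.form_nucleotide(Precursor(D), 0, p, rng)
            assert len(out.products) == 1
            assert out.products[0].chirality is D
            out = kinetics.decay_nucleotide(Nucleotide(0, L), p, rng)
            assert len(out.products) == 1
            assert out.products[0].chirality is L
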