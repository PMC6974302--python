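"""Surface-mediated and template-directed synthesis at the object level:
cross-inhibition blocking, chiral selection, primer ladders, attraction
fidelity and replicase credits."""

import math

import numpy as np
import pytest

from chirosim.core import (
    Attachment,
    Chirality,
    D,
    L,
    Nucleotide,
    Params,
    PrimerLadder,
    RNAChain,
    TemplateComplex,
)
from chirosim import polymerization as poly


def binom_3sigma(n, p):
    return 3 * math.sqrt(n * p * (1 - p))


def chain(seq, chir):
    return RNAChain.from_string(seq, chir)


class TestEndBlocked:
    def test_opposite_terminal_blocks(self):
        ch = chain("AUCG", [D, D, D, L])
        assert poly.end_blocked(ch, 1) is True
        assert poly.end_blocked(ch, 0) is False

    def test_homochiral_never_blocked(self):
        ch = chain("AUCG", D)
        assert not poly.end_blocked(ch, 0) and not poly.end_blocked(ch, 1)

    def test_monomer_never_blocked(self):
        assert not poly.end_blocked(chain("A", L), 0)

    def test_no_termination_variant_unblocks(self):
        ch = chain("AUCG", [D, D, D, L])
        assert poly.end_blocked(ch, 1, no_termination=True) is False


class TestSurfaceLigationRate:
    def test_primer_ladder_scaling(self):
        # extension of an established polymer is 20x the dimer rate and
        # 200x the monomer rate under the strongest printed ladder
        lad = PrimerLadder(1, 10, 200, 200)
        p = Params(P_RL=1e-6)
        r_n = poly.surface_ligation_rate(D, D, 5, p, lad)
        r_2 = poly.surface_ligation_rate(D, D, 2, p, lad)
        r_1 = poly.surface_ligation_rate(D, D, 1, p, lad)
        assert r_n == pytest.approx(2e-4)
        assert r_n == pytest.approx(20 * r_2)
        assert r_n == pytest.approx(200 * r_1)

    def test_complete_chiral_selection_blocks_opposite(self):
        p = Params(F_CSS=0.0)
        assert poly.surface_ligation_rate(D, L, 3, p, PrimerLadder()) == 0.0

    def test_no_selection_no_primer_effect_symmetric(self):
        p = Params(F_CSS=1.0)
        lad = PrimerLadder()
        same = poly.surface_ligation_rate(D, D, 4, p, lad)
        opp = poly.surface_ligation_rate(D, L, 4, p, lad)
        assert same == opp == p.P_RL

    def test_clamped_to_unit_interval(self):
        p = Params(P_RL=0.9)
        assert poly.surface_ligation_rate(D, D, 9, p, PrimerLadder(1, 1, 9, 9)) == 1.0


class TestRandomLigationRound:
    def test_single_molecule_unchanged(self, rng):
        room = [chain("AAA", D)]
        out = poly.random_ligation_round(room, Params(), PrimerLadder(), rng)
        assert len(out) == 1

    def test_zero_rate_never_ligates(self, rng):
        p = Params(P_RL=0.0)
        room = [chain("AAA", D), chain("UUU", D)]
        for _ in range(500):
            out = poly.random_ligation_round(room, p, PrimerLadder(), rng)
            assert len(out) == 2

    def test_merge_frequency_matches_formula(self, rng):
        # two homochiral trimers: extender length 3 selects R3, so the
        # merge probability is P_RL * R3
        p = Params(P_RL=0.01)
        lad = PrimerLadder(1, 1, 20, 20)
        expect = 0.2
        n = 20_000
        merges = 0
        for _ in range(n):
            room = [chain("AAA", D), chain("UUU", D)]
            out = poly.random_ligation_round(room, p, lad, rng)
            merges += len(out) == 1
        assert abs(merges - n * expect) < binom_3sigma(n, expect)

    def test_cross_inhibition_encoded_structurally(self, rng):
        # an opposite-handed join leaves a heterochiral junction at an end
        p = Params(P_RL=1.0, F_CSS=1.0)
        room = [chain("AAA", D), chain("U", L)]
        out = poly.random_ligation_round(room, p, PrimerLadder(), rng)
        assert len(out) == 1
        merged = out[0]
        assert len(merged) == 4 and not merged.is_homochiral()
        blocked_ends = [poly.end_blocked(merged, e) for e in (0, 1)]
        assert sum(blocked_ends) == 1


class TestAttractSubstrate:
    def test_complementary_monomer_frequency(self, rng):
        p = Params(P_AT=0.5)
        tmpl = chain("AAAA", D)
        sub = Nucleotide(1, D)  # U pairs every template position
        n = 10_000
        hits = sum(poly.attract_substrate(tmpl, sub, p, rng) is not None
                   for _ in range(n))
        assert abs(hits - n * 0.5) < binom_3sigma(n, 0.5)

    def test_mismatch_frequency_is_pat_times_pfp(self, rng):
        p = Params(P_AT=0.5, P_FP=0.1)
        tmpl = chain("AAAA", D)
        sub = Nucleotide(0, D)  # A against A: false pair only
        n = 20_000
        hits = sum(poly.attract_substrate(tmpl, sub, p, rng) is not None
                   for _ in range(n))
        assert abs(hits - n * 0.05) < binom_3sigma(n, 0.05)

    def test_disabled_when_pat_zero(self, rng):
        p = Params(P_AT=0.0)
        tmpl = chain("AAAA", D)
        for _ in range(200):
            assert poly.attract_substrate(tmpl, Nucleotide(1, D), p, rng) is None

    def test_attraction_is_chirality_agnostic(self, rng):
        # an L monomer is attracted onto a D template at the same rate
        p = Params(P_AT=1.0)
        tmpl = chain("AAAA", D)
        cx = poly.attract_substrate(tmpl, Nucleotide(1, L), p, rng)
        assert isinstance(cx, TemplateComplex)
        assert cx.paired_count == 1

    def test_substrate_longer_than_template_rejected(self, rng):
        p = Params(P_AT=1.0)
        tmpl = chain("AAA", D)
        sub = chain("UUUU", D)
        assert poly.attract_substrate(tmpl, sub, p, rng) is None

    def test_lone_nucleotide_is_not_a_template(self, rng):
        p = Params(P_AT=1.0)
        assert poly.attract_substrate(chain("A", D), Nucleotide(1, D), p, rng) is None

    def test_subsequent_substrates_contiguous(self, rng):
        p = Params(P_AT=1.0, P_FP=1.0)  # always attach wherever aligned
        tmpl = chain("AAAAAA", D)
        cx = TemplateComplex(tmpl, [Attachment(2, chain("U", D))])
        for _ in range(40):
            before = [a.start for a in cx.attachments]
            out = poly.attract_substrate(cx, Nucleotide(1, D), p, rng)
            assert out is cx
            starts = sorted(a.start for a in cx.attachments)
            spans = []
            for a in sorted(cx.attachments, key=lambda a: a.start):
                spans.extend(range(a.start, a.end + 1))
            assert spans == list(range(min(starts), min(starts) + len(spans)))
            if cx.paired_count == 6:
                break
        assert cx.paired_count == 6


class TestTemplateLigationRound:
    def _complex(self, tmpl_chir=D, left_chir=D, right_chir=D):
        tmpl = chain("AAAAAA", tmpl_chir)
        left = Attachment(0, chain("UUU", left_chir))
        right = Attachment(3, chain("UU", right_chir))
        return TemplateComplex(tmpl, [left, right])

    def test_rep_catalysis_frequency_and_credit(self, rng):
        p = Params(P_TLR=0.9, P_TL=0.0)
        n = 5000
        fired = 0
        for _ in range(n):
            cx = self._complex()
            credits = {D: 1, L: 0}
            used = poly.template_ligation_round(cx, credits, p, PrimerLadder(), rng)
            if len(cx.attachments) == 1:
                fired += 1
                assert used == 1 and credits[D] == 0
            else:
                assert used == 0 and credits[D] == 1
        assert abs(fired - n * 0.9) < binom_3sigma(n, 0.9)

    def test_rep_requires_full_handedness_agreement(self, rng):
        # an L replicase cannot ligate D substrates; without credits of the
        # right handedness the non-enzymatic rate applies (here zero)
        p = Params(P_TLR=0.9, P_TL=0.0)
        cx = self._complex()
        used = poly.template_ligation_round(cx, {D: 0, L: 5}, p, PrimerLadder(), rng)
        assert used == 0 and len(cx.attachments) == 2

    def test_complete_selection_blocks_opposite_incomer(self, rng):
        p = Params(P_TL=1.0, F_CST=0.0)
        for _ in range(100):
            cx = self._complex(right_chir=L)  # incomer (shorter) is L
            poly.template_ligation_round(cx, {}, p, PrimerLadder(), rng)
            assert len(cx.attachments) == 2

    def test_no_selection_still_terminates_after_opposite(self, rng):
        # F_CST=1 lets the opposite incomer in, but the heterochiral
        # junction then blocks further extension at that end
        p = Params(P_TL=1.0, F_CST=1.0)
        tmpl = chain("AAAAAA", D)
        cx = TemplateComplex(tmpl, [Attachment(0, chain("UUU", D)),
                                    Attachment(3, chain("U", L))])
        poly.template_ligation_round(cx, {}, p, PrimerLadder(), rng)
        assert len(cx.attachments) == 1
        merged = cx.attachments[0].chain
        assert poly.end_blocked(merged, 1)
        # a further same-template ligation at that end is now forbidden
        cx.attachments.append(Attachment(4, chain("U", D)))
        poly.template_ligation_round(cx, {}, p, PrimerLadder(), rng)
        assert len(cx.attachments) == 2

    def test_nonenzymatic_rate_uses_template_ladder(self, rng):
        p = Params(P_TL=0.01)
        lad = PrimerLadder(1, 1, 20, 20)  # extender is the 3-mer: R3
        n = 20_000
        fired = 0
        for _ in range(n):
            cx = self._complex()
            poly.template_ligation_round(cx, {}, p, lad, rng)
            fired += len(cx.attachments) == 1
        assert abs(fired - n * 0.2) < binom_3sigma(n, 0.2)


class TestHomochiralityInvariant:
    def test_complete_selection_only_builds_homochiral_chains(self, rng):
        """With F_CSS = 0 and termination on, every surface-built chain in
        a mixed pool stays homochiral."""
        p = Params(P_RL=0.5, F_CSS=0.0)
        room = [Nucleotide(int(rng.integers(4)), D if rng.random() < 0.5 else L)
                for _ in range(40)]
        for _ in range(50):
            room = poly.random_ligation_round(room, p, PrimerLadder(), rng)
        for mol in room:
            if isinstance(mol, RNAChain):
                assert mol.is_homochiral()

    def test_no_termination_builds_chimeras(self, rng):
        p = Params(P_RL=1.0, F_CSS=1.0)
        room = [Nucleotide(0, D if i % 2 else L) for i in range(32)]
        for _ in range(10):
            room = poly.random_ligation_round(room, p, PrimerLadder(), rng,
                                              no_termination=True)
        switches = 0
        for mol in room:
            if isinstance(mol, RNAChain):
                ch = mol.chirs
                switches = max(switches, sum(
                    ch[i] != ch[i + 1] for i in range(len(ch) - 1)))
        assert switches > 1  # chains with more than one handedness switch
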