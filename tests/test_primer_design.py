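"""Consensus construction, window scanning, pairing, Tm bounds, tails."""

import math

import numpy as np
import pytest

from lepiprime import (
    Alignment,
    DegeneratePrimer,
    SimSpec,
    ValidationError,
    attach_tails,
    consensus_iupac,
    design_primers,
    pair_primers,
    scan_windows,
    simulate_alignment,
    tm_bounds,
)
from lepiprime.primer_design import CandidateWindow, PrimerPair
from lepiprime.seqio import IUPAC_EXPANSION, expand


class TestConsensus:
    def test_examples(self):
        assert consensus_iupac([("A", "A", "A")]) == "A"
        assert consensus_iupac([("A", "G")]) == "R"
        assert consensus_iupac([tuple("ACGT")]) == "N"
        aln = Alignment(("a", "b", "c"), ("AAT", "AAT", "AGT"))
        assert consensus_iupac(aln) == "ART"

    def test_gaps_ignored_all_gap_rejected(self):
        assert consensus_iupac([("A", "-", "A")]) == "A"
        with pytest.raises(ValidationError, match="all-gap"):
            consensus_iupac([("-", "-")])

    def test_consensus_of_expansions_round_trips(self):
        # consensus over all expansions of a degenerate string recovers it
        for s in ("ART", "NDA", "wskm", "ACGT"):
            rows = list(expand(s))
            cols = [tuple(r[i] for r in rows) for i in range(len(s))]
            assert consensus_iupac(cols) == s.upper()

    def test_minimality_against_set_cover_oracle(self):
        # no IUPAC code with a strictly smaller expansion covers the column
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = rng.integers(2, 7)
            col = tuple("ACGT"[i] for i in rng.integers(0, 4, size=n))
            code = consensus_iupac([col])
            observed = set(col)
            assert observed <= IUPAC_EXPANSION[code]
            for other, bases in IUPAC_EXPANSION.items():
                if len(bases) < len(IUPAC_EXPANSION[code]):
                    assert not observed <= bases, (col, code, other)


class TestScanWindows:
    def test_conserved_alignment_all_windows_qualify(self, conserved_alignment):
        windows = scan_windows(conserved_alignment)
        L = conserved_alignment.length
        expected = 2 * sum(L - wlen + 1 for wlen in range(18, 28))
        assert len(windows) == expected
        assert all(w.conservation == 1.0 and w.window_degeneracy == 1 for w in windows)

    def test_three_prime_clamp_excludes_degenerate_terminus(self):
        # last column of the 20-bp window expands to {A,C,G}: forward
        # orientation is clamped out, reverse (3' at left edge) survives
        rows = ["ACGTACGTACGTACGTACGA", "ACGTACGTACGTACGTACGC", "ACGTACGTACGTACGTACGG"]
        aln = Alignment(("a", "b", "c"), tuple(rows))
        windows = scan_windows(aln, len_range=(20, 20), min_conservation=0.5)
        orientations = {w.orientation for w in windows if w.start == 0}
        assert orientations == {"reverse"}

    def test_planted_invariant_block_is_reported(self):
        aln, truth = simulate_alignment(
            SimSpec(n_taxa=8, length=400, substitution_prob=0.3,
                    planted_windows=((120, 20),), seed=3)
        )
        windows = scan_windows(aln)
        starts = {w.start for w in windows if w.length == 20}
        assert 120 in starts

    def test_inverted_length_range_rejected(self, conserved_alignment):
        with pytest.raises(ValidationError):
            scan_windows(conserved_alignment, len_range=(27, 18))

    def test_raising_degeneracy_cap_only_adds_candidates(self):
        aln, _ = simulate_alignment(
            SimSpec(n_taxa=6, length=300, substitution_prob=0.15, seed=9)
        )
        key = lambda w: (w.start, w.length, w.orientation)
        tight = {key(w) for w in scan_windows(aln, max_degeneracy=8)}
        loose = {key(w) for w in scan_windows(aln, max_degeneracy=64)}
        assert tight <= loose

    def test_gap_rich_columns_disqualify_windows(self):
        row = "ACGTACGTACGTACGTACGTACGT"
        row = row + row  # 48 columns
        gapped = row[:10] + "-" + row[11:]
        aln = Alignment(("a", "b"), (row, gapped))
        windows = scan_windows(aln, len_range=(18, 18))
        assert windows
        assert all(not (w.start <= 10 < w.start + w.length) for w in windows)


def _win(start, length, orientation, cons=1.0, seq=None):
    from lepiprime import degeneracy

    seq = seq or "A" * length
    return CandidateWindow(start, length, orientation, seq, cons, degeneracy(seq))


class TestPairPrimers:
    def test_amplicon_bounds_inclusive(self):
        fwd = [_win(0, 20, "forward")]
        for rev_end, expected in [(367, 1), (199, 1), (499, 1), (198, 0), (500, 0)]:
            rev = [_win(rev_end - 19, 20, "reverse")]
            pairs = pair_primers(fwd, rev)
            assert len(pairs) == expected, rev_end
            if pairs:
                assert pairs[0].amplicon_len == rev_end + 1
                assert pairs[0].marker_len == pairs[0].amplicon_len - 40

    def test_empty_candidates_give_empty_result(self):
        assert pair_primers([], []) == []

    def test_score_ties_broken_by_degeneracy_then_position(self):
        fwd = [
            _win(0, 20, "forward", cons=1.0, seq="RR" + "A" * 18),
            _win(2, 20, "forward", cons=1.0),
        ]
        rev = [_win(330, 20, "reverse", cons=1.0)]
        pairs = pair_primers(fwd, rev, degeneracy_penalty=0.0)
        assert [p.fwd_start for p in pairs] == [2, 0]  # equal score, lower degeneracy first

    def test_score_formula(self):
        fwd = [_win(0, 20, "forward", cons=0.9, seq="RR" + "A" * 18)]
        rev = [_win(330, 20, "reverse", cons=0.7, seq="RRR" + "A" * 17)]
        (pair,) = pair_primers(fwd, rev)
        assert pair.score == pytest.approx((0.9 + 0.7) / 2 - 0.02 * math.log2(32))

    def test_emitted_pairs_respect_bounds_on_random_alignments(self):
        for seed in range(5):
            aln, _ = simulate_alignment(
                SimSpec(n_taxa=8, length=650, substitution_prob=0.25,
                        planted_windows=((50, 25), (400, 25)), seed=seed)
            )
            pairs = design_primers(aln, compute_tm=False, with_tails=False)
            assert pairs
            for p in pairs:
                assert 200 <= p.amplicon_len <= 500
                assert p.amplicon_len == p.marker_len + len(p.forward.core) + len(p.reverse.core)


# Unified nearest-neighbor parameters (Allawi & SantaLucia 1997):
# (dH kcal/mol, dS cal/mol/K) per propagation step, plus terminal initiation.
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT = {"A": (2.3, 4.1), "T": (2.3, 4.1), "G": (0.1, -2.8), "C": (0.1, -2.8)}


def nn_tm_oracle(seq: str, na_mM=50.0, primer_nM=250.0) -> float:
    """Independent brute-force NN sum: unified params, entropy salt correction."""
    dh = _INIT[seq[0]][0] + _INIT[seq[-1]][0]
    ds = _INIT[seq[0]][1] + _INIT[seq[-1]][1]
    for a, b in zip(seq, seq[1:]):
        dh += _NN[a + b][0]
        ds += _NN[a + b][1]
    ds += 0.368 * (len(seq) - 1) * math.log(na_mM * 1e-3)
    k = primer_nM * 1e-9
    return 1000.0 * dh / (ds + 1.987 * math.log(k)) - 273.15


class TestTmBounds:
    def test_degeneracy_one_bounds_coincide(self):
        p = DegeneratePrimer("x_F", "ACGTACGTACGTACGTACGT", "forward")
        lo, hi = tm_bounds(p)
        assert lo == hi

    def test_matches_independent_nn_oracle(self):
        seq = "ACGTACGTACGTACGTACGT"
        lo, _ = tm_bounds(DegeneratePrimer("x_F", seq, "forward"))
        assert lo == pytest.approx(nn_tm_oracle(seq), abs=0.5)

    def test_degenerate_primer_brackets_its_expansions(self):
        p = DegeneratePrimer("x_F", "ACGTRYACGTACGWACGT", "forward")
        lo, hi = tm_bounds(p)
        assert lo < hi

    def test_appending_gc_triplet_never_lowers_upper_bound(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            core = "".join("ACGT"[i] for i in rng.integers(0, 4, size=18))
            p1 = DegeneratePrimer("x_F", core, "forward")
            p2 = DegeneratePrimer("x_F", core + "GCG", "forward")
            assert tm_bounds(p2)[1] >= tm_bounds(p1)[1]

    def test_short_core_outside_model_domain(self):
        with pytest.raises(ValidationError):
            tm_bounds(DegeneratePrimer("x_F", "ACGTACG", "forward"))


class TestAttachTails:
    def _pair(self, fwd_core="atwgaratyatggartt", rev_core="ccrtccatytchac"):
        return PrimerPair(
            gene="AFG3a",
            forward=DegeneratePrimer("AFG3a_F", fwd_core, "forward"),
            reverse=DegeneratePrimer("AFG3a_R", rev_core, "reverse"),
            fwd_start=0,
            rev_end=335,
            amplicon_len=336,
            marker_len=336 - len(fwd_core) - len(rev_core),
            score=1.0,
        )

    def test_tails_prepended_cores_unchanged(self):
        tailed = attach_tails(self._pair())
        assert tailed.forward.full_sequence == "TAATACGACTCACTATAGGGatwgaratyatggartt"
        assert tailed.reverse.full_sequence == "ATTAACCCTCACTAAAGGGccrtccatytchac"
        assert tailed.forward.core == "atwgaratyatggartt"

    def test_clamp_stays_part_of_core(self):
        # a published-style core carrying an uppercase clamp keeps it 3' of the tail
        tailed = attach_tails(self._pair(rev_core="TGTTGTTGTATTAAAAccrtccatytchac"))
        assert tailed.reverse.full_sequence == (
            "ATTAACCCTCACTAAAGGG" + "TGTTGTTGTATTAAAA" + "ccrtccatytchac"
        )

    def test_attaching_twice_is_rejected(self):
        tailed = attach_tails(self._pair())
        with pytest.raises(ValidationError):
            attach_tails(tailed)
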