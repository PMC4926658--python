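"""Degenerate consensus primer design from multi-species alignments.

Given an alignment of one candidate exon across a genome panel, the design
pipeline is:

1. ``consensus_iupac`` — collapse each alignment column to the minimal
   IUPAC code covering every non-gap base observed in it.
2. ``scan_windows`` — slide windows of primer length over the alignment
   and keep those whose consensus is usable as a degenerate primer:
   bounded total degeneracy, a low-degeneracy 3' clamp (mismatches and
   ambiguity at the 3' terminus are what stall the polymerase), enough
   conserved columns, and no indel-rich columns.
3. ``pair_primers`` — combine forward and reverse windows into pairs whose
   amplicon (primers included) falls within the configured length band,
   scored by mean window conservation penalized by log2 total degeneracy.
4. ``tm_bounds`` — bracket each primer's nearest-neighbor melting
   temperature by evaluating its weakest- and strongest-stacking
   expansions.
5. ``attach_tails`` — prepend the constant T7/T3 sequencing tails.

Amplicons are kept short (200-500 bp by default) deliberately: the primers
target decades-old, partly degraded museum extracts where long templates
rarely survive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from Bio.SeqUtils import MeltingTemp as mt

from .seqio import (
    Alignment,
    CODE_FOR_SET,
    DegeneratePrimer,
    IUPAC_EXPANSION,
    MASK_FOR,
    T3_REVERSE_TAIL,
    T7_FORWARD_TAIL,
    ValidationError,
    degeneracy,
    reverse_complement,
)

__all__ = [
    "CandidateWindow",
    "PrimerPair",
    "consensus_iupac",
    "scan_windows",
    "pair_primers",
    "tm_bounds",
    "with_tm",
    "attach_tails",
    "design_primers",
]

_MASK_TO_CODE = {
    sum({"A": 1, "C": 2, "G": 4, "T": 8}[b] for b in bases): code
    for code, bases in IUPAC_EXPANSION.items()
    for bases in [IUPAC_EXPANSION[code]]
}

# base preference when picking extreme-stacking expansions for Tm bounds
_WEAK_ORDER = "ATCG"
_STRONG_ORDER = "GCTA"


@dataclass(frozen=True)
class CandidateWindow:
    """One alignment window usable as a degenerate primer.

    ``sequence`` is written primer 5'->3': for a reverse window it is the
    reverse complement of the alignment-strand consensus, so its 3' end
    corresponds to the window's *first* alignment column.
    """

    start: int  # 0-based alignment column of the window's left edge
    length: int
    orientation: str  # "forward" | "reverse"
    sequence: str
    conservation: float
    window_degeneracy: int

    @property
    def end(self) -> int:
        """0-based exclusive right edge."""
        return self.start + self.length


@dataclass(frozen=True)
class PrimerPair:
    gene: str
    forward: DegeneratePrimer
    reverse: DegeneratePrimer
    fwd_start: int  # 0-based alignment column of forward primer 5' end
    rev_end: int  # 0-based alignment column of reverse primer 5' end (rightmost)
    amplicon_len: int  # 5' of forward through 3'... both primers included
    marker_len: int  # inter-primer region: the sequence left after trimming
    score: float

    def __post_init__(self) -> None:
        expected = self.marker_len + len(self.forward.core) + len(self.reverse.core)
        if self.amplicon_len != expected:
            raise ValidationError(
                f"{self.gene}: amplicon_len {self.amplicon_len} != marker_len + cores {expected}"
            )


def consensus_iupac(columns: list[tuple[str, ...]] | Alignment, start: int = 0,
                    end: int | None = None) -> str:
    """Minimal IUPAC consensus of aligned columns.

    Each output symbol is the smallest ambiguity code whose expansion
    covers all non-gap bases observed in that column; gaps in individual
    rows are ignored, but an all-gap column is an error because no base
    can be placed there.
    """
    if isinstance(columns, Alignment):
        end = columns.length if end is None else end
        cols = [columns.column(i) for i in range(start, end)]
    else:
        cols = list(columns)
    out = []
    for i, col in enumerate(cols):
        bases: set[str] = set()
        for ch in col:
            if ch == "-":
                continue
            c = ch.upper()
            if c == "U":
                c = "T"
            if c not in IUPAC_EXPANSION:
                raise ValidationError(f"consensus: non-IUPAC character {ch!r} in column {i}")
            bases |= IUPAC_EXPANSION[c]
        if not bases:
            raise ValidationError(f"consensus: column {i} is all-gap")
        out.append(CODE_FOR_SET[frozenset(bases)])
    return "".join(out)


def _column_profile(aln: Alignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column (IUPAC union mask, expansion size, gap fraction)."""
    n, L = aln.n_taxa, aln.length
    codes = np.zeros((n, L), dtype=np.uint8)
    gaps = np.zeros((n, L), dtype=bool)
    for i, row in enumerate(aln.rows):
        for j, ch in enumerate(row):
            if ch == "-":
                gaps[i, j] = True
                continue
            c = ch.upper()
            if c == "U":
                c = "T"
            if c not in MASK_FOR:
                raise ValidationError(f"alignment row {aln.taxa[i]!r}: bad symbol {ch!r} at column {j}")
            codes[i, j] = MASK_FOR[c]
    masks = np.bitwise_or.reduce(codes, axis=0)
    sizes = np.unpackbits(masks.reshape(-1, 1), axis=1).sum(axis=1)
    gapfrac = gaps.sum(axis=0) / n
    return masks, sizes.astype(np.int64), gapfrac


def scan_windows(
    aln: Alignment,
    len_range: tuple[int, int] = (18, 27),
    max_degeneracy: int = 512,
    clamp_len: int = 3,
    clamp_max_deg: int = 2,
    min_conservation: float = 0.5,
    max_gap_frac: float = 0.5,
) -> list[CandidateWindow]:
    """Enumerate all primer-suitable windows of the alignment, both orientations.

    A window qualifies when its consensus degeneracy is at most
    ``max_degeneracy``, each of its ``clamp_len`` 3'-terminal positions
    expands to at most ``clamp_max_deg`` bases, the fraction of
    single-state (non-gap) columns is at least ``min_conservation``, and
    no column is gapped in ``max_gap_frac`` or more of the rows.  The 3'
    clamp sits at the window's right edge for forward primers and at its
    left edge for reverse primers, so the two orientations admit
    different windows.
    """
    lo, hi = len_range
    if lo > hi:
        raise ValidationError(f"inverted window length range {len_range}")
    if lo < 1:
        raise ValidationError("window length must be positive")
    if aln.length < hi:
        raise ValidationError(f"alignment ({aln.length} bp) shorter than max window ({hi} bp)")

    masks, sizes, gapfrac = _column_profile(aln)
    L = aln.length
    valid = (gapfrac < max_gap_frac) & (sizes >= 1)
    conserved = (sizes == 1) & valid

    csum_valid = np.concatenate([[0], np.cumsum(valid)])
    csum_cons = np.concatenate([[0], np.cumsum(conserved)])
    log2sizes = np.log2(np.where(sizes >= 1, sizes, 1).astype(float))
    csum_logdeg = np.concatenate([[0.0], np.cumsum(log2sizes)])

    if clamp_len > 0:
        clamp_ok_col = sizes <= clamp_max_deg
        cview = np.lib.stride_tricks.sliding_window_view(clamp_ok_col, clamp_len)
        clamp_ok = cview.all(axis=1)  # clamp_ok[s]: columns s..s+clamp_len-1 all pass
    else:
        clamp_ok = np.ones(L + 1, dtype=bool)

    codes = [_MASK_TO_CODE[int(m)] for m in masks]
    out: list[CandidateWindow] = []
    log_cap = math.log2(max_degeneracy) + 1e-9
    for wlen in range(lo, hi + 1):
        if clamp_len > wlen:
            continue
        starts = np.arange(L - wlen + 1)
        n_valid = csum_valid[starts + wlen] - csum_valid[starts]
        n_cons = csum_cons[starts + wlen] - csum_cons[starts]
        logdeg = csum_logdeg[starts + wlen] - csum_logdeg[starts]
        base_ok = (n_valid == wlen) & (logdeg <= log_cap) & (
            n_cons >= min_conservation * wlen - 1e-9
        )
        fwd_ok = base_ok & clamp_ok[starts + wlen - clamp_len] if clamp_len else base_ok
        rev_ok = base_ok & clamp_ok[starts] if clamp_len else base_ok
        for s in starts[fwd_ok | rev_ok]:
            s = int(s)
            consensus = "".join(codes[s : s + wlen])
            deg = degeneracy(consensus)
            if deg > max_degeneracy:
                continue
            cons = float(n_cons[s]) / wlen
            if fwd_ok[s]:
                out.append(
                    CandidateWindow(s, wlen, "forward", consensus, cons, deg)
                )
            if rev_ok[s]:
                out.append(
                    CandidateWindow(
                        s, wlen, "reverse", reverse_complement(consensus), cons, deg
                    )
                )
    return out


def pair_primers(
    fwd: list[CandidateWindow],
    rev: list[CandidateWindow],
    amplicon_range: tuple[int, int] = (200, 500),
    degeneracy_penalty: float = 0.02,
    gene: str = "locus",
    compute_tm: bool = False,
    max_windows_per_orientation: int | None = None,
) -> list[PrimerPair]:
    """Combine candidate windows into amplicon-length-constrained pairs.

    The amplicon spans the forward primer's 5' end through the reverse
    primer's 5' end on the alignment, primers included; bounds are
    inclusive.  Pairs are ranked by
    ``mean(conservation) - degeneracy_penalty * log2(product degeneracy)``,
    ties broken by lower total degeneracy, then smaller forward start.

    The score is separable into per-window quality, so when
    ``max_windows_per_orientation`` is set, each orientation is thinned to
    its best windows before the quadratic join; on near-invariant
    alignments this avoids enumerating millions of redundant pairs.
    """
    lo, hi = amplicon_range
    if lo > hi:
        raise ValidationError(f"inverted amplicon range {amplicon_range}")

    def quality(w: CandidateWindow) -> float:
        return w.conservation - 2 * degeneracy_penalty * math.log2(w.window_degeneracy)

    def thin(windows: list[CandidateWindow], cap: int) -> list[CandidateWindow]:
        # keep the best windows by quality; windows tied at the cutoff are
        # sampled evenly along the alignment so pairing still sees every
        # region (a plain sort would collapse onto one edge when many
        # windows tie, e.g. on a near-invariant alignment)
        if len(windows) <= cap:
            return windows
        ranked = sorted(windows, key=lambda w: (-quality(w), w.start, w.length))
        q_cut = quality(ranked[cap - 1])
        keep = [w for w in ranked if quality(w) > q_cut + 1e-12]
        ties = [w for w in ranked if abs(quality(w) - q_cut) <= 1e-12]
        slots = cap - len(keep)
        idx = np.unique(np.linspace(0, len(ties) - 1, slots).round().astype(int))
        return keep + [ties[i] for i in idx]

    fwd_windows = [w for w in fwd if w.orientation == "forward"]
    rev_windows = [w for w in rev if w.orientation == "reverse"]
    if max_windows_per_orientation is not None:
        fwd_windows = thin(fwd_windows, max_windows_per_orientation)
        rev_windows = thin(rev_windows, max_windows_per_orientation)
    pairs: list[PrimerPair] = []
    for f in fwd_windows:
        for r in rev_windows:
            if r.start < f.end:
                continue  # primers must not overlap
            amplicon = r.end - f.start  # columns spanned, both primers included
            if not lo <= amplicon <= hi:
                continue
            deg_product = f.window_degeneracy * r.window_degeneracy
            score = (f.conservation + r.conservation) / 2.0 - (
                degeneracy_penalty * math.log2(deg_product)
            )
            fp = DegeneratePrimer(name=f"{gene}_F", core=f.sequence, orientation="forward")
            rp = DegeneratePrimer(name=f"{gene}_R", core=r.sequence, orientation="reverse")
            if compute_tm and min(len(fp.core), len(rp.core)) >= 8:
                fp = replace(fp, tm_low=tm_bounds(fp)[0], tm_high=tm_bounds(fp)[1])
                rp = replace(rp, tm_low=tm_bounds(rp)[0], tm_high=tm_bounds(rp)[1])
            pairs.append(
                PrimerPair(
                    gene=gene,
                    forward=fp,
                    reverse=rp,
                    fwd_start=f.start,
                    rev_end=r.end - 1,
                    amplicon_len=amplicon,
                    marker_len=amplicon - f.length - r.length,
                    score=score,
                )
            )
    pairs.sort(
        key=lambda p: (
            -p.score,
            p.forward.degeneracy * p.reverse.degeneracy,
            p.fwd_start,
        )
    )
    return pairs


def with_tm(pair: PrimerPair) -> PrimerPair:
    """Return the pair with nearest-neighbor Tm bounds filled in."""
    fp, rp = pair.forward, pair.reverse
    if min(len(fp.core), len(rp.core)) < 8:
        return pair
    f_lo, f_hi = tm_bounds(fp)
    r_lo, r_hi = tm_bounds(rp)
    return replace(
        pair,
        forward=replace(fp, tm_low=f_lo, tm_high=f_hi),
        reverse=replace(rp, tm_low=r_lo, tm_high=r_hi),
    )


def _extreme_expansion(core: str, order: str) -> str:
    """One expansion choosing the first available base in ``order`` everywhere."""
    out = []
    for ch in core:
        c = ch.upper()
        if c == "U":
            c = "T"
        bases = IUPAC_EXPANSION[c]
        out.append(next(b for b in order if b in bases))
    return "".join(out)


def tm_bounds(
    primer: DegeneratePrimer, na_mM: float = 50.0, primer_uM: float = 0.25
) -> tuple[float, float]:
    """Bracket a degenerate primer's melting temperature.

    Nearest-neighbor Tm (unified parameter set, monovalent-salt-corrected)
    is evaluated on two extreme expansions of the core: at every ambiguous
    position the weakest-stacking base (A > T > C > G preference) for the
    lower bound and the strongest (G > C > T > A) for the upper bound.
    Tails are excluded; they do not anneal in the first cycles.
    """
    core = primer.core
    if len(core) < 8:
        raise ValidationError(
            f"primer {primer.name}: core of {len(core)} nt is below the nearest-neighbor model domain"
        )
    if "-" in core:
        raise ValidationError(f"primer {primer.name}: gap in core")
    kwargs = dict(Na=na_mM, dnac1=primer_uM * 1000.0, dnac2=0.0, saltcorr=5)
    low = mt.Tm_NN(_extreme_expansion(core, _WEAK_ORDER), **kwargs)
    high = mt.Tm_NN(_extreme_expansion(core, _STRONG_ORDER), **kwargs)
    if low > high:  # preference heuristic picked a weaker stack for "strong"
        low, high = high, low
    return float(low), float(high)


def attach_tails(
    pair: PrimerPair,
    fwd_tail: str = T7_FORWARD_TAIL,
    rev_tail: str = T3_REVERSE_TAIL,
) -> PrimerPair:
    """Prepend the universal sequencing tails to both primers' 5' ends.

    Cores are untouched; a pair whose primers already carry a tail is
    rejected rather than double-tailed.
    """
    for primer, tail in ((pair.forward, fwd_tail), (pair.reverse, rev_tail)):
        if primer.tail:
            raise ValidationError(f"primer {primer.name} already carries a tail")
        if primer.core.upper().startswith(tail.upper()):
            raise ValidationError(
                f"primer {primer.name}: core already begins with the tail sequence"
            )
    return replace(
        pair,
        forward=replace(pair.forward, tail=fwd_tail),
        reverse=replace(pair.reverse, tail=rev_tail),
    )


def design_primers(
    aln: Alignment,
    gene: str = "locus",
    amplicon_range: tuple[int, int] = (200, 500),
    with_tails: bool = True,
    top: int | None = None,
    compute_tm: bool = True,
    max_windows_per_orientation: int | None = 300,
    **scan_kwargs,
) -> list[PrimerPair]:
    """Full design pass: scan windows, pair, trim, add Tm bounds and tails."""
    windows = scan_windows(aln, **scan_kwargs)
    fwd = [w for w in windows if w.orientation == "forward"]
    rev = [w for w in windows if w.orientation == "reverse"]
    pairs = pair_primers(
        fwd,
        rev,
        amplicon_range=amplicon_range,
        gene=gene,
        max_windows_per_orientation=max_windows_per_orientation,
    )
    if top is not None:
        pairs = pairs[:top]
    if compute_tm:
        pairs = [with_tm(p) for p in pairs]
    if with_tails:
        pairs = [attach_tails(p) for p in pairs]
    return pairs
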