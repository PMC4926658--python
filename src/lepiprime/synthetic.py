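"""Synthetic data with planted ground truth for exercising the pipeline.

Real marker discovery starts from whole-genome assemblies; the generator
replaces them with small, fully-controlled stand-ins.  Alignments follow a
star topology: a random ancestral sequence is mutated independently per
taxon at a fixed per-site substitution probability (a Jukes-Cantor-like
uniform replacement model), except inside *planted windows* that are kept
invariant — these emulate the conserved blocks primers are designed
against, and their coordinates are returned as ground truth.  Template
collections for in-silico PCR embed primer annealing sites mutated on a
per-taxon divergence schedule, with the expected amplification outcome
evaluated by an independent brute-force oracle.

Everything is driven by an explicit integer seed and is byte-reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .seqio import Alignment, ValidationError, expand, reverse_complement
from .primer_design import PrimerPair

__all__ = [
    "SimSpec",
    "simulate_alignment",
    "simulate_templates",
    "planted_recovery_rate",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one synthetic alignment."""

    n_taxa: int = 8
    length: int = 700
    substitution_prob: float = 0.3
    planted_windows: tuple[tuple[int, int], ...] = ()  # (start, length) invariant blocks
    indel_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.substitution_prob < 1:
            raise ValidationError("substitution_prob must be in [0, 1)")
        if not 0 <= self.indel_prob < 1:
            raise ValidationError("indel_prob must be in [0, 1)")
        if self.n_taxa < 1 or self.length < 1:
            raise ValidationError("n_taxa and length must be positive")
        spans = sorted((s, s + l) for s, l in self.planted_windows)
        for (s, e) in spans:
            if s < 0 or e > self.length:
                raise ValidationError(f"planted window {(s, e)} outside alignment")
        for (_, e1), (s2, _) in itertools.pairwise(spans):
            if s2 < e1:
                raise ValidationError("planted windows overlap")


def simulate_alignment(spec: SimSpec) -> tuple[Alignment, list[tuple[int, int]]]:
    """Simulate an alignment; returns it with the planted-window truth.

    Each taxon's row is the ancestral sequence with independent per-site
    substitutions at ``substitution_prob`` (to one of the three other
    bases, uniformly) outside the planted windows, plus optional per-taxon
    gap columns at ``indel_prob`` (also sparing planted windows).
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    ancestor = rng.integers(0, 4, size=L)
    mutable = np.ones(L, dtype=bool)
    for start, length in spec.planted_windows:
        mutable[start : start + length] = False

    rows = []
    for _ in range(spec.n_taxa):
        row = ancestor.copy()
        mut = (rng.random(L) < spec.substitution_prob) & mutable
        # shift by 1..3 mod 4 guarantees a different base
        row[mut] = (row[mut] + rng.integers(1, 4, size=int(mut.sum()))) % 4
        chars = _BASES[row]
        if spec.indel_prob > 0:
            gaps = (rng.random(L) < spec.indel_prob) & mutable
            chars = np.where(gaps, "-", chars)
        rows.append("".join(chars))
    taxa = tuple(f"taxon{i + 1}" for i in range(spec.n_taxa))
    return Alignment(taxa, tuple(rows)), [(s, l) for s, l in spec.planted_windows]


def planted_recovery_rate(
    n_replicates: int = 100,
    seed: int = 0,
    n_taxa: int = 8,
    length: int = 700,
    substitution_prob: float = 0.3,
    window_len: int = 22,
) -> float:
    """Fraction of replicates where design recovers both planted windows.

    Each replicate plants two invariant ``window_len``-bp blocks at seeded
    random positions whose implied amplicon falls inside the default
    200-500 bp band, in an otherwise ``substitution_prob``-divergent
    alignment of ``n_taxa`` rows, then runs the full window-scan/pairing
    design.  A replicate counts as recovered when the top-ranked pair's
    forward primer overlaps the first planted block and its reverse primer
    the second.
    """
    from .primer_design import pair_primers, scan_windows

    rng = np.random.default_rng(seed)
    recovered = 0
    for _ in range(n_replicates):
        s1 = int(rng.integers(40, 120))
        gap = int(rng.integers(230, 400))
        s2 = s1 + window_len + gap
        rep_seed = int(rng.integers(0, 2**31 - 1))
        aln, _ = simulate_alignment(
            SimSpec(
                n_taxa=n_taxa,
                length=length,
                substitution_prob=substitution_prob,
                planted_windows=((s1, window_len), (s2, window_len)),
                seed=rep_seed,
            )
        )
        windows = scan_windows(aln)
        fwd = [w for w in windows if w.orientation == "forward"]
        rev = [w for w in windows if w.orientation == "reverse"]
        pairs = pair_primers(fwd, rev, gene="replicate")
        if not pairs:
            continue
        top = pairs[0]
        f_lo, f_hi = top.fwd_start, top.fwd_start + len(top.forward.core)
        r_lo, r_hi = top.rev_end - len(top.reverse.core) + 1, top.rev_end + 1
        fwd_overlaps = f_lo < s1 + window_len and f_hi > s1
        rev_overlaps = r_lo < s2 + window_len and r_hi > s2
        if fwd_overlaps and rev_overlaps:
            recovered += 1
    return recovered / n_replicates


def _mutate(seq: str, rate: float, rng: np.random.Generator,
            protect: set[int] | None = None) -> str:
    out = list(seq)
    for i, ch in enumerate(out):
        if protect and i in protect:
            continue
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != ch]
            out[i] = choices[rng.integers(0, 3)]
    return "".join(out)


def _oracle_sites(core: str, template: str, max_mm: int, clamp: int) -> tuple[set[int], set[int]]:
    """Brute-force annealing sites: min-over-expansions Hamming matching.

    Independent of the production matcher: enumerates every unambiguous
    expansion of the core and slides it with plain character comparison.
    Returns start positions on the + strand for the core as written and
    for its reverse complement.
    """
    plus: set[int] = set()
    minus: set[int] = set()
    for oriented, bucket in ((core, plus), (reverse_complement(core), minus)):
        clamp_idx = (
            set(range(len(core) - clamp, len(core)))
            if bucket is plus
            else set(range(clamp))
        )
        for exp in expand(oriented):
            for start in range(len(template) - len(exp) + 1):
                window = template[start : start + len(exp)]
                mism = [i for i in range(len(exp)) if window[i] != exp[i]]
                if len(mism) <= max_mm and not (set(mism) & clamp_idx):
                    bucket.add(start)
    return plus, minus


def _oracle_success(fc: str, rc: str, template: str, max_mm: int, clamp: int,
                    size_range: tuple[int, int]) -> bool:
    """Does any in-range product exist, per the brute-force site oracle?"""
    f_plus, f_minus = _oracle_sites(fc, template, max_mm, clamp)
    r_plus, r_minus = _oracle_sites(rc, template, max_mm, clamp)
    lo, hi = size_range
    for f in f_plus:
        for r in r_minus:
            length = r + len(rc) - f
            if r >= f + len(fc) and lo <= length <= hi:
                return True
    for r in r_plus:
        for f in f_minus:
            length = f + len(fc) - r
            if f >= r + len(rc) and lo <= length <= hi:
                return True
    return False


def simulate_templates(
    pair: PrimerPair,
    n_taxa: int = 24,
    divergence_schedule: list[float] | None = None,
    seed: int = 0,
    spacer_len: int = 330,
    flank_len: int = 60,
    clamp_knockout_taxa: set[int] | None = None,
    max_mm: int = 3,
    clamp_mm_free: int = 3,
    size_range: tuple[int, int] = (100, 2000),
) -> tuple[list[tuple[str, str]], dict[str, bool]]:
    """Build per-taxon templates embedding the pair's annealing sites.

    Each template is random flank + a forward-primer site + spacer + a
    reverse-primer site (reverse complemented) + flank.  Sites start from
    a seeded random expansion of each core and are mutated at the taxon's
    scheduled divergence.  ``clamp_knockout_taxa`` forces an incompatible
    substitution into the forward site's 3'-terminal base for the listed
    taxa (0-based), which must abolish amplification under the clamp rule.

    Returns the templates and a ground-truth success table evaluated by
    the brute-force expansion oracle under the stated mismatch policy.
    """
    if divergence_schedule is None:
        divergence_schedule = [0.0] * n_taxa
    if len(divergence_schedule) != n_taxa:
        raise ValidationError("divergence schedule length != n_taxa")
    rng = np.random.default_rng(seed)
    fc, rc = pair.forward.core.upper(), pair.reverse.core.upper()
    templates: list[tuple[str, str]] = []
    truth: dict[str, bool] = {}
    for i, div in enumerate(divergence_schedule):
        fwd_exps = list(expand(fc))
        rev_exps = list(expand(rc))
        fwd_site = fwd_exps[rng.integers(0, len(fwd_exps))]
        rev_site = reverse_complement(rev_exps[rng.integers(0, len(rev_exps))])
        fwd_site = _mutate(fwd_site, div, rng)
        rev_site = _mutate(rev_site, div, rng)
        if clamp_knockout_taxa and i in clamp_knockout_taxa:
            # replace the forward 3'-terminal base with one outside the
            # core's expansion at that position
            pos = len(fwd_site) - 1
            allowed = set(expand(fc[pos]))
            bad = next(b for b in "ACGT" if b not in allowed and b != fwd_site[pos])
            fwd_site = fwd_site[:pos] + bad + fwd_site[pos + 1 :]
        flank5 = "".join(_BASES[rng.integers(0, 4, size=flank_len)])
        flank3 = "".join(_BASES[rng.integers(0, 4, size=flank_len)])
        spacer = "".join(_BASES[rng.integers(0, 4, size=spacer_len)])
        template = flank5 + fwd_site + spacer + rev_site + flank3
        name = f"taxon{i + 1}"
        templates.append((name, template))
        truth[name] = _oracle_success(
            fc, rc, template, max_mm, clamp_mm_free, size_range
        )
    return templates, truth
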