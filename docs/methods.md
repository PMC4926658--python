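# Methods

## Scope and model of the problem

The toolkit automates the desk half of universal-primer development for
Lepidoptera systematics: choosing marker loci from a panel of sequenced
genomes, designing one degenerate primer pair per locus that should anneal
across the order, predicting which taxa a pair will amplify, and scoring
the resulting markers' phylogenetic informativeness. The wet half —
thermal cycling, gels, Sanger reads — is out of scope; amplification
"success" in this package always means the in-silico criterion defined
below.

## Marker screening

A candidate locus is a protein-coding gene that is (a) **single copy** in
every genome of the panel and (b) contains an **exon strictly longer than
500 bp**. The length rule exists because intron lengths vary enormously
between lepidopteran lineages, so a primer pair spanning an intron has an
unpredictable product size; an amplicon must fit inside one exon. The
threshold is strict (`> 500`), so a 500 bp exon fails.

Copy number is decided from tabular homology hits (BLAST outfmt-6): hits
of one gene on the same contig are merged into a locus when separated by
at most `cluster_gap` (default 1000 bp, config-exposed), which unifies the
split HSPs a single divergent locus typically produces; a gene passes only
with exactly one merged locus in *every* panel genome. This is a
deterministic formalization of what is otherwise done by manual curation;
the merge rule is order-independent (intervals are sorted before
merging). Coordinates are 1-based inclusive in files, converted to
half-open arithmetic internally.

## Consensus and window scanning

Each alignment column is collapsed to the **minimal IUPAC code** covering
all non-gap bases observed in it (gap-only columns are errors; `U` maps
to `T`). Minimality is exact because the 15 IUPAC codes are exactly the
non-empty subsets of {A,C,G,T}.

Candidate primer windows are scanned at every start and length in
`len_range` (default 18–27 nt) in both orientations. A window qualifies
when:

* consensus degeneracy ≤ `max_degeneracy` (default 512) — degeneracy is
  the product of per-position expansion sizes, i.e. how many distinct
  oligos the mixture contains; beyond a few hundred the effective
  concentration of the matching oligo becomes too low;
* each of the `clamp_len` = 3 positions at the primer's 3′ end expands to
  ≤ `clamp_max_deg` = 2 bases — 3′ ambiguity, like 3′ mismatch, is what
  prevents polymerase extension. For a forward window the clamp is the
  window's right edge; for a reverse window (whose sequence is the
  reverse complement of the alignment-strand consensus) it is the left
  edge, so the two orientations admit different windows;
* the fraction of single-state non-gap columns ≥ `min_conservation`
  (default 0.5);
* no column is gapped in ≥ `max_gap_frac` (default 0.5) of rows — primers
  cannot span indel-rich regions.

The published constraint the design reproduces exactly is the **amplicon
length band, 200–500 bp inclusive** (short enough for degraded museum
extracts). Window length range, the degeneracy cap, clamp geometry and
the conservation threshold are this package's own documented defaults,
all exposed as configuration, because the upstream web service originally
used for design does not publish its internals. The bundled published
cores range ~14–35 nt, so the window range is a knob, not a claim.

## Pairing and ranking

A forward window at column *f* and a non-overlapping reverse window
ending at column *r* form a pair with `amplicon_len = r − f + 1` (primers
included) and `marker_len = amplicon_len − |forward| − |reverse|` (the
primer-trimmed sequence; this is the length reported by the statistics
module, matching how sequenced markers are trimmed before alignment).
Pairs are ranked by

    score = mean(conservation_f, conservation_r) − λ·log₂(deg_f · deg_r),   λ = 0.02

with ties broken by lower total degeneracy, then smaller forward start.
Design is fully deterministic; there is no stochastic tie-shuffling.

Because the score is separable into per-window quality, the pairing step
optionally thins each orientation to its `max_windows_per_orientation`
best windows (default 300 in the high-level entry points, unlimited in
`pair_primers` itself) before the quadratic join. Windows tied at the
quality cutoff are sampled evenly along the alignment rather than taken
in positional order: on a near-invariant alignment thousands of windows
tie, and a positional cut would leave one orientation with no partners in
range.

## Melting temperatures

A degenerate primer is a mixture, so it has a Tm *range*. The bounds are
computed by nearest-neighbor thermodynamics (unified parameter set,
entropy salt correction at 50 mM monovalent Na⁺, 0.25 µM primer, via
Biopython's `MeltingTemp.Tm_NN`) on two extreme expansions: choosing at
every ambiguous position the weakest-stacking available base
(A > T > C > G preference) for the lower bound and the strongest
(G > C > T > A) for the upper. Degeneracy-1 primers therefore get
`tm_low == tm_high`. Cores shorter than 8 nt are rejected (outside the
NN model's sensible domain). Tails are excluded from Tm: they do not
anneal in the first cycles. The unit tests check the implementation
against an independent hand-coded NN summation to 0.5 °C.

## Universal tails

Forward primers carry the T7-promoter tail `TAATACGACTCACTATAGGG`,
reverse primers the T3 tail `ATTAACCCTCACTAAAGGG`, both prepended at the
5′ end so a single pair of sequencing primers reads every amplicon.
Tails are annotation: they are excluded from annealing-site matching and
from Tm. Attaching tails twice is an error, not a no-op. In the bundled
published resource the tail is recognized case-insensitively and
everything 3′ of it — including uppercase non-degenerate clamp segments —
is kept as core; a primer lacking its expected tail is flagged, never
silently truncated. The resource preserves the published case convention
(uppercase tail/clamp, lowercase degenerate core) as typography only.

## In-silico PCR

Two IUPAC codes are **compatible** when their expansion sets intersect;
this treats primer degeneracy and template ambiguity symmetrically and
equals min-over-expansions Hamming matching (oracle-verified in the
tests). A core anneals at a site when at most `max_mm` = 3 positions are
incompatible and the 3′-terminal `clamp_mm_free` = 3 positions are all
compatible. Both strands are searched via 4-bit base masks and a sliding
window, so matching is vectorized and strand-symmetric. A pair predicts a
product for every forward site with a downstream convergent reverse site
whose length (both primers included) lies in `size_range` (default
100–2000 bp); nothing is suppressed for nesting. Success = at least one
in-range product — an explicit, configurable stand-in for "a band on the
gel". Reported coordinates are 1-based inclusive on the + strand.

## Marker statistics

Site classification treats gaps, `N` and `?` as missing data: a column
with ≤ 1 distinct observed state is conserved (an all-missing column
counts as conserved by convention and is flagged in the report), one with
≥ 2 states each in ≥ 2 sequences is parsimony-informative, any other
variable column is a singleton. Percentages are over all alignment
columns and rounded half-up to one decimal, which is why
`variable + conserved` can miss 100.0 by 0.1 in tabulated data. Base
frequencies pool all non-missing characters across sequences. The
bundled 38-row evaluation panel (30 new markers + 8 standard reference
genes: CAD, COI, EF1a, GAPDH, IDH, MDH, RpS5, wingless) is data, not a
recomputation — the underlying per-taxon alignments are not shipped —
and the panel-comparison function summarizes min/mean/max variability
and the extreme genes per panel. The locus tabulated as "ArgK" is also
known as "ArgKin"; the resource records the alias.

## Synthetic data

`simulate_alignment` uses a star topology: one random ancestral sequence,
each taxon mutated independently at a per-site substitution probability
(uniform replacement among the three other bases — Jukes–Cantor-like, no
rate heterogeneity, no shared internal branches), except inside *planted
windows*, which stay invariant and are returned as ground truth.
Optional per-taxon gaps are sprinkled at `indel_prob`. This is
deliberately not a phylogenetic simulator: it is sufficient for
planted-structure recovery tests and keeps the expected pairwise
divergence in closed form, `q = 1 − ((1−p)² + p²/3)`, which the tests
verify. Real data differ in having tree structure, rate variation among
sites and lineages, and real indel processes, so passing recovery tests
demonstrate correctness of the design machinery, not field performance.

`simulate_templates` embeds a seeded random expansion of each core
(reverse primer site reverse-complemented) around a fixed spacer, mutates
the sites on a per-taxon divergence schedule, and emits a ground-truth
success table computed by an independent brute-force oracle (explicit
expansion enumeration + Hamming matching + product geometry) under the
same default mismatch policy; the tests require the production matcher to
agree exactly. All generators take mandatory integer seeds and are
byte-reproducible.

The recovery experiment used by the acceptance script runs 100
replicates of an 8-taxon, 700-bp, 30%-divergence alignment (matching the
size of the original eight-genome design panel) with two planted 22-bp
windows at seeded random positions whose implied amplicon falls inside
the 200–500 bp band; a replicate is recovered when the top-ranked pair's
primers overlap both planted windows.

## Command-line interface

`lepiprime` exposes the stages as subcommands (`screen`, `design`, `pcr`,
`stats`, `simulate`, `primers`). Parameter precedence is defaults <
flags < config file — the flat `key = value` config wins, so a recorded
config reproduces a run exactly; unknown config keys are rejected and all
effective parameters are logged to stderr. Exit codes: 2 for missing
inputs, 1 for validation failures.

## Known limitations

* No hairpin/self-dimer/cross-dimer screening and no codon-aware
  (protein-guided) design; degeneracy, conservation, clamp and Tm are the
  only quality axes.
* The Tm extremes are per-position greedy (weakest/strongest base at each
  ambiguous site); for the unified NN parameters this brackets the
  mixture in practice, but it is a heuristic, not a proven min/max over
  all expansions.
* The in-silico success criterion ignores annealing kinetics and
  polymerase behaviour; it cannot distinguish PCR failure from sequencing
  failure, and the bundled evaluation panel does not either.
* The single-copy filter counts merged homology loci; it is not an
  orthology inference.
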