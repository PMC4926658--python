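# lepiprime

Universal degenerate PCR primer design and evaluation for phylogenetic
marker loci in lepidopteran nuclear genomes.

## The problem

Molecular systematics of Lepidoptera leans on millions of legacy genomic
DNA extracts — often a single dried leg's worth, stored for years — that
yield too little and too degraded DNA for genome-scale methods, but
amplify fine with PCR. The limiting resource is *primers*: a locus is only
useful across a family or the whole order if one degenerate primer pair
anneals in every lineage and amplifies a short (200–500 bp), single-copy,
protein-coding fragment informative enough to resolve trees.

`lepiprime` implements that discovery-and-design pipeline end to end:

1. **marker_screen** — select candidate genes from a genome panel:
   single-copy (exactly one merged homology locus per genome, split HSPs
   within 1 kb unified) with an exon strictly longer than 500 bp, so a
   complete amplicon fits inside one exon regardless of intron-length
   variation between taxa.
2. **primer_design** — from a multi-species alignment of the exon, build
   the minimal IUPAC consensus per column, scan 18–27 bp windows with
   bounded degeneracy (≤ 512), a low-degeneracy 3′ clamp, and ≥ 50%
   conserved columns; pair forward/reverse windows under the inclusive
   200–500 bp amplicon constraint; rank by
   `mean(conservation) − 0.02·log₂(degeneracy product)`; bracket each
   primer's nearest-neighbor melting temperature over its extreme
   expansions; and prepend the universal sequencing tails
   (T7 promoter `TAATACGACTCACTATAGGG` to forward primers, T3
   `ATTAACCCTCACTAAAGGG` to reverse primers) so one sequencing-primer
   pair reads every amplicon.
3. **insilico_pcr** — degenerate-aware, mismatch-tolerant annealing-site
   search (compatibility = non-empty intersection of IUPAC expansion
   sets; ≤ 3 mismatches, none in the 3′-terminal 3 nt), amplicon
   prediction on both strands, and gene × taxon success matrices with
   margin summaries.
4. **align_stats** — per-marker informativeness: variable, parsimony-
   informative and conserved site percentages and pooled base
   frequencies, plus comparison of a new-marker panel against the
   standard reference genes.
5. **synthetic** — seeded generators for alignments with planted
   invariant windows and for PCR templates with scheduled per-taxon
   divergence, each emitting ground truth for oracle-checked testing.

The package also ships, as machine-readable data, the published resource
of 30 universal primer pairs for new nuclear gene regions (with their
tails), the 38-gene marker-statistics panel (30 new + 8 standard
reference genes), and the 24-taxon test panel they were evaluated on.

## Worked example

Design primers against a synthetic 8-taxon alignment (30% per-site
divergence) with two planted 22-bp conserved blocks:

```python
from lepiprime import SimSpec, simulate_alignment, design_primers, marker_report

spec = SimSpec(n_taxa=8, length=700, substitution_prob=0.3,
               planted_windows=((100, 22), (430, 22)), seed=5)
aln, planted = simulate_alignment(spec)
best = design_primers(aln, gene="locus1", top=1)[0]
print(f"forward : {best.forward.full_sequence}")
print(f"reverse : {best.reverse.full_sequence}")
print(f"columns : {best.fwd_start}..{best.rev_end}  amplicon {best.amplicon_len} bp, "
      f"marker {best.marker_len} bp, score {best.score:.3f}")
print(f"Tm range: {best.forward.tm_low:.1f}-{best.forward.tm_high:.1f} C (forward), "
      f"{best.reverse.tm_low:.1f}-{best.reverse.tm_high:.1f} C (reverse)")
r = marker_report(aln, "locus1")
print(f"stats   : variable {r.variable_pct}%  pars.inf. {r.parsinf_pct}%  conserved {r.conserved_pct}%")
```

prints

```
forward : TAATACGACTCACTATAGGGTATTCCTTGCATCGGACG
reverse : ATTAACCCTCACTAAAGGGACAGTCCGCAGTATGCAA
columns : 100..447  amplicon 348 bp, marker 312 bp, score 1.000
Tm range: 53.4-53.4 C (forward), 55.4-55.4 C (reverse)
stats   : variable 88.6%  pars.inf. 48.0%  conserved 11.4%
```

The top-ranked pair sits exactly on the two planted blocks (columns
100 and 430): each full sequence is the universal tail plus an 18-nt
degeneracy-1 core (hence the single-valued Tm), the amplicon spans 348 bp
including primers, and trimming the primers leaves a 312-bp marker. The
`marker_report` line is the marker-statistics summary of the same alignment:
at 30% divergence nearly every unplanted column varies, and 48% of
columns are parsimony-informative.

The same stages are scriptable from the shell:

```sh
lepiprime primers                      # dump the bundled 30-pair resource
lepiprime design locus1.fasta --top 5  # scan -> pair -> tails
lepiprime pcr templates.fasta          # in-silico PCR + success matrix
lepiprime stats locus1.fasta           # marker informativeness TSV
lepiprime --seed 11 simulate --plant 100:22 --plant 430:22
```

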