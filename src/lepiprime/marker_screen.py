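"""Candidate marker screening: long single-copy exons across a genome panel.

A locus is a usable PCR marker only if (a) some exon is long enough that a
200-500 bp amplicon fits inside it regardless of intron-length variation
between taxa, and (b) the gene is single copy in every genome of the panel,
so universal primers amplify orthologues rather than paralogues.  This
module formalizes both filters over standard file formats: exon models in
GFF3-like tab format and homology hits in BLAST tabular (outfmt 6) format.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from .seqio import ParseError, ValidationError

__all__ = [
    "ExonRecord",
    "HomologyHit",
    "read_exon_gff",
    "read_homology_hits",
    "screen_exons",
    "merge_loci",
    "single_copy_filter",
]


@dataclass(frozen=True)
class ExonRecord:
    """One exon on a genome contig; coordinates are 1-based inclusive."""

    genome_id: str
    gene_id: str
    exon_id: str
    contig: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValidationError(
                f"exon {self.exon_id}: bad coordinates {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HomologyHit:
    """One homology-search hit of a query gene against a genome."""

    query_gene: str
    genome_id: str
    contig: str
    start: int
    end: int
    bitscore: float
    identity: float

    def __post_init__(self) -> None:
        if min(self.start, self.end) < 1:
            raise ValidationError(f"hit for {self.query_gene}: non-positive coordinate")
        if not 0 <= self.identity <= 100:
            raise ValidationError(f"hit for {self.query_gene}: identity out of [0,100]")


_GENE_ID_RE = re.compile(r'gene_id[ =]+"?([^";]+)"?')


def read_exon_gff(path: str | Path, genome_id: str) -> list[ExonRecord]:
    """Read exon features from a GFF3-like tab file.

    Only ``type == exon`` rows are kept.  The gene identifier is taken from
    a ``gene_id`` key in the attributes column (GTF or GFF3 style); the
    exon id from an ``exon_id``/``ID`` key when present, else synthesized.
    """
    path = Path(path)
    exons: list[ExonRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}:{lineno}: expected 9 tab-separated columns")
            contig, _source, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype != "exon":
                continue
            m = _GENE_ID_RE.search(attrs)
            if not m:
                raise ParseError(f"{path}:{lineno}: no gene_id in attributes")
            gene = m.group(1)
            em = re.search(r'(?:exon_id|ID)[ =]+"?([^";]+)"?', attrs)
            exon_id = em.group(1) if em else f"{gene}.exon{len(exons) + 1}"
            exons.append(
                ExonRecord(
                    genome_id=genome_id,
                    gene_id=gene,
                    exon_id=exon_id,
                    contig=contig,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                )
            )
    return exons


def read_homology_hits(path: str | Path, genome_id: str) -> list[HomologyHit]:
    """Read BLAST outfmt-6 rows (qseqid sseqid pident ... sstart send evalue bitscore)."""
    path = Path(path)
    hits: list[HomologyHit] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: expected >=12 outfmt-6 columns")
            sstart, send = int(f[8]), int(f[9])
            hits.append(
                HomologyHit(
                    query_gene=f[0],
                    genome_id=genome_id,
                    contig=f[1],
                    start=min(sstart, send),
                    end=max(sstart, send),
                    bitscore=float(f[11]),
                    identity=float(f[2]),
                )
            )
    return hits


def screen_exons(exons: list[ExonRecord], min_exon_len: int = 500) -> set[str]:
    """Genes having at least one exon strictly longer than ``min_exon_len``.

    The length threshold is strict: a 500 bp exon does not pass the default.
    """
    selected: set[str] = set()
    for exon in exons:
        if exon.length > min_exon_len:
            selected.add(exon.gene_id)
    return selected


def merge_loci(
    intervals: list[tuple[int, int]], cluster_gap: int = 1000
) -> list[tuple[int, int]]:
    """Merge intervals on one contig whose gap is at most ``cluster_gap`` bp.

    Split HSPs of a single locus are thereby unified; order-independent.
    """
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start - merged[-1][1] - 1 <= cluster_gap:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def single_copy_filter(
    hits: list[HomologyHit], genomes: set[str], cluster_gap: int = 1000
) -> set[str]:
    """Genes with exactly one merged homology locus in every panel genome.

    Hits on the same contig within ``cluster_gap`` bp of each other count
    as one locus (split HSPs of one alignment); a gene absent from any
    genome in ``genomes``, or with two or more distinct loci anywhere in
    the panel, fails.
    """
    per_gene: dict[str, dict[str, dict[str, list[tuple[int, int]]]]] = {}
    for h in hits:
        per_gene.setdefault(h.query_gene, {}).setdefault(h.genome_id, {}).setdefault(
            h.contig, []
        ).append((h.start, h.end))

    passing: set[str] = set()
    for gene, by_genome in per_gene.items():
        if set(genomes) - set(by_genome):
            continue  # missing from some genome
        ok = True
        for genome in genomes:
            n_loci = sum(
                len(merge_loci(iv, cluster_gap)) for iv in by_genome[genome].values()
            )
            if n_loci != 1:
                ok = False
                break
        if ok:
            passing.add(gene)
    return passing
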