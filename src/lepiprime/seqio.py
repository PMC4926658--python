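"""Sequence I/O, IUPAC nucleotide algebra, and the bundled primer resource.

The degenerate-primer toolkit manipulates three kinds of sequence objects:
plain FASTA records, multiple sequence alignments, and IUPAC-coded
oligonucleotides.  This module provides the 15-letter IUPAC ambiguity-code
algebra (expansion, complement, degeneracy, minimal consensus codes) that
everything downstream builds on, plus the parser for the published resource
of 30 universal primer pairs that ships with the package.

The published primers carry constant 5' sequencing tails: the T7-promoter
sequence on every forward primer and the T3 sequence on every reverse
primer, so a single pair of sequencing primers works for all amplicons.
Only the gene-specific core anneals to the target; tails are annotation.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "LepiprimeError",
    "ParseError",
    "ValidationError",
    "IUPAC_EXPANSION",
    "MASK_FOR",
    "CODE_FOR_SET",
    "T7_FORWARD_TAIL",
    "T3_REVERSE_TAIL",
    "GENE_ALIASES",
    "expansion",
    "code_for",
    "complement",
    "reverse_complement",
    "degeneracy",
    "expand",
    "Alignment",
    "DegeneratePrimer",
    "PrimerTable",
    "read_fasta",
    "read_alignment",
    "write_fasta",
    "parse_primer_table",
    "load_bundled_primers",
    "bundled_data_path",
]


class LepiprimeError(Exception):
    """Base class for all toolkit errors."""


class ParseError(LepiprimeError):
    """Malformed input file or record."""


class ValidationError(LepiprimeError):
    """Input violated a documented precondition."""


# ---------------------------------------------------------------------------
# IUPAC nucleotide algebra
# ---------------------------------------------------------------------------

IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

CODE_FOR_SET: dict[frozenset[str], str] = {v: k for k, v in IUPAC_EXPANSION.items()}

_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

# 4-bit base masks (A=1, C=2, G=4, T=8) used for fast compatibility tests.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
MASK_FOR: dict[str, int] = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC_EXPANSION.items()
}

T7_FORWARD_TAIL = "TAATACGACTCACTATAGGG"
T3_REVERSE_TAIL = "ATTAACCCTCACTAAAGGG"

# The locus called "ArgK" in the tabulated resource is referred to as
# "ArgKin" elsewhere in the literature; both names resolve to the same gene.
GENE_ALIASES: dict[str, str] = {"ArgKin": "ArgK"}


def _normalize(symbol: str, pos: int, context: str) -> str:
    """Uppercase one symbol, map U->T, reject anything outside the alphabet."""
    s = symbol.upper()
    if s == "U":
        s = "T"
    if s not in IUPAC_EXPANSION:
        raise ValidationError(
            f"{context}: non-IUPAC character {symbol!r} at position {pos}"
        )
    return s


def expansion(symbol: str) -> frozenset[str]:
    """Set of unambiguous bases denoted by one IUPAC code (case-insensitive)."""
    return IUPAC_EXPANSION[_normalize(symbol, 0, "expansion")]


def code_for(bases: frozenset[str] | set[str]) -> str:
    """Minimal IUPAC code covering a non-empty set of unambiguous bases."""
    key = frozenset(bases)
    if key not in CODE_FOR_SET:
        raise ValidationError(f"no IUPAC code for base set {sorted(bases)}")
    return CODE_FOR_SET[key]


def complement(seq: str) -> str:
    out = []
    for i, ch in enumerate(seq):
        out.append(_COMPLEMENT[_normalize(ch, i, "complement")])
    return "".join(out)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the full 15-letter IUPAC alphabet.

    Ambiguity codes map to the code of the complemented base set
    (R<->Y, S<->S, W<->W, K<->M, B<->V, D<->H, N<->N), so the operation
    is an involution on any IUPAC string.
    """
    return complement(seq)[::-1]


def degeneracy(seq: str) -> int:
    """Number of distinct unambiguous oligos a degenerate sequence denotes.

    The product of per-position expansion sizes.  Gaps are not part of an
    oligo and are rejected.
    """
    d = 1
    for i, ch in enumerate(seq):
        if ch == "-":
            raise ValidationError(f"degeneracy: gap at position {i}")
        d *= len(IUPAC_EXPANSION[_normalize(ch, i, "degeneracy")])
    return d


def expand(seq: str) -> Iterator[str]:
    """Yield every unambiguous expansion of a degenerate sequence.

    Intended for small degeneracies (oracles, clamp checks); the number of
    expansions is ``degeneracy(seq)``.
    """
    sets = [sorted(IUPAC_EXPANSION[_normalize(c, i, "expand")]) for i, c in enumerate(seq)]

    def rec(i: int, prefix: list[str]) -> Iterator[str]:
        if i == len(sets):
            yield "".join(prefix)
            return
        for b in sets[i]:
            prefix.append(b)
            yield from rec(i + 1, prefix)
            prefix.pop()

    yield from rec(0, [])


# ---------------------------------------------------------------------------
# FASTA and alignments
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Alignment:
    """A multiple sequence alignment: equal-length IUPAC rows with labels."""

    taxa: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise ValidationError("taxa and rows differ in number")
        if not self.rows:
            raise ValidationError("alignment has no sequences")
        if any(not t for t in self.taxa):
            raise ValidationError("empty taxon label")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon labels")
        L = len(self.rows[0])
        if any(len(r) != L for r in self.rows):
            raise ValidationError("alignment rows have unequal lengths")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_taxa(self) -> int:
        return len(self.rows)

    def column(self, i: int) -> tuple[str, ...]:
        return tuple(r[i] for r in self.rows)

    @classmethod
    def from_records(cls, records: list[tuple[str, str]]) -> "Alignment":
        return cls(tuple(n for n, _ in records), tuple(s for _, s in records))


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (label, sequence) pairs, order preserved.

    Gaps and case are retained untouched.  Zero-length records and empty
    files raise :class:`ParseError` naming the offending record.
    """
    path = Path(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not rec.id:
            raise ParseError(f"{path}: record with empty header")
        if not seq:
            raise ParseError(f"{path}: zero-length record {rec.id!r}")
        records.append((rec.description or rec.id, seq))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def read_alignment(path: str | Path) -> Alignment:
    """Read an aligned FASTA file, requiring equal-length rows."""
    return Alignment.from_records(read_fasta(path))


def write_fasta(records: list[tuple[str, str]] | Alignment, path: str | Path) -> None:
    """Write records (or an Alignment) as FASTA, one line per sequence."""
    if isinstance(records, Alignment):
        records = list(zip(records.taxa, records.rows))
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


# ---------------------------------------------------------------------------
# Degenerate primers and the bundled primer resource
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegeneratePrimer:
    """An IUPAC-coded oligo, optionally carrying a constant 5' tail.

    ``core`` is the gene-specific annealing part (everything 3' of the
    tail, including any non-degenerate clamp written in uppercase in the
    published resource); only the core is matched against templates.
    The full synthesized sequence is ``tail + core`` read 5'->3'.
    """

    name: str
    core: str
    orientation: str  # "forward" | "reverse"
    tail: str = ""
    tm_low: float | None = None
    tm_high: float | None = None
    flagged: str = ""  # non-empty when the record violated a contract

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValidationError(f"bad orientation {self.orientation!r}")
        if not self.core:
            raise ValidationError(f"primer {self.name}: empty core")
        degeneracy(self.core)  # validates the alphabet
        if self.tm_low is not None and self.tm_high is not None:
            if self.tm_low > self.tm_high + 1e-9:
                raise ValidationError(f"primer {self.name}: tm_low > tm_high")

    @property
    def degeneracy(self) -> int:
        return degeneracy(self.core)

    @property
    def full_sequence(self) -> str:
        return self.tail + self.core


@dataclass
class PrimerTable:
    """The paired primer resource: one forward + one reverse primer per gene."""

    pairs: list[tuple[str, DegeneratePrimer, DegeneratePrimer]] = field(
        default_factory=list
    )
    aliases: dict[str, str] = field(default_factory=lambda: dict(GENE_ALIASES))

    def __post_init__(self) -> None:
        genes = [g for g, _, _ in self.pairs]
        if len(set(genes)) != len(genes):
            raise ValidationError("duplicate gene names in primer table")

    @property
    def genes(self) -> list[str]:
        return [g for g, _, _ in self.pairs]

    def get(self, gene: str) -> tuple[str, DegeneratePrimer, DegeneratePrimer]:
        gene = self.aliases.get(gene, gene)
        for row in self.pairs:
            if row[0] == gene:
                return row
        raise KeyError(gene)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)


def _split_tail(name: str, seq: str) -> tuple[str, str, str, str]:
    """Return (orientation, tail, core, flag) for one primer record."""
    if name.endswith("_F"):
        orientation, tail = "forward", T7_FORWARD_TAIL
    elif name.endswith("_R"):
        orientation, tail = "reverse", T3_REVERSE_TAIL
    else:
        raise ParseError(f"primer {name!r}: name must end in _F or _R")
    if seq.upper().startswith(tail):
        # everything after the constant tail is core, case preserved
        return orientation, seq[: len(tail)], seq[len(tail):], ""
    return orientation, "", seq, f"missing expected {orientation} tail"


def parse_primer_table(path: str | Path) -> PrimerTable:
    """Parse a TSV of (name, full sequence) rows into paired primers.

    Names are suffixed ``_F``/``_R``; the known constant tails are
    recognised case-insensitively and split off.  A primer lacking its
    expected tail is kept but flagged, never silently truncated.  A gene
    with a missing mate raises :class:`ParseError`.
    """
    path = Path(path)
    by_gene: dict[str, dict[str, DegeneratePrimer]] = {}
    order: list[str] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.lower().startswith("name\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
            name, seq = parts[0].strip(), parts[1].strip()
            orientation, tail, core, flag = _split_tail(name, seq)
            primer = DegeneratePrimer(
                name=name, core=core, tail=tail, orientation=orientation, flagged=flag
            )
            gene = name[:-2]
            if gene not in by_gene:
                by_gene[gene] = {}
                order.append(gene)
            if orientation in by_gene[gene]:
                raise ParseError(f"{path}: duplicate {orientation} primer for {gene}")
            by_gene[gene][orientation] = primer
    pairs = []
    for gene in order:
        d = by_gene[gene]
        if set(d) != {"forward", "reverse"}:
            raise ParseError(f"{path}: gene {gene} lacks a complete primer pair")
        pairs.append((gene, d["forward"], d["reverse"]))
    return PrimerTable(pairs=pairs)


def bundled_data_path(filename: str) -> Path:
    """Path to a data file shipped inside the package."""
    return Path(importlib.resources.files("lepiprime") / "data" / filename)


def load_bundled_primers() -> PrimerTable:
    """Load the published resource of 30 universal primer pairs."""
    return parse_primer_table(bundled_data_path("primer_pairs.tsv"))
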