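"""In-silico PCR: degenerate-aware primer matching and success matrices.

Wet-lab amplification success is operational (a band on a gel); the
in-silico analogue makes the policy explicit: a primer anneals where at
most ``max_mm`` template positions are IUPAC-incompatible with the core
and the 3'-terminal ``clamp_mm_free`` positions all match, and a pair
amplifies a template when a forward site and a downstream reverse site
bracket a product of plausible size.  Compatibility between two IUPAC
codes means their expansion sets intersect, so degenerate primers and
ambiguous template bases are handled symmetrically.

Per-gene, per-taxon outcomes are collected into a boolean success matrix
with the margin summaries used to compare markers: how many taxa each
gene amplified from, and how many genes each taxon yielded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import (
    DegeneratePrimer,
    MASK_FOR,
    ValidationError,
    bundled_data_path,
    reverse_complement,
)
from .primer_design import PrimerPair

__all__ = [
    "AnnealSite",
    "AmpliconHit",
    "SuccessMatrix",
    "match_primer",
    "predict_amplicons",
    "build_success_matrix",
    "load_test_taxa",
]


@dataclass(frozen=True)
class AnnealSite:
    """One primer annealing site; ``start`` is 0-based on the + strand."""

    start: int
    strand: str  # "+": core reads left-to-right on the + strand
    mismatches: int

    @property
    def position(self) -> int:
        """1-based leftmost template coordinate."""
        return self.start + 1


@dataclass(frozen=True)
class AmpliconHit:
    """A predicted PCR product; coordinates 1-based inclusive, + strand."""

    template_id: str
    strand: str  # strand the forward primer anneals in ("+" or "-")
    fwd_start: int
    rev_end: int
    amplicon_len: int
    fwd_mismatches: int
    rev_mismatches: int

    def __post_init__(self) -> None:
        if self.amplicon_len != self.rev_end - self.fwd_start + 1:
            raise ValidationError("amplicon_len inconsistent with coordinates")


def _encode(seq: str, context: str) -> np.ndarray:
    out = np.zeros(len(seq), dtype=np.uint8)
    for i, ch in enumerate(seq):
        c = ch.upper()
        if c == "U":
            c = "T"
        if c not in MASK_FOR:
            raise ValidationError(f"{context}: non-IUPAC character {ch!r} at position {i}")
        out[i] = MASK_FOR[c]
    return out


def _scan(core_mask: np.ndarray, tpl_mask: np.ndarray, max_mm: int,
          clamp_slice: slice) -> list[tuple[int, int]]:
    """(start, mismatches) of every admissible placement of core on template."""
    k, n = len(core_mask), len(tpl_mask)
    if k > n:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(tpl_mask, k)
    compat = (windows & core_mask) != 0
    mm = k - compat.sum(axis=1)
    ok = (mm <= max_mm) & compat[:, clamp_slice].all(axis=1)
    return [(int(i), int(mm[i])) for i in np.flatnonzero(ok)]


def match_primer(
    primer: DegeneratePrimer | str,
    template: str,
    max_mm: int = 3,
    clamp_mm_free: int = 3,
) -> list[AnnealSite]:
    """Find annealing sites of a degenerate primer core on both strands.

    Only the core anneals; tails are ignored.  A position is a mismatch
    when the expansions of the primer and template codes are disjoint.
    Sites violating the mismatch-free 3' clamp are discarded.  "+" sites
    are occurrences of the core itself on the + strand (primer extends
    rightward); "-" sites are occurrences of its reverse complement
    (primer anneals to the + strand and extends leftward).
    """
    core = primer.core if isinstance(primer, DegeneratePrimer) else primer
    if not core:
        raise ValidationError("empty primer core")
    clamp = min(clamp_mm_free, len(core))
    tpl = _encode(template, "template")
    fwd_mask = _encode(core, "primer core")
    rev_mask = _encode(reverse_complement(core), "primer core")
    sites = [
        AnnealSite(i, "+", m)
        for i, m in _scan(fwd_mask, tpl, max_mm, slice(len(core) - clamp, len(core)))
    ]
    # reverse-complemented placement: the primer 3' end maps to the window's left edge
    sites += [
        AnnealSite(i, "-", m) for i, m in _scan(rev_mask, tpl, max_mm, slice(0, clamp))
    ]
    sites.sort(key=lambda s: (s.start, s.strand))
    return sites


def predict_amplicons(
    pair: PrimerPair,
    templates: list[tuple[str, str]],
    size_range: tuple[int, int] = (100, 2000),
    max_mm: int = 3,
    clamp_mm_free: int = 3,
) -> list[AmpliconHit]:
    """Predict every PCR product of a primer pair on a template collection.

    Each combination of a forward site and a downstream, convergently
    oriented reverse site whose product length falls in ``size_range`` is
    reported; nested and overlapping products are all kept.  Zero hits on
    a template is a predicted amplification failure, not an error.
    """
    lo, hi = size_range
    fc, rc = pair.forward.core, pair.reverse.core
    hits: list[AmpliconHit] = []
    for tpl_id, seq in templates:
        fsites = match_primer(pair.forward, seq, max_mm, clamp_mm_free)
        rsites = match_primer(pair.reverse, seq, max_mm, clamp_mm_free)
        # product on the + strand: forward core at f (+), reverse core RC at r (-)
        for f in (s for s in fsites if s.strand == "+"):
            for r in (s for s in rsites if s.strand == "-"):
                end = r.start + len(rc) - 1
                length = end - f.start + 1
                if r.start >= f.start + len(fc) and lo <= length <= hi:
                    hits.append(
                        AmpliconHit(tpl_id, "+", f.start + 1, end + 1, length,
                                    f.mismatches, r.mismatches)
                    )
        # product on the - strand: reverse core at r (+), forward core RC at f (-)
        for r in (s for s in rsites if s.strand == "+"):
            for f in (s for s in fsites if s.strand == "-"):
                end = f.start + len(fc) - 1
                length = end - r.start + 1
                if f.start >= r.start + len(rc) and lo <= length <= hi:
                    hits.append(
                        AmpliconHit(tpl_id, "-", r.start + 1, end + 1, length,
                                    f.mismatches, r.mismatches)
                    )
    return hits


@dataclass
class SuccessMatrix:
    """Gene x taxon amplification outcomes with margin summaries."""

    table: pd.DataFrame  # bool, index=genes, columns=taxa

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.table.columns)

    @property
    def per_gene(self) -> pd.Series:
        """Taxa amplified per gene."""
        return self.table.sum(axis=1)

    @property
    def per_taxon(self) -> pd.Series:
        """Genes amplified per taxon."""
        return self.table.sum(axis=0)

    def summary(self) -> dict[str, float]:
        pg, pt = self.per_gene, self.per_taxon
        return {
            "per_gene_min": int(pg.min()) if len(pg) else 0,
            "per_gene_max": int(pg.max()) if len(pg) else 0,
            "per_gene_mean": float(pg.mean()) if len(pg) else 0.0,
            "per_taxon_min": int(pt.min()) if len(pt) else 0,
            "per_taxon_max": int(pt.max()) if len(pt) else 0,
            "per_taxon_mean": float(pt.mean()) if len(pt) else 0.0,
        }

    def to_tsv(self, path) -> None:
        out = self.table.astype(int).copy()
        out["n_taxa_successful"] = self.per_gene
        out.to_csv(path, sep="\t")


def build_success_matrix(
    results: list[tuple[str, str, bool | list]],
    genes: list[str] | None = None,
    taxa: list[str] | None = None,
) -> SuccessMatrix:
    """Assemble (gene, taxon, outcome) records into a success matrix.

    ``outcome`` may be a boolean or a list of :class:`AmpliconHit`; a
    non-empty hit list counts as success.  Duplicate (gene, taxon) records
    are an error.  Cells without a record are failures.
    """
    seen: set[tuple[str, str]] = set()
    cells: dict[tuple[str, str], bool] = {}
    gene_order: list[str] = list(genes) if genes else []
    taxon_order: list[str] = list(taxa) if taxa else []
    for gene, taxon, outcome in results:
        key = (gene, taxon)
        if key in seen:
            raise ValidationError(f"duplicate result for gene {gene!r}, taxon {taxon!r}")
        seen.add(key)
        cells[key] = bool(outcome) if isinstance(outcome, bool) else len(outcome) > 0
        if genes is None and gene not in gene_order:
            gene_order.append(gene)
        if taxa is None and taxon not in taxon_order:
            taxon_order.append(taxon)
    table = pd.DataFrame(False, index=gene_order, columns=taxon_order, dtype=bool)
    for (gene, taxon), ok in cells.items():
        if gene in table.index and taxon in table.columns:
            table.loc[gene, taxon] = ok
    return SuccessMatrix(table=table)


def load_test_taxa() -> pd.DataFrame:
    """The bundled 24-taxon test panel with per-taxon success counts.

    Columns: voucher, family, genus, species, n_genes_sequenced.  The
    panel spans the order's major lineages, from early-diverging
    (non-ditrysian) families through derived Ditrysia.
    """
    return pd.read_csv(bundled_data_path("test_taxa.tsv"), sep="\t")
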