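"""Per-marker informativeness statistics and panel comparisons.

For each sequenced marker alignment we report the site-class breakdown a
systematist uses to judge phylogenetic utility: the percentage of variable
columns, of parsimony-informative columns (at least two states each seen
in at least two sequences — the columns that can discriminate between tree
topologies under parsimony), their complement (conserved columns), and the
pooled base composition.  A comparison helper summarizes a panel of new
markers against a reference panel of standard genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .seqio import Alignment, ValidationError, bundled_data_path

__all__ = [
    "MarkerReport",
    "classify_column",
    "marker_report",
    "panel_compare",
    "reports_to_frame",
    "load_marker_panel",
    "panel_reports",
]

_MISSING = {"-", "N", "n", "?"}


def _round1(x: float) -> float:
    """Round half-up to one decimal, as tabulated reports conventionally do."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class MarkerReport:
    """One row of marker statistics; percentages to one decimal."""

    gene: str
    length: int
    variable_pct: float
    parsinf_pct: float
    conserved_pct: float
    freq_A: float
    freq_T: float
    freq_C: float
    freq_G: float
    n_success: int | None = None
    gene_db_id: str | None = None
    all_missing_columns: int = 0  # flagged: counted as conserved by convention


def classify_column(column: tuple[str, ...] | list[str]) -> str:
    """Classify one alignment column for parsimony analysis.

    Gaps, ``N`` and ``?`` are missing data, not states.  A column with at
    most one distinct observed state is ``conserved`` (an all-missing
    column falls here by convention and is flagged upstream); one with at
    least two states each present in at least two sequences is
    ``parsimony_informative``; any other variable column carries only
    singleton variation and is ``variable_uninformative``.
    """
    counts: dict[str, int] = {}
    for ch in column:
        c = ch.upper()
        if ch in _MISSING or c in _MISSING:
            continue
        counts[c] = counts.get(c, 0) + 1
    if len(counts) <= 1:
        return "conserved"
    if sum(1 for n in counts.values() if n >= 2) >= 2:
        return "parsimony_informative"
    return "variable_uninformative"


def marker_report(aln: Alignment, gene: str, n_success: int | None = None,
                  gene_db_id: str | None = None) -> MarkerReport:
    """Compute the statistics row for one marker alignment.

    Site-class percentages are over all alignment columns; base
    frequencies pool every non-missing character across all sequences.
    """
    if aln.length == 0:
        raise ValidationError(f"{gene}: zero-length alignment")
    tallies = {"conserved": 0, "variable_uninformative": 0, "parsimony_informative": 0}
    all_missing = 0
    for j in range(aln.length):
        col = aln.column(j)
        if all(ch in _MISSING or ch.upper() in _MISSING for ch in col):
            all_missing += 1
        tallies[classify_column(col)] += 1
    L = aln.length
    variable = tallies["variable_uninformative"] + tallies["parsimony_informative"]

    base_counts = {"A": 0, "T": 0, "C": 0, "G": 0}
    total = 0
    for row in aln.rows:
        for ch in row:
            c = ch.upper()
            if c in base_counts:
                base_counts[c] += 1
                total += 1
    if total == 0:
        raise ValidationError(f"{gene}: no unambiguous bases in alignment")
    return MarkerReport(
        gene=gene,
        length=L,
        variable_pct=_round1(100.0 * variable / L),
        parsinf_pct=_round1(100.0 * tallies["parsimony_informative"] / L),
        conserved_pct=_round1(100.0 * tallies["conserved"] / L),
        freq_A=_round1(100.0 * base_counts["A"] / total),
        freq_T=_round1(100.0 * base_counts["T"] / total),
        freq_C=_round1(100.0 * base_counts["C"] / total),
        freq_G=_round1(100.0 * base_counts["G"] / total),
        n_success=n_success,
        gene_db_id=gene_db_id,
        all_missing_columns=all_missing,
    )


def _panel_summary(reports: list[MarkerReport]) -> dict:
    if not reports:
        raise ValidationError("empty panel")
    by_parsinf = sorted(reports, key=lambda r: (r.parsinf_pct, r.gene))
    by_var = sorted(reports, key=lambda r: (r.variable_pct, r.gene))
    return {
        "n_genes": len(reports),
        "parsinf_min": by_parsinf[0].parsinf_pct,
        "parsinf_min_gene": by_parsinf[0].gene,
        "parsinf_max": by_parsinf[-1].parsinf_pct,
        "parsinf_max_gene": by_parsinf[-1].gene,
        "parsinf_mean": _round1(sum(r.parsinf_pct for r in reports) / len(reports)),
        "variable_min": by_var[0].variable_pct,
        "variable_min_gene": by_var[0].gene,
        "variable_max": by_var[-1].variable_pct,
        "variable_max_gene": by_var[-1].gene,
        "variable_mean": _round1(sum(r.variable_pct for r in reports) / len(reports)),
    }


def panel_compare(
    new_reports: list[MarkerReport], reference_reports: list[MarkerReport]
) -> dict[str, dict]:
    """Summarize variability of a new marker panel against a reference panel."""
    return {"new": _panel_summary(new_reports), "reference": _panel_summary(reference_reports)}


def reports_to_frame(reports: list[MarkerReport]) -> pd.DataFrame:
    """Reports as a tidy DataFrame, column layout matching the bundled panel."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in reports],
            "length_bp": [r.length for r in reports],
            "n_success": [r.n_success for r in reports],
            "variable_pct": [r.variable_pct for r in reports],
            "parsinf_pct": [r.parsinf_pct for r in reports],
            "conserved_pct": [r.conserved_pct for r in reports],
            "freq_A": [r.freq_A for r in reports],
            "freq_T": [r.freq_T for r in reports],
            "freq_C": [r.freq_C for r in reports],
            "freq_G": [r.freq_G for r in reports],
            "gene_db_id": [r.gene_db_id for r in reports],
        }
    )


def load_marker_panel(panel: str | None = None) -> pd.DataFrame:
    """The bundled marker-statistics panel (30 new + 8 reference genes).

    ``panel`` filters to ``"new"`` or ``"reference"``; default returns all
    38 rows.
    """
    df = pd.read_csv(bundled_data_path("marker_panel.tsv"), sep="\t")
    if panel is not None:
        if panel not in {"new", "reference"}:
            raise ValidationError(f"unknown panel {panel!r}")
        df = df[df["panel"] == panel].reset_index(drop=True)
    return df


def panel_reports(df: pd.DataFrame) -> list[MarkerReport]:
    """Convert bundled-panel rows into :class:`MarkerReport` objects."""
    return [
        MarkerReport(
            gene=row.gene,
            length=int(row.length_bp),
            variable_pct=float(row.variable_pct),
            parsinf_pct=float(row.parsinf_pct),
            conserved_pct=float(row.conserved_pct),
            freq_A=float(row.freq_A),
            freq_T=float(row.freq_T),
            freq_C=float(row.freq_C),
            freq_G=float(row.freq_G),
            n_success=int(row.n_success),
            gene_db_id=None if pd.isna(row.gene_db_id) else str(row.gene_db_id),
        )
        for row in df.itertuples(index=False)
    ]
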