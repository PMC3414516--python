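"""Intron counting and gene-structure classification.

Plant TPS genes fall into two classes with sharply different gene
structures: class I genes carry 16 introns in the protein-coding region,
class II genes carry 2.  Counting introns over the CDS intervals of a gene
model therefore corroborates the phylogenetic class assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import GeneRecord
from .errors import InvalidGeneModelError

DEFAULT_STRUCTURE_RULE = {"I": 16, "II": 2}


@dataclass
class GeneStructureSummary:
    gene_id: str
    exon_count: int
    intron_count: int
    intron_lengths: list[int]
    cds_length: int


def count_introns(
    g: GeneRecord, region: str = "protein_coding"
) -> GeneStructureSummary:
    """Count introns as gaps between consecutive intervals of a region.

    ``region='protein_coding'`` uses the CDS intervals when annotated
    (falling back to exons clipped to the CDS span); ``'full_transcript'``
    uses the exon intervals.  Minus-strand genes are re-sorted into genomic
    order before gap arithmetic, so strand never changes the count.
    """
    if region == "protein_coding":
        ivals = g.cds_exons or _clip_to_cds_span(g)
    elif region == "full_transcript":
        ivals = g.exons
    else:
        raise ValueError(f"unknown region {region!r}")
    if not ivals:
        raise InvalidGeneModelError(f"{g.gene_id}: no intervals for {region}")
    ivals = sorted(ivals)
    for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
        if s2 <= e1:
            raise InvalidGeneModelError(
                f"{g.gene_id}: overlapping intervals ({s1},{e1})/({s2},{e2})"
            )
    intron_lengths = [
        s2 - e1 - 1 for (s1, e1), (s2, e2) in zip(ivals, ivals[1:])
    ]
    return GeneStructureSummary(
        gene_id=g.gene_id,
        exon_count=len(ivals),
        intron_count=len(ivals) - 1,
        intron_lengths=intron_lengths,
        cds_length=sum(e - s + 1 for s, e in ivals),
    )


def _clip_to_cds_span(g: GeneRecord) -> list[tuple[int, int]]:
    """Exon intervals intersected with the CDS genomic span.

    Used when a gene model annotates exons but not CDS features; introns
    lying entirely in the UTRs are thereby excluded from the
    protein-coding count.
    """
    if not g.exons:
        return []
    if g.start is None or g.end is None:
        return sorted(g.exons)
    lo, hi = g.start, g.end
    out = []
    for s, e in sorted(g.exons):
        s2, e2 = max(s, lo), min(e, hi)
        if s2 <= e2:
            out.append((s2, e2))
    return out


def classify_by_structure(
    s: GeneStructureSummary, rule: dict[str, int] | None = None
) -> str:
    """Map an intron count to a class via an exact-match rule.

    The default rule is {I: 16, II: 2}; any other count is 'unknown'.
    """
    rule = DEFAULT_STRUCTURE_RULE if rule is None else rule
    for label, count in rule.items():
        if s.intron_count == count:
            return label
    return "unknown"


def structure_summary_table(
    records: list[GeneRecord],
    region: str = "protein_coding",
    rule: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Per-gene structure summary with the inferred class (TSV-ready)."""
    rows = []
    for g in records:
        summ = count_introns(g, region=region)
        rows.append(
            {
                "gene_id": g.gene_id,
                "exon_count": summ.exon_count,
                "intron_count": summ.intron_count,
                "cds_length": summ.cds_length,
                "inferred_class": classify_by_structure(summ, rule),
            }
        )
    return pd.DataFrame(rows)
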