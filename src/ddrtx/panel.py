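"""Synthetic coordinate map for the enrollment and monitoring gene panels.

Real panel BED coordinates are proprietary; these regions preserve what the
pipeline needs — each gene on its native chromosome, a contiguous body that
segments and mutations can overlap — with synthetic positions.
"""

from __future__ import annotations

from typing import NamedTuple


class GeneRegion(NamedTuple):
    chrom: str
    start: int
    end: int


_GENE_CHROMS = {
    "ATM": "chr11", "BRCA1": "chr17", "BRCA2": "chr13", "CDK12": "chr17",
    "RNASEH2B": "chr13", "PALB2": "chr16", "SETD2": "chr3", "NBN": "chr8",
    "RAD51C": "chr17", "CHEK2": "chr22",
    # monitoring-panel genes seen in ctDNA but not used for enrollment
    "TP53": "chr17", "KRAS": "chr12", "PIK3CA": "chr3", "APC": "chr5",
    "PTEN": "chr10", "EGFR": "chr7",
}

GENE_SPAN = 200_000

# Deterministic layout: genes sharing a chromosome get disjoint 10-Mb slots.
GENE_REGIONS: dict[str, GeneRegion] = {}
_slot_count: dict[str, int] = {}
for _gene in sorted(_GENE_CHROMS):
    _chrom = _GENE_CHROMS[_gene]
    _slot = _slot_count.get(_chrom, 0)
    _slot_count[_chrom] = _slot + 1
    _start = 1_000_000 + _slot * 10_000_000
    GENE_REGIONS[_gene] = GeneRegion(_chrom, _start, _start + GENE_SPAN - 1)

ENROLLMENT_GENES = ("ATM", "BRCA1", "BRCA2", "CDK12", "RNASEH2B", "PALB2",
                    "SETD2", "NBN", "RAD51C", "CHEK2")
MONITORING_GENES = ("TP53", "KRAS", "PIK3CA", "APC", "PTEN", "EGFR")


def overlapping_segments(segments, gene: str):
    """Segments overlapping the gene body (1-based inclusive coordinates)."""
    region = GENE_REGIONS[gene]
    return [s for s in segments
            if s.chrom == region.chrom
            and s.start <= region.end and s.end >= region.start]
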