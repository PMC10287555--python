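"""Allele-specific copy number (simplified segment model) and allelic status.

Forward model
-------------
A tumor sample is a mixture of tumor cells (fraction rho, the purity) and
diploid normal cells.  For a segment with integer allele copy numbers
(major, minor), total_cn = major + minor, and sample ploidy psi:

    expected log2R        = log2( (rho*total_cn + 2(1-rho)) / (rho*psi + 2(1-rho)) )
    expected folded BAF   = (rho*major + (1-rho)) / (rho*total_cn + 2(1-rho))
    expected mutation VAF = m*rho / (rho*total_cn + 2(1-rho))   (m mutated copies)

Observed log2R is the log2 tumor:reference coverage ratio, median-centered
so the genome-wide median is zero; observed folded BAF is the mean
heterozygous-SNP b-allele fraction folded into [0.5, 1].

Inference is an exhaustive grid search over 0 <= minor <= major <= 8
minimizing the squared error against the two observables, ties broken
toward the smaller total copy number.

Allelic status
--------------
Mutation plus copy-number evidence for a gene maps to one of six
categories, evaluated in order: CHIP (the enrollment alteration is
hematopoietic, not tumor) -> subclonal (enrollment alteration at
lower-than-expected VAF) -> biallelic via (1) homozygous deletion,
(2) compound heterozygous mutation, (3) mutation and LOH, or
(4) mutation and non-overlapping loss -> monoallelic (mutation without
LOH, or heterozygous loss alone) -> no_loss; insufficient evidence maps
to unknown.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy import stats

from .io_model import SegmentCN, ValidationError

MAX_CN = 8
LOG2R_FLOOR = -8.0
SUBCLONAL_ALPHA = 0.01        # one-sided binomial tail for depletion
SUBCLONAL_FRACTION = 0.6      # and observed VAF < 0.6 x expected
VAF_CONSISTENCY_ALPHA = 0.05  # two-sided binomial for retained-allele residence

BIALLELIC_CRITERIA = ("homozygous_deletion", "compound_heterozygous",
                      "mutation_and_LOH", "mutation_and_nonoverlapping_loss")


@dataclass(frozen=True)
class Mutation:
    """One pathogenic mutation in the gene under evaluation (tumor assay)."""

    pos: int
    alt_reads: int
    total_reads: int
    germline: bool = False
    is_enrollment: bool = False

    @property
    def vaf(self) -> float:
        return self.alt_reads / self.total_reads if self.total_reads else 0.0


@dataclass
class GeneEvidence:
    gene: str
    mutations: list[Mutation] = field(default_factory=list)
    segments: list[SegmentCN] = field(default_factory=list)  # overlapping the gene
    purity: float = 1.0
    ploidy: float = 2.0
    enrollment_is_chip: bool = False


@dataclass(frozen=True)
class AllelicStatus:
    category: str   # biallelic | monoallelic | no_loss | CHIP | subclonal | unknown
    criterion: str  # one of BIALLELIC_CRITERIA, or "none"


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def expected_log2r(purity: float, ploidy: float, total_cn: int,
                   floor: float = LOG2R_FLOOR) -> float:
    """Purity/ploidy-adjusted expected log2 coverage ratio for a segment."""
    if not 0.0 < purity <= 1.0:
        raise ValidationError("purity outside (0, 1]")
    if ploidy <= 0:
        raise ValidationError("ploidy must be > 0")
    num = purity * total_cn + 2.0 * (1.0 - purity)
    den = purity * ploidy + 2.0 * (1.0 - purity)
    if num <= 0:
        return floor
    return max(math.log2(num / den), floor)


def expected_folded_baf(purity: float, major: int, minor: int) -> float:
    """Expected heterozygous-SNP BAF folded to [0.5, 1]."""
    den = purity * (major + minor) + 2.0 * (1.0 - purity)
    if den <= 0:
        return 0.5  # homozygous deletion at purity 1: no reads, uninformative
    return (purity * major + (1.0 - purity)) / den


def expected_vaf(purity: float, total_cn: int, mutated_copies: int) -> float:
    """Expected mutation VAF with m mutated copies on total_cn tumor copies."""
    if not 1 <= mutated_copies <= max(total_cn, 1):
        raise ValidationError("mutated_copies must be in [1, total_cn]")
    return (mutated_copies * purity) / (total_cn * purity + 2.0 * (1.0 - purity))


# ---------------------------------------------------------------------------
# Observables and inverse model
# ---------------------------------------------------------------------------

def compute_log2r(segments: Sequence[SegmentCN]) -> list[Optional[float]]:
    """Per-segment log2 tumor:reference coverage ratio, median-centered.

    Segments with zero reference coverage are unevaluable (None) and are
    excluded from the centering median.  Results are also stored on the
    segments' ``log2r`` attribute.
    """
    raw: list[Optional[float]] = []
    for seg in segments:
        if seg.reference_coverage <= 0 or seg.tumor_coverage <= 0:
            raw.append(None)
        else:
            raw.append(math.log2(seg.tumor_coverage / seg.reference_coverage))
    finite = sorted(v for v in raw if v is not None)
    if finite:
        mid = len(finite) // 2
        median = (finite[mid] if len(finite) % 2
                  else 0.5 * (finite[mid - 1] + finite[mid]))
    else:
        median = 0.0
    centered = [None if v is None else v - median for v in raw]
    for seg, value in zip(segments, centered):
        seg.log2r = value
    return centered


def summarize_baf(segment: SegmentCN) -> Optional[float]:
    """Mean folded heterozygous-SNP BAF for a segment.

    Falls back to a precomputed ``baf_folded`` summary (e.g. read from
    segments.tsv) when per-SNP counts are not in memory.
    """
    segment.baf_folded = segment.folded_baf_summary()
    return segment.baf_folded


def infer_segment_cn(log2r: Optional[float], baf_folded: Optional[float],
                     purity: float, ploidy: float,
                     max_cn: int = MAX_CN) -> tuple[Optional[int], Optional[int]]:
    """Grid search for the integer (major, minor) pair explaining (log2R, BAF).

    Objective: squared log2R error plus squared folded-BAF error; ties are
    broken toward the smaller total copy number (totals are scanned in
    ascending order and only a strict improvement replaces the incumbent).
    Without a BAF summary the minor copy number is undetermined.
    """
    if log2r is None or baf_folded is None:
        return None, None
    best: tuple[Optional[int], Optional[int]] = (None, None)
    best_cost = math.inf
    for total in range(0, 2 * max_cn + 1):
        for minor in range(0, total // 2 + 1):
            major = total - minor
            if major > max_cn:
                continue
            cost = ((log2r - expected_log2r(purity, ploidy, total)) ** 2
                    + (baf_folded - expected_folded_baf(purity, major, minor)) ** 2)
            if cost < best_cost - 1e-12:
                best_cost = cost
                best = (major, minor)
    return best


def infer_patient_segments(segments: Sequence[SegmentCN], purity: float,
                           ploidy: float) -> None:
    """Median-center log2R across a patient's segments, then infer CN in place."""
    compute_log2r(segments)
    for seg in segments:
        baf = summarize_baf(seg)
        seg.major_cn, seg.minor_cn = infer_segment_cn(seg.log2r, baf, purity, ploidy)


# ---------------------------------------------------------------------------
# Subclonality and the decision engine
# ---------------------------------------------------------------------------

def test_subclonal(alt_reads: int, total_reads: int,
                   expected: float,
                   alpha: float = SUBCLONAL_ALPHA,
                   fraction: float = SUBCLONAL_FRACTION) -> Optional[bool]:
    """Is the observed VAF significantly below the clonal expectation?

    Subclonal iff the one-sided exact binomial tail
    P(X <= alt_reads | n, p=expected) < alpha AND the observed VAF is below
    ``fraction`` times the expectation.  Undetermined (None) at zero depth.
    """
    if total_reads == 0:
        return None
    tail = stats.binom.cdf(alt_reads, total_reads, expected)
    observed = alt_reads / total_reads
    return bool(tail < alpha and observed < fraction * expected)


def _vaf_consistent(mut: Mutation, total_cn: int, purity: float,
                    mutated_copies: int = 1,
                    alpha: float = VAF_CONSISTENCY_ALPHA) -> bool:
    """Two-sided exact binomial check of the observed VAF against expectation.

    Germline mutations are also carried by the admixed normal cells, so
    their expectation gains a (1 - purity) term in the numerator.
    """
    if mut.total_reads == 0 or total_cn == 0:
        return False
    if mut.germline:
        p = ((mutated_copies * purity + (1.0 - purity))
             / (total_cn * purity + 2.0 * (1.0 - purity)))
    else:
        p = expected_vaf(purity, total_cn, mutated_copies)
    test = stats.binomtest(mut.alt_reads, mut.total_reads, p)
    return test.pvalue >= alpha


def classify_allelic_status(evidence: GeneEvidence) -> AllelicStatus:
    """Map gene-level mutation + copy-number evidence to one category.

    Evaluation order: CHIP -> subclonal -> biallelic criteria (1)-(4) ->
    monoallelic -> no_loss; insufficient data yields unknown.  The function
    is total and deterministic over valid evidence.
    """
    if evidence.enrollment_is_chip:
        return AllelicStatus("CHIP", "none")

    usable = [s for s in evidence.segments if s.total_cn is not None]
    muts = evidence.mutations
    ploidy_ref = max(2, round(evidence.ploidy))

    def seg_at(pos: int) -> Optional[SegmentCN]:
        for seg in usable:
            if seg.contains(pos):
                return seg
        return None

    # --- subclonal: enrollment alteration depleted relative to clonal VAF
    enrollment = next((m for m in muts if m.is_enrollment), None)
    if enrollment is not None and not enrollment.germline:
        seg = seg_at(enrollment.pos)
        if seg is not None and seg.total_cn and seg.total_cn > 0:
            exp = expected_vaf(evidence.purity, seg.total_cn, 1)
            if test_subclonal(enrollment.alt_reads, enrollment.total_reads, exp):
                return AllelicStatus("subclonal", "none")

    # --- biallelic criteria, in the stated order
    if any(s.total_cn == 0 for s in usable):
        return AllelicStatus("biallelic", "homozygous_deletion")
    if len({m.pos for m in muts}) >= 2:
        # Two distinct pathogenic hits assumed in trans (no phasing available).
        return AllelicStatus("biallelic", "compound_heterozygous")
    for m in muts:
        seg = seg_at(m.pos)
        if seg is not None and seg.minor_cn == 0 and seg.total_cn >= 1:
            return AllelicStatus("biallelic", "mutation_and_LOH")
    for m in muts:
        seg = seg_at(m.pos)
        if seg is None or seg.minor_cn is None or seg.minor_cn == 0:
            continue
        for other in usable:
            if other.contains(m.pos):
                continue
            # A deletion elsewhere in the gene, with the mutation VAF
            # consistent with residing on the retained allele.
            if (other.total_cn < ploidy_ref and other.minor_cn == 0
                    and _vaf_consistent(m, seg.total_cn, evidence.purity)):
                return AllelicStatus("biallelic", "mutation_and_nonoverlapping_loss")

    # --- monoallelic: mutation without LOH, or heterozygous loss alone
    covered = [(m, seg_at(m.pos)) for m in muts]
    if any(seg is not None and seg.minor_cn is not None and seg.minor_cn >= 1
           for _, seg in covered):
        return AllelicStatus("monoallelic", "none")
    het_loss = any(s.minor_cn == 0 and 1 <= s.total_cn < ploidy_ref for s in usable)
    if not muts and het_loss:
        return AllelicStatus("monoallelic", "none")

    # --- no loss / unknown
    if muts:
        return AllelicStatus("unknown", "none")  # mutation present but uncovered
    if usable:
        return AllelicStatus("no_loss", "none")
    return AllelicStatus("unknown", "none")
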