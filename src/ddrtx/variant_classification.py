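"""Variant-origin classification against matched PBMC sequencing.

ctDNA assays see three kinds of variants: true tumor-derived somatic calls,
germline polymorphisms, and clones of hematopoietic origin (CHIP) that shed
DNA into plasma.  Matched PBMC sequencing separates them:

* germline — the variant is present in PBMCs near heterozygous/homozygous
  fractions (PBMC VAF >= 0.30 by default; the band is a package choice since
  no quantitative germline rule is standard for targeted panels);
* CHIP — the PBMC:ctDNA VAF ratio is >= 0.25 with >= 5 supporting PBMC reads;
* somatic_tumor — everything else;
* ambiguous — PBMC-positive below the germline band while the variant is
  never detected in ctDNA, so the VAF ratio is undefined.

The reference ctDNA VAF for the ratio is the baseline VAF, falling back to
the maximum on-treatment VAF when the variant is undetected at baseline.

The module also flags patients whose *enrollment* alteration is CHIP-derived
(these are excluded from tumor biallelic classification downstream) and
applies the immunohistochemistry loss cutoffs (ATM <= 5% positive tumor
cells; RNASEH2B 0-10%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .io_model import PatientRecord, ValidationError, VariantCall

GERMLINE_PBMC_VAF = 0.30
CHIP_MIN_PBMC_READS = 5
CHIP_MIN_VAF_RATIO = 0.25

IHC_LOSS_CUTOFF = {"ATM": 5.0, "RNASEH2B": 10.0}


@dataclass(frozen=True)
class OriginCall:
    """Origin assignment for one distinct variant of one patient."""

    key: tuple
    origin: str
    pbmc_vaf: float
    ctdna_ref_vaf: float
    vaf_ratio: float
    pbmc_alt_reads: int


@dataclass(frozen=True)
class IHCResult:
    marker: str
    percent_positive_tumor_cells: float
    loss: bool


@dataclass(frozen=True)
class EnrollmentChipFlag:
    is_chip: bool
    detected: bool  # False when the enrollment alteration was never assayed


def reference_ctdna_vaf(ctdna_calls: Sequence[VariantCall]) -> float:
    """Baseline VAF, falling back to the maximum on-treatment VAF."""
    baseline = [c.vaf for c in ctdna_calls if c.is_baseline]
    if baseline and max(baseline) > 0:
        return max(baseline)
    on_tx = [c.vaf for c in ctdna_calls if not c.is_baseline]
    return max(on_tx, default=0.0)


def classify_origin(ctdna_calls: Sequence[VariantCall],
                    pbmc_call: Optional[VariantCall] = None,
                    germline_pbmc_vaf: float = GERMLINE_PBMC_VAF,
                    chip_min_reads: int = CHIP_MIN_PBMC_READS,
                    chip_min_ratio: float = CHIP_MIN_VAF_RATIO) -> OriginCall:
    """Assign one origin to a variant from its ctDNA series and PBMC call.

    An absent PBMC call is treated as 0/0 reads (the panel covers the locus
    in both assays by construction), which routes to somatic_tumor.
    """
    if not ctdna_calls:
        raise ValidationError("classify_origin requires a non-empty ctDNA series")
    key = ctdna_calls[0].key
    if pbmc_call is None:
        pbmc_vaf, pbmc_alt = 0.0, 0
    else:
        if pbmc_call.total_reads == 0 and pbmc_call.alt_reads > 0:
            raise ValidationError("PBMC call has alt reads but zero total reads")
        pbmc_vaf, pbmc_alt = pbmc_call.vaf, pbmc_call.alt_reads

    ref_vaf = reference_ctdna_vaf(ctdna_calls)
    ratio = pbmc_vaf / ref_vaf if ref_vaf > 0 else float("inf") if pbmc_vaf > 0 else 0.0

    if pbmc_vaf >= germline_pbmc_vaf:
        origin = "germline"
    elif ref_vaf == 0 and pbmc_alt > 0:
        origin = "ambiguous"
    elif pbmc_alt >= chip_min_reads and ratio >= chip_min_ratio:
        origin = "CHIP"
    else:
        origin = "somatic_tumor"
    return OriginCall(key=key, origin=origin, pbmc_vaf=pbmc_vaf,
                      ctdna_ref_vaf=ref_vaf, vaf_ratio=ratio,
                      pbmc_alt_reads=pbmc_alt)


def classify_patient_origins(patient: PatientRecord, **kwargs) -> dict[tuple, OriginCall]:
    """Classify every distinct ctDNA variant of one patient.

    Variants seen only in PBMC or tumor assays get no origin call here: the
    partition is over ctDNA variants, which is where germline/CHIP
    contamination matters for response monitoring.
    """
    by_key: dict[tuple, list[VariantCall]] = {}
    for call in patient.calls("ctDNA"):
        by_key.setdefault(call.key, []).append(call)
    pbmc_by_key = {c.key: c for c in patient.calls("PBMC")}
    return {key: classify_origin(series, pbmc_by_key.get(key), **kwargs)
            for key, series in by_key.items()}


def flag_enrollment_chip(patient: PatientRecord,
                         origin_calls: dict[tuple, OriginCall]) -> EnrollmentChipFlag:
    """True iff the patient's designated enrollment alteration is CHIP-derived.

    Such patients carry a hematopoietic, not tumor, copy of the alteration
    and are assigned allelic-status category CHIP downstream.  An enrollment
    alteration absent from every assay is reported as not detected rather
    than raising.
    """
    key = patient.enrollment_key
    if key is None:
        raise ValidationError(f"{patient.patient_id}: no designated enrollment alteration")
    call = origin_calls.get(key)
    if call is None:
        # Not in ctDNA; a PBMC-only observation can still establish CHIP.
        pbmc = next((c for c in patient.calls("PBMC") if c.key == key), None)
        if pbmc is None:
            return EnrollmentChipFlag(is_chip=False, detected=False)
        is_chip = (pbmc.vaf < GERMLINE_PBMC_VAF
                   and pbmc.alt_reads >= CHIP_MIN_PBMC_READS)
        return EnrollmentChipFlag(is_chip=is_chip, detected=True)
    return EnrollmentChipFlag(is_chip=call.origin == "CHIP", detected=True)


def classify_ihc(marker: str, percent_positive: float) -> IHCResult:
    """Apply the marker-specific protein-loss cutoff (boundary counts as loss)."""
    if marker not in IHC_LOSS_CUTOFF:
        raise ValidationError(f"unknown IHC marker: {marker!r}")
    if not 0.0 <= percent_positive <= 100.0:
        raise ValidationError("percent_positive outside [0, 100]")
    return IHCResult(marker=marker,
                     percent_positive_tumor_cells=percent_positive,
                     loss=percent_positive <= IHC_LOSS_CUTOFF[marker])
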