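"""Shared data model and tabular/VCF I/O for the translational-genomics pipeline.

All genomic coordinates are 1-based inclusive (VCF convention), including
copy-number segments, so that variant/segment overlap tests never need an
off-by-one adjustment.  Timepoints are continuous weeks from first dose; the
baseline sample is the unique timepoint < 0.5 weeks.

Tables are UTF-8 TSV with a header row and ``.`` for missing values.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional, Sequence

BASELINE_CUTOFF_WEEKS = 0.5
MISSING = "."

ASSAYS = ("ctDNA", "PBMC", "tumor")
ORIGINS = ("germline", "CHIP", "somatic_tumor", "ambiguous")
ENROLLMENT_ORIGINS = ("germline", "somatic", "undetermined")


class FormatError(ValueError):
    """A table or file does not have the expected layout."""


class ValidationError(ValueError):
    """A parsed record violates a domain invariant."""


def _fmt(value) -> str:
    """Canonical text form for one cell; idempotent under parse/format."""
    if value is None:
        return MISSING
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        if math.isnan(value):
            return MISSING
        return repr(value)  # shortest exact round-trip representation
    return str(value)


def _parse_float(text: str) -> Optional[float]:
    return None if text == MISSING else float(text)


def _parse_int(text: str) -> Optional[int]:
    return None if text == MISSING else int(text)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantCall:
    """One observed allele at one sample/timepoint with read support."""

    patient_id: str
    assay: str
    timepoint_weeks: float
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    alt_reads: int
    total_reads: int
    vaf: float

    @property
    def key(self) -> tuple:
        """Variant identity within a patient (assay/timepoint independent)."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def is_baseline(self) -> bool:
        return self.timepoint_weeks < BASELINE_CUTOFF_WEEKS

    def violations(self) -> list[str]:
        out = []
        if self.assay not in ASSAYS:
            out.append(f"assay: {self.assay!r} not one of {ASSAYS}")
        if self.timepoint_weeks < 0:
            out.append("timepoint_weeks: must be >= 0")
        if self.pos < 1:
            out.append("pos: must be >= 1")
        if self.alt_reads < 0 or self.total_reads < 0:
            out.append("alt_reads/total_reads: must be >= 0")
        if self.alt_reads > self.total_reads:
            out.append("alt_reads: exceeds total_reads")
        if not 0.0 <= self.vaf <= 1.0:
            out.append("vaf: outside [0, 1]")
        elif self.total_reads > 0 and abs(self.vaf - self.alt_reads / self.total_reads) > 1e-9:
            out.append("vaf: inconsistent with alt_reads/total_reads")
        return out

    def check(self, row: Optional[int] = None) -> "VariantCall":
        bad = self.violations()
        if bad:
            where = f" (row {row})" if row is not None else ""
            raise ValidationError(f"invalid VariantCall{where}: " + "; ".join(bad))
        return self

    @staticmethod
    def from_reads(patient_id, assay, timepoint_weeks, chrom, pos, ref, alt,
                   gene, alt_reads, total_reads) -> "VariantCall":
        vaf = alt_reads / total_reads if total_reads > 0 else 0.0
        return VariantCall(patient_id, assay, float(timepoint_weeks), chrom,
                           int(pos), ref, alt, gene, int(alt_reads),
                           int(total_reads), vaf)


@dataclass(frozen=True)
class VariantAnnotation:
    """Origin and enrollment annotation for one distinct variant of a patient."""

    origin: str  # germline | CHIP | somatic_tumor | ambiguous
    pathogenic: bool
    is_enrollment_alteration: bool

    def violations(self) -> list[str]:
        if self.origin not in ORIGINS:
            return [f"origin: {self.origin!r} not one of {ORIGINS}"]
        return []


class SNP(NamedTuple):
    """Allele counts at one heterozygous SNP inside a segment."""

    pos: int
    alt_reads: int
    ref_reads: int

    @property
    def baf(self) -> float:
        n = self.alt_reads + self.ref_reads
        return self.alt_reads / n if n else math.nan


@dataclass
class SegmentCN:
    """One copy-number segment: coverage evidence and inferred allelic state."""

    chrom: str
    start: int
    end: int
    tumor_coverage: float
    reference_coverage: float
    snps: list[SNP] = field(default_factory=list)
    log2r: Optional[float] = None
    baf_folded: Optional[float] = None
    major_cn: Optional[int] = None
    minor_cn: Optional[int] = None

    @property
    def total_cn(self) -> Optional[int]:
        if self.major_cn is None or self.minor_cn is None:
            return None
        return self.major_cn + self.minor_cn

    @property
    def loh(self) -> Optional[bool]:
        """Loss of heterozygosity: minor allele copy number of zero."""
        return None if self.minor_cn is None else self.minor_cn == 0

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def folded_baf_summary(self) -> Optional[float]:
        """Mean heterozygous-SNP BAF folded to [0.5, 1] (None without SNPs)."""
        bafs = [s.baf for s in self.snps if s.alt_reads + s.ref_reads > 0]
        if not bafs:
            return self.baf_folded
        return sum(max(b, 1.0 - b) for b in bafs) / len(bafs)

    def violations(self) -> list[str]:
        out = []
        if self.end < self.start:
            out.append("end: segment end < start")
        if self.tumor_coverage < 0 or self.reference_coverage < 0:
            out.append("coverage: must be >= 0")
        if self.major_cn is not None and self.minor_cn is not None:
            if self.minor_cn < 0 or self.major_cn < self.minor_cn:
                out.append("copy numbers: require 0 <= minor_cn <= major_cn")
        return out


@dataclass(frozen=True)
class LesionMeasurement:
    lesion_id: str
    kind: str  # target | non_target
    timepoint_weeks: float
    longest_diameter_mm: float
    new_lesion: bool = False

    def violations(self) -> list[str]:
        out = []
        if self.kind not in ("target", "non_target"):
            out.append(f"kind: {self.kind!r}")
        if self.longest_diameter_mm < 0:
            out.append("longest_diameter_mm: must be >= 0")
        if self.timepoint_weeks < 0:
            out.append("timepoint_weeks: must be >= 0")
        return out


@dataclass(frozen=True)
class MarkerMeasurement:
    marker: str  # PSA | CA125 | CA19_9
    timepoint_weeks: float
    value: float

    def violations(self) -> list[str]:
        out = []
        if self.marker not in ("PSA", "CA125", "CA19_9"):
            out.append(f"marker: {self.marker!r}")
        if self.value < 0:
            out.append("value: must be >= 0")
        return out


@dataclass
class PatientRecord:
    """All per-patient inputs: treatment, tumor sample state and measurements."""

    patient_id: str
    tumor_type: str
    enrollment_gene: str
    enrollment_origin: str  # germline | somatic | undetermined
    dose_mg_per_day: float
    schedule: str
    purity: float
    ploidy: float
    treatment_start_weeks: float = 0.0
    treatment_stop_weeks: float = 0.0
    progression_time_weeks: Optional[float] = None
    death_time_weeks: Optional[float] = None
    data_cutoff_weeks: float = 0.0
    enrollment_chrom: Optional[str] = None
    enrollment_pos: Optional[int] = None
    enrollment_ref: Optional[str] = None
    enrollment_alt: Optional[str] = None
    variants: list[VariantCall] = field(default_factory=list)
    segments: list[SegmentCN] = field(default_factory=list)
    lesions: list[LesionMeasurement] = field(default_factory=list)
    markers: list[MarkerMeasurement] = field(default_factory=list)

    @property
    def enrollment_key(self) -> Optional[tuple]:
        if self.enrollment_pos is None:
            return None
        return (self.enrollment_chrom, self.enrollment_pos,
                self.enrollment_ref, self.enrollment_alt)

    def calls(self, assay: str) -> list[VariantCall]:
        return [v for v in self.variants if v.assay == assay]

    def violations(self) -> list[str]:
        out = []
        if not 0.0 < self.purity <= 1.0:
            out.append("purity: outside (0, 1]")
        if self.ploidy <= 0:
            out.append("ploidy: must be > 0")
        if self.enrollment_origin not in ENROLLMENT_ORIGINS:
            out.append(f"enrollment_origin: {self.enrollment_origin!r}")
        if self.treatment_stop_weeks < self.treatment_start_weeks:
            out.append("treatment_stop_weeks: before treatment_start_weeks")
        for name in ("progression_time_weeks", "death_time_weeks"):
            v = getattr(self, name)
            if v is not None and v < 0:
                out.append(f"{name}: must be >= 0")
        return out


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = group and columns = outcome (success, failure)."""

    a: int
    b: int
    c: int
    d: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def violations(self) -> list[str]:
        out = []
        if min(self.a, self.b, self.c, self.d) < 0:
            out.append("counts: must be >= 0")
        if self.total == 0:
            out.append("total: must be > 0")
        return out

    def check(self) -> "ContingencyTable2x2":
        bad = self.violations()
        if bad:
            raise ValidationError("invalid ContingencyTable2x2: " + "; ".join(bad))
        return self


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ["patient_id", "assay", "timepoint_weeks", "chrom", "pos",
                   "ref", "alt", "gene", "alt_reads", "total_reads", "vaf"]
SEGMENT_COLUMNS = ["patient_id", "chrom", "start", "end", "tumor_coverage",
                   "reference_coverage", "log2r", "baf_folded", "n_het_snps",
                   "major_cn", "minor_cn"]
LESION_COLUMNS = ["patient_id", "lesion_id", "kind", "timepoint_weeks",
                  "longest_diameter_mm", "new_lesion"]
MARKER_COLUMNS = ["patient_id", "marker", "timepoint_weeks", "value"]
PATIENT_COLUMNS = ["patient_id", "tumor_type", "enrollment_gene",
                   "enrollment_origin", "dose_mg_per_day", "schedule",
                   "purity", "ploidy", "treatment_start_weeks",
                   "treatment_stop_weeks", "progression_time_weeks",
                   "death_time_weeks", "data_cutoff_weeks",
                   "enrollment_chrom", "enrollment_pos", "enrollment_ref",
                   "enrollment_alt"]


def _open_reader(path):
    handle = open(path, "r", encoding="utf-8", newline="")
    reader = csv.reader(handle, delimiter="\t")
    return handle, reader


def _require_columns(header: Sequence[str], expected: Sequence[str], path) -> dict:
    missing = [c for c in expected if c not in header]
    if missing:
        raise FormatError(f"{path}: missing column: {missing[0]}")
    return {c: header.index(c) for c in expected}


def read_variant_table(path) -> list[VariantCall]:
    """Parse variants.tsv, validating every row; row order is preserved."""
    path = Path(path)
    handle, reader = _open_reader(path)
    with handle:
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file, header expected") from None
        idx = _require_columns(header, VARIANT_COLUMNS, path)
        calls = []
        for rownum, row in enumerate(reader, start=1):
            if not row:
                continue
            try:
                call = VariantCall(
                    patient_id=row[idx["patient_id"]],
                    assay=row[idx["assay"]],
                    timepoint_weeks=float(row[idx["timepoint_weeks"]]),
                    chrom=row[idx["chrom"]],
                    pos=int(row[idx["pos"]]),
                    ref=row[idx["ref"]],
                    alt=row[idx["alt"]],
                    gene=row[idx["gene"]],
                    alt_reads=int(row[idx["alt_reads"]]),
                    total_reads=int(row[idx["total_reads"]]),
                    vaf=float(row[idx["vaf"]]),
                )
            except (ValueError, IndexError) as exc:
                raise FormatError(f"{path} row {rownum}: {exc}") from exc
            call.check(row=rownum)
            calls.append(call)
    return calls


def write_variant_table(calls: Iterable[VariantCall], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(VARIANT_COLUMNS)
        for v in calls:
            writer.writerow([v.patient_id, v.assay, _fmt(v.timepoint_weeks),
                             v.chrom, v.pos, v.ref, v.alt, v.gene,
                             v.alt_reads, v.total_reads, _fmt(v.vaf)])


def read_segment_table(path) -> dict[str, list[SegmentCN]]:
    """Parse segments.tsv into per-patient segment lists (SNP-level counts are
    carried in memory only; the table stores the folded-BAF summary)."""
    path = Path(path)
    handle, reader = _open_reader(path)
    out: dict[str, list[SegmentCN]] = {}
    with handle:
        header = next(reader)
        idx = _require_columns(header, SEGMENT_COLUMNS, path)
        for rownum, row in enumerate(reader, start=1):
            if not row:
                continue
            seg = SegmentCN(
                chrom=row[idx["chrom"]],
                start=int(row[idx["start"]]),
                end=int(row[idx["end"]]),
                tumor_coverage=float(row[idx["tumor_coverage"]]),
                reference_coverage=float(row[idx["reference_coverage"]]),
                log2r=_parse_float(row[idx["log2r"]]),
                baf_folded=_parse_float(row[idx["baf_folded"]]),
                major_cn=_parse_int(row[idx["major_cn"]]),
                minor_cn=_parse_int(row[idx["minor_cn"]]),
            )
            bad = seg.violations()
            if bad:
                raise ValidationError(f"{path} row {rownum}: " + "; ".join(bad))
            out.setdefault(row[idx["patient_id"]], []).append(seg)
    return out


def write_segment_table(segments_by_patient: dict[str, list[SegmentCN]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(SEGMENT_COLUMNS)
        for pid, segs in segments_by_patient.items():
            for s in segs:
                writer.writerow([pid, s.chrom, s.start, s.end,
                                 _fmt(s.tumor_coverage), _fmt(s.reference_coverage),
                                 _fmt(s.log2r), _fmt(s.folded_baf_summary()),
                                 len(s.snps),
                                 _fmt(s.major_cn), _fmt(s.minor_cn)])


def read_lesion_table(path) -> dict[str, list[LesionMeasurement]]:
    path = Path(path)
    handle, reader = _open_reader(path)
    out: dict[str, list[LesionMeasurement]] = {}
    with handle:
        header = next(reader)
        idx = _require_columns(header, LESION_COLUMNS, path)
        for row in reader:
            if not row:
                continue
            les = LesionMeasurement(
                lesion_id=row[idx["lesion_id"]],
                kind=row[idx["kind"]],
                timepoint_weeks=float(row[idx["timepoint_weeks"]]),
                longest_diameter_mm=float(row[idx["longest_diameter_mm"]]),
                new_lesion=row[idx["new_lesion"]] == "1",
            )
            out.setdefault(row[idx["patient_id"]], []).append(les)
    return out


def write_lesion_table(lesions_by_patient: dict[str, list[LesionMeasurement]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(LESION_COLUMNS)
        for pid, lesions in lesions_by_patient.items():
            for les in lesions:
                writer.writerow([pid, les.lesion_id, les.kind,
                                 _fmt(les.timepoint_weeks),
                                 _fmt(les.longest_diameter_mm),
                                 _fmt(les.new_lesion)])


def read_marker_table(path) -> dict[str, list[MarkerMeasurement]]:
    path = Path(path)
    handle, reader = _open_reader(path)
    out: dict[str, list[MarkerMeasurement]] = {}
    with handle:
        header = next(reader)
        idx = _require_columns(header, MARKER_COLUMNS, path)
        for row in reader:
            if not row:
                continue
            m = MarkerMeasurement(marker=row[idx["marker"]],
                                  timepoint_weeks=float(row[idx["timepoint_weeks"]]),
                                  value=float(row[idx["value"]]))
            out.setdefault(row[idx["patient_id"]], []).append(m)
    return out


def write_marker_table(markers_by_patient: dict[str, list[MarkerMeasurement]], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(MARKER_COLUMNS)
        for pid, ms in markers_by_patient.items():
            for m in ms:
                writer.writerow([pid, m.marker, _fmt(m.timepoint_weeks), _fmt(m.value)])


def read_patient_table(path) -> list[PatientRecord]:
    path = Path(path)
    handle, reader = _open_reader(path)
    out = []
    with handle:
        header = next(reader)
        idx = _require_columns(header, PATIENT_COLUMNS, path)
        for row in reader:
            if not row:
                continue
            rec = PatientRecord(
                patient_id=row[idx["patient_id"]],
                tumor_type=row[idx["tumor_type"]],
                enrollment_gene=row[idx["enrollment_gene"]],
                enrollment_origin=row[idx["enrollment_origin"]],
                dose_mg_per_day=float(row[idx["dose_mg_per_day"]]),
                schedule=row[idx["schedule"]],
                purity=float(row[idx["purity"]]),
                ploidy=float(row[idx["ploidy"]]),
                treatment_start_weeks=float(row[idx["treatment_start_weeks"]]),
                treatment_stop_weeks=float(row[idx["treatment_stop_weeks"]]),
                progression_time_weeks=_parse_float(row[idx["progression_time_weeks"]]),
                death_time_weeks=_parse_float(row[idx["death_time_weeks"]]),
                data_cutoff_weeks=float(row[idx["data_cutoff_weeks"]]),
                enrollment_chrom=(row[idx["enrollment_chrom"]] or None)
                    if row[idx["enrollment_chrom"]] != MISSING else None,
                enrollment_pos=_parse_int(row[idx["enrollment_pos"]]),
                enrollment_ref=(None if row[idx["enrollment_ref"]] == MISSING
                                else row[idx["enrollment_ref"]]),
                enrollment_alt=(None if row[idx["enrollment_alt"]] == MISSING
                                else row[idx["enrollment_alt"]]),
            )
            out.append(rec)
    return out


def write_patient_table(patients: Iterable[PatientRecord], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(PATIENT_COLUMNS)
        for p in patients:
            writer.writerow([p.patient_id, p.tumor_type, p.enrollment_gene,
                             p.enrollment_origin, _fmt(p.dose_mg_per_day),
                             p.schedule, _fmt(p.purity), _fmt(p.ploidy),
                             _fmt(p.treatment_start_weeks),
                             _fmt(p.treatment_stop_weeks),
                             _fmt(p.progression_time_weeks),
                             _fmt(p.death_time_weeks),
                             _fmt(p.data_cutoff_weeks),
                             _fmt(p.enrollment_chrom), _fmt(p.enrollment_pos),
                             _fmt(p.enrollment_ref), _fmt(p.enrollment_alt)])


def write_cohort(patients: Sequence[PatientRecord], outdir) -> dict[str, Path]:
    """Write the full TSV bundle (patients/variants/segments/lesions/markers)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / f"{name}.tsv"
             for name in ("patients", "variants", "segments", "lesions", "markers")}
    write_patient_table(patients, paths["patients"])
    write_variant_table([v for p in patients for v in p.variants], paths["variants"])
    write_segment_table({p.patient_id: p.segments for p in patients if p.segments},
                        paths["segments"])
    write_lesion_table({p.patient_id: p.lesions for p in patients if p.lesions},
                       paths["lesions"])
    write_marker_table({p.patient_id: p.markers for p in patients if p.markers},
                       paths["markers"])
    return paths


def read_cohort(indir) -> list[PatientRecord]:
    """Read the TSV bundle back into assembled PatientRecords."""
    indir = Path(indir)
    patients = read_patient_table(indir / "patients.tsv")
    variants = read_variant_table(indir / "variants.tsv")
    segments = read_segment_table(indir / "segments.tsv") if (indir / "segments.tsv").exists() else {}
    lesions = read_lesion_table(indir / "lesions.tsv") if (indir / "lesions.tsv").exists() else {}
    markers = read_marker_table(indir / "markers.tsv") if (indir / "markers.tsv").exists() else {}
    by_pid = {p.patient_id: p for p in patients}
    for v in variants:
        if v.patient_id in by_pid:
            by_pid[v.patient_id].variants.append(v)
    for pid, segs in segments.items():
        if pid in by_pid:
            by_pid[pid].segments = segs
    for pid, les in lesions.items():
        if pid in by_pid:
            by_pid[pid].lesions = les
    for pid, ms in markers.items():
        if pid in by_pid:
            by_pid[pid].markers = ms
    return patients


# ---------------------------------------------------------------------------
# Minimal VCF 4.2 output
# ---------------------------------------------------------------------------

def _chrom_sort_key(chrom: str):
    body = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (0, int(body)) if body.isdigit() else (1, body)


def write_vcf(calls: Sequence[VariantCall], path) -> None:
    """Write calls for one patient/assay as minimal VCF 4.2.

    Records are sorted by (chrom, pos); AD and DP are carried in FORMAT.
    An empty input yields a header-only file that standard parsers accept.
    """
    patients = {c.patient_id for c in calls}
    assays = {c.assay for c in calls}
    if len(patients) > 1 or len(assays) > 1:
        raise ValidationError("write_vcf expects calls from one patient and one assay")
    sample = next(iter(patients)) if patients else "SAMPLE"
    ordered = sorted(calls, key=lambda c: (_chrom_sort_key(c.chrom), c.pos))
    chroms = []
    for c in ordered:
        if c.chrom not in chroms:
            chroms.append(c.chrom)
    with open(path, "w", encoding="utf-8", newline="") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                     'Description="Allelic depths for the ref and alt alleles">\n')
        handle.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        for chrom in sorted(chroms, key=_chrom_sort_key):
            handle.write(f"##contig=<ID={chrom}>\n")
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     f"{sample}\n")
        for c in ordered:
            ref_reads = c.total_reads - c.alt_reads
            handle.write(f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t.\t.\t.\t"
                         f"AD:DP\t{ref_reads},{c.alt_reads}:{c.total_reads}\n")


# ---------------------------------------------------------------------------
# Cohort validation
# ---------------------------------------------------------------------------

class Violation(NamedTuple):
    patient_id: str
    field: str
    rule: str


def validate_cohort(patients: Sequence[PatientRecord]) -> list[Violation]:
    """Check every domain invariant; violations are returned as data."""
    out: list[Violation] = []
    for p in patients:
        for msg in p.violations():
            fld, _, rule = msg.partition(": ")
            out.append(Violation(p.patient_id, fld, rule))
        seen = set()
        for v in p.variants:
            for msg in v.violations():
                fld, _, rule = msg.partition(": ")
                out.append(Violation(p.patient_id, f"variant.{fld}", rule))
            ident = (v.patient_id, v.assay, v.timepoint_weeks, *v.key)
            if ident in seen:
                out.append(Violation(p.patient_id, "variant",
                                     f"duplicate call at {v.chrom}:{v.pos} "
                                     f"{v.ref}>{v.alt} ({v.assay}, t={v.timepoint_weeks})"))
            seen.add(ident)
        for s in p.segments:
            for msg in s.violations():
                fld, _, rule = msg.partition(": ")
                out.append(Violation(p.patient_id, f"segment.{fld}", rule))
        for les in p.lesions:
            for msg in les.violations():
                fld, _, rule = msg.partition(": ")
                out.append(Violation(p.patient_id, f"lesion.{fld}", rule))
        for m in p.markers:
            for msg in m.violations():
                fld, _, rule = msg.partition(": ")
                out.append(Violation(p.patient_id, f"marker.{fld}", rule))
    return out
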