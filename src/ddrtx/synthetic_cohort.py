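"""Trial-like synthetic cohorts with planted ground truth.

The generator emulates the observables the pipeline consumes — longitudinal
ctDNA variant calls with matched PBMC sequencing, tumor-assay mutations,
segment-level copy-number evidence from the purity/ploidy mixture forward
model, lesion and tumor-marker trajectories, and treatment/progression
times — as deterministic-plus-noise functions of a planted truth under one
master seed.  Read counts are binomial given depth and planted VAF; segment
coverage carries small lognormal noise; survival dynamics are tied to the
planted benefit label.

Defaults mirror the trial conditions: 120 patients with enrollment-gene
frequencies proportional to the reported enrollment counts (ATM 44, BRCA1
25, BRCA2 15, CDK12 9, ...), a 43% molecular-response rate among which
responders' variant levels decline 70-95% (median time to a >= 50% decline
of about 3 weeks) versus 0-30% for non-responders, ctDNA sampled every
3-week cycle, scans every 6 weeks for three assessments then every 9 weeks,
and three patients whose enrollment alteration is CHIP-derived.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .allelic_status import expected_folded_baf, expected_log2r, expected_vaf
from .io_model import (LesionMeasurement, MarkerMeasurement, PatientRecord,
                       SegmentCN, SNP, ValidationError, VariantCall)
from .panel import ENROLLMENT_GENES, GENE_REGIONS, MONITORING_GENES
from .pk_nca import ConcentrationProfile

# Enrollment counts as reported for the 120-patient cohort.
DEFAULT_GENE_COUNTS = {"ATM": 44, "BRCA1": 25, "BRCA2": 15, "CDK12": 9,
                       "RNASEH2B": 5, "PALB2": 5, "SETD2": 5, "NBN": 4,
                       "RAD51C": 4, "CHEK2": 4}
# Determinate allelic-status counts (biallelic 57, monoallelic 20, ...).
DEFAULT_ALLELIC_WEIGHTS = {"biallelic": 57, "monoallelic": 20,
                           "no_loss": 3, "subclonal": 1}
TUMOR_TYPES_BY_GENE = {
    "ATM": ("prostate", "pancreatic", "lung"),
    "BRCA1": ("ovarian", "breast"),
    "BRCA2": ("breast", "prostate"),
    "RAD51C": ("ovarian",),
    "CDK12": ("prostate",),
}
BASES = ("A", "C", "G", "T")


def key_str(key: tuple) -> str:
    return "{}:{}:{}:{}".format(*key)


@dataclass
class CohortConfig:
    n_patients: int = 120
    seed: int = 0
    gene_frequencies: dict = field(default_factory=lambda: dict(DEFAULT_GENE_COUNTS))
    allelic_weights: dict = field(default_factory=lambda: dict(DEFAULT_ALLELIC_WEIGHTS))
    chip_enrollment_count: int = 3
    mr_true_rate: float = 0.43
    responder_decline_range: tuple = (0.70, 0.95)
    nonresponder_decline_range: tuple = (0.0, 0.30)
    ctdna_depth: int = 5000
    pbmc_depth: int = 500
    tumor_depth: int = 400
    purity_range: tuple = (0.3, 0.9)
    ploidy: float = 2.0
    germline_enrollment_fraction: float = 0.57
    p_extra_germline: float = 0.5
    p_chip_variant: float = 0.38
    chip_vaf_range: tuple = (0.01, 0.10)
    n_somatic_range: tuple = (2, 5)
    n_background_segments: int = 8
    snps_per_segment: int = 12
    coverage_noise_sd: float = 0.02
    overdispersion: Optional[float] = None  # beta-binomial rho; None = binomial
    ctdna_schedule: tuple = (0.0, 3.0, 6.0, 9.0, 12.0)
    scan_schedule: tuple = (0.0, 6.0, 12.0, 18.0, 27.0, 36.0, 45.0, 54.0)
    data_cutoff_weeks: float = 60.0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValidationError("n_patients must be positive")
        if not self.gene_frequencies or min(self.gene_frequencies.values()) < 0:
            raise ValidationError("gene_frequencies must be non-negative")
        unknown = set(self.gene_frequencies) - set(ENROLLMENT_GENES)
        if unknown:
            raise ValidationError(f"unknown enrollment genes: {sorted(unknown)}")
        for name in ("mr_true_rate", "p_extra_germline", "p_chip_variant",
                     "germline_enrollment_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} outside [0, 1]")
        for name in ("responder_decline_range", "nonresponder_decline_range",
                     "chip_vaf_range", "purity_range"):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValidationError(f"{name} must be an interval within [0, 1]")
        if self.chip_enrollment_count > self.n_patients:
            raise ValidationError("chip_enrollment_count exceeds n_patients")
        if min(self.ctdna_depth, self.pbmc_depth, self.tumor_depth) <= 0:
            raise ValidationError("sequencing depths must be positive")


def _draw_reads(rng: np.random.Generator, depth: int, vaf: float,
                overdispersion: Optional[float]) -> int:
    """Binomial read counts; optional beta-binomial overdispersion."""
    vaf = min(max(vaf, 0.0), 1.0)
    if vaf == 0.0:
        return 0
    if overdispersion:
        conc = (1.0 - overdispersion) / overdispersion
        p = rng.beta(vaf * conc, (1.0 - vaf) * conc)
        return int(rng.binomial(depth, p))
    return int(rng.binomial(depth, vaf))


def forward_segment(major: int, minor: int, purity: float, ploidy: float,
                    chrom: str, start: int, end: int,
                    depth: int = 400, n_snps: int = 12,
                    rng: Optional[np.random.Generator] = None,
                    coverage_noise_sd: float = 0.0) -> SegmentCN:
    """Generate one segment's observables from the purity/ploidy mixture.

    With ``rng`` None the output is noise-free: coverage exactly matches the
    expected log2 ratio and the folded-BAF summary equals its expectation.
    """
    l2r = expected_log2r(purity, ploidy, major + minor)
    tumor_cov = depth * (2.0 ** l2r)
    seg = SegmentCN(chrom=chrom, start=start, end=end,
                    tumor_coverage=tumor_cov, reference_coverage=float(depth))
    baf = expected_folded_baf(purity, major, minor)
    if rng is None:
        seg.baf_folded = baf
        return seg
    if coverage_noise_sd > 0:
        seg.tumor_coverage = tumor_cov * math.exp(rng.normal(0.0, coverage_noise_sd))
    positions = np.sort(rng.integers(start, end + 1, size=n_snps))
    for pos in positions:
        p = baf if rng.random() < 0.5 else 1.0 - baf
        alt = int(rng.binomial(depth, p))
        seg.snps.append(SNP(pos=int(pos), alt_reads=alt, ref_reads=depth - alt))
    return seg


def _variant_identity(rng: np.random.Generator, chrom: str, pos: int) -> tuple:
    ref = BASES[rng.integers(0, 4)]
    alt = BASES[(BASES.index(ref) + 1 + rng.integers(0, 3)) % 4]
    return chrom, pos, ref, alt


def _decline_factor(t: float, decline: float, t_reach: float) -> float:
    """Multiplier applied to a baseline VAF at on-treatment time t."""
    if t <= 0:
        return 1.0
    if t >= t_reach:
        return 1.0 - decline
    return 1.0 - decline * (t / t_reach)


def simulate_cohort(config: CohortConfig) -> tuple[list[PatientRecord], dict]:
    """Generate (patients, truth).  Fully reproducible given config.seed;
    each patient draws from a substream derived from (seed, index)."""
    config.validate()
    master = np.random.default_rng(config.seed)
    genes = sorted(config.gene_frequencies)
    gene_p = np.array([config.gene_frequencies[g] for g in genes], dtype=float)
    gene_p /= gene_p.sum()
    cats = sorted(config.allelic_weights)
    cat_p = np.array([config.allelic_weights[c] for c in cats], dtype=float)
    cat_p /= cat_p.sum()
    chip_patients = set(master.choice(config.n_patients,
                                      size=config.chip_enrollment_count,
                                      replace=False).tolist())
    patients, truth = [], {}
    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, i])
        pid = f"P{i + 1:04d}"
        is_chip_patient = i in chip_patients
        gene = "ATM" if is_chip_patient else str(rng.choice(genes, p=gene_p))
        category = "CHIP" if is_chip_patient else str(rng.choice(cats, p=cat_p))
        patient, pt_truth = _simulate_patient(pid, gene, category, config, rng)
        patients.append(patient)
        truth[pid] = pt_truth
    return patients, truth


def _simulate_patient(pid: str, gene: str, category: str,
                      config: CohortConfig,
                      rng: np.random.Generator) -> tuple[PatientRecord, dict]:
    purity = float(rng.uniform(*config.purity_range))
    ploidy = config.ploidy
    region = GENE_REGIONS[gene]
    is_chip_patient = category == "CHIP"
    # Subclonal events are by definition somatic; CHIP is hematopoietic.
    germline = (not is_chip_patient and category != "subclonal"
                and rng.random() < config.germline_enrollment_fraction)
    tumor_types = TUMOR_TYPES_BY_GENE.get(gene, ("other",))
    tumor_type = str(rng.choice(tumor_types))

    patient = PatientRecord(
        patient_id=pid, tumor_type=tumor_type, enrollment_gene=gene,
        enrollment_origin="germline" if germline else "somatic",
        dose_mg_per_day=float(rng.choice([120.0, 160.0, 160.0, 200.0])),
        schedule="3/4", purity=purity, ploidy=ploidy,
        data_cutoff_weeks=config.data_cutoff_weeks,
    )
    variant_origins: dict[str, str] = {}

    # ------------------------------------------------------------------
    # Copy-number segments and the enrollment-gene tumor mutation(s)
    # ------------------------------------------------------------------
    mid = (region.start + region.end) // 2
    segments: list[SegmentCN] = []
    planted_cn: list[tuple] = []
    criterion = "none"

    def add_segment(major, minor, chrom, start, end):
        seg = forward_segment(major, minor, purity, ploidy, chrom, start, end,
                              depth=config.tumor_depth,
                              n_snps=config.snps_per_segment, rng=rng,
                              coverage_noise_sd=config.coverage_noise_sd)
        segments.append(seg)
        planted_cn.append((chrom, start, end, major, minor))

    def add_tumor_call(pos, m_copies, total_cn, is_germline):
        chrom, p, ref, alt = _variant_identity(rng, region.chrom, pos)
        if is_germline:
            num = m_copies * purity + (1.0 - purity)
        else:
            num = m_copies * purity
        vaf = num / (total_cn * purity + 2.0 * (1.0 - purity))
        alt_reads = max(_draw_reads(rng, config.tumor_depth, vaf,
                                    config.overdispersion), 1)
        patient.variants.append(VariantCall.from_reads(
            pid, "tumor", 0.0, chrom, p, ref, alt, gene,
            alt_reads, config.tumor_depth))
        return chrom, p, ref, alt

    mut_keys: list[tuple] = []
    if category == "biallelic":
        criterion = str(rng.choice(["homozygous_deletion", "compound_heterozygous",
                                    "mutation_and_LOH",
                                    "mutation_and_nonoverlapping_loss"]))
        if criterion == "homozygous_deletion":
            add_segment(0, 0, region.chrom, region.start, region.end)
        elif criterion == "compound_heterozygous":
            add_segment(1, 1, region.chrom, region.start, region.end)
            mut_keys.append(add_tumor_call(mid - 20_000, 1, 2, germline))
            mut_keys.append(add_tumor_call(mid + 20_000, 1, 2, False))
        elif criterion == "mutation_and_LOH":
            major = int(rng.choice([1, 2]))
            add_segment(major, 0, region.chrom, region.start, region.end)
            mut_keys.append(add_tumor_call(mid, major, major, germline))
        else:  # mutation and non-overlapping loss
            split = mid + 40_000
            add_segment(1, 1, region.chrom, region.start, split)
            add_segment(1, 0, region.chrom, split + 1, region.end)
            mut_keys.append(add_tumor_call(mid, 1, 2, germline))
    elif category == "monoallelic":
        if rng.random() < 0.5:
            add_segment(1, 1, region.chrom, region.start, region.end)
            mut_keys.append(add_tumor_call(mid, 1, 2, germline))
        else:  # heterozygous loss without a mutation
            add_segment(1, 0, region.chrom, region.start, region.end)
    elif category == "subclonal":
        add_segment(1, 1, region.chrom, region.start, region.end)
        chrom, p, ref, alt = _variant_identity(rng, region.chrom, mid)
        sub_vaf = 0.3 * expected_vaf(purity, 2, 1)
        alt_reads = max(_draw_reads(rng, config.tumor_depth, sub_vaf,
                                    config.overdispersion), 1)
        patient.variants.append(VariantCall.from_reads(
            pid, "tumor", 0.0, chrom, p, ref, alt, gene,
            alt_reads, config.tumor_depth))
        mut_keys.append((chrom, p, ref, alt))
    else:  # no_loss and CHIP: neutral gene segment, no tumor mutation
        add_segment(1, 1, region.chrom, region.start, region.end)

    # Background copy-neutral segments anchor the log2R median at zero.
    for j in range(config.n_background_segments):
        start = 50_000_000 + j * 2_000_000
        chrom = f"chr{(j % 12) + 1}"
        add_segment(1, 1, chrom, start, start + 1_000_000)
    patient.segments = segments

    # Designated enrollment alteration
    if mut_keys:
        enr = mut_keys[0]
    elif is_chip_patient or category in ("no_loss",):
        # Alteration reported by an outside assay; plant an identity so the
        # CHIP/not-detected paths are exercised downstream.
        enr = _variant_identity(rng, region.chrom, mid)
    else:
        enr = None
    if enr is not None:
        patient.enrollment_chrom, patient.enrollment_pos, \
            patient.enrollment_ref, patient.enrollment_alt = enr

    # ------------------------------------------------------------------
    # ctDNA and PBMC calls
    # ------------------------------------------------------------------
    is_mr = bool(rng.random() < config.mr_true_rate)
    decline_range = (config.responder_decline_range if is_mr
                     else config.nonresponder_decline_range)
    decline = float(rng.uniform(*decline_range))
    t_reach = float(rng.choice([3.0, 6.0], p=[0.7, 0.3]))

    n_som = int(rng.integers(config.n_somatic_range[0],
                             config.n_somatic_range[1] + 1))
    plasma: list[tuple[tuple, str, float, str]] = []  # key, gene, base vaf, origin
    for j in range(n_som):
        mgene = str(rng.choice(MONITORING_GENES))
        mregion = GENE_REGIONS[mgene]
        key = _variant_identity(rng, mregion.chrom,
                                int(mregion.start + 1_000 + j * 631))
        base = (float(rng.uniform(0.02, 0.15)) if j == 0
                else float(np.exp(rng.uniform(np.log(0.004), np.log(0.08)))))
        plasma.append((key, mgene, base, "somatic_tumor"))
    if is_chip_patient and enr is not None:
        chip_vaf = float(rng.uniform(*config.chip_vaf_range))
        plasma.append((enr, gene, chip_vaf, "CHIP"))
    elif enr is not None and category not in ("no_loss",):
        # The enrollment alteration is itself monitorable in plasma.
        base = float(rng.uniform(0.02, 0.15))
        if germline:
            plasma.append((enr, gene, 0.5, "germline"))
        else:
            plasma.append((enr, gene, base, "somatic_tumor"))
    if rng.random() < config.p_extra_germline:
        key = _variant_identity(rng, "chr2", int(rng.integers(1e6, 2e6)))
        plasma.append((key, "other", 0.5, "germline"))
    if rng.random() < config.p_chip_variant:
        for j in range(int(rng.integers(1, 3))):
            key = _variant_identity(rng, GENE_REGIONS["TP53"].chrom,
                                    int(GENE_REGIONS["TP53"].start + 500 + 97 * j))
            chip_vaf = float(rng.uniform(*config.chip_vaf_range))
            plasma.append((key, "TP53", chip_vaf, "CHIP"))

    for key, vgene, base, origin in plasma:
        variant_origins[key_str(key)] = origin
        for t in config.ctdna_schedule:
            if origin == "somatic_tumor":
                vaf_t = base * _decline_factor(t, decline, t_reach)
            else:
                vaf_t = base  # germline and CHIP levels do not track the tumor
            alt = _draw_reads(rng, config.ctdna_depth, vaf_t, config.overdispersion)
            if alt > 0:
                patient.variants.append(VariantCall.from_reads(
                    pid, "ctDNA", t, *key, vgene, alt, config.ctdna_depth))
        if origin in ("germline", "CHIP"):
            pbmc_vaf = base if origin == "CHIP" else 0.5
            alt = _draw_reads(rng, config.pbmc_depth, pbmc_vaf,
                              config.overdispersion)
            if alt > 0:
                patient.variants.append(VariantCall.from_reads(
                    pid, "PBMC", 0.0, *key, vgene, alt, config.pbmc_depth))

    # ------------------------------------------------------------------
    # Clinical course tied to the planted benefit label
    # ------------------------------------------------------------------
    benefit = bool(rng.random() < (0.7 if is_mr else 0.2))
    recist_responder = bool(benefit and rng.random() < 0.3)
    cutoff = config.data_cutoff_weeks
    if benefit:
        prog = 18.0 + float(rng.exponential(16.0))
        scans_after = [t for t in config.scan_schedule if t >= prog]
        progression = scans_after[0] if scans_after and scans_after[0] <= cutoff else None
    else:
        progression = float(rng.choice([6.0, 12.0]))
    stop = min(progression, cutoff) if progression is not None else cutoff
    patient.progression_time_weeks = progression
    patient.treatment_stop_weeks = stop

    baseline_lesions = [float(rng.uniform(20.0, 50.0)) for _ in range(2)]
    shrink = float(rng.uniform(0.40, 0.60)) if recist_responder else 0.0
    scan_times = [t for t in config.scan_schedule
                  if t <= (progression if progression is not None else cutoff)]
    for t in scan_times:
        for k, base_mm in enumerate(baseline_lesions):
            if t == 0:
                factor = 1.0
            elif recist_responder:
                factor = max(1.0 - shrink * min(t / 12.0, 1.0), 1.0 - shrink)
            elif benefit:
                factor = float(rng.uniform(0.95, 1.05))
            else:
                factor = 1.0 if (progression is None or t < progression) \
                    else float(rng.uniform(1.25, 1.45))
            patient.lesions.append(LesionMeasurement(
                lesion_id=f"{pid}-T{k + 1}", kind="target", timepoint_weeks=t,
                longest_diameter_mm=round(base_mm * factor, 1)))
        if (not benefit and progression is not None and t == progression):
            patient.lesions.append(LesionMeasurement(
                lesion_id=f"{pid}-NEW", kind="target", timepoint_weeks=t,
                longest_diameter_mm=12.0, new_lesion=True))

    marker = {"prostate": "PSA", "ovarian": "CA125"}.get(tumor_type)
    if marker is not None:
        base_value = 50.0 if marker == "PSA" else 400.0
        # Marker kinetics follow the planted clinical course: deep declines
        # only for molecular responders who also derive benefit.
        marker_decline = decline if (is_mr and benefit) else 0.1
        for t in config.ctdna_schedule:
            value = base_value * _decline_factor(t, marker_decline, t_reach)
            patient.markers.append(MarkerMeasurement(
                marker=marker, timepoint_weeks=t, value=round(value, 2)))

    pt_truth = {
        "enrollment_gene": gene,
        "enrollment_origin": patient.enrollment_origin,
        "allelic_category": category,
        "biallelic_criterion": criterion,
        "purity": purity, "ploidy": ploidy,
        "segments": planted_cn,
        "variant_origins": variant_origins,
        "is_mr": is_mr, "decline": decline,
        "benefit": benefit, "recist_responder": recist_responder,
        "enrollment_key": key_str(enr) if enr is not None else None,
    }
    return patient, pt_truth


# ---------------------------------------------------------------------------
# Truth recovery report
# ---------------------------------------------------------------------------

def _confusion(pairs: Sequence[tuple[str, str]]) -> dict:
    table: dict[str, dict[str, int]] = {}
    for truth_label, called in pairs:
        table.setdefault(truth_label, {}).setdefault(called, 0)
        table[truth_label][called] += 1
    return table


def truth_report(truth: dict,
                 origin_calls: Optional[dict] = None,
                 mr_results: Optional[Sequence] = None,
                 allelic_calls: Optional[dict] = None,
                 benefit_calls: Optional[dict] = None) -> dict:
    """Confusion matrices and recovery metrics for pipeline outputs.

    Each argument is keyed by patient id and compared against the planted
    truth; a patient set mismatch is an error.
    """
    report: dict = {}
    if origin_calls is not None:
        if set(origin_calls) - set(truth):
            raise ValidationError("origin_calls contain unknown patients")
        pairs = []
        for pid, calls in origin_calls.items():
            planted = truth[pid]["variant_origins"]
            for key, call in calls.items():
                ks = key_str(key) if isinstance(key, tuple) else key
                if ks in planted:
                    pairs.append((planted[ks], call.origin))
        correct = sum(t == c for t, c in pairs)
        report["origin"] = {"n": len(pairs),
                            "accuracy": correct / len(pairs) if pairs else float("nan"),
                            "confusion": _confusion(pairs)}
    if mr_results is not None:
        pairs = [(truth[r.patient_id]["is_mr"], r.is_mr)
                 for r in mr_results if r.evaluable]
        tp = sum(t and c for t, c in pairs)
        fn = sum(t and not c for t, c in pairs)
        tn = sum(not t and not c for t, c in pairs)
        fp = sum(not t and c for t, c in pairs)
        report["mr"] = {
            "n_evaluable": len(pairs),
            "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
            "specificity": tn / (tn + fp) if tn + fp else float("nan"),
            "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
        }
    if allelic_calls is not None:
        pairs = [(truth[pid]["allelic_category"], status.category)
                 for pid, status in allelic_calls.items()]
        correct = sum(t == c for t, c in pairs)
        report["allelic"] = {"n": len(pairs),
                             "accuracy": correct / len(pairs) if pairs else float("nan"),
                             "confusion": _confusion(pairs)}
    if benefit_calls is not None:
        pairs = [(truth[pid]["benefit"], called)
                 for pid, called in benefit_calls.items()]
        correct = sum(t == c for t, c in pairs)
        report["benefit"] = {"n": len(pairs),
                             "accuracy": correct / len(pairs) if pairs else float("nan")}
    return report


def write_truth(truth: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(truth, handle, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# PK profile simulation (one-compartment with first-order absorption)
# ---------------------------------------------------------------------------

PK_T_HALF_H = 5.8       # reported median terminal half-life, used as the
                        # simulator's elimination parameter
PK_KA_PER_H = 2.0       # absorption rate giving Tmax in the reported 1-2 h
PK_V_OVER_F_L = 50.0

PK_SAMPLING_H = (0.25, 0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 24.0)


def one_compartment_conc(dose_mg: float, t_h: np.ndarray,
                         ke: float = math.log(2.0) / PK_T_HALF_H,
                         ka: float = PK_KA_PER_H,
                         v_over_f: float = PK_V_OVER_F_L) -> np.ndarray:
    """ng/mL concentrations for an oral dose under first-order absorption."""
    scale = dose_mg * 1e6 / (v_over_f * 1e3)  # mg -> ng, L -> mL
    return scale * ka / (ka - ke) * (np.exp(-ke * t_h) - np.exp(-ka * t_h))


def simulate_pk_profiles(doses_mg: Sequence[float], n_per_dose: int, seed: int,
                         cv: float = 0.2, fed_ratio: float = 1.0,
                         times_h: Sequence[float] = PK_SAMPLING_H,
                         lloq: float = 1.0) -> list[ConcentrationProfile]:
    """Profiles with lognormal between-subject variability on clearance.

    ``fed_ratio`` scales exposure for a fed occasion (paired fed profiles
    share the subject's random effect so the planted ratio is exact in
    expectation).
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(times_h, dtype=float)
    out = []
    subject = 0
    for dose in doses_mg:
        for _ in range(n_per_dose):
            subject += 1
            eta = rng.normal(0.0, cv) if cv > 0 else 0.0
            for fed in ((False, True) if fed_ratio != 1.0 else (False,)):
                conc = one_compartment_conc(dose, t) * math.exp(eta)
                if fed:
                    conc = conc * fed_ratio
                values = [float(c) if c >= lloq else None for c in conc]
                out.append(ConcentrationProfile(
                    patient_id=f"S{subject:03d}", dose_mg=float(dose),
                    fed=fed, times_h=list(t), concentrations=values, lloq=lloq))
    return out
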