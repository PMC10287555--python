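"""Stage orchestration: run each analysis over a cohort and emit the bundle.

Stages form a DAG: simulate -> classify -> mr -> allelic -> endpoints ->
stats -> nca -> report.  Each stage is a plain function over in-memory
records; the CLI wraps these with file I/O, hashing and logging.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import allelic_status as al
from . import clinical_endpoints as ce
from . import molecular_response as mr
from . import variant_classification as vc
from .io_model import PatientRecord
from .panel import overlapping_segments
from .reference_tables import REFERENCE_COMPARISONS, printed_p_matches


def classify_cohort_origins(patients: Sequence[PatientRecord]) -> dict:
    """Per-patient variant-origin calls plus the enrollment-CHIP flag."""
    out = {}
    for p in patients:
        origins = vc.classify_patient_origins(p)
        flag = (vc.flag_enrollment_chip(p, origins)
                if p.enrollment_key is not None
                else vc.EnrollmentChipFlag(is_chip=False, detected=False))
        out[p.patient_id] = {"origins": origins, "enrollment_chip": flag}
    return out


def origins_table(classified: dict) -> pd.DataFrame:
    rows = []
    for pid, entry in classified.items():
        for call in entry["origins"].values():
            chrom, pos, ref, alt = call.key
            rows.append({"patient_id": pid, "chrom": chrom, "pos": pos,
                         "ref": ref, "alt": alt, "origin": call.origin,
                         "pbmc_vaf": call.pbmc_vaf,
                         "ctdna_ref_vaf": call.ctdna_ref_vaf,
                         "vaf_ratio": call.vaf_ratio,
                         "pbmc_alt_reads": call.pbmc_alt_reads})
    return pd.DataFrame(rows, columns=["patient_id", "chrom", "pos", "ref",
                                       "alt", "origin", "pbmc_vaf",
                                       "ctdna_ref_vaf", "vaf_ratio",
                                       "pbmc_alt_reads"])


def call_cohort_mr(patients: Sequence[PatientRecord],
                   classified: dict) -> list[mr.MolecularResponseResult]:
    return [mr.call_molecular_response(p, classified[p.patient_id]["origins"])
            for p in patients]


def mr_table(results: Sequence[mr.MolecularResponseResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "patient_id": r.patient_id, "evaluable": int(r.evaluable),
        "n_monitorable": len(r.monitorable_variants),
        "best_mvafr": r.best_mvafr if r.best_mvafr is not None else float("nan"),
        "is_mr": int(r.is_mr),
        "time_to_mr_weeks": (r.time_to_mr_weeks if r.time_to_mr_weeks is not None
                             else float("nan")),
    } for r in results])


def build_gene_evidence(patient: PatientRecord,
                        enrollment_is_chip: bool) -> al.GeneEvidence:
    """Assemble mutation + copy-number evidence for the enrollment gene."""
    germline_key = (patient.enrollment_key
                    if patient.enrollment_origin == "germline" else None)
    mutations = [
        al.Mutation(pos=v.pos, alt_reads=v.alt_reads, total_reads=v.total_reads,
                    germline=v.key == germline_key,
                    is_enrollment=v.key == patient.enrollment_key)
        for v in patient.calls("tumor") if v.gene == patient.enrollment_gene
    ]
    segments = overlapping_segments(patient.segments, patient.enrollment_gene)
    return al.GeneEvidence(gene=patient.enrollment_gene, mutations=mutations,
                           segments=segments, purity=patient.purity,
                           ploidy=patient.ploidy,
                           enrollment_is_chip=enrollment_is_chip)


def classify_cohort_allelic(patients: Sequence[PatientRecord],
                            classified: dict) -> dict[str, al.AllelicStatus]:
    """Infer segment copy numbers, then classify each enrollment gene."""
    out = {}
    for p in patients:
        al.infer_patient_segments(p.segments, p.purity, p.ploidy)
        flag = classified[p.patient_id]["enrollment_chip"]
        evidence = build_gene_evidence(p, flag.is_chip)
        out[p.patient_id] = al.classify_allelic_status(evidence)
    return out


def allelic_table(calls: dict) -> pd.DataFrame:
    return pd.DataFrame([{"patient_id": pid, "category": s.category,
                          "criterion": s.criterion}
                         for pid, s in calls.items()])


def derive_cohort_endpoints(patients: Sequence[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in patients:
        recist = ce.evaluate_recist(p.patient_id, p.lesions)
        markers_present = {m.marker for m in p.markers}
        marker_resp = any(
            ce.evaluate_marker_response(p.markers, m, p.progression_time_weeks)
            for m in markers_present)
        responder = recist.responder or marker_resp
        pfs, dot = ce.derive_pfs_dot(p)
        benefit = ce.derive_clinical_benefit(responder, dot.time_weeks,
                                             p.progression_time_weeks)
        rows.append({"patient_id": p.patient_id,
                     "best_overall": recist.best_overall,
                     "best_pct_change_tl": recist.best_pct_change_tl,
                     "recist_responder": int(recist.responder),
                     "marker_responder": int(marker_resp),
                     "responder": int(responder),
                     "clinical_benefit": int(benefit),
                     "pfs_weeks": pfs.time_weeks, "pfs_event": int(pfs.event),
                     "dot_weeks": dot.time_weeks, "dot_event": int(dot.event)})
    return pd.DataFrame(rows)


def cohort_stats(endpoints: pd.DataFrame, mr_results: Sequence,
                 allelic_calls: dict) -> dict:
    """Group comparisons over a cohort: MR and CBR by allelic status
    (Fisher), PFS and DOT by MR (log-rank, with KM medians)."""
    stats: dict = {}
    mr_by_pid = {r.patient_id: r for r in mr_results}
    biallelic = {pid for pid, s in allelic_calls.items() if s.category == "biallelic"}
    non_biallelic = {pid for pid, s in allelic_calls.items()
                     if s.category in ("monoallelic", "no_loss", "subclonal")}

    def fisher_groups(flag_by_pid: dict) -> Optional[dict]:
        a = sum(flag_by_pid.get(pid, 0) for pid in biallelic if pid in flag_by_pid)
        b = sum(1 for pid in biallelic if pid in flag_by_pid) - a
        c = sum(flag_by_pid.get(pid, 0) for pid in non_biallelic if pid in flag_by_pid)
        d = sum(1 for pid in non_biallelic if pid in flag_by_pid) - c
        if a + b == 0 or c + d == 0:
            return None
        return {"table": [[a, b], [c, d]],
                "p": ce.fisher_exact([[a, b], [c, d]])}

    benefit_by_pid = dict(zip(endpoints.patient_id, endpoints.clinical_benefit))
    stats["cbr_by_allelic_status"] = fisher_groups(benefit_by_pid)
    mr_flag = {pid: int(r.is_mr) for pid, r in mr_by_pid.items() if r.evaluable}
    stats["mr_by_allelic_status"] = fisher_groups(mr_flag)

    mr_group, no_mr_group = [], []
    for _, row in endpoints.iterrows():
        r = mr_by_pid.get(row.patient_id)
        if r is None or not r.evaluable:
            continue
        datum_pfs = ce.SurvivalDatum(row.pfs_weeks, bool(row.pfs_event))
        (mr_group if r.is_mr else no_mr_group).append(datum_pfs)
    if mr_group and no_mr_group:
        stat, p = ce.logrank_test([mr_group, no_mr_group])
        _, med_mr = ce.km_estimate(mr_group)
        _, med_no = ce.km_estimate(no_mr_group)
        stats["pfs_by_mr"] = {"logrank_statistic": stat, "p": p,
                              "median_mr_weeks": med_mr,
                              "median_no_mr_weeks": med_no}
    return stats


def reproduce_reference_tables() -> pd.DataFrame:
    """Recompute each embedded published comparison and flag agreement."""
    rows = []
    for cmp in REFERENCE_COMPARISONS:
        p = ce.fisher_exact(cmp.table)
        rows.append({"comparison": cmp.name, "group1": cmp.group1,
                     "group2": cmp.group2,
                     "a": cmp.table.a, "b": cmp.table.b,
                     "c": cmp.table.c, "d": cmp.table.d,
                     "computed_p": p, "printed_p": cmp.printed_p,
                     "match": printed_p_matches(p, cmp.printed_p),
                     "primary": cmp.primary})
    return pd.DataFrame(rows)


def file_sha256(path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(1 << 16), b""):
            digest.update(chunk)
    return digest.hexdigest()


def append_log(log_path: Path, entry: dict) -> None:
    log_path.parent.mkdir(parents=True, exist_ok=True)
    with open(log_path, "a", encoding="utf-8") as handle:
        handle.write(json.dumps(entry, sort_keys=True, default=str) + "\n")
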