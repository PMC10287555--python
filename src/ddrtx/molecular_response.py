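"""ctDNA molecular-response calling from longitudinal variant allele fractions.

The statistic is the mean VAF (mVAF) over a patient's *monitorable* somatic
variants at each timepoint, and the on-treatment ratio to baseline
(mVAFR_t = mVAF_t / mVAF_0).  A molecular response (MR) is a >= 50%
reduction in mVAFR at at least one on-treatment timepoint, i.e.
best mVAFR (the minimum) <= 0.5.

Monitorable variants are tumor-somatic ctDNA variants (germline, CHIP and
ambiguous PBMC-positive calls are filtered first) whose VAF exceeds 0.5% at
any timepoint; the patient is evaluable when at least one monitorable
variant exceeds 1% at any timepoint, a baseline and at least one
on-treatment sample exist, and the baseline mVAF is positive.

The monitorable set is fixed from the union of all timepoints and a variant
undetected at a given timepoint contributes VAF 0 there, which keeps the
mean comparable across timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd

from .io_model import PatientRecord, VariantCall
from .variant_classification import OriginCall

VARIANT_MIN_VAF = 0.005   # per-variant monitorability threshold (> 0.5%)
PATIENT_MIN_VAF = 0.01    # at least one variant must exceed 1%
MR_THRESHOLD = 0.5        # mVAFR <= 0.5 is a molecular response


@dataclass
class MolecularResponseResult:
    patient_id: str
    monitorable_variants: set = field(default_factory=set)
    mvaf_by_timepoint: dict = field(default_factory=dict)
    mvafr_by_timepoint: dict = field(default_factory=dict)
    best_mvafr: Optional[float] = None
    is_mr: bool = False
    time_to_mr_weeks: Optional[float] = None
    evaluable: bool = False


def select_monitorable(ctdna_calls: Sequence[VariantCall],
                       origins: dict[tuple, OriginCall]) -> tuple[set, bool]:
    """Return (monitorable variant keys, patient evaluable).

    Evaluability here covers the sampling requirements (a variant > 1% and
    both baseline and on-treatment samples present); a zero baseline mVAF is
    handled by the caller.
    """
    max_vaf: dict[tuple, float] = {}
    timepoints = set()
    for call in ctdna_calls:
        timepoints.add(call.timepoint_weeks)
        origin = origins.get(call.key)
        if origin is not None and origin.origin != "somatic_tumor":
            continue
        max_vaf[call.key] = max(max_vaf.get(call.key, 0.0), call.vaf)
    monitorable = {k for k, v in max_vaf.items() if v > VARIANT_MIN_VAF}
    has_baseline = any(t < 0.5 for t in timepoints)
    has_on_tx = any(t >= 0.5 for t in timepoints)
    evaluable = (has_baseline and has_on_tx
                 and any(max_vaf[k] > PATIENT_MIN_VAF for k in monitorable))
    return monitorable, evaluable


def compute_mvaf(calls_at_timepoint: Sequence[VariantCall],
                 monitorable: set) -> float:
    """Arithmetic mean VAF over the monitorable set (undetected -> 0)."""
    if not monitorable:
        raise ValueError("mVAF undefined for an empty monitorable set")
    observed = {c.key: c.vaf for c in calls_at_timepoint}
    return sum(observed.get(k, 0.0) for k in monitorable) / len(monitorable)


def call_molecular_response(patient: PatientRecord,
                            origins: dict[tuple, OriginCall]) -> MolecularResponseResult:
    """Full per-patient trajectory: mVAF per timepoint, mVAFR, best, MR call."""
    result = MolecularResponseResult(patient_id=patient.patient_id)
    ctdna = patient.calls("ctDNA")
    monitorable, evaluable = select_monitorable(ctdna, origins)
    result.monitorable_variants = monitorable
    if not evaluable:
        return result

    by_timepoint: dict[float, list[VariantCall]] = {}
    for call in ctdna:
        by_timepoint.setdefault(call.timepoint_weeks, []).append(call)
    timepoints = sorted(by_timepoint)
    result.mvaf_by_timepoint = {t: compute_mvaf(by_timepoint[t], monitorable)
                                for t in timepoints}
    baseline_ts = [t for t in timepoints if t < 0.5]
    baseline = result.mvaf_by_timepoint[baseline_ts[0]]
    if baseline <= 0:
        return result  # mVAFR undefined; patient remains non-evaluable

    result.evaluable = True
    result.mvafr_by_timepoint = {t: result.mvaf_by_timepoint[t] / baseline
                                 for t in timepoints if t >= 0.5}
    result.best_mvafr = min(result.mvafr_by_timepoint.values())
    result.is_mr = result.best_mvafr <= MR_THRESHOLD
    if result.is_mr:
        result.time_to_mr_weeks = min(t for t, r in result.mvafr_by_timepoint.items()
                                      if r <= MR_THRESHOLD)
    return result


def summarize_mr_by_group(results: Sequence[MolecularResponseResult],
                          labels: dict[str, str]) -> pd.DataFrame:
    """Per-group MR numerators (MR) over evaluable denominators.

    ``labels`` maps patient_id -> group.  The output is suitable for 2x2
    Fisher testing; rates are NaN for groups with no evaluable patients.
    """
    rows = []
    for group in sorted(set(labels.values())):
        members = [r for r in results if labels.get(r.patient_id) == group]
        n_eval = sum(r.evaluable for r in members)
        n_mr = sum(r.is_mr for r in members if r.evaluable)
        rows.append({"group": group, "n_evaluable": n_eval, "n_mr": n_mr,
                     "mr_rate": n_mr / n_eval if n_eval else float("nan")})
    return pd.DataFrame(rows)
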