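"""Clinical endpoint derivation and trial comparison statistics.

Implements a simplified RECIST 1.1 evaluation (sum of <= 5 target-lesion
diameters, no nodal short-axis special-casing), confirmed tumor-marker
responses (PSA per PCWG3, CA-125 per GCIG), the modified clinical-benefit
definition (response, or >= 16 weeks on treatment without prior
progression), PFS/DOT survival data with their censoring rules, Kaplan-Meier
and log-rank analyses (via lifelines), and a two-sided Fisher exact test
using the point-probability rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import hypergeom

from .io_model import (ContingencyTable2x2, LesionMeasurement,
                       MarkerMeasurement, PatientRecord, ValidationError)

PR_THRESHOLD = 0.70          # TL sum <= 70% of baseline
PD_NADIR_FACTOR = 1.20       # TL sum >= 120% of nadir ...
PD_MIN_INCREASE_MM = 5.0     # ... with an absolute increase >= 5 mm
CONFIRM_WINDOW_WEEKS = 4.0   # RECIST and CA-125 confirmation >= 28 days
PSA_CONFIRM_WEEKS = 3.0      # PSA confirmation >= 3 weeks
MARKER_DECLINE = 0.5         # confirmed >= 50% decline
CA125_ULN = 35.0             # U/mL; baseline must be >= 2x ULN
CBR_MIN_WEEKS = 16.0
PROGRESSION_GUARD_WEEKS = 4.0


@dataclass
class ResponseAssessment:
    patient_id: str
    categories_by_timepoint: dict = field(default_factory=dict)  # t -> CR/PR/SD/PD/NE
    best_overall: str = "NE"          # CR | cPR | uPR | SD | PD | NE
    best_pct_change_tl: Optional[float] = None
    responder: bool = False           # RECIST CR/PR (confirmed or not)
    marker_responder: bool = False


@dataclass(frozen=True)
class SurvivalDatum:
    time_weeks: float
    event: bool
    group: str = ""


# ---------------------------------------------------------------------------
# RECIST 1.1 (simplified)
# ---------------------------------------------------------------------------

def evaluate_recist(patient_id: str,
                    lesions: Sequence[LesionMeasurement]) -> ResponseAssessment:
    """Per-timepoint RECIST category and best overall response.

    PR: TL sum <= 0.70 x baseline.  CR: TL sum 0 with no residual
    non-target disease and no new lesion.  PD: TL sum >= 1.20 x nadir with
    an absolute increase >= 5 mm, or any new lesion.  SD otherwise.
    PR/CR is confirmed by a qualifying assessment >= 28 days later.
    """
    out = ResponseAssessment(patient_id=patient_id)
    timepoints = sorted({les.timepoint_weeks for les in lesions})
    baseline_ts = [t for t in timepoints if t < 0.5]
    if not baseline_ts:
        return out

    def tl_sum(t: float) -> float:
        return sum(les.longest_diameter_mm for les in lesions
                   if les.kind == "target" and les.timepoint_weeks == t)

    baseline_sum = tl_sum(baseline_ts[0])
    if baseline_sum <= 0:
        return out

    on_tx = [t for t in timepoints if t >= 0.5]
    nadir = baseline_sum
    sums = {}
    for t in on_tx:
        s = sums[t] = tl_sum(t)
        new_lesion = any(les.new_lesion for les in lesions
                         if les.timepoint_weeks == t)
        nontarget_present = any(les.kind == "non_target"
                                and les.longest_diameter_mm > 0
                                for les in lesions if les.timepoint_weeks == t)
        pd_by_tl = (s >= PD_NADIR_FACTOR * nadir
                    and s - nadir >= PD_MIN_INCREASE_MM)
        if pd_by_tl or new_lesion:
            cat = "PD"
        elif s == 0 and not nontarget_present:
            cat = "CR"
        elif s <= PR_THRESHOLD * baseline_sum:
            cat = "PR"
        else:
            cat = "SD"
        out.categories_by_timepoint[t] = cat
        nadir = min(nadir, s)

    if on_tx:
        out.best_pct_change_tl = 100.0 * (min(sums.values()) - baseline_sum) / baseline_sum

    cats = out.categories_by_timepoint
    resp_ts = [t for t, c in cats.items() if c in ("PR", "CR")]
    confirmed = any(t2 - t1 >= CONFIRM_WINDOW_WEEKS
                    for i, t1 in enumerate(resp_ts)
                    for t2 in resp_ts[i + 1:])
    if any(c == "CR" for c in cats.values()):
        cr_ts = [t for t, c in cats.items() if c == "CR"]
        cr_confirmed = any(t2 - t1 >= CONFIRM_WINDOW_WEEKS
                           for i, t1 in enumerate(cr_ts) for t2 in cr_ts[i + 1:])
        out.best_overall = "CR" if cr_confirmed else ("cPR" if confirmed else "uPR")
    elif resp_ts:
        out.best_overall = "cPR" if confirmed else "uPR"
    elif any(c == "SD" for c in cats.values()):
        out.best_overall = "SD"
    elif cats:
        out.best_overall = "PD"
    out.responder = out.best_overall in ("CR", "cPR", "uPR")
    return out


# ---------------------------------------------------------------------------
# Tumor-marker response (PCWG3 PSA / GCIG CA-125)
# ---------------------------------------------------------------------------

def evaluate_marker_response(series: Sequence[MarkerMeasurement], marker: str,
                             progression_time_weeks: Optional[float] = None) -> bool:
    """Confirmed >= 50% marker decline from baseline.

    Confirmation requires a second qualifying value >= 3 weeks (PSA) or
    >= 28 days (CA-125) after the initial decline, and no progression
    before or within 4 weeks of the initial decline.  CA-125 additionally
    requires a baseline >= 2x the upper limit of normal (35 U/mL).
    """
    values = sorted([m for m in series if m.marker == marker],
                    key=lambda m: m.timepoint_weeks)
    baseline = [m for m in values if m.timepoint_weeks < 0.5]
    if not baseline:
        return False
    base = baseline[0].value
    if base <= 0:
        return False
    if marker == "CA125" and base < 2 * CA125_ULN:
        return False
    confirm_gap = PSA_CONFIRM_WEEKS if marker == "PSA" else CONFIRM_WINDOW_WEEKS
    qualifying = [m.timepoint_weeks for m in values
                  if m.timepoint_weeks >= 0.5 and m.value <= MARKER_DECLINE * base]
    if not qualifying:
        return False
    t_initial = qualifying[0]
    if progression_time_weeks is not None and \
            progression_time_weeks < t_initial + PROGRESSION_GUARD_WEEKS:
        return False
    return any(t2 - t_initial >= confirm_gap for t2 in qualifying[1:])


# ---------------------------------------------------------------------------
# Clinical benefit and time-to-event data
# ---------------------------------------------------------------------------

def derive_clinical_benefit(responder: bool, dot_weeks: float,
                            progression_time_weeks: Optional[float]) -> bool:
    """Response, or >= 16 weeks of treatment without prior progression."""
    if responder:
        return True
    no_early_progression = (progression_time_weeks is None
                            or progression_time_weeks >= CBR_MIN_WEEKS)
    return dot_weeks >= CBR_MIN_WEEKS and no_early_progression


def derive_pfs_dot(patient: PatientRecord,
                   group: str = "") -> tuple[SurvivalDatum, SurvivalDatum]:
    """PFS and DOT survival data with the trial's censoring rules.

    PFS: event at the earlier of progression and death; otherwise censored
    at the last tumor assessment before cutoff.  DOT: event at treatment
    discontinuation; patients still on treatment are censored at the data
    cutoff.
    """
    cutoff = patient.data_cutoff_weeks
    events = [t for t in (patient.progression_time_weeks,
                          patient.death_time_weeks) if t is not None and t <= cutoff]
    if events:
        pfs = SurvivalDatum(min(events), True, group)
    else:
        assessed = [les.timepoint_weeks for les in patient.lesions
                    if les.timepoint_weeks <= cutoff]
        last = max(assessed, default=patient.treatment_start_weeks)
        pfs = SurvivalDatum(max(last, 1e-9), False, group)
    if patient.treatment_stop_weeks < cutoff:
        dot = SurvivalDatum(max(patient.treatment_stop_weeks
                                - patient.treatment_start_weeks, 1e-9), True, group)
    else:
        dot = SurvivalDatum(max(cutoff - patient.treatment_start_weeks, 1e-9),
                            False, group)
    return pfs, dot


def km_estimate(data: Sequence[SurvivalDatum]) -> tuple[pd.DataFrame, Optional[float]]:
    """Product-limit survival estimate and median (None if never reached).

    The median is the smallest time with S(t) <= 0.5.
    """
    if not data:
        raise ValidationError("km_estimate requires at least one subject")
    kmf = KaplanMeierFitter()
    kmf.fit([d.time_weeks for d in data], [d.event for d in data])
    surv = kmf.survival_function_
    surv = surv.rename(columns={surv.columns[0]: "S"})
    median = kmf.median_survival_time_
    if math.isinf(median):
        median = None
    return surv, median


def logrank_test(groups: Sequence[Sequence[SurvivalDatum]]) -> tuple[float, float]:
    """Log-rank chi-square (1 d.f. for two groups) and two-sided p."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValidationError("logrank_test requires >= 2 non-empty groups")
    times, events, labels = [], [], []
    for i, group in enumerate(groups):
        for d in group:
            times.append(d.time_weeks)
            events.append(d.event)
            labels.append(i)
    res = multivariate_logrank_test(np.asarray(times), np.asarray(labels),
                                    np.asarray(events))
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# Fisher's exact test (two-sided, point-probability rule)
# ---------------------------------------------------------------------------

TableLike = Union[ContingencyTable2x2, Sequence[Sequence[int]]]


def fisher_exact(table: TableLike) -> float:
    """Two-sided p: sum of hypergeometric probabilities of all margin-fixed
    tables whose point probability is <= that of the observed table.

    A table with a zero margin carries no information and returns p = 1.
    """
    if isinstance(table, ContingencyTable2x2):
        table.check()
        a, b, c, d = table.a, table.b, table.c, table.d
    else:
        (a, b), (c, d) = table
        ContingencyTable2x2(a, b, c, d).check()
    n1, n2, k = a + b, c + d, a + c
    n = n1 + n2
    if min(n1, n2, k, n - k) == 0:
        return 1.0
    support = np.arange(max(0, k - n2), min(k, n1) + 1)
    pmf = hypergeom.pmf(support, n, n1, k)
    p_obs = hypergeom.pmf(a, n, n1, k)
    return float(min(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum(), 1.0))
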