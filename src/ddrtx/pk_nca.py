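"""Non-compartmental pharmacokinetic analysis (NCA).

Parameters are computed from observed concentration-time profiles with no
model assumption: Cmax/Tmax are the observed maxima; AUC uses the
linear-up/log-down trapezoid (linear while concentrations rise, logarithmic
while they fall, which integrates mono-exponential decline exactly); the
terminal slope lambda_z comes from a log-linear least-squares fit over the
terminal points after Tmax, choosing the window (>= 3 points) that
maximizes adjusted r^2 and requiring r^2 >= 0.8; t1/2 = ln 2 / lambda_z and
AUC_0-inf = AUC_0-last + C_last / lambda_z.

Below-limit (BLQ) samples are set to zero before Tmax and excluded after
Tmax.  All computations use actual sampling times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io_model import ValidationError

LAMBDA_Z_MIN_POINTS = 3
LAMBDA_Z_MIN_R2 = 0.8


@dataclass
class ConcentrationProfile:
    """One dosing occasion: (time_h, concentration ng/mL) samples.

    A concentration of None marks a below-limit-of-quantification sample;
    values below ``lloq`` are likewise treated as BLQ.
    """

    patient_id: str
    dose_mg: float
    fed: bool
    times_h: Sequence[float]
    concentrations: Sequence[Optional[float]]
    lloq: float = 0.0

    def __post_init__(self):
        t = list(self.times_h)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValidationError("sampling times must be strictly increasing")
        if len(t) != len(self.concentrations):
            raise ValidationError("times and concentrations differ in length")

    def quantifiable(self) -> list[tuple[float, float]]:
        return [(t, c) for t, c in zip(self.times_h, self.concentrations)
                if c is not None and c >= self.lloq and c > 0]


@dataclass
class NCAResult:
    patient_id: str
    dose_mg: float
    fed: bool
    cmax: float
    tmax_h: float
    auc_0_last: float
    auc_0_12: Optional[float]
    auc_0_inf: Optional[float]
    lambda_z_per_h: Optional[float]
    t_half_h: Optional[float]
    terminal_fit_r2: Optional[float]
    n_terminal_points: int = 0


def _interval_auc(t1: float, c1: float, t2: float, c2: float) -> float:
    """Linear-up/log-down trapezoid over one interval."""
    dt = t2 - t1
    if c1 > c2 > 0:
        return dt * (c1 - c2) / math.log(c1 / c2)
    return dt * 0.5 * (c1 + c2)


def _interp_conc(t1: float, c1: float, t2: float, c2: float, t: float) -> float:
    """Concentration at t within [t1, t2] under the same up/down convention."""
    frac = (t - t1) / (t2 - t1)
    if c1 > c2 > 0:
        return c1 * (c2 / c1) ** frac
    return c1 + frac * (c2 - c1)


def _auc_to(points: list[tuple[float, float]], t_end: float) -> Optional[float]:
    """AUC from the first sample to t_end, interpolating the endpoint."""
    if points[-1][0] < t_end:
        return None
    total = 0.0
    for (t1, c1), (t2, c2) in zip(points, points[1:]):
        if t2 <= t_end:
            total += _interval_auc(t1, c1, t2, c2)
        else:
            c_end = _interp_conc(t1, c1, t2, c2, t_end)
            total += _interval_auc(t1, c1, t_end, c_end)
            break
    return total


def _fit_lambda_z(points: list[tuple[float, float]],
                  tmax: float) -> tuple[Optional[float], Optional[float], int]:
    """Terminal log-linear fit: (lambda_z, r^2, n points used).

    Candidate windows end at the last quantifiable point and start strictly
    after Tmax; the window maximizing adjusted r^2 wins, with ties going to
    the longer window.
    """
    terminal = [(t, c) for t, c in points if t > tmax and c > 0]
    if len(terminal) < LAMBDA_Z_MIN_POINTS:
        return None, None, 0
    best = (None, None, 0)
    best_adj = -math.inf
    for start in range(0, len(terminal) - LAMBDA_Z_MIN_POINTS + 1):
        window = terminal[start:]
        t = np.array([p[0] for p in window])
        logc = np.log([p[1] for p in window])
        fit = stats.linregress(t, logc)
        r2 = fit.rvalue ** 2
        n = len(window)
        adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
        if adj > best_adj + 1e-12:
            best_adj = adj
            best = (-fit.slope, r2, n)
    lam, r2, n = best
    if lam is None or lam <= 0 or r2 < LAMBDA_Z_MIN_R2:
        return None, (r2 if lam else None), 0
    return lam, r2, n


def run_nca(profile: ConcentrationProfile) -> NCAResult:
    """Full NCA for one profile; terminal-phase parameters are absent when
    fewer than 3 usable terminal points exist or the fit r^2 < 0.8."""
    quant = profile.quantifiable()
    if not quant:
        raise ValidationError(f"{profile.patient_id}: no quantifiable samples")
    cmax = max(c for _, c in quant)
    tmax = min(t for t, c in quant if c == cmax)

    # BLQ handling: before Tmax as zero, after Tmax excluded.
    points: list[tuple[float, float]] = []
    for t, c in zip(profile.times_h, profile.concentrations):
        blq = c is None or c < profile.lloq or c <= 0
        if blq:
            if t < tmax:
                points.append((t, 0.0))
        else:
            points.append((t, c))
    if points[0][0] > 0:
        points.insert(0, (0.0, 0.0))  # extravascular dosing: C(0) = 0

    auc_last = sum(_interval_auc(t1, c1, t2, c2)
                   for (t1, c1), (t2, c2) in zip(points, points[1:]))
    auc_12 = _auc_to(points, 12.0)

    lam, r2, n_term = _fit_lambda_z(points, tmax)
    if lam is not None:
        t_half = math.log(2.0) / lam
        auc_inf = auc_last + points[-1][1] / lam
    else:
        t_half = auc_inf = None
    return NCAResult(patient_id=profile.patient_id, dose_mg=profile.dose_mg,
                     fed=profile.fed, cmax=cmax, tmax_h=tmax,
                     auc_0_last=auc_last, auc_0_12=auc_12, auc_0_inf=auc_inf,
                     lambda_z_per_h=lam, t_half_h=t_half,
                     terminal_fit_r2=r2, n_terminal_points=n_term)


@dataclass(frozen=True)
class PowerModelFit:
    slope: float
    intercept: float
    stderr: float
    r2: float


def dose_proportionality(results: Sequence[NCAResult],
                         parameter: str = "auc_0_inf") -> PowerModelFit:
    """Power-model slope of ln(parameter) on ln(dose); 1 = proportional."""
    pairs = [(r.dose_mg, getattr(r, parameter)) for r in results
             if getattr(r, parameter) is not None]
    doses = {d for d, _ in pairs}
    if len(doses) < 3:
        raise ValidationError("dose_proportionality requires >= 3 dose levels")
    x = np.log([d for d, _ in pairs])
    y = np.log([v for _, v in pairs])
    fit = stats.linregress(x, y)
    return PowerModelFit(slope=float(fit.slope), intercept=float(fit.intercept),
                         stderr=float(fit.stderr), r2=float(fit.rvalue ** 2))


@dataclass(frozen=True)
class RatioEstimate:
    gmr: float
    ci90_low: float
    ci90_high: float
    n_pairs: int


def food_effect_ratio(fed: Sequence[NCAResult], fasted: Sequence[NCAResult],
                      parameter: str = "cmax") -> RatioEstimate:
    """Geometric mean fed:fasted ratio with a 90% CI over paired patients.

    Patients present in only one arm are excluded.
    """
    fed_by = {r.patient_id: r for r in fed}
    fasted_by = {r.patient_id: r for r in fasted}
    paired = sorted(set(fed_by) & set(fasted_by))
    logr = []
    for pid in paired:
        a = getattr(fed_by[pid], parameter)
        b = getattr(fasted_by[pid], parameter)
        if a is not None and b is not None and a > 0 and b > 0:
            logr.append(math.log(a / b))
    if not logr:
        raise ValidationError("no complete fed/fasted pairs")
    logr = np.asarray(logr)
    mean = float(logr.mean())
    n = len(logr)
    if n > 1:
        half = stats.t.ppf(0.95, n - 1) * logr.std(ddof=1) / math.sqrt(n)
    else:
        half = 0.0
    return RatioEstimate(gmr=math.exp(mean), ci90_low=math.exp(mean - half),
                         ci90_high=math.exp(mean + half), n_pairs=n)
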