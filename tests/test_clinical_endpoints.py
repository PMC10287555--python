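"""RECIST, marker response, clinical benefit, survival and Fisher's test."""

import math

import numpy as np
import pytest

from ddrtx.clinical_endpoints import (SurvivalDatum, derive_clinical_benefit,
                                      derive_pfs_dot, evaluate_marker_response,
                                      evaluate_recist, fisher_exact,
                                      km_estimate, logrank_test)
from ddrtx.io_model import (ContingencyTable2x2, LesionMeasurement,
                            MarkerMeasurement, PatientRecord, ValidationError)


def _lesions(sums_by_week: dict, new_at=()) -> list:
    out = []
    for t, total in sums_by_week.items():
        out.append(LesionMeasurement("L1", "target", t, total / 2.0))
        out.append(LesionMeasurement("L2", "target", t, total / 2.0))
    for t in new_at:
        out.append(LesionMeasurement("NEW", "target", t, 10.0, new_lesion=True))
    return out


class TestRecist:
    def test_complete_target_lesion_resolution(self):
        res = evaluate_recist("P", _lesions({0: 50.0, 6: 20.0, 12: 0.0, 18: 0.0}))
        assert res.best_pct_change_tl == pytest.approx(-100.0)
        assert res.best_overall == "CR"

    def test_thirty_percent_decrease_boundary_is_pr(self):
        res = evaluate_recist("P", _lesions({0: 50.0, 6: 35.0}))
        assert res.categories_by_timepoint[6] == "PR"
        assert res.best_overall == "uPR"  # single assessment: unconfirmed

    def test_confirmation_window(self):
        res = evaluate_recist("P", _lesions({0: 50.0, 6: 34.0, 12: 33.0}))
        assert res.best_overall == "cPR" and res.responder

    def test_pd_requires_both_conditions(self):
        # nadir 40 -> 48.5 is +21.3% and +8.5 mm: PD
        res = evaluate_recist("P", _lesions({0: 50.0, 6: 40.0, 12: 48.5}))
        assert res.categories_by_timepoint[12] == "PD"
        # +21% of a small nadir fails the 5 mm absolute guard
        res2 = evaluate_recist("P", _lesions({0: 22.0, 6: 20.0, 12: 24.2}))
        assert res2.categories_by_timepoint[12] == "SD"

    def test_new_lesion_is_pd(self):
        res = evaluate_recist("P", _lesions({0: 50.0, 6: 50.0}, new_at=(6,)))
        assert res.categories_by_timepoint[6] == "PD"
        assert res.best_overall == "PD"

    def test_missing_baseline_not_evaluable(self):
        res = evaluate_recist("P", _lesions({6: 50.0}))
        assert res.best_overall == "NE"

    def test_lesion_order_invariance(self):
        lesions = _lesions({0: 50.0, 6: 30.0, 12: 28.0})
        forward = evaluate_recist("P", lesions)
        backward = evaluate_recist("P", list(reversed(lesions)))
        assert forward == backward


class TestMarkerResponse:
    def test_confirmed_ca125_decline(self):
        series = [MarkerMeasurement("CA125", 0.0, 1000.0),
                  MarkerMeasurement("CA125", 6.0, 180.0),
                  MarkerMeasurement("CA125", 10.0, 150.0)]
        assert evaluate_marker_response(series, "CA125") is True

    def test_forty_nine_percent_psa_decline_fails(self):
        series = [MarkerMeasurement("PSA", 0.0, 100.0),
                  MarkerMeasurement("PSA", 3.0, 51.0),
                  MarkerMeasurement("PSA", 9.0, 51.0)]
        assert evaluate_marker_response(series, "PSA") is False

    def test_progression_within_four_weeks_excludes(self):
        series = [MarkerMeasurement("PSA", 0.0, 100.0),
                  MarkerMeasurement("PSA", 3.0, 40.0),
                  MarkerMeasurement("PSA", 9.0, 38.0)]
        assert evaluate_marker_response(series, "PSA",
                                        progression_time_weeks=6.0) is False
        assert evaluate_marker_response(series, "PSA",
                                        progression_time_weeks=20.0) is True

    def test_ca125_baseline_below_twice_uln_not_assessable(self):
        series = [MarkerMeasurement("CA125", 0.0, 60.0),
                  MarkerMeasurement("CA125", 6.0, 20.0),
                  MarkerMeasurement("CA125", 10.0, 18.0)]
        assert evaluate_marker_response(series, "CA125") is False


class TestClinicalBenefit:
    def test_sixteen_week_boundary(self):
        assert derive_clinical_benefit(False, 16.0, None) is True
        assert derive_clinical_benefit(False, 15.0, None) is False

    def test_early_progression_negates_duration(self):
        assert derive_clinical_benefit(False, 20.0, 12.0) is False

    def test_response_counts_despite_progression(self):
        assert derive_clinical_benefit(True, 8.0, 12.0) is True


def _patient(progression=None, death=None, stop=30.0, cutoff=30.0,
             scans=(0.0, 6.0, 12.0, 18.0)) -> PatientRecord:
    p = PatientRecord(patient_id="P1", tumor_type="other",
                      enrollment_gene="ATM", enrollment_origin="somatic",
                      dose_mg_per_day=160, schedule="3/4", purity=0.5,
                      ploidy=2.0, treatment_stop_weeks=stop,
                      progression_time_weeks=progression,
                      death_time_weeks=death, data_cutoff_weeks=cutoff)
    p.lesions = [LesionMeasurement("L1", "target", t, 30.0) for t in scans]
    return p


class TestPfsDot:
    def test_event_at_earlier_of_progression_and_death(self):
        pfs, _ = derive_pfs_dot(_patient(progression=12.0, death=20.0))
        assert pfs == SurvivalDatum(12.0, True, "")

    def test_censored_at_last_assessment(self):
        pfs, _ = derive_pfs_dot(_patient(scans=(0.0, 6.0, 12.0, 18.0)))
        assert pfs.time_weeks == 18.0 and not pfs.event

    def test_dot_censored_at_cutoff_when_on_treatment(self):
        _, dot = derive_pfs_dot(_patient(stop=30.0, cutoff=30.0))
        assert dot.time_weeks == 30.0 and not dot.event

    def test_dot_event_at_discontinuation(self):
        _, dot = derive_pfs_dot(_patient(stop=12.0, cutoff=30.0))
        assert dot == SurvivalDatum(12.0, True, "")


class TestKaplanMeier:
    def test_all_events_at_same_time(self):
        data = [SurvivalDatum(10.0, True) for _ in range(10)]
        _, median = km_estimate(data)
        assert median == 10.0

    def test_hand_worked_product_limit_table(self):
        """{4+, 6, 8, 10+, 12}: S(6)=3/4, S(8)=1/2, S(12)=0; median 8."""
        data = [SurvivalDatum(4.0, False), SurvivalDatum(6.0, True),
                SurvivalDatum(8.0, True), SurvivalDatum(10.0, False),
                SurvivalDatum(12.0, True)]
        surv, median = km_estimate(data)
        s = surv["S"]
        assert s.loc[6.0] == pytest.approx(0.75)
        assert s.loc[8.0] == pytest.approx(0.5)
        assert s.loc[12.0] == pytest.approx(0.0)
        assert median == 8.0

    def test_median_absent_with_few_events(self):
        data = [SurvivalDatum(10.0, True)] + \
               [SurvivalDatum(20.0, False) for _ in range(9)]
        _, median = km_estimate(data)
        assert median is None

    def test_no_censoring_median_is_sample_median(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(10.0, size=101)
        data = [SurvivalDatum(float(t), True) for t in times]
        _, median = km_estimate(data)
        assert median == pytest.approx(np.median(times))

    def test_curve_monotone_from_one(self):
        rng = np.random.default_rng(5)
        data = [SurvivalDatum(float(t), bool(e))
                for t, e in zip(rng.exponential(10.0, 50),
                                rng.integers(0, 2, 50))]
        surv, _ = km_estimate(data)
        s = surv["S"].to_numpy()
        assert s[0] <= 1.0 and np.all(np.diff(s) <= 1e-12)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        g = [SurvivalDatum(t, True) for t in (2.0, 4.0, 6.0, 8.0)]
        stat, p = logrank_test([g, list(g)])
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_power_against_planted_hazard_ratio(self):
        """HR 3 with n=200/arm is detected at p < 0.001 almost always."""
        rng = np.random.default_rng(6)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            a = [SurvivalDatum(float(t), True)
                 for t in rng.exponential(30.0, 200)]
            b = [SurvivalDatum(float(t), True)
                 for t in rng.exponential(10.0, 200)]
            _, p = logrank_test([a, b])
            hits += p < 0.001
        assert hits >= 95

    def test_agrees_with_permutation_null(self):
        """Asymptotic p within Monte-Carlo error of a 5,000-permutation p.

        The permutation oracle uses its own numpy log-rank statistic,
        verified against the package's statistic on the observed labels.
        """
        rng = np.random.default_rng(7)
        times = np.concatenate([rng.exponential(10.0, 15),
                                rng.exponential(22.0, 15)])
        labels = np.array([0] * 15 + [1] * 15)

        def groups_for(perm_labels):
            return [[SurvivalDatum(float(t), True)
                     for t, l in zip(times, perm_labels) if l == g]
                    for g in (0, 1)]

        observed_stat, asymptotic_p = logrank_test(groups_for(labels))
        assert numpy_logrank_stat(times, labels) == \
            pytest.approx(observed_stat, rel=1e-9)
        n_perm = 5000
        exceed = 0
        for _ in range(n_perm):
            perm = rng.permutation(labels)
            exceed += numpy_logrank_stat(times, perm) >= observed_stat - 1e-12
        perm_p = (exceed + 1) / (n_perm + 1)
        mc_sd = math.sqrt(perm_p * (1 - perm_p) / n_perm)
        assert abs(perm_p - asymptotic_p) < 4 * mc_sd + 0.02

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test([[SurvivalDatum(1.0, True)], []])


def numpy_logrank_stat(times, labels) -> float:
    """Independent two-group log-rank chi-square (all subjects events).

    At each distinct event time t: d_j deaths total, d1_j in group 1, n_j
    and n1_j at risk; O - E = sum(d1_j - d_j n1_j / n_j) with the usual
    hypergeometric variance.
    """
    times = np.asarray(times, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(times)
    times, labels = times[order], labels[order]
    o_minus_e = 0.0
    var = 0.0
    n = len(times)
    i = 0
    while i < n:
        j = i
        while j < n and times[j] == times[i]:
            j += 1
        d = j - i
        d1 = int(np.sum(labels[i:j] == 0))
        n_at_risk = n - i
        n1_at_risk = int(np.sum(labels[i:] == 0))
        o_minus_e += d1 - d * n1_at_risk / n_at_risk
        if n_at_risk > 1:
            var += (d * (n1_at_risk / n_at_risk)
                    * (1 - n1_at_risk / n_at_risk)
                    * (n_at_risk - d) / (n_at_risk - 1))
        i = j
    return o_minus_e ** 2 / var


def brute_force_fisher(a, b, c, d) -> float:
    """Enumerate every table with the observed margins; sum the
    probabilities of tables no more probable than the observed one."""
    n1, n2, k = a + b, c + d, a + c
    n = n1 + n2

    def table_prob(x):
        return (math.comb(n1, x) * math.comb(n2, k - x)) / math.comb(n, k)

    p_obs = table_prob(a)
    total = 0.0
    for x in range(max(0, k - n2), min(k, n1) + 1):
        p = table_prob(x)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return total


class TestFisherExact:
    @pytest.mark.parametrize("table,expected", [
        ((1, 12, 7, 5), 0.01),    # ATM IHC comparison, printed precision
        ((7, 41, 2, 19), 0.71),   # response by allelic status
    ])
    def test_printed_precision_cases(self, table, expected):
        assert round(fisher_exact(ContingencyTable2x2(*table)), 2) == expected

    def test_identical_rows_no_association(self):
        assert fisher_exact(ContingencyTable2x2(5, 5, 5, 5)) == pytest.approx(1.0)

    def test_zero_margin_is_one(self):
        assert fisher_exact(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            n = int(rng.integers(4, 41))
            cells = rng.multinomial(n, [0.25] * 4)
            a, b, c, d = (int(x) for x in cells)
            if (a + b) == 0 or (c + d) == 0:
                continue
            ours = fisher_exact(ContingencyTable2x2(a, b, c, d))
            assert ours == pytest.approx(brute_force_fisher(a, b, c, d),
                                         abs=1e-9)

    def test_matches_scipy_reference(self):
        from scipy.stats import fisher_exact as scipy_fisher
        rng = np.random.default_rng(9)
        for _ in range(50):
            cells = rng.integers(0, 30, size=4)
            a, b, c, d = (int(x) for x in cells)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            ours = fisher_exact(ContingencyTable2x2(a, b, c, d))
            assert ours == pytest.approx(
                scipy_fisher([[a, b], [c, d]]).pvalue, abs=1e-9)
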