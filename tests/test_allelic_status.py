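"""Copy-number forward/inverse models and allelic-status classification."""

import math

import numpy as np
import pytest
from scipy import stats

from ddrtx.allelic_status import (AllelicStatus, GeneEvidence, Mutation,
                                  classify_allelic_status, compute_log2r,
                                  expected_folded_baf, expected_log2r,
                                  expected_vaf, infer_segment_cn)
from ddrtx.allelic_status import test_subclonal as check_subclonal
from ddrtx.io_model import SegmentCN
from ddrtx.synthetic_cohort import forward_segment


class TestExpectedLog2r:
    def test_neutral_segment_at_full_purity(self):
        assert expected_log2r(1.0, 2.0, 2) == 0.0

    @pytest.mark.parametrize("purity,total,ploidy,expected", [
        (0.5, 1, 2.0, math.log2(1.5 / 2.0)),   # -0.415
        (0.5, 4, 2.0, math.log2(3.0 / 2.0)),   # +0.585
    ])
    def test_closed_forms(self, purity, total, ploidy, expected):
        assert expected_log2r(purity, ploidy, total) == pytest.approx(expected,
                                                                      abs=5e-4)

    def test_homozygous_deletion_floored_at_full_purity(self):
        assert expected_log2r(1.0, 2.0, 0) == -8.0


class TestExpectedVaf:
    @pytest.mark.parametrize("purity,total,m,expected", [
        (1.0, 2, 1, 0.5),
        (0.5, 2, 1, 0.25),
        (0.4, 1, 1, 0.4 / 1.6),   # mutation retained under LOH
    ])
    def test_closed_forms(self, purity, total, m, expected):
        assert expected_vaf(purity, total, m) == pytest.approx(expected)


class TestComputeLog2r:
    def test_flat_genome_is_zero(self):
        segs = [SegmentCN("chr1", 1, 100, 100.0, 100.0) for _ in range(5)]
        assert compute_log2r(segs) == [0.0] * 5

    def test_halved_coverage_is_minus_one(self):
        segs = [SegmentCN("chr1", 1, 100, 100.0, 100.0) for _ in range(4)]
        segs.append(SegmentCN("chr2", 1, 100, 50.0, 100.0))
        assert compute_log2r(segs)[-1] == pytest.approx(-1.0)

    def test_zero_reference_flagged_unevaluable(self):
        segs = [SegmentCN("chr1", 1, 100, 100.0, 0.0),
                SegmentCN("chr2", 1, 100, 100.0, 100.0)]
        values = compute_log2r(segs)
        assert values[0] is None and values[1] == 0.0

    def test_forward_model_segments_recovered_within_tolerance(self):
        """Noisy forward segments at 400x land within 0.05 of expectation."""
        rng = np.random.default_rng(2)
        purity, ploidy = 0.6, 2.0
        plan = [(1, 1)] * 20 + [(2, 0), (3, 1), (1, 0)] * 3 + [(1, 1)]
        segs = [forward_segment(ma, mi, purity, ploidy, "chr1",
                                1 + i * 1000, 1000 + i * 1000, depth=400,
                                rng=rng, coverage_noise_sd=0.01)
                for i, (ma, mi) in enumerate(plan)]
        compute_log2r(segs)
        for seg, (ma, mi) in zip(segs, plan):
            assert seg.log2r == pytest.approx(
                expected_log2r(purity, ploidy, ma + mi), abs=0.05)


class TestInferSegmentCn:
    def test_loh_round_trip(self):
        purity, ploidy = 0.6, 2.0
        got = infer_segment_cn(expected_log2r(purity, ploidy, 2),
                               expected_folded_baf(purity, 2, 0),
                               purity, ploidy)
        assert got == (2, 0)

    def test_balanced_diploid_any_purity(self):
        for purity in (0.3, 0.5, 0.8, 1.0):
            got = infer_segment_cn(0.0, expected_folded_baf(purity, 1, 1),
                                   purity, 2.0)
            assert got == (1, 1)

    def test_missing_baf_leaves_minor_undetermined(self):
        assert infer_segment_cn(0.0, None, 0.5, 2.0) == (None, None)

    def test_noise_free_grid_recovered_exactly(self):
        """Forward-inverse consistency over purity 0.3-1.0, ploidy 2-4."""
        for purity in np.linspace(0.3, 1.0, 8):
            for ploidy in (2, 3, 4):
                for major in range(0, 9):
                    for minor in range(0, min(major, 8 - major) + 1):
                        l2r = expected_log2r(purity, ploidy, major + minor)
                        baf = expected_folded_baf(purity, major, minor)
                        assert infer_segment_cn(l2r, baf, purity, ploidy) == \
                            (major, minor), (purity, ploidy, major, minor)


class TestSubclonal:
    def test_observation_at_expectation_not_subclonal(self):
        assert check_subclonal(50, 200, 0.25) is False

    def test_depleted_observation_subclonal(self):
        # binomial tail for 10/200 at p=0.25 is far below 0.01; 0.05 < 0.15
        assert stats.binom.cdf(10, 200, 0.25) < 1e-10
        assert check_subclonal(10, 200, 0.25) is True

    def test_point_estimate_guard(self):
        # 45/200 = 0.225 exceeds 0.6 x 0.25, so not subclonal
        assert check_subclonal(45, 200, 0.25) is False

    def test_zero_depth_undetermined(self):
        assert check_subclonal(0, 0, 0.25) is None


def _segment(major, minor, start=1, end=200_000):
    seg = SegmentCN("chr11", start, end, 100.0, 100.0)
    seg.major_cn, seg.minor_cn = major, minor
    return seg


class TestClassifyAllelicStatus:
    def test_homozygous_deletion_is_biallelic(self):
        ev = GeneEvidence(gene="ATM", segments=[_segment(0, 0)], purity=0.6)
        status = classify_allelic_status(ev)
        assert status == AllelicStatus("biallelic", "homozygous_deletion")

    def test_mutation_with_loh_is_biallelic(self):
        ev = GeneEvidence(gene="ATM",
                          mutations=[Mutation(100, 40, 100, is_enrollment=True)],
                          segments=[_segment(1, 0)], purity=0.6)
        assert classify_allelic_status(ev) == \
            AllelicStatus("biallelic", "mutation_and_LOH")

    def test_compound_heterozygous(self):
        muts = [Mutation(100, 25, 100, is_enrollment=True),
                Mutation(500, 25, 100)]
        ev = GeneEvidence(gene="ATM", mutations=muts,
                          segments=[_segment(1, 1)], purity=0.5)
        assert classify_allelic_status(ev) == \
            AllelicStatus("biallelic", "compound_heterozygous")

    def test_nonoverlapping_loss(self):
        # mutation in a (1,1) segment, deletion elsewhere in the gene,
        # VAF consistent with the retained allele (expected 0.25 at purity 0.5)
        muts = [Mutation(100, 25, 100, is_enrollment=True)]
        ev = GeneEvidence(gene="ATM", mutations=muts,
                          segments=[_segment(1, 1, 1, 1000),
                                    _segment(1, 0, 1001, 200_000)],
                          purity=0.5)
        assert classify_allelic_status(ev) == \
            AllelicStatus("biallelic", "mutation_and_nonoverlapping_loss")

    def test_mutation_without_loh_is_monoallelic(self):
        ev = GeneEvidence(gene="ATM",
                          mutations=[Mutation(100, 25, 100, is_enrollment=True)],
                          segments=[_segment(2, 1)], purity=0.5)
        assert classify_allelic_status(ev).category == "monoallelic"

    def test_heterozygous_loss_alone_is_monoallelic(self):
        ev = GeneEvidence(gene="ATM", segments=[_segment(1, 0)], purity=0.5)
        assert classify_allelic_status(ev).category == "monoallelic"

    def test_chip_enrollment_short_circuits(self):
        ev = GeneEvidence(gene="ATM", segments=[_segment(0, 0)],
                          enrollment_is_chip=True)
        assert classify_allelic_status(ev).category == "CHIP"

    def test_subclonal_enrollment(self):
        # expected VAF 0.25 at purity 0.5; observed 10/200 is depleted
        ev = GeneEvidence(gene="ATM",
                          mutations=[Mutation(100, 10, 200, is_enrollment=True)],
                          segments=[_segment(1, 1)], purity=0.5)
        assert classify_allelic_status(ev).category == "subclonal"

    def test_clean_segments_without_mutation_no_loss(self):
        ev = GeneEvidence(gene="ATM", segments=[_segment(1, 1)], purity=0.5)
        assert classify_allelic_status(ev).category == "no_loss"

    def test_no_evidence_unknown(self):
        assert classify_allelic_status(GeneEvidence(gene="ATM")).category == \
            "unknown"

    def test_categories_mutually_exclusive_on_cohort(self, small_cohort):
        from ddrtx import pipeline as pl
        patients, _ = small_cohort
        classified = pl.classify_cohort_origins(patients)
        calls = pl.classify_cohort_allelic(patients, classified)
        valid = {"biallelic", "monoallelic", "no_loss", "CHIP", "subclonal",
                 "unknown"}
        for status in calls.values():
            assert status.category in valid
            assert (status.criterion != "none") == (status.category == "biallelic")


def test_ihc_concordance_mirrors_biallelic_enrichment(make_cohort):
    """When protein loss is planted for biallelic events, biallelic patients
    are called IHC-positive less often than non-biallelic patients."""
    import numpy as np
    from ddrtx import pipeline as pl
    from ddrtx.variant_classification import classify_ihc

    patients, truth = make_cohort(n_patients=120, seed=13)
    rng = np.random.default_rng(99)
    positive = {True: [], False: []}
    for p in patients:
        planted = truth[p.patient_id]["allelic_category"]
        if planted not in ("biallelic", "monoallelic", "no_loss"):
            continue
        biallelic = planted == "biallelic"
        percent = rng.uniform(0, 4) if biallelic else rng.uniform(20, 100)
        result = classify_ihc("ATM", percent)
        positive[biallelic].append(not result.loss)
    rate_biallelic = np.mean(positive[True])
    rate_other = np.mean(positive[False])
    assert rate_biallelic < rate_other
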