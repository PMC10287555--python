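"""Published 2x2 contingency comparisons from the camonsertib (RP-3500)
phase 1 monotherapy trial, embedded as a documented fixture.

Each entry records the group counts (numerator/denominator for each arm),
the p-value as printed in the trial report, and whether the printed value is
reproduced by a two-sided Fisher exact test (point-probability rule) on the
printed counts.  Six primary comparisons reproduce exactly at printed
precision.  One further reported comparison (CHIP-derived ATM alterations by
germline-ATM enrollment, printed P = 0.002) is not reproducible from its
printed counts under Fisher's exact test (computed 0.00026) nor under
chi-square variants; it is retained here with ``primary=False`` so the
discrepancy stays visible in the reproduction report.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_model import ContingencyTable2x2


@dataclass(frozen=True)
class ReferenceComparison:
    name: str
    description: str
    group1: str
    group2: str
    table: ContingencyTable2x2  # rows: group1/group2; cols: success/failure
    printed_p: str              # as printed: "0.007", "<0.001", ">0.99"
    primary: bool = True


REFERENCE_COMPARISONS: tuple[ReferenceComparison, ...] = (
    ReferenceComparison(
        name="cbr_by_allelic_status",
        description="Clinical benefit: biallelic 24/48 vs non-biallelic 3/21",
        group1="biallelic", group2="non_biallelic",
        table=ContingencyTable2x2(24, 24, 3, 18), printed_p="0.007"),
    ReferenceComparison(
        name="response_by_allelic_status",
        description="Clinical response: biallelic 7/48 vs non-biallelic 2/21",
        group1="biallelic", group2="non_biallelic",
        table=ContingencyTable2x2(7, 41, 2, 19), printed_p="0.71"),
    ReferenceComparison(
        name="mr_by_allelic_status",
        description="Molecular response: biallelic 15/27 vs non-biallelic 4/18",
        group1="biallelic", group2="non_biallelic",
        table=ContingencyTable2x2(15, 12, 4, 14), printed_p="0.035"),
    ReferenceComparison(
        name="atm_ihc_by_allelic_status",
        description="ATM protein positive by IHC: biallelic ATM 1/13 vs "
                    "non-biallelic ATM 7/12",
        group1="biallelic_atm", group2="non_biallelic_atm",
        table=ContingencyTable2x2(1, 12, 7, 5), printed_p="0.01"),
    ReferenceComparison(
        name="mr_by_enrollment_origin",
        description="Molecular response: somatic 13/28 vs germline 11/22",
        group1="somatic", group2="germline",
        table=ContingencyTable2x2(13, 15, 11, 11), printed_p=">0.99"),
    ReferenceComparison(
        name="mr_by_clinical_benefit",
        description="Molecular response: clinical benefit 19/25 vs none 8/38",
        group1="clinical_benefit", group2="no_clinical_benefit",
        table=ContingencyTable2x2(19, 6, 8, 30), printed_p="<0.001"),
    ReferenceComparison(
        name="atm_chip_by_germline_atm",
        description="CHIP-derived ATM variant: germline-ATM enrollment 8/14 "
                    "vs other enrollment 6/63 (printed value not reproducible "
                    "from the printed counts under any standard test)",
        group1="germline_atm", group2="other_enrollment",
        table=ContingencyTable2x2(8, 6, 6, 57), printed_p="0.002",
        primary=False),
)


def printed_p_matches(computed: float, printed: str) -> bool:
    """Does a computed p-value agree with the printed one at its precision?"""
    if printed.startswith("<"):
        return computed < float(printed[1:])
    if printed.startswith(">"):
        return computed > float(printed[1:])
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    return round(computed, decimals) == float(printed)
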