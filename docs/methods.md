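# Methods

This note documents the models behind each stage, the parameters that
matter, what the synthetic-cohort generator does and does not emulate, and
the numerical and design choices made where conventions were genuinely
open.

## Variant-origin classification

ctDNA from a targeted liquid-biopsy panel mixes tumor-derived fragments
with germline DNA and with DNA shed by hematopoietic clones (CHIP).
Matched PBMC sequencing separates them per variant:

1. **germline** — PBMC VAF >= 0.30. No quantitative germline band is
   standard for targeted panels; 0.30 is this package's choice, set to
   capture heterozygous (~0.5) and homozygous (~1.0) carriers while
   staying above realistic CHIP clone fractions (<~0.2).
2. **CHIP** — PBMC alt reads >= 5 and PBMC:ctDNA VAF ratio >= 0.25.
3. **somatic_tumor** — everything else, including variants with no PBMC
   signal (an absent PBMC call is treated as 0/0 reads, justified because
   the two panels cover the same loci by construction).
4. **ambiguous** — PBMC-positive below the germline band while the
   variant is never detected in ctDNA, so the ratio is undefined.

The reference ctDNA VAF for the ratio is the baseline VAF, falling back
to the maximum on-treatment VAF when the variant is undetected at
baseline; baseline is the least treatment-confounded choice, and the
fallback keeps late-appearing variants classifiable. Prominent CHIP
genes absent from both panels (DNMT3A, ASXL1, TET2) are simply not
represented — CHIP detection here is limited to the shared panel
footprint. IHC protein-loss cutoffs are <= 5% positive tumor cells for
ATM and 0–10% for RNASEH2B; boundary values count as loss.

## Molecular response

Monitorable variants are tumor-somatic ctDNA variants (germline, CHIP
and ambiguous calls filtered first) with VAF > 0.5% at any timepoint; a
patient is evaluable when at least one monitorable variant exceeds 1%, a
baseline (< 0.5 weeks from first dose) and at least one on-treatment
sample exist, and baseline mVAF > 0 (the ratio is otherwise undefined).
The monitorable set is fixed from the union of all timepoints, and a
variant undetected at a timepoint contributes VAF 0 — zero-imputation
keeps the mean comparable across timepoints; carrying the last
observation forward would bias the ratio upward under response. mVAFR_t
is mVAF_t over baseline mVAF; the *best* mVAFR is the minimum (the
deepest decline), and MR is best mVAFR <= 0.5, so a reduction of exactly
50% qualifies.

## Allele-specific copy number and allelic status

A tumor sample is modeled as a two-population mixture: fraction rho
(purity) of tumor cells with integer allele copy numbers (major, minor),
total t = major + minor, against diploid normal cells; psi is the tumor
ploidy. The forward model:

    E[log2R]       = log2( (rho t + 2(1-rho)) / (rho psi + 2(1-rho)) )
    E[folded BAF]  = (rho major + (1-rho)) / (rho t + 2(1-rho))
    E[VAF | m]     = m rho / (rho t + 2(1-rho))       (somatic, m mutated copies)
                     (germline mutations gain a +(1-rho) numerator term)

Observed log2R is the per-segment log2 tumor:reference coverage ratio,
median-centered so the genome-wide median is 0 (correct when most of the
panel footprint is copy-neutral, which holds for the simulated cohorts
and for targeted panels dominated by diploid background). Observed
folded BAF is the mean heterozygous-SNP alt fraction folded into
[0.5, 1]. Inference minimizes the summed squared error of the two
observables over the integer grid 0 <= minor <= major <= 8, scanning
totals in ascending order so exact ties resolve to the smaller total.
The noise-free forward-inverse map is exact over the full grid for
purity in [0.3, 1] and ploidy 2–4 (verified exhaustively in the tests).
Expected log2R is floored at -8 to keep homozygous deletions at purity 1
finite. Segmentation and purity/ploidy estimation are inputs, not
outputs: segments arrive precomputed (or planted by the simulator).

Gene-level classification proceeds in a fixed order — CHIP (the
enrollment alteration is hematopoietic), subclonal, biallelic,
monoallelic, no loss — returning exactly one category:

* **subclonal** — the somatic enrollment mutation is depleted relative
  to its clonal heterozygous expectation: one-sided exact binomial tail
  P(X <= alt | n, E[VAF]) < 0.01 *and* observed VAF < 0.6 x expected.
  Both thresholds are this package's choices (no published values
  exist); the binomial gate controls false positives at high depth, the
  0.6x point-estimate gate blocks trivial significance for marginal
  depletion.
* **biallelic** — (1) homozygous deletion (any overlapping segment with
  total 0); (2) compound heterozygous (two distinct pathogenic hits,
  assumed in trans since no phasing is available, and flagged with that
  criterion for review); (3) mutation + LOH (overlapping segment with
  minor 0); (4) mutation + non-overlapping loss, read as: one allele
  mutated inside a non-LOH segment, the other lost by a deletion
  elsewhere in the gene — accepted only when the mutation VAF is
  consistent with residing on a retained allele (two-sided exact
  binomial p >= 0.05 against E[VAF]).
* **monoallelic** — mutation without LOH, or heterozygous loss alone
  (minor 0 with total below the rounded ploidy).
* **no loss** — neither mutation nor copy-number loss; **unknown** — a
  mutation at an uncovered locus, no usable segments, or minor copy
  number undetermined (no heterozygous SNPs).

## Clinical endpoints

RECIST 1.1 is implemented in simplified form: sums of <= 5 target-lesion
diameters, no nodal short-axis special-casing, since response evaluation
is an applied criterion here, not a contribution. Per timepoint: PD when
the sum reaches 120% of the nadir with an absolute increase >= 5 mm, or
any new lesion; CR when the sum is 0 with no residual non-target
disease; PR at <= 70% of baseline; SD otherwise. PR/CR confirmation
requires a qualifying assessment >= 28 days later; unconfirmed PRs still
count as responses, matching how the trial tabulated them. Marker
responses are confirmed >= 50% declines (second qualifying value >= 3
weeks later for PSA, >= 28 days for CA-125; CA-125 baseline must be
>= 2x an upper limit of normal fixed at 35 U/mL per GCIG convention),
with no progression before or within 4 weeks of the initial decline.
Clinical benefit is response, or >= 16 weeks on treatment without prior
progression (the trial's modified definition; the original protocol
definition is not implemented). PFS takes an event at the earlier of
progression and death, censoring at the last tumor assessment; DOT takes
an event at discontinuation, censoring at the data cutoff.

Kaplan-Meier estimation and the log-rank test delegate to lifelines; the
KM median is the smallest time with S(t) <= 0.5 and is reported absent
when never reached. Fisher's exact test is computed in-package by
hypergeometric enumeration with the two-sided point-probability rule
(all margin-fixed tables whose point probability is at most that of the
observed table, with a 1e-7 relative tolerance on the comparison). This
rule — rather than doubling or mid-p — is what reproduces the published
p-values 0.007 / 0.035 / 0.71 / 0.01 from their printed counts. One
published comparison (CHIP-derived ATM by germline-ATM enrollment,
printed P = 0.002 from 8/14 vs 6/63) is not reproducible from its
printed counts under Fisher's exact test (computed 0.00026) or
chi-square variants; the embedded fixture retains it as a non-primary
row so the discrepancy stays visible.

## Pharmacokinetics

NCA uses the linear-up/log-down trapezoid (exact for mono-exponential
decline), observed Cmax/Tmax at actual sampling times, and a terminal
log-linear fit over the points after Tmax: among candidate windows of
>= 3 points ending at the last quantifiable sample, the one maximizing
adjusted r^2 wins (ties to the longer window — a deterministic,
reproducible rule), and lambda_z is reported only when r^2 >= 0.8.
AUC_0-inf adds C_last / lambda_z; AUC_0-12 interpolates the 12-h
concentration under the same up/down convention. BLQ samples are zero
before Tmax and excluded after. Dose proportionality is the least-squares
slope of ln AUC on ln dose (slope 1 = proportional); the food effect is
the geometric mean of paired fed:fasted log ratios with a t-based 90% CI,
unpaired subjects excluded.

## Synthetic cohorts

The generator's defaults are the study conditions: 120 patients;
enrollment genes drawn with probabilities proportional to the reported
enrollment counts (ATM 44, BRCA1 25, BRCA2 15, CDK12 9, RNASEH2B /
PALB2 / SETD2 5 each, NBN / RAD51C / CHEK2 4 each); allelic categories
proportional to the determinate counts (biallelic 57, monoallelic 20,
no-loss 3, subclonal 1) with exactly 3 CHIP-enrollment patients (forced
to ATM, as observed); 43% planted molecular responders whose variant
levels decline by 70–95% (reaching the full decline by week 3 with
probability 0.7, else week 6, putting the median time to MR near the
reported ~3 weeks) versus 0–30% for non-responders; ctDNA at 5,000x
every 3-week cycle; PBMCs at 500x; tumor assay and SNPs at 400x; purity
uniform on [0.3, 0.9] at ploidy 2; scans every 6 weeks for three
assessments then every 9 weeks, with a 60-week data cutoff. Read counts
are binomial given depth and planted VAF (an optional beta-binomial
overdispersion parameter exists but is off by default — panel UMI
consensus calling is close to binomial); segment coverage carries 2%
lognormal noise; germline PBMC VAF is 0.5, CHIP clones are uniform on
[1%, 10%]. Survival and treatment duration are exponential conditional
on the planted benefit label — closed-form and sufficient for KM /
log-rank testing. Each patient draws from an independent substream
keyed by (seed, patient index), so cohorts are reproducible and
patient-insertion stable.

What the generator does **not** emulate: sequencing artifacts and
error-driven false calls, overdispersed or batch-correlated depth,
subclonal tumor architecture in ctDNA (each variant follows one decline
trajectory), segmentation error (segments are planted, never inferred
from noisy bins), reversion-mutation dynamics, and measurement noise in
lesion diameters. Passing recovery tests therefore demonstrates that the
decision rules invert the stated generative model at trial-like depths —
not that they are robust to artifact modes absent from that model; on
real data the PBMC-ratio and subclonality thresholds in particular
should be revisited against assay-specific error profiles.

## Numerical choices and degenerate inputs

Zero-depth PBMC calls with alt reads are rejected as invalid; zero
reference coverage marks a segment unevaluable rather than raising;
empty monitorable sets make mVAF undefined and the patient
non-evaluable; zero-margin contingency tables return p = 1; all-censored
survival input reports an absent median; profiles with fewer than three
usable terminal points report lambda_z, t1/2 and AUC_0-inf as absent.
TSV floats are serialized with `repr` (shortest exact round-trip form),
making read-write cycles byte-identical. VCF output is minimal 4.2
(CHROM/POS/REF/ALT plus AD and DP in FORMAT), sorted by position, and
parses cleanly under standard readers.
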