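# Methods

## The quantification model

All quantification follows the comparative-Ct (ΔΔCt) model with assumed
perfect PCR efficiency (one doubling per cycle). For assay *i* in sample
*j*:

- ΔCt(i, j) = Ct(i, j) − ref(j), where ref(j) aggregates the detected
  endogenous-control wells of sample *j* (arithmetic mean by default,
  median selectable). A sample with no detected control well is a hard
  error — there is no basis for normalization.
- ΔΔCt(i, j) = ΔCt(i, j) − ΔCt(i, c) for a single designated calibrator
  sample *c*; RQ(i, j) = 2^−ΔΔCt(i, j), so log2 RQ = −ΔΔCt exactly and the
  calibrator has RQ = 1 for every assay detected in it.

Subtracting a per-sample reference makes ΔCt invariant to per-sample
loading shifts; subtracting a per-assay calibrator ΔCt rescales every
sample of an assay by the same factor, so two-group comparisons are
unaffected by the calibrator choice except through which assays are
*defined* (an assay undetected in the calibrator has undefined ΔΔCt and is
excluded, with the exclusion logged). The single-sample calibrator policy
(default: the first control sample) is the default because per-group-mean
calibration would force one group's mean RQ to 1, which is not how
screening tables of this kind behave; a control-group-mean policy is
available (`policy="control-mean"`).

Technical replicates are collapsed before normalization to the mean of
*detected* replicates (median selectable); a cell is non-detected only when
every replicate is. Non-detection is never imputed at the detection limit:
a censored well stays missing through every stage, which biases per-group
means of weakly expressed assays but avoids inventing values the instrument
did not report.

## Flags, retention and confidence tiers

Within each sample the detected assays are ranked by ΔCt and labelled by
quartile: the lowest-ΔCt (strongest) quartile *good*, the highest *low*,
the middle half *normal*. The quartile population is within-sample across
assays — "strong expression" is read as strength relative to the rest of
that sample's miRNA complement — but a within-assay-across-samples variant
is selectable (`population="within-assay"`). Quantiles use linear
interpolation between order statistics; thresholds are boundary-inclusive
(ΔCt ≤ 25th percentile → good, ≥ 75th → low). Two conservative degenerate
rules keep the labels meaningful: samples with fewer than four detected
assays, and samples whose 25th and 75th percentiles coincide (massive
ties), label everything *normal*.

Per assay and group the flags are counted (*values* + *nd* = group size,
*good* + *normal* + *low* = *values*), and an assay is retained only with
*values* ≥ 2 in both groups — below that no spread, hence no test
statistic, exists.

Confidence tiers triage retained assays: *low* if any sample anywhere
flagged the assay low; otherwise *top* if both groups contain at least one
good flag; otherwise *medium*. Assays with good flags in exactly one group
fall between the classic top/medium definitions; they are assigned
*medium* (the conservative choice) and are distinguishable from true
mediums via the flag report.

## The discovery screen

Group statistics (n, mean, SD with n−1 denominator, CV = 100·SD/mean,
max/min ratio, median) are computed on linear RQ values per group, using
detected cells only. Expression ratios (case over control) of group means
and medians are reported as signed fold-changes, sfc(r) = r if r ≥ 1 else
−1/r, making 2-fold up and down symmetric at ±2 (sfc(1/r) = −sfc(r),
|sfc| ≥ 1).

The test is the two-sided Welch unequal-variance t-test, by default on
linear RQ values — the scale on which screening tables of this kind report
their statistics — with a log2-scale option (`test_scale="log"`,
equivalent to testing −ΔΔCt), since qPCR noise is closer to normal on the
cycle scale. Degenerate-spread conventions: both groups zero-variance with
equal means → p = 1; with unequal means → p = 0.

The differential-expression call is the union rule p ≤ 0.1 ∨ |mean FC| ≥ 2
∨ |median FC| ≥ 2 (all thresholds inclusive and configurable). The union
is deliberately permissive: with 10 + 10 samples and the high intra-group
CVs typical of low-density cards, intersection rules miss real effects;
the tiers and the validation stage carry the burden of specificity. No
multiple-testing correction is applied in the screen — that is the
screening convention this pipeline reproduces; downstream consumers can
correct the reported p-values if they need error control at this stage.

## The validation stage

The candidate panel is re-quantified (replicates → ΔCt against the card's
endogenous control, RNU6B in the default design → RQ) and each assay's
groups are compared with the two-sided Mann–Whitney–Wilcoxon test;
reporting is median RQ (min–max) per group, and significance is strict
(p < α, default 0.05).

Mode `auto` uses the exact null distribution when nx·ny ≤ 64 and the
pooled values are tie-free, otherwise a normal approximation with
continuity correction. Because the exact U distribution is mildly
platykurtic, the plain continuity-corrected normal approximation can miss
the exact two-sided p by up to ≈ 0.011 at nx = ny = 8 (mid-range U); the
approximation therefore adds the Edgeworth fourth-cumulant term, using
κ₄(U) = −nx·ny·(n+1)·(nx² + ny² + nx·ny + n)/120 for tie-free data (the
closed form was derived from the exact distribution and verified against
enumeration across group sizes), which reduces the worst-case error at
8 + 8 to ≈ 0.0006. With ties the classical tie-corrected variance is used
and the kurtosis term — whose closed form assumes no ties — is dropped.
When every pooled value is identical the test is uninformative and p = 1
by convention.

## The synthetic-data generator

The simulator emulates the two-card study design on the cycle scale, where
a linear fold-change f is an additive Ct shift of −log2(|f|) (down-
regulation, written f = −2, shifts Ct up one cycle — so ΔΔCt is an
unbiased estimator of ∓log2|f|):

    Ct(i, j, r) = B_i + L_j + s_i·[j ∈ case] + ε_ijr

with B_i ~ U(22, 35) cycles (assay abundance), L_j ~ N(0, 0.5) (per-sample
loading), ε ~ N(0, 0.4) (technical noise, per well), endogenous-control
wells at a fixed baseline of 20 cycles with s = 0 but the same loading and
noise, and censoring of any well at ≥ 40 cycles (the run length) to
non-detected. Defaults: 667 target assays + 8 control wells, 10 + 10
samples, single wells (discovery); 15 targets + RNU6B in triplicate,
21 + 25 samples (validation design). The noise magnitudes are fixed design
values on the order of inter-replicate qPCR variation; with them the
intra-group CVs of RQ span a few percent to >100% across assays, the range
such cards exhibit in practice.

What the generator does **not** model: PCR efficiency ≠ 2, card/batch
effects, an amplification-dropout process separate from censoring,
assay-specific noise, and cross-miRNA correlation structure. Passing tests
therefore demonstrate correctness of the arithmetic, the calibration of
the tests under the assumed noise model, and power against clean planted
effects — not robustness to efficiency bias or batch structure in real
card data.

One structural consequence of faithful endogenous-control simulation is
worth flagging: because every assay in a sample is normalized by the same
measured (noisy) control aggregate, all assays on a card share that
per-sample reference error. Its between-group difference acts as a small
random common shift (SD ≈ 0.06 cycles with 8 control wells and 10 + 10
samples), so single-card null rejection fractions fluctuate well beyond
binomial (≈ 0.075–0.13 across cards at nominal 0.1). The test-calibration
check in the suite consequently averages the rejection fraction over five
independently seeded replicate cards, which estimates the marginal type-I
rate (≈ 0.095) at near-binomial precision. Larger control-well counts
shrink this shared term; it is a real property of reference-gene
normalization, not an artifact of the simulator.

## Determinism and numerics

Every stochastic component draws from a single `numpy` Generator seeded
from the run configuration (the orchestrated run derives the validation
seed as seed + 1); fixed seed + config ⇒ byte-identical reports, with a
manifest embedding the configuration and SHA-256 checksums of all inputs.
Outputs are sorted (records by tier, then p, then assay id) so results are
independent of input ordering. Detection handling is idempotent: censoring
at the same cutoff twice is a no-op, and "Undetermined"-style tokens are
configurable because instrument exports vary.

## Known limitations

- Efficiency-corrected (standard-curve / Pfaffl) quantification is out of
  scope; RQ assumes exact doubling.
- The screen's union rule plus no correction means its DE list has a high
  false-positive rate by construction (≈ 10% of nulls via the p-arm
  alone); it is a triage, not an inference.
- Median-based fold-changes with ≤ 10 samples per group are coarse; ties
  in RQ (exactly repeated values) are rare on continuous data but are
  handled via midranks in the validation test.
- With heavy non-detection the retained-assay statistics are computed on
  the detected subset, i.e. conditionally on detection — a selection
  effect the pipeline reports (values/nd counts) but does not correct.
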