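# Methods

`cagmosaic` quantifies somatic instability of a CAG repeat at an
HTT-exon-1-like locus from amplicon sequencing reads, and models how that
instability depends on inherited repeat length and age. This note records the
models, the calibration of the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## The instability statistic

For one inherited allele, let `n` be the number of reads whose decomposed
repeat structure matches the allele exactly, and `n₊ᵢ` the number of reads
with the same interruption structure and `i` more pure CAG units. The
**ratio of CAG expansions** is

    ratio = ( Σ_{i=1..10} n₊ᵢ ) / n .

Only gains are counted (the assay is expansion-biased and contractions are
confounded with backward PCR slippage), the window is capped at +10 units,
and reads are attributed to an allele only when their interruption structure
(`canonical` = CAACAG·CCGCCA cassette present, `loss_of_interruption` = the
whole intervening sequence absent) matches. Reads beyond +10 stay in the raw
histogram but not in the statistic.

## Read decomposition and genotyping

Reads are anchored by two constant flanks (defaults: 24 nt immediately 5' of
the CAG tract, 21 nt immediately 3' of the CCT tract), each tolerating up to
2 substitutions and no indels. The inter-anchor segment is decomposed
greedily, left to right, into `(CAG)n (CAACAG)m (CCGCCA)k (CCG)p (CCT)q`
with no backtracking; any residual base fails the read. `cag` counts only
the pure uninterrupted tract — the CAA-CAG of the cassette is not included.
This is a convention choice (capillary sizing conventions differ by +2);
all internal quantities use it consistently. Only the forward read is used:
a 400 nt forward read spans the repeat for every allele this package
targets, so no merging logic is needed.

Inherited alleles are called from the `(variant_tag, cag)` histogram of
passing reads. Candidate peaks are per-structure local maxima above a noise
floor (`min_peak_fraction`, default 5 % of the largest peak). A candidate
with a strictly larger same-structure bin within `stutter_absorb_window`
(default 2) CAG on *either* side is absorbed — below a larger peak it is
backward stutter, above one it is a forward-slippage or somatic-expansion
shoulder. Alleles closer than the absorption window are inherently
unresolvable by histogram peak calling; such pairs are also excluded by the
eligibility rule below. For heavily mosaic samples (measured ratios ≳ 1,
as in full-penetrance alleles) the expansion smear is broad and its sampling
noise can fake isolated local maxima; widening `stutter_absorb_window` to
3–4 absorbs these shoulders and is the recommended setting there. A
homozygous call is made when the top surviving peak holds more than
`homozygosity_fraction` (default 0.85) of the surviving-peak reads; more
than two surviving peaks raise an ambiguous-genotype error rather than
guessing.

## Allele eligibility

Backward slippage products of the longer allele extend a few CAG below it.
If both alleles share the same interruption structure and the shorter
allele's expansion window reaches into that zone, its ratio is
uninterpretable. The rule: the longer allele is always scored; the shorter
allele is scored iff its structure differs from the longer allele's, or the
CAG gap exceeds `window + guard` (defaults 10 + 2). The guard band covers
backward slips of more than the one-unit-per-event bulk; both knobs are
configurable. This two-clause rule is this package's explicit stand-in for
allele-selection criteria that are not publicly specified; it excludes
exactly the interference mechanism that motivates selection.

## PCR-stutter model and the single-molecule baseline

Amplification is a branching process: each cycle every molecule produces one
copy, and each copy event independently loses one repeat unit with
probability `p_minus` or gains one with `p_plus` (single-unit slips only —
the single-molecule benchmark shows only +1 artifact products). Slip
probabilities scale by `length_scaling^(cag − 33)`, so longer tracts slip
more. Because expectation is linear, the expected product-length
distribution after `cycles` cycles is computed exactly by a small transition
recurrence (`expected_pool_distribution`); a random final molecule has
Binomial(cycles, ½) copy events in its lineage, so with backward slips off
the expected slipped fraction has the closed form `1 − (1 − p_plus/2)^cycles`,
which the stochastic simulator reproduces.

Defaults (versioned in `config/stutter_defaults.yaml`): 30 cycles,
`p_minus = 0.01`, `length_scaling = 1.05`, and `p_plus = 1.5382e-3` solved
so that the *expected* +1/inherited read proportion of a single 33 CAG
template equals 0.023, the measured single-molecule benchmark. The cycle
count and polymerase behaviour of the underlying protocol are not public,
so this calibration is phenomenological: it pins one observable (the +1
artifact proportion at 33 CAG) and takes plausible values for the rest.
`p_minus` is set so backward stutter is an order of magnitude stronger than
forward, as microsatellite assays typically show.

The same expectation model supplies the **baseline** for genuineness calls:
a measured ratio is genuine somatic expansion only if it exceeds the
stutter-only expected ratio for its inherited length (strict point
comparison, matching the qualitative "well above baseline" argument; an
optional one-sided binomial test is available but off by default). Note that
one *individual* single-molecule reaction is high-variance — an early-cycle
slip amplifies exponentially — so single reactions scatter widely around the
expected baseline; the benchmark value is a pooled expectation.

## Synthetic tissue fixtures

Somatic mosaicism is modelled at the template-pool stage: a fraction of
input molecules carries `inherited + i` CAG before amplification. Measured
ratios therefore contain both mosaicism and stutter. The shipped ten-tissue
fixture stores per-tissue *measured* per-offset targets and inverts the
expectation model (`solve_template_freqs`, a damped fixed point) to obtain
template frequencies, so the full pipeline — reads → decomposition →
genotyping → ratio — reproduces the targets without any tuning constant.
Putamen (total 0.103) and cerebellum (0.048) targets solve the four
published constraints (two tissue totals; 2× and 5× putamen/cerebellum fold
changes at +1 and +2) exactly; the other eight tissues are synthetic
interpolations following the striatum > cortex > brainstem/cerebellum
gradient, as no per-tissue numbers are published for them. The default
template pool (2×10⁵ molecules) keeps template-sampling noise well below
read-sampling noise at the default 20 000-read depth.

Reads are rendered as `5'flank + repeat + 3'flank` with a uniform per-base
substitution error (default 10⁻³). A substitution inside the repeat region
breaks exact decomposition, so pass probability falls as
`(1−e)^(3·cag + const)`; the expectation model includes the relative
`(1−e)^(3i)` factor across offsets.

## Cohort generator and regression layer

Cohort tables draw integer CAG uniformly on the category range and age
uniformly on 20–90 y, then set
`ratio = β₀ + β_cag·CAG + β_age·age + β_int·CAG·age + N(0, σ)` truncated at
0 (a mild departure from Gaussian residuals, relevant only where the plane
approaches 0). Generating slopes are the published per-category estimates;
the interaction coefficient is 0 in all shipped scenarios. Intercepts and
noise σ are not published, so they are calibrated per category:

* **Intermediate (n=135)**: σ = 0.0065 and β₀ = −0.074, chosen so the
  expected cohort minimum/maximum (plane corner ± 2.47 σ, the expected
  extreme of 135 normal deviates) spans the published 0.020–0.091. Because
  cohort extremes do not in fact sit at the covariate corners, the realised
  span is ≈ 0.027–0.084; the corner approximation is kept for transparency.
* **Reduced penetrance (n=37)**: same corner rule against 0.063–0.878
  (σ = 0.1055, β₀ = −1.457).
* **Full penetrance and normal**: the published ranges are visibly shaped
  by outliers and non-uniform CAG coverage, so σ is instead derived from
  the published R² against the variance the covariates explain under
  uniform sampling (σ = 0.385 / 0.28 for the ≥40 and 40–50 windows;
  normal uses a compromise σ = 0.003), with β₀ anchoring the expected
  minimum near the published category minimum.

Published confidence intervals are printed at coarse precision (e.g. age CI
"0.0001, 0.0002"); recovery checks in the test suite treat a printed bound
as ± half a unit in its last printed digit.

The statistical layer is ordinary least squares (statsmodels): covariates
raw (uncentred); main effects and R² from the no-interaction model; the
CAG×age p-value from a second fit adding the product term; Wald 95 % CIs;
two-sided α = 0.05; no multiple-testing correction. The full-penetrance
category is fit either on the 40–50 CAG window (`table1` mode) or on all
≥40 records (`results_text` mode) because the two published summaries use
different windows. The per-CAG age scan fits ratio on age within each exact
CAG length and, optionally, within cumulative ≥CAG strata (which of the two
the original supplementary analysis used is not stated; both are provided,
entries with <3 records are marked not estimable). The group comparison is
an ANCOVA of ratio on a group indicator plus CAG and age, with adjusted
means evaluated at the covariate grand means.

## Numerical choices and degenerate inputs

* Anchor search: leftmost exact match first, then a leftmost ≤k-mismatch
  scan (vectorised sliding window); indels in anchors are not tolerated so
  anchoring stays deterministic.
* Decomposition memoises identical sequences per read set; amplicon read
  sets are dominated by a few exact length classes, so this is the main
  throughput lever.
* Peak ties: surviving peaks are ordered by count, then by CAG; a
  candidate requires `count > left` and `count ≥ right` neighbour.
* Zero reads at the inherited length, mismatched baselines, zero
  denominator frequencies, rank-deficient designs (the collinear column is
  named), missing metadata columns, and sub-100-read tissue simulations all
  raise typed errors rather than returning numbers.
* All randomness flows from one `numpy` Generator per simulation, seeded
  explicitly; identical seed + configuration gives byte-identical FASTQ.

## Problem sizes used by the test and acceptance runs

Monte-Carlo experiments are sized to make their assertions sharp but cheap:
cohort recovery uses 100 replicates at the published cohort sizes
(ratio-level, no reads); the ten-tissue fixture runs 50 seeds × 20 000 reads
in the acceptance script and 6 seeds in the test suite (assertions scale
with the empirical standard error); the read-level chain test runs 3
replicates of 60-sample cohorts at 3 000 reads per sample; null-calibration
checks use 200–1000 replicates. At the published sample sizes the sampling
standard error of the age slope exceeds 10 % of its value for the
intermediate and normal categories (the published CI widths imply the
same), so bias checks allow a Monte-Carlo term alongside the 10 % band.

## What passing tests do and do not show

The generator emulates exactly the structure the analysis assumes:
single-unit per-cycle slippage, template-pool mosaicism, uniform sequencing
error, linear cohort models with Gaussian (truncated) residuals, uniform
covariate sampling. Real data differ in known ways: non-uniform CAG and age
distributions, length-dependent amplification efficiency between alleles,
indel sequencing errors, multi-unit slips, chimeric reads, and base-quality
structure are all absent. Passing tests therefore demonstrate that the
pipeline's measurement and inference layers are correct and unbiased under
the stated model — not that the model captures every artifact of a real
MiSeq run. The eligibility rule is a reconstruction, not the original
selection protocol; and the eight interpolated tissue targets are
placeholders with the right ordering, not measurements.
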