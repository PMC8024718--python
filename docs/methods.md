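# Methods

## Problem setting

Multiple liver metastases resected from one colorectal-cancer patient
are profiled for total DNA copy number and segmented per lesion.
Because each lesion's segmentation has its own breakpoints, the
profiles must be harmonized before any cross-lesion comparison.  The
package implements the downstream analysis chain on such data:
harmonization, aberration calling, burden and heterogeneity
quantification, amplification concordance, mutation grouping, and
cancer-specific survival stratification.  Sex chromosomes are excluded
at load time; all coordinates are 0-based half-open internally, with
SEG I/O converting from/to the 1-based inclusive convention and BED
staying 0-based half-open.

## Harmonization and calling

The smallest-regions-of-overlap partition takes the union of every
segment start and end across all lesions per chromosome; candidate
intervals covered by no lesion are dropped, so the region footprint
equals the union of the input footprints and the operation is
idempotent.  Where a lesion has no segment the matrix holds a missing
value; missing regions are excluded from that lesion's burden
denominator and handled pairwise-complete in distances, since nothing
in the data model forces complete coverage.

The per-lesion baseline ("median genome-wide copy number") is the
**length-weighted** median of segment values, defined to agree exactly
with the ordinary median of the profile expanded to one value per base
pair.  An unweighted median over segments would be biased by how
finely a profile happens to be segmented.  Gains and losses are called
with closed comparisons: a region is a gain when `value − baseline ≥
gain_threshold` (default +1 copy) and a loss when `≤ loss_threshold`
(default −1).  CNA burden is 100 × (aberrant length) / (covered
length) per lesion, averaged per patient.

Gene-level calls assign each gene the call of the overlapping region
with the largest overlap, ties broken toward the earlier region —
deterministic and independent of input order.  Cohort-level CNA
frequencies count a patient as gained (lost) in a region when at
least one lesion carries the call there; a patient can contribute a
gain and a loss in the same region.

## Heterogeneity estimators

Four per-patient scores, all operating on the harmonized region-level
matrix with one coordinate per region (unweighted by default; the
paper-scale score range is cohort-specific, and only the ranking feeds
the median split):

* **Euclidean** — mean pairwise Euclidean distance over all lesion
  pairs, pairwise-complete; pairs sharing fewer than 10 regions are
  refused with a status.
* **Correlation** — mean pairwise 1 − Pearson r, in [0, 2]; a
  constant lesion vector makes the pair undefined (identical vectors
  are distance 0 by definition, avoiding floating-point residue).
* **Discordant gene fraction** — among genes with a non-neutral call
  in ≥ 1 lesion, the fraction whose ternary calls are not identical
  across lesions.  Genes gained in all lesions with different
  amplitudes count as concordant: amplitude is deliberately ignored
  once the calls agree, making this the most conservative estimator.
* **Variance-filtered** — regions with across-lesion variance ≤ 0.03
  are dropped, then mean pairwise Euclidean distance on the remainder;
  when no region survives the score is 0 with an explanatory status.
  The threshold is configurable (`variance_threshold`).

The optional length-weighted distance mode weights squared
differences by region length divided by the **total shared length** of
the pair.  Normalizing by a mean region length instead would make the
score depend on how the shared footprint is partitioned — splitting a
segment changes the mean region length but not the data — so the
total-length normalization is the only choice under which distances
are invariant to segment subdivision, a property the test suite
asserts.  Under the default unweighted mode that invariance is *not*
claimed; permutation invariance over region and lesion order is
asserted for all measures instead.

Scores are dichotomized at the cohort median with a strict rule:
"high" means strictly above the median, ties go to "low", undefined
scores are labelled missing and excluded from the median.  This keeps
the split deterministic and conservative.

## Amplifications

Additional copies are copy number minus the lesion's ploidy estimate
(supplied with the profile, or the median-copy-number baseline as a
fallback), left unrounded.  A region qualifies as a high-level
amplification when any lesion reaches ≥ 15 additional copies; runs of
coordinate-adjacent qualifying regions merge into one event whose
per-lesion value is the maximum over member regions.  Concordance
depends only on the minimum over lesions: ≥ 15 everywhere ⇒
homogeneous, ≥ 5 everywhere ⇒ intermediate-concordant, otherwise
heterogeneous.  Single-lesion patients classify trivially as
homogeneous and are flagged so concordance summaries can exclude them.
Events are the unit of analysis (a merged genomic region per patient);
per-gene views are derived by annotation against the input gene
intervals and their cancer-critical flag.

## Mutation groups

Per-gene patient status is "mutated" if any lesion is mutated,
"wild-type" if all known calls are wild-type, "unknown" only when no
call is known; patients with both mutated and wild-type lesions are
flagged heterogeneous but remain mutated.  Groups: co-mutation (RAS or
BRAF V600E mutated *and* TP53 mutated), RAS/BRAF-only, TP53-only,
double wild-type.  A patient whose defining gene is unknown is
excluded from group-stratified analyses rather than defaulted to
wild-type.  KRAS/NRAS/BRAF mutations are expected mutually exclusive;
violations are reported, never silently fixed.

## Survival conventions

End point is 5-year cancer-specific survival: time from start of
treatment, CRC deaths are events, other-cause deaths and living
patients are censored at follow-up.  Only MSS patients with R0/R1
resection enter survival analyses; exclusion counts are logged and
recorded in the pipeline manifest.  Kaplan–Meier estimation, two-group
log-rank and Cox regression are delegated to lifelines; Cox uses the
Efron tie approximation (month-resolution times make ties likely and
Efron is the less biased standard choice).  The survival probability
at 60 months is read from the step function with last value carried
forward.  P values are never adjusted for multiple testing.

The log-rank trend test for ≥ 3 ordered groups is implemented
in-package (no established Python equivalent exists): at each event
time the observed-minus-expected event vector and the multivariate
hypergeometric covariance accumulate; the statistic is the squared
standardized contrast of O−E with the ordered group scores, 1 df.  Its
signed root is exposed so order reversal visibly flips the sign.
Combined mutation × CNA strata are ordered co-mut/high < co-mut/low <
no-co-mutation, with no-co-mutation as the Cox reference.

Group-association tests use Wilcoxon rank-sum for continuous and
Fisher's exact test for 2×2 categorical comparisons; tables larger
than 2×2 fall back to the chi-square test, as no exact r×c test is
available in the scientific Python stack (the reproduced analyses are
all two-group).

## Synthetic cohort generator

The generator emulates the statistical structure of a multi-lesion
CRLM series, not its biology in detail.  Per patient: 2–8 lesions;
ploidy drawn from a two-level mixture (near-diploid 2.0 / near-triploid
3.5, probabilities 0.55/0.45, small jitter), identical across a
patient's lesions; truncal events (Poisson, default rate 8 per
patient) shared by all lesions; private events (Poisson, default rate
2 per lesion) drawn independently per lesion.  Events are arm-level or
sub-arm intervals drawn from a prior weighted 6:1 toward the arms
recurrently altered in colorectal cancer (gains of 7, 8q, 13q, 20q;
losses of 1p, 4, 8p, 17p, 18); gains add +1 (70%) or +2 copies, losses
subtract 1, values floor at zero.  A uniform placement mode exists for
unbiased property tests.  With default rates the aberrant fraction
stays well under half the genome, so the length-weighted median
baseline equals the ploidy exactly — which is what makes analytic
truth computation possible.

High-level amplifications are injected per patient with probability
0.34, as a small region whose per-lesion additional copies follow a
homogeneous / intermediate / heterogeneous pattern with probabilities
0.31/0.38/0.31 (at least one lesion ≥ 15 additional copies).  When the
private-event rate is zero the injector uses identical amplitudes in
every lesion: amplitude scatter is lesion-private variation by nature,
and the zero-rate configuration must produce exactly identical
lesions.

Driver mutations come from one categorical draw per patient (KRAS
0.427, NRAS 0.047, BRAF V600E 0.018 — mutual exclusivity by
construction) with TP53 an independent Bernoulli(0.725); a small rate
(0.08) of TP53-heterogeneous patients gets one wild-type lesion call.
Survival times are exponential with hazard = base hazard ×
group hazard ratio × heterogeneity-class ratio; defaults are
co-mutation 3.9, RAS/BRAF-only 1.5, TP53-only 1.2, double wild-type
1.0, high-heterogeneity ×1.8, base hazard 0.006/month.  The base
hazard was calibrated analytically so the default mixture's marginal
5-year CSS lands near 40%, the rate typical of resected-CRLM series.
Exponential times were chosen because they make analytic expectations
available for recovery tests; uniform administrative censoring
(36–120 months) and a small other-cause death hazard (0.002/month) are
superimposed, with other-cause deaths labelled distinctly so the
censoring convention is exercised.

The truth record stores event lists, group labels, hazards and the
**true discordant-gene fraction**, computed from the event lists at
gene midpoints against the patient ploidy — independent of the
harmonize/call code path, so estimator-recovery tests have a genuine
external target.  Gene panels are tiled evenly (default 2500 genes)
with short genes relative to event lengths, keeping
midpoint-vs-largest-overlap discrepancies rare; the recovery tolerance
(±0.05) absorbs the residual edge cases.

What the generator does **not** model: subclonal fractions and purity,
whole-genome doubling as a process, segmentation noise, probe-level
data, lesion phylogenies, and gene-targeted mutation hotspots.
Passing recovery tests therefore demonstrates correctness of the
estimators under the generative assumptions, not robustness to array
noise or segmentation artifacts in real data.

## Problem sizes and determinism

Tests and the acceptance script run on a miniature genome (22
autosomes × 1 Mb) where brute-force per-base oracles are feasible, and
on the full hg19-scale genome for the 64-patient end-to-end fixture
(interval arithmetic is size-independent).  Simulation-based checks
use 8 rate levels × 8–20 cohorts of 8 patients (heterogeneity
monotonicity), 200 replicates at n = 400 (Cox coverage), 10,000
permutation draws (log-rank oracle) and n = 10,000 (prevalence
convergence).  Every random quantity derives from an explicit seed;
cohort generation is byte-identical given (config, seed), and the
pipeline writes a config hash into every output so reruns can be
verified byte-for-byte.

## Known limitations

* Distances are region-level; probe-level input is out of scope.
* No purity/ACF correction of copy numbers; ploidy is taken as given.
* The amplification merge rule treats regions separated by an
  uncovered gap as distinct events.
* The Cox layer reports convergence and separation flags but no
  proportional-hazards diagnostics.
* Multivariable Cox covariate selection is configuration, not
  inference: the pipeline fits what it is told to fit.
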