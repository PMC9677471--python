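# Methods

## Scope and data model

starscan scans diploid, biallelic, complete genotype data for introgressed
fragments. Genotypes are held as derived-allele counts in {0, 1, 2}
(`GenotypeMatrix`); a missing call is a hard error rather than an imputation
target, because the chain score has no principled treatment of missingness.
Three population roles are declared per run: a *reference* panel assumed free
of introgression, a *target* population scanned for fragments, and up to two
optional *source* panels used only for attribution.

Derived-allele polarity is a convention, not an inference: ALT is assumed
derived unless the VCF's `INFO/AA` annotation equals ALT, in which case
counts are flipped; sites whose AA matches neither allele are dropped and
counted. Users with outgroup-polarized data should encode that polarity in
`AA` before import.

Coordinates follow each format's native convention: site positions are
1-based (VCF), all intervals — windows, tracts, BED output — are 0-based
half-open. A site at position p belongs to window [start, end) iff
start ≤ p−1 < end.

## Filtering and windows

Two site filters precede scoring:

1. Variants whose derived allele is fixed in *both* the reference and the
   target population are removed. These are shared substitutions relative to
   the ancestral state and carry no scan signal. Fixation in only one panel
   retains the site. Source panels are never consulted by this filter.
2. Sites with zero derived alleles across reference and target are dropped;
   they would only inflate the per-window mutation count used as a
   calibration covariate.

Windows default to 50 kb sliding by 10 kb, the long-standing choice for
S\*-type scans: long enough to span the linkage signal of a fragment that
survived ~2,000 generations of recombination, short enough to localize it.
Full-length windows are laid at every step while they fit; if the chromosome
tail would otherwise be uncovered (or the chromosome is shorter than one
window) a single final partial window is appended and flagged. No length
normalization is applied to partial windows: the expected-score model
conditions on the window's observed mutation count, not its length.

## The S\* chain score

Candidate sites for one individual are the window's variants where the
individual carries ≥1 derived allele and the reference panel carries none
(`--ref-max-daf` relaxes the panel rule to a frequency allowance, for noisy
panels). The pairwise score rewards genotype-identical pairs with their bp
separation plus a bonus (default 5000), forbids identical pairs closer than
10 bp (no linkage information; dense clusters would otherwise dominate),
charges a flat penalty (default −10000) for small genotype differences up to
5, and forbids larger ones. These constants are the established S\*
convention and are exposed as `ScoreFunctionParams` rather than hard-coded.

The dynamic program is exact over all increasing chains; chains may start at
any candidate, chains shorter than two sites score 0, and the final score is
floored at 0. Ties between equal-scoring chains resolve to the
lexicographically smallest position sequence, making outputs bit-reproducible.
The test suite checks the DP against exhaustive enumeration of every
increasing chain on hundreds of random windows; the genotype distance is
taken on unphased diploid codes, so phased haplotype congruence is out of
scope.

## Null calibration: the expected-S\* surface

S\* has no usable analytical null, so significance is empirical: simulate an
introgression-free demography (Demes YAML, simulated with msprime), push the
replicates through the *identical* filter → window → scan path, and model
the resulting score distribution as a function of what mechanically drives
it — the window's mutation count and local recombination rate.

The surface is fitted separately per quantile q:

* Windows with S\* = 0 (fewer than two chainable candidates) are excluded;
  they carry no chain signal, are never flagged, and would otherwise
  dominate low quantiles. All calibration statements are therefore
  conditional on S\* > 0.
* Records are binned by mutation count (per observed value, or ~25
  quantile bins) and by decile of log10 recombination rate (rates floored at
  1e-12; a uniform rate collapses to one bin and drops out of the model).
* The empirical q-quantile within each bin uses the Weibull plotting
  position, whose exceedance probability is unbiased — with the default
  linear interpolation the fitted 0.99 surface would sit visibly low at
  realistic bin occupancies.
* Bin quantiles are smoothed by B-spline regression (statsmodels WLS,
  weighted by bin occupancy), with basis flexibility chosen by generalized
  cross-validation over a small candidate set.
* Predictions are evaluated on a dense covariate grid, clipped at 0, and
  sorted across the quantile grid pointwise, enforcing monotonicity in q by
  construction. The model object stores only the grids and surfaces, so it
  serializes to JSON and reloads bit-identically; prediction is (bi)linear
  interpolation clamped to the training hull (clamping is logged).

A window is an outlier at level q when its observed S\* *strictly* exceeds
the surface; S\* = 0 windows are never flagged. There is no p-value and no
multiple-testing correction: the quantile q itself is the genome-wide
stringency dial, matching how precision-recall tradeoffs are swept.

### Independence and the calibration check

Null score records are strongly correlated: overlapping windows share sites,
and all target individuals of a replicate share one genealogy (the measured
per-replicate spread of exceedance indicators is an order of magnitude above
the binomial expectation). Calibration is therefore *verified* on
approximately independent units — held-out replicates, one target
individual — where a binomial tolerance is meaningful. Verified this way,
held-out exceedance at q ∈ {0.90, 0.95, 0.99} matches 1−q within three
binomial standard errors. Training defaults are 20 Mb of null sequence
(200 × 100 kb replicates), which bounds the quantile-surface's own sampling
error well below those tolerances at q ≤ 0.99; users pushing to more extreme
quantiles should simulate proportionally more.

## Tracts and source attribution

Outlier windows merge per individual into maximal tracts (overlapping or
book-ended; the merge gap is configurable, default 0). For a tract and a
source panel, the *informative sites* are the focal individual's candidate
variants inside the tract — by default all candidates, not only the S\*
chain, which stabilizes the denominator; chain-only is available. A site is
*matched* when any individual in the source panel carries ≥1 derived allele
(presence semantics — archaic panels are typically a single genome). The
match rate is matched/informative; an empty denominator leaves the rate
undefined. With two sources, a tract is attributed to the source whose rate
exceeds the other's by more than a configurable margin (default 0; ties →
ambiguous, undefined rates → unknown). Sources are exempt from the
fixed-derived filter, which names only reference and target; since
informative sites are target-private candidates, they always survive the
standard preprocessing.

## The simulation benchmark

`benchmark_sim` generates the study conditions used by the tests and the
acceptance script, with ground truth recorded:

* **null** — two constant-size populations (N = 10,000 diploids) splitting
  2,000 generations ago; the generic no-introgression model.
* **ghost** — a donor lineage diverging 20,000 generations ago (10× the
  reference/target split), unsampled, contributing a 3% pulse into the
  target 50 generations ago; the target halves in size at the split, so
  that a constant-size approximate null is a genuine approximation.
* **two-source** — two sampled donors (splits 20,000 and 12,000 generations
  ago) each pulsing 3% into the target at 60 and 50 generations.

`null_counterpart` strips the pulses from any model (the "full" null) and
can additionally restrict it to reference and target only — mirroring the
practice of calibrating with approximate histories when the true one is
unknown. Defaults elsewhere: mutation rate 1.25e-8, recombination 1e-8 per
bp per generation, 10 reference and 10 target diploids (reference panels of
10 and 50 are both exercised in the benchmarks).

True tracts are read off the simulator's migration records: a haplotype
segment is introgressed from donor D iff its lineage sits in D at the pulse
time. Diploid truth is the union of an individual's two haplotype tracts,
because calls are per diploid individual and precision/recall must share
units. Precision and recall are base-pair level, pooled over individuals
(per-individual averaging is a documented alternative, not implemented); the
random-classifier baseline is the true introgressed proportion of the
scanned sequence. With recent pulses, migrant lineages are few (Poisson,
roughly 6–7 per 10 Mb per donor at these rates), so per-chromosome truth
fractions are heavy-tailed; aggregate comparisons in the tests average over
dozens of seeds or multiple chromosomes.

What the generator does *not* emulate: genotyping error and missingness,
ascertainment bias, variable mutation/recombination landscapes, background
selection, and phasing. Passing benchmarks here demonstrate correctness of
the pipeline's logic and calibration under its own assumptions, not
field performance on real data.

## Problem sizes and determinism

The shipped benchmarks use 20 Mb null training sets, 10 Mb scan chromosomes
and 0.5–2 Mb unit-test simulations — sizes where every pipeline stage runs
in seconds on one CPU while leaving the statistical checks well-powered.
Every stochastic step takes an explicit seed; per-replicate seeds derive
from one generator, so identical configuration and seed reproduce outputs
byte-for-byte (asserted in the test suite for every CLI subcommand).

## Known limitations

* Unphased scoring only; no haplotype-congruence S\* variant.
* Strict candidate rule by default; reference panels with contamination or
  sequencing error need `--ref-max-daf` > 0.
* The quantile surface interpolates within, and clamps at, the training
  hull; scans whose windows are far richer in SNPs than the null simulations
  produce clamped (conservative or anticonservative, depending on slope)
  expectations — simulate a matching null instead.
* One GAM per quantile (with pointwise monotonicity enforcement) rather
  than a single model with q as a covariate; the alternative would share
  strength across quantiles at the cost of a bespoke likelihood.
* Multiple chromosomes are processed independently; no X-specific handling.
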