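# Methods

`rohtrack` implements a genome-wide runs-of-homozygosity (ROH) analysis for
SNP-array genotype cohorts: ROH calling per sample, per-locus frequency
tracks, fragile-site proximity statistics, and cohort-comparison tests.
This note records the models, the parameters that matter, the synthetic
data the package is validated on, and the numerical and design choices.

## Coordinate and data model

All core coordinates are 1-based inclusive base pairs on autosomes 1-22;
sex chromosomes are excluded throughout because hemizygous male X genotypes
are indistinguishable from ROH on an array. BED and bedGraph writers
convert to 0-based half-open intervals at the writer boundary only.
Genotypes are a four-letter alphabet — HOM_A, HET, HOM_B, NoCall — aligned
to a sorted SNP map. The two homozygote classes are carried only so that
callers can be verified invariant under relabeling; every analysis reduces
to HOM / HET / NoCall.

## ROH calling

### Two-state hidden-Markov segmentation

States are *non-ROH* and *ROH*. Emissions depend only on heterozygosity:

* P(HET | non-ROH) = `het_rate` (default 0.30, the typical background
  heterozygosity of an outbred sample on a 500K array);
* P(HET | ROH) = `error_rate` (default 0.02, bracketing array genotyping
  miscall rates; inside a true homozygous run a HET call can only be an
  error);
* homozygous calls carry the complementary mass; NoCall is emission-neutral
  (equal likelihood under both states), which keeps the distance-dependent
  transitions accumulating across missing loci instead of splitting runs.

Transitions are inhomogeneous in physical distance: between adjacent loci
separated by d bp, the probability of leaving either state is
`max_switch_prob * (1 - exp(-d / transition_scale_bp))` (defaults 0.05 and
10 Mb). The switch probability saturates at `max_switch_prob` for distant
loci and vanishes for dense ones, so a run is cheap to maintain across a
dense stretch and state changes concentrate at real boundaries. The prior
probability of starting a chromosome in ROH is `initial_roh_prob` (0.1).

Decoding is exact Viterbi in log space, batched across samples. Ties are
broken toward the non-ROH state — both in the per-step predecessor choice
and at the terminal state — making output deterministic and conservative.
Maximal runs of the decoded ROH state become segments with endpoints
snapped to observed SNP positions; no interpolation beyond flanking SNPs.
The decoder is verified against exhaustive enumeration of all 2^n paths on
chromosomes of up to 12 loci.

A note on a tempting but false intuition: raising `error_rate` toward
`het_rate` does *not* monotonically shrink the called territory. A higher
`error_rate` makes interior HET calls cheaper to absorb into a run, which
extends and merges segments; only near-degenerate rates (where the states'
emissions coincide and tie-breaking takes over) collapse the calls. The
test suite asserts the two-point comparison that is actually true.

### Fixed-window scan

A PLINK-style `--homozyg` scan: a window of `window_snps` consecutive loci
(discarded when its physical span exceeds `window_kb`) is *homozygous* when
it contains at most `max_het_per_window` HET and `max_missing_per_window`
NoCall calls. Each locus scores the fraction of retained windows
overlapping it that are homozygous, and is in ROH state when that fraction
reaches `hit_fraction`. Maximal ROH-state runs are split at adjacent-SNP
gaps above `max_gap_kb`, then filtered by `min_snps_per_segment`,
`min_length_kb` and the average-spacing cap `max_density_kb_per_snp`.
Defaults (50 SNPs / 5000 kb, 1 het, 5 missing, 0.05, 100 SNPs, 1000 kb,
1000 kb, 50 kb/SNP) are the canonical published defaults of the method.

Because the hit fraction is permissive, boundary windows that reach a few
homozygous flanking loci extend a called segment slightly beyond a planted
run — the brute-force reimplementation used as oracle shows identical
behavior; it is a property of the method, not an implementation artifact.

On sparse synthetic maps the canonical thresholds must be rescaled: with a
minimum of 100 SNPs per segment, a 50-99-SNP run is structurally uncallable
at any data quality. The recovery experiments therefore use window 25
SNPs, minimum 50 SNPs / 1000 kb, 2 missing at the synthetic map's ~30 kb
spacing, and the HMM's `error_rate` set to the generator's true error rate
— a data-model match, not a tuned constant.

## Frequency tracks and regional summaries

ROHF at a locus is the fraction of cohort samples whose called segments
cover it; every sample counts in the denominator at every locus (ROHF is
defined over samples, not over called genotypes). HDF is the fraction of
samples with integer copy number exactly 1, consumed from a copy-number
matrix; the package does not compute copy number from intensities. Tracks
are kept separate per caller, never merged.

The regional summary around an anchor (a fragile site) is the mean of the
track values at or above the 95th percentile within ±5 Mb — an upper-tail
mean that suppresses background relative to a plain regional mean.
Percentiles use linear interpolation between order statistics and values
equal to the cutoff are retained; percentile 0 degenerates to the plain
window mean. Window membership is a closed interval; the window is
anchored at the site's midpoint (passing explicit bounds covers the
span-based variant). Fold changes between cohort means are rounded
half-up at the quoted precision.

## Fragile sites and proximity

Fragile sites are catalogued by cytogenetic band only. A gene table
carrying both band labels and genomic coordinates maps each site to the
(minimum start, maximum end) envelope of the genes whose band label matches
*exactly* — "9p21" does not match "9p21.3"; no sub-band expansion rule is
applied, which is reproducible but can leave sites unmapped (they are
reported, not dropped). The site's anchor is the region midpoint, rounded
down. Proximity is measured feature-point to anchor; a feature near two
sites counts once. Proximity ratios print with 3 decimals below 0.1 and 2
otherwise, matching the mixed precision convention of published tables.
High-ROHF bands without a fragile site are maximal runs of loci whose
±5 Mb upper-tail summary clears a threshold with no anchor within the
radius; the band's peak is the locus of maximum raw ROHF, middle locus on
ties.

## Cohort comparison

* **Adjusted correlation**: both tracks are residualized on covariates
  (least squares with intercept; the local SNP density covariate is
  SNPs/Mb in a centered 1 Mb window, HDF the other), then Pearson r of
  residuals with p from the t distribution on n − k − 2 df and Bonferroni
  scaling. With no covariates this is exactly plain Pearson. Constant
  residuals are flagged `undefined`, mirroring "NA" entries for
  chromosomes without any fragile site.
* **Stepwise cutoffs**: Pearson r recomputed on loci where the reference
  track exceeds its q-quantile, for rising q.
* **Top-difference selection**: loci ranked by track difference
  descending, ties broken by map order; the cutoff value at rank N is
  reported with the tie count.
* **Adult-vs-young resampling**: the 60-adult cohort is shrunk to the
  30-young size by sampling without replacement, 1000 times by default,
  with distinct subsets across draws ("non-redundant"). Each dataset's
  ROHF track is compared to the young track by a t-test across loci
  (paired by locus by default; unpaired available), significant below
  alpha / n_tests with n_tests the locus count — the genome-wide
  Bonferroni scale. Power is summarized by the proportion of significant
  datasets with positive mean difference; zero significant datasets yield
  a flagged None, never a silent NaN.

### A calibration caveat that matters

The per-dataset t-test across loci answers "is this subsample's track
different from the young track" — and conditional on the two *realized*
cohorts, the expected difference is the finite-sample cohort difference,
which is nonzero whenever per-sample ROH burden varies at all. With
Poisson segment counts and exponential lengths (any realistic model),
burden variance is irreducible, so under a *distributional* null the
procedure declares significance in far more than 5% of repetitions (0.66-
0.78 measured over 50 seeded repetitions at desk scale). The acceptance
suite keeps the nominal-level assertion and it fails honestly; the
procedure's sign *symmetry* under the null does hold (the majority sign of
significant datasets is positive about half the time, assessed per
repetition because datasets within a repetition share cohorts), and under
a planted +0.05 adult hotspot excess the positive proportion among
significant datasets is ~1.0. An across-sample test would be calibrated;
it is not what the across-loci formulation computes.

## Synthetic cohorts: what they emulate, and what not

The generator produces 500K-array-like call matrices: background HET rate
0.3 outside ROH, HET at the error rate inside, NoCall overlaid
independently of state (0.5% control-like, 4.2% tumor-like), shared
hotspots carried independently per sample at a cohort-specific frequency,
private segments at a Poisson per-chromosome rate with exponential
lengths, and homozygote class assigned by a per-locus allele-frequency
draw. Carriers' hotspot runs can extend beyond the shared core by
exponential per-side draws — severe cohorts as *extensions* of runs present
in mild cohorts, which is what makes the two cohorts' spatial ROHF
profiles genuinely correlated rather than plateau-shaped. Every planted
segment covers at least one locus and at least one homozygous call (the
middle locus is pinned homozygous in the rare case the error/NoCall
overlay wipes a tiny segment).

Not emulated: linkage disequilibrium, allele-frequency spectra, pedigree
structure (the adult/young comparison is emulated as two cohorts with a
per-hotspot frequency delta — the test operates on cohort tracks, not
pedigrees), and raw intensities. Passing recovery tests therefore show
that the callers segment state-switch processes of realistic geometry
under realistic noise; they do not certify behavior under LD-induced
homozygosity stretches, which are shorter and denser than disease ROH.

## Reference experiment scales

Chosen once as the package's desk-scale study conditions:

* **Recovery**: 200 samples x 20,000 loci (10 chromosomes x 2,000 SNPs
  over 60 Mb, ~30 kb spacing), het 0.3 / error 0.01 / NoCall 0.01, one
  6 Mb hotspot per chromosome at frequency 0.4, private segments mean 5 Mb.
  Both callers reach per-locus sensitivity and precision ≥ 0.95 against
  planted segments of ≥ 50 SNPs and ≥ 1 Mb, and hotspot ROHF lands within
  3 binomial SD of the realized carrier fraction.
* **Resampling**: a thinned genome-wide map (2,000 loci over 10 x 260 Mb,
  ~1.3 Mb spacing — scale reduction preserves the genome span that the
  segment-length scale lives on), 60 adults / 30 young, two 10 Mb shared
  hotspots per chromosome (~8% of loci covered) at frequency 0.10, null
  repeated 50 times at 100 draws each; the power experiment plants +0.05
  adult hotspot excess and pools 10 cohort pairs x 200 draws.
* **Stepwise cutoffs**: 2,000 loci over 5 chromosomes, 4 shared 1 Mb
  hotspot cores per chromosome with log-uniform control frequencies
  (0.02-0.5; tumor 3x + 0.1, capped), carrier extensions 6 Mb tumor / 1 Mb
  control, private rate 1.0; the correlation series is averaged over 10
  replicate cohort pairs. The quantile grid stops at 0.75: beyond it the
  selection collapses the retained loci onto a few hotspot plateaus and
  classical range restriction reverses the rise at desk-scale locus
  counts. The genome-scale analyses this emulates retain tens of
  thousands of loci even at the 0.95 quantile and keep climbing; that
  regime is not reachable with 2,000 loci.

## Known limitations

* ROH only — no matched normals, so no ROH/LOH distinction; no
  copy-number-aware calling; no genetic-map (cM) transitions.
* Exact band matching can under-map fragile sites against gene tables
  annotated at sub-band resolution.
* The resampling test's across-loci t-test is anti-conservative at the
  distribution level (above); its outputs should be read as descriptions
  of realized cohort differences, with the positive proportion as the
  interpretable summary.
* The stepwise-cutoff rise is regime-dependent: it measures noise-floor
  removal and reverses under extreme-tail range restriction.
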