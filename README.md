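# rohtrack

Genome-wide runs-of-homozygosity (ROH) analysis for SNP-array genotype
cohorts.

Extended stretches of homozygous genotype calls — ROH, known as loss of
heterozygosity (LOH) when confined to tumor cells — recur at shared genomic
positions across individuals, and cancer cell lines show the same spatial
pattern as healthy cohorts at much higher intensity. `rohtrack` provides
the full analysis chain for studying that phenomenon on desk-scale data:

* **simulation** of 500K-array-like genotype cohorts (samples × loci call
  matrices over a SNP map) with planted ROH segments, shared hotspots,
  genotyping error and NoCall overlay, plus ground truth for scoring;
* **ROH calling** per sample by two methods — a two-state hidden-Markov
  segmentation with distance-dependent transitions decoded by Viterbi, and
  a PLINK-style fixed-window homozygosity scan;
* **frequency tracks**: per-locus ROH frequency, ROHF(j) = (# samples whose
  ROH cover locus j)/n, and hemizygous-deletion frequency, HDF(j) =
  (# samples with copy number 1 at j)/n; regional summaries as the mean of
  the upper-95th-percentile ROHF within ±5 Mb of an anchor;
* **fragile-site analysis**: cytoband→genomic mapping of fragile sites
  (FRAs) through a gene table, miRNA proximity counts and ratios, per-site
  ROHF tables, and detection of high-ROHF bands with no fragile site
  nearby;
* **cohort comparison**: covariate-adjusted (partial) correlation of ROHF
  tracks, stepwise-cutoff correlation, top-difference locus selection, and
  an adult-vs-young resampling test (repeated subsampling of the larger
  cohort to the smaller cohort's size, per-dataset t-tests across loci
  under genome-wide Bonferroni, positive-proportion power summary).

See `docs/methods.md` for the models, defaults and limitations.

## Worked example

The numbered scripts under `analysis/` run the full chain on a simulated
tumor-like (60 samples) vs control-like (90 samples) cohort pair sharing
hotspot positions at different carrier frequencies (10,000 loci over five
chromosomes):

```sh
python analysis/01_simulate_cohorts.py
python analysis/02_call_roh.py
python analysis/03_frequency_tracks.py
python analysis/04_fragile_sites.py
python analysis/05_comparative_statistics.py
python analysis/06_published_summaries.py
```

Outputs land in `results/analysis/`. Representative printed output:

```
tumor/hmm: 212 segments, median length 10.70 Mb, sensitivity 0.992, precision 0.990
control/hmm: 118 segments, median length 5.62 Mb, sensitivity 0.928, precision 0.972
ROHF tumor/hmm: mean 0.1343, max 0.617
ROHF control/hmm: mean 0.0200, max 0.144
tumor/control mean ROHF fold change (hmm): 6.7
adjusted tumor/control ROHF correlation: r = 0.720, Bonferroni p = 0.00e+00 (covariates: snp_density, hdf)
resampling (200 draws of 30 from 60 adults): 181 positive mean differences,
143 Bonferroni-significant, proportion positive among significant = 98.6%
```

Reading this: both callers recover the planted segments at high per-locus
sensitivity/precision; the tumor-like cohort's mean ROHF is ~6.7× the
control's because the same hotspots are carried at higher frequency with
longer runs; the two cohorts' tracks correlate strongly after adjusting
for SNP density and HDF; and splitting the control cohort 60/30 and
resampling shows the positive-proportion summary the comparison machinery
reports. Script 06 recomputes the headline published summaries from the
packaged fragile-site table (30 of 111 sites with tumor-cohort regional
ROHF > 0.5, four sites with cohort difference ≥ 0.5, miRNA proximity
ratios 0.066 / 0.35, fold changes 11 and 1.02, resampling proportions
73.9% and 92.3%).

A single-command variant of the pipeline, driven by a declarative JSON
config, is also available:

```sh
rohtrack run --config configs/demo.json
```

with subcommands `simulate`, `call`, `rohf`, `hdf`, `annotate`, `compare`
for the individual stages (`rohtrack --help`).

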