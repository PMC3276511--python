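"""Recompute the headline published summaries from the packaged tables:
fragile-site threshold counts, miRNA proximity ratios, cohort fold changes
and resampling positive proportions for the NCI-60 vs HapMap comparison.
"""

from rohtrack import published


def main() -> None:
    counts = published.fra_threshold_counts()
    print(f"fragile sites with tumor-cohort regional ROHF > 0.5: "
          f"{counts['n_high_rohf']} of 111 "
          f"({counts['n_without_elevation']} without such elevation)")
    print(f"sites with cohort ROHF difference >= 0.5: {counts['n_big_diff']} "
          f"({', '.join(counts['big_diff_names'])})")
    print(f"mean miRNA count within ±5 Mb of the elevated sites: "
          f"{counts['mean_mirna_5mb_high']}")
    ratios = published.mirna_summary()
    print(f"miRNA/fragile-site proximity ratios: {ratios['ratio_1mb']} (±1 Mb), "
          f"{ratios['ratio_5mb']} (±5 Mb); "
          f"prior-study ±1 Mb ratio {ratios['ratio_prior_study_1mb']}")
    fc = published.cohort_fold_changes()
    print(f"mean ROHF fold change, tumor vs control cohort: "
          f"{fc['fold_tumor_vs_control']:.0f}")
    print(f"adult vs young: fold change {fc['fold_adult_vs_young']}, "
          f"difference {fc['adult_young_diff_pct']} percentage points")
    props = published.resampling_proportions()
    print(f"positive proportion among significant resampled datasets: "
          f"{props['hmm']}% (HMM calls), {props['window']}% (window calls)")


if __name__ == "__main__":
    main()
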