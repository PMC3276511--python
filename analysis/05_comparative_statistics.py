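"""Cohort-comparison statistics on the demo cohorts: covariate-adjusted
correlation between the tumor and control ROHF tracks (adjusting for local
SNP density and HDF), stepwise-cutoff correlation, fragile-site proximity
correlation, top-difference locus selection, and the adult-vs-young
subsample resampling test run on a split of the control cohort.
"""

import json
from pathlib import Path

import numpy as np

from rohtrack import (
    adjusted_correlation, adult_young_resampling, fra_proximity_correlation,
    generate_annotations, local_snp_density, map_fra_to_genomic,
    segments_to_locus_state, stepwise_cutoff_correlation, top_diff_snps,
)
from rohtrack.io import read_segments_tsv, read_snp_map_tsv, read_track_tsv, read_tped

OUT = Path("results/analysis")


def main() -> None:
    snp_map = read_snp_map_tsv(OUT / "snp_map.tsv")
    track_t, _ = read_track_tsv(OUT / "rohf_tumor_hmm.tsv")
    track_c, _ = read_track_tsv(OUT / "rohf_control_hmm.tsv")
    hdf, _ = read_track_tsv(OUT / "hdf_tumor.tsv")
    density = local_snp_density(snp_map)

    adj = adjusted_correlation(
        track_t, track_c, {"snp_density": density, "hdf": hdf.values},
        alpha_adjust_n=len(snp_map),
    )
    print(f"adjusted tumor/control ROHF correlation: r = {adj.r:.3f}, "
          f"Bonferroni p = {adj.p_bonferroni:.2e} "
          f"(covariates: {', '.join(adj.covariates_used)})")

    for q, n, r in stepwise_cutoff_correlation(track_t, track_c,
                                               [0.0, 0.25, 0.5, 0.75]):
        print(f"stepwise cutoff q={q:.2f}: {n} loci retained, r = {r:.3f}")

    ann = generate_annotations(snp_map, n_fras=8, genes_per_band=3,
                               n_mirna=60, seed=9)
    fras, _ = map_fra_to_genomic(ann.fra_records, ann.gene_table)
    prox = fra_proximity_correlation(track_t, snp_map, fras)
    genome = prox["all"]
    print(f"ROHF / fragile-site proximity correlation (genome-wide): "
          f"r = {genome.r:.3f}")
    na = [c for c, res in prox.items() if c != "all" and res.undefined]
    if na:
        print(f"  chromosomes without informative proximity indicator: {na}")

    top = top_diff_snps(track_t, track_c, top_n=500)
    print(f"top-500 ROHF-difference loci: cutoff {top.cutoff_value:.3f}, "
          f"{top.n_ties_at_cutoff} tie(s) at the cutoff")

    # adult/young emulation: split the 90 control samples 60/30
    control = read_tped(OUT / "control")
    segs = read_segments_tsv(OUT / "segments_control_hmm.tsv")
    state = segments_to_locus_state(segs, snp_map, control.sample_ids)
    res = adult_young_resampling(state[:60], state[60:], n_iter=200,
                                 subsample_size=30, seed=13)
    print(f"resampling (200 draws of 30 from 60 adults): "
          f"{res.n_positive} positive mean differences, "
          f"{res.n_significant} Bonferroni-significant, "
          f"proportion positive among significant = "
          f"{'NA' if res.proportion is None else f'{res.proportion:.1%}'}")
    (OUT / "comparative_summary.json").write_text(json.dumps({
        "adjusted_r": adj.r,
        "adjusted_p_bonferroni": adj.p_bonferroni,
        "top_diff_cutoff": top.cutoff_value,
        "resampling": {
            "n_positive": res.n_positive,
            "n_significant": res.n_significant,
            "n_significant_positive": res.n_significant_positive,
            "proportion": res.proportion,
        },
    }, indent=2, default=float))


if __name__ == "__main__":
    main()
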