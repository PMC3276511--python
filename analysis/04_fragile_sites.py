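"""Fragile-site analysis on the demo cohorts: map synthetic FRA cytobands to
genomic regions through the gene table, tabulate regional upper-95th
percentile ROHF around each site for both cohorts, count nearby miRNAs, and
search for high-ROHF bands with no fragile site in the vicinity.

Writes the per-site table and the band list under results/analysis/.
"""

from pathlib import Path

import pandas as pd

from rohtrack import (
    count_within, fra_rohf_table, generate_annotations,
    high_rohf_bands_without_fra, map_fra_to_genomic,
)
from rohtrack.io import read_snp_map_tsv, read_track_tsv

OUT = Path("results/analysis")
RADIUS = 5_000_000


def main() -> None:
    snp_map = read_snp_map_tsv(OUT / "snp_map.tsv")
    ann = generate_annotations(snp_map, n_fras=8, genes_per_band=3,
                               n_mirna=60, seed=9)
    fras, unmapped = map_fra_to_genomic(ann.fra_records, ann.gene_table)
    print(f"mapped {len(fras)} fragile sites, {len(unmapped)} unmapped")
    track_t, _ = read_track_tsv(OUT / "rohf_tumor_hmm.tsv", cohort="tumor")
    track_c, _ = read_track_tsv(OUT / "rohf_control_hmm.tsv", cohort="control")
    table = fra_rohf_table(
        fras, track_t, track_c, snp_map, radius_bp=RADIUS,
        features=ann.mirna, feature_radii_bp=(RADIUS, 1_000_000),
    )
    table.to_csv(OUT / "fra_rohf_table.tsv", sep="\t", index=False)
    high = table[table["rohf_a"] > 0.5]
    print(f"{len(high)} of {len(table)} sites with tumor regional ROHF > 0.5; "
          f"{int((table['rohf_diff'] >= 0.5).sum())} with cohort difference >= 0.5")
    for radius in (1_000_000, RADIUS):
        count, ratio = count_within(ann.mirna, fras, radius)
        print(f"miRNAs within ±{radius // 1_000_000} Mb of a fragile site: "
              f"{count} of {len(ann.mirna)} (ratio = {ratio})")
    bands = high_rohf_bands_without_fra(track_t, snp_map, fras,
                                        radius_bp=RADIUS, threshold=0.6)
    pd.DataFrame(bands).to_csv(OUT / "high_rohf_bands_no_fra.tsv",
                               sep="\t", index=False)
    print(f"{len(bands)} high-ROHF band(s) with no fragile site within "
          f"±{RADIUS // 1_000_000} Mb")
    for b in bands:
        print(f"  chr{b['chromosome']} peak {b['peak_position_bp']:,} "
              f"[{b['band_start_bp']:,}-{b['band_end_bp']:,}] "
              f"summary {b['summary']:.3f}")


if __name__ == "__main__":
    main()
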