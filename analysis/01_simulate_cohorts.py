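"""Simulate the demo cohort pair: a tumor-like and a control-like SNP-array
cohort sharing ROH hotspot positions at different carrier frequencies.

Writes PLINK transposed-text genotypes, the SNP map, and the ground truth
under results/analysis/.
"""

from pathlib import Path

from rohtrack import generate_cohort, generate_snp_map
from rohtrack.io import write_snp_map_tsv, write_tped, write_truth
from rohtrack.types import Hotspot

OUT = Path("results/analysis")
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    snp_map = generate_snp_map(
        n_chromosomes=5, snps_per_chromosome=2000,
        chromosome_length_bp=60_000_000, seed=SEED,
    )
    spots_tumor, spots_control = [], []
    for c in snp_map.chromosomes:
        lo, hi = snp_map.chrom_range(int(c))
        mid = (lo + hi) // 2
        spots_tumor.append(Hotspot(int(c), mid - 3_000_000, mid + 3_000_000, 0.5))
        spots_control.append(Hotspot(int(c), mid - 3_000_000, mid + 3_000_000, 0.1))
    tumor, truth_t = generate_cohort(
        snp_map, 60, het_rate=0.3, error_rate=0.01, nocall_rate=0.042,
        hotspots=spots_tumor, private_roh_rate=0.3,
        private_roh_mean_len_bp=5_000_000, seed=SEED + 1, sample_prefix="T",
        hotspot_extension_mean_bp=4_000_000,
    )
    control, truth_c = generate_cohort(
        snp_map, 90, het_rate=0.3, error_rate=0.01, nocall_rate=0.005,
        hotspots=spots_control, private_roh_rate=0.3,
        private_roh_mean_len_bp=2_500_000, seed=SEED + 2, sample_prefix="C",
    )
    write_snp_map_tsv(snp_map, OUT / "snp_map.tsv")
    write_tped(tumor, OUT / "tumor")
    write_tped(control, OUT / "control")
    write_truth(truth_t, OUT / "truth_tumor")
    write_truth(truth_c, OUT / "truth_control")
    print(f"map: {len(snp_map)} loci on {len(snp_map.chromosomes)} chromosomes")
    print(f"tumor cohort: {tumor.n_samples} samples, "
          f"mean NoCall {tumor.nocall_fraction().mean():.3f}, "
          f"{len(truth_t.planted_segments)} planted segments")
    print(f"control cohort: {control.n_samples} samples, "
          f"mean NoCall {control.nocall_fraction().mean():.3f}, "
          f"{len(truth_c.planted_segments)} planted segments")


if __name__ == "__main__":
    main()
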