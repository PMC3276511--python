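"""Per-locus frequency tracks: ROHF for each cohort and caller, plus a
hemizygous-deletion frequency (HDF) track from simulated copy numbers.

Reads segments from 02_call_roh.py; writes tracks (TSV + bedGraph) under
results/analysis/ and prints the cohort means and their fold change.
"""

from pathlib import Path

from rohtrack import (
    compute_hdf, compute_rohf, fold_change, generate_copy_number,
    segments_to_locus_state,
)
from rohtrack.io import (
    read_segments_tsv, read_tped, write_track_bedgraph, write_track_tsv,
)

OUT = Path("results/analysis")


def main() -> None:
    means = {}
    for cohort in ("tumor", "control"):
        genotypes = read_tped(OUT / cohort)
        for caller in ("hmm", "window"):
            segs = read_segments_tsv(OUT / f"segments_{cohort}_{caller}.tsv")
            state = segments_to_locus_state(segs, genotypes.snp_map,
                                            genotypes.sample_ids)
            track = compute_rohf(state, cohort=cohort)
            write_track_tsv(track, genotypes.snp_map,
                            OUT / f"rohf_{cohort}_{caller}.tsv")
            write_track_bedgraph(track, genotypes.snp_map,
                                 OUT / f"rohf_{cohort}_{caller}.bedgraph")
            means[(cohort, caller)] = track.values.mean()
            print(f"ROHF {cohort}/{caller}: mean {track.values.mean():.4f}, "
                  f"max {track.values.max():.3f}")
    for caller in ("hmm", "window"):
        fc = fold_change(means[("tumor", caller)], means[("control", caller)], 1)
        print(f"tumor/control mean ROHF fold change ({caller}): {fc}")
    tumor = read_tped(OUT / "tumor")
    cn = generate_copy_number(tumor.snp_map, tumor.sample_ids,
                              hemi_del_segment_rate=0.6,
                              mean_len_bp=2_000_000, seed=5)
    hdf = compute_hdf(cn, cohort="tumor")
    write_track_tsv(hdf, tumor.snp_map, OUT / "hdf_tumor.tsv")
    print(f"HDF: fraction of cn=1 entries {(cn.cn == 1).mean():.4f}, "
          f"max HDF {hdf.values.max():.3f}")


if __name__ == "__main__":
    main()
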