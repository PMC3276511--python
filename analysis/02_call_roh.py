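"""Call ROH segments in both demo cohorts with both callers (two-state HMM
and fixed-window scan) and score them against the planted truth.

Reads the cohorts written by 01_simulate_cohorts.py; writes per-caller
segment tables under results/analysis/ and prints per-locus sensitivity and
precision for each cohort and caller.
"""

import json
from pathlib import Path

import numpy as np

from rohtrack import (
    HmmParams, WindowParams, call_roh_hmm, call_roh_window,
    segments_to_locus_state,
)
from rohtrack.io import read_tped, write_segments_bed, write_segments_tsv
from rohtrack.types import CohortTruth, Hotspot, PlantedSegment

OUT = Path("results/analysis")

HMM = HmmParams(het_rate=0.30, error_rate=0.01)
WINDOW = WindowParams(
    window_snps=25, max_het_per_window=1, max_missing_per_window=2,
    min_snps_per_segment=50, min_length_kb=1000,
)


def _truth_state(prefix, snp_map, sample_ids):
    meta = json.loads((OUT / f"truth_{prefix}.json").read_text())
    segs = []
    for line in (OUT / f"truth_{prefix}.bed").read_text().splitlines():
        chrom, start, end, sid = line.split("\t")
        segs.append(PlantedSegment(sid, int(chrom[3:]), int(start) + 1, int(end)))
    truth = CohortTruth(segs, [Hotspot(*h) for h in meta["hotspots"]],
                        meta["generator_params"], meta["seed"])
    return truth.state_matrix(snp_map, sample_ids)


def main() -> None:
    for cohort in ("tumor", "control"):
        genotypes = read_tped(OUT / cohort)
        truth = _truth_state(cohort, genotypes.snp_map, genotypes.sample_ids)
        for caller, fn, params in (
            ("hmm", call_roh_hmm, HMM),
            ("window", call_roh_window, WINDOW),
        ):
            segs = fn(genotypes, params)
            write_segments_tsv(segs, OUT / f"segments_{cohort}_{caller}.tsv")
            write_segments_bed(segs, OUT / f"segments_{cohort}_{caller}.bed")
            state = segments_to_locus_state(segs, genotypes.snp_map,
                                            genotypes.sample_ids)
            tp = int((state & truth).sum())
            sens = tp / truth.sum() if truth.sum() else float("nan")
            prec = tp / state.sum() if state.sum() else float("nan")
            lengths = [s.length_bp for s in segs]
            print(
                f"{cohort}/{caller}: {len(segs)} segments, "
                f"median length {np.median(lengths) / 1e6:.2f} Mb, "
                f"sensitivity {sens:.3f}, precision {prec:.3f}"
            )


if __name__ == "__main__":
    main()
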