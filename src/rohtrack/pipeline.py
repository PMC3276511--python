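"""End-to-end pipeline orchestration.

One call runs: simulate (or load) genotype cohorts -> ROH calling (one or
both callers) -> frequency tracks -> fragile-site annotation table ->
comparative statistics (adjusted correlation, stepwise cutoffs, adult-vs-
young resampling, top-difference loci), and writes every stage output plus
a JSON manifest of inputs, parameters and seeds.  Two runs with the same
config are byte-identical.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

from . import __version__
from .annotation import count_within, fra_rohf_table, map_fra_to_genomic
from .calling import call_roh_hmm, call_roh_window, segments_to_locus_state
from .compare import (
    adjusted_correlation,
    adult_young_resampling,
    local_snp_density,
    stepwise_cutoff_correlation,
    top_diff_snps,
)
from .config import PipelineConfig
from .io import (
    read_genotypes,
    write_segments_bed,
    write_segments_tsv,
    write_snp_map_tsv,
    write_track_tsv,
    write_truth,
    write_tped,
)
from .simulate import (
    generate_annotations,
    generate_cohort,
    generate_copy_number,
    generate_snp_map,
)
from .tracks import compute_hdf, compute_rohf
from .types import Hotspot

__all__ = ["run_pipeline"]


def _hotspots(cfg, snp_map, freq) -> list[Hotspot]:
    sim = cfg.simulate
    spots = []
    chroms = snp_map.chromosomes
    for k in range(sim.n_hotspots):
        c = int(chroms[k % len(chroms)])
        lo, hi = snp_map.chrom_range(c)
        span = hi - lo
        # Deterministic placement: evenly spaced, one-per-chromosome rotation.
        center = lo + int(span * (0.25 + 0.5 * (k // len(chroms)) / max(1, (sim.n_hotspots - 1) // len(chroms) + 1)))
        half = sim.hotspot_length_bp // 2
        start = max(lo, center - half)
        end = min(hi, center + half)
        spots.append(Hotspot(c, start, end, freq))
    return spots


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns the manifest dict.

    Stage failures raise with the stage name prefixed; outputs written
    before the failure are left in place for inspection.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "config": cfg.to_dict(),
        "stages": [],
    }
    stage = "setup"
    try:
        sim = cfg.simulate
        stage = "simulate-or-load"
        if cfg.genotypes_tumor and cfg.genotypes_control:
            tumor = read_genotypes(cfg.genotypes_tumor)
            control = read_genotypes(cfg.genotypes_control)
            snp_map = tumor.snp_map
            truth_tumor = truth_control = None
        else:
            snp_map = generate_snp_map(
                sim.n_chromosomes, sim.snps_per_chromosome,
                sim.chromosome_length_bp, seed=cfg.seed,
            )
            spots_t = _hotspots(cfg, snp_map, sim.hotspot_freq_tumor)
            spots_c = _hotspots(cfg, snp_map, sim.hotspot_freq_control)
            tumor, truth_tumor = generate_cohort(
                snp_map, sim.n_samples_tumor, sim.het_rate, sim.error_rate,
                sim.nocall_rate_tumor, spots_t, sim.private_roh_rate,
                sim.private_roh_mean_len_bp, seed=cfg.seed + 1,
                sample_prefix="T",
            )
            control, truth_control = generate_cohort(
                snp_map, sim.n_samples_control, sim.het_rate, sim.error_rate,
                sim.nocall_rate_control, spots_c, sim.private_roh_rate,
                sim.private_roh_mean_len_bp, seed=cfg.seed + 2,
                sample_prefix="C",
            )
            write_snp_map_tsv(snp_map, out / "snp_map.tsv")
            write_tped(tumor, out / "tumor")
            write_tped(control, out / "control")
            write_truth(truth_tumor, out / "truth_tumor")
            write_truth(truth_control, out / "truth_control")
        manifest["stages"].append(stage)

        stage = "copy-number"
        cn = generate_copy_number(
            snp_map, tumor.sample_ids, hemi_del_segment_rate=0.5,
            mean_len_bp=2_000_000, seed=cfg.seed + 3,
        )
        hdf = compute_hdf(cn, cohort="tumor")
        write_track_tsv(hdf, snp_map, out / "hdf_tumor.tsv")
        manifest["stages"].append(stage)

        stage = "roh-calling"
        callers = ["hmm", "window"] if cfg.caller == "both" else [cfg.caller]
        tracks: dict[str, dict] = {}
        states: dict[str, dict] = {}
        for caller in callers:
            call = call_roh_hmm if caller == "hmm" else call_roh_window
            params = cfg.hmm if caller == "hmm" else cfg.window
            seg_t = call(tumor, params)
            seg_c = call(control, params)
            write_segments_tsv(seg_t + seg_c, out / f"segments_{caller}.tsv")
            write_segments_bed(seg_t + seg_c, out / f"segments_{caller}.bed")
            st_t = segments_to_locus_state(seg_t, snp_map, tumor.sample_ids)
            st_c = segments_to_locus_state(seg_c, snp_map, control.sample_ids)
            rohf_t = compute_rohf(st_t, cohort="tumor")
            rohf_c = compute_rohf(st_c, cohort="control")
            write_track_tsv(rohf_t, snp_map, out / f"rohf_tumor_{caller}.tsv")
            write_track_tsv(rohf_c, snp_map, out / f"rohf_control_{caller}.tsv")
            tracks[caller] = {"tumor": rohf_t, "control": rohf_c}
            states[caller] = {"tumor": st_t, "control": st_c}
        manifest["stages"].append(stage)

        stage = "annotation"
        ann = generate_annotations(
            snp_map, n_fras=cfg.n_fras, genes_per_band=3,
            n_mirna=cfg.n_mirna, seed=cfg.seed + 4,
        )
        fras, unmapped = map_fra_to_genomic(ann.fra_records, ann.gene_table)
        ann_tables = {}
        for caller in callers:
            table = fra_rohf_table(
                fras, tracks[caller]["tumor"], tracks[caller]["control"],
                snp_map, radius_bp=cfg.proximity_radius_bp,
                percentile=cfg.percentile, features=ann.mirna,
                feature_radii_bp=(cfg.proximity_radius_bp, cfg.mirna_radius_bp),
            )
            table.to_csv(out / f"fra_rohf_table_{caller}.tsv", sep="\t", index=False)
            ann_tables[caller] = table
        n_near, ratio = count_within(ann.mirna, fras, cfg.mirna_radius_bp)
        manifest["mirna_proximity"] = {
            "count": n_near, "ratio": ratio, "n_mirna": len(ann.mirna),
            "unmapped_fras": unmapped,
        }
        manifest["stages"].append(stage)

        stage = "comparative"
        density = local_snp_density(snp_map)
        comp: dict = {}
        for caller in callers:
            t, c = tracks[caller]["tumor"], tracks[caller]["control"]
            adj = adjusted_correlation(
                t, c, {"snp_density": density, "hdf": hdf.values},
                alpha_adjust_n=len(snp_map),
            )
            steps = stepwise_cutoff_correlation(
                t, c, [0.0, 0.25, 0.5, 0.75, 0.9]
            )
            st_c = states[caller]["control"]
            n_adult = (2 * st_c.shape[0]) // 3
            res = adult_young_resampling(
                st_c[:n_adult], st_c[n_adult:],
                n_iter=cfg.resampling.n_iter,
                subsample_size=cfg.resampling.subsample_size,
                alpha=cfg.resampling.alpha,
                paired=cfg.resampling.paired,
                seed=cfg.seed + 5,
            )
            top = top_diff_snps(t, c, top_n=min(200, len(snp_map)))
            high = ann_tables[caller]
            comp[caller] = {
                "adjusted_correlation": {
                    "r": adj.r, "p_raw": adj.p_raw,
                    "p_bonferroni": adj.p_bonferroni,
                    "undefined": adj.undefined,
                },
                "stepwise": [
                    {"quantile": q, "n_loci": n, "r": r} for q, n, r in steps
                ],
                "resampling": {
                    "n_positive": res.n_positive,
                    "n_significant": res.n_significant,
                    "n_significant_positive": res.n_significant_positive,
                    "proportion": res.proportion,
                },
                "top_diff_cutoff": top.cutoff_value,
                "n_fra_high_rohf": int(
                    (high["rohf_a"] > cfg.fra_rohf_threshold).sum()
                ),
            }
        manifest["comparative"] = comp
        manifest["stages"].append(stage)
    except Exception as e:  # noqa: BLE001 - annotate failing stage, re-raise
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=float, sort_keys=True)
    return manifest
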