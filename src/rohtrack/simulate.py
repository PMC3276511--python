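"""Synthetic SNP-array cohorts with planted runs of homozygosity.

The generator emulates 500K-array-like genotype data: background per-sample
heterozygosity around 0.25-0.35 outside ROH, a small residual heterozygote
(genotyping-error) rate inside ROH, an independent NoCall overlay (~0.5% for
a control-like cohort, ~4.2% for a tumor-like cohort), population-shared ROH
hotspots whose carrier frequency differs between cohorts, and private
(sample-specific) segments with exponential lengths.  Every planted segment
is recorded in a CohortTruth so downstream callers and statistics can be
scored against known state.

No linkage-disequilibrium, allele-frequency-spectrum or pedigree structure is
simulated; the analyses downstream operate on HOM/HET/NOCALL state only.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .types import (
    HET,
    HOM_A,
    HOM_B,
    NOCALL,
    CohortTruth,
    CopyNumberMatrix,
    GenotypeMatrix,
    Hotspot,
    PlantedSegment,
    SnpMap,
)

__all__ = [
    "generate_snp_map",
    "generate_cohort",
    "generate_copy_number",
    "generate_annotations",
    "AnnotationSet",
]


def generate_snp_map(
    n_chromosomes: int,
    snps_per_chromosome: int,
    chromosome_length_bp: int,
    seed: int,
) -> SnpMap:
    """Uniform-random SNP map on `n_chromosomes` autosomes.

    Positions are drawn uniformly on [1, chromosome_length_bp], de-duplicated
    and sorted; chromosomes are numbered 1..n_chromosomes (max 22).
    """
    if n_chromosomes < 1 or n_chromosomes > 22:
        raise ValueError("n_chromosomes must be in 1..22 (autosomes only)")
    if snps_per_chromosome < 1 or chromosome_length_bp < 1:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    ids, chroms, positions = [], [], []
    for c in range(1, n_chromosomes + 1):
        if snps_per_chromosome > chromosome_length_bp:
            raise ValueError(
                f"chromosome {c}: requested {snps_per_chromosome} SNPs but only "
                f"{chromosome_length_bp} distinct positions available"
            )
        pool = np.array([], dtype=np.int64)
        # Uniform draws de-duplicated; top up until enough distinct positions.
        while len(pool) < snps_per_chromosome:
            extra = rng.integers(
                1, chromosome_length_bp + 1, size=snps_per_chromosome + 16
            )
            pool = np.unique(np.concatenate([pool, extra]))
        pos = np.sort(rng.choice(pool, size=snps_per_chromosome, replace=False))
        positions.append(pos)
        chroms.append(np.full(snps_per_chromosome, c, dtype=np.int64))
        ids.extend(f"rs{c}_{k}" for k in range(snps_per_chromosome))
    return SnpMap(
        snp_id=np.array(ids, dtype=object),
        chromosome=np.concatenate(chroms),
        position_bp=np.concatenate(positions),
    )


def _validate_hotspots(snp_map: SnpMap, hotspots: Sequence[Hotspot]) -> list[Hotspot]:
    spots = [Hotspot(*h) for h in hotspots]
    by_chrom: dict[int, list[Hotspot]] = {}
    for h in spots:
        if not 0.0 <= h.frequency <= 1.0:
            raise ValueError(f"hotspot frequency {h.frequency} outside [0,1]")
        lo, hi = snp_map.chrom_range(h.chromosome)
        if h.start_bp < lo or h.end_bp > hi or h.start_bp > h.end_bp:
            raise ValueError(
                f"hotspot {h} outside map range [{lo},{hi}] of chromosome "
                f"{h.chromosome}"
            )
        by_chrom.setdefault(h.chromosome, []).append(h)
    for c, hs in by_chrom.items():
        hs = sorted(hs, key=lambda h: h.start_bp)
        for a, b in zip(hs, hs[1:]):
            if b.start_bp <= a.end_bp:
                raise ValueError(
                    f"overlapping hotspots on chromosome {c}: {a} / {b} "
                    "(ground truth would be ambiguous)"
                )
    return spots


def _place_private_segments(
    rng: np.random.Generator,
    snp_map: SnpMap,
    sample_id: str,
    rate_per_chromosome: float,
    mean_len_bp: float,
) -> list[PlantedSegment]:
    segs = []
    for c in snp_map.chromosomes:
        lo, hi = snp_map.chrom_range(int(c))
        n_seg = rng.poisson(rate_per_chromosome)
        for _ in range(n_seg):
            start = int(rng.integers(lo, hi + 1))
            length = max(1, int(rng.exponential(mean_len_bp)))
            end = min(hi, start + length - 1)
            segs.append(PlantedSegment(sample_id, int(c), start, end))
    return segs


def generate_cohort(
    snp_map: SnpMap,
    n_samples: int,
    het_rate: float = 0.3,
    error_rate: float = 0.02,
    nocall_rate: float = 0.005,
    hotspots: Sequence[Hotspot] = (),
    private_roh_rate: float = 0.0,
    private_roh_mean_len_bp: float = 2_000_000.0,
    seed: int = 0,
    sample_prefix: str = "S",
    hotspot_extension_mean_bp: float = 0.0,
) -> tuple[GenotypeMatrix, CohortTruth]:
    """Simulate a genotype cohort with planted ROH segments.

    Outside planted segments each locus is HET with probability `het_rate`;
    inside a planted segment HET appears only at `error_rate` (genotyping
    error).  NoCall is overlaid independently of ROH state at `nocall_rate`.
    Each sample carries each hotspot independently with that hotspot's
    frequency; carriers receive a planted segment covering the hotspot
    interval, extended on each side by an independent exponential draw of
    mean `hotspot_extension_mean_bp` (0 = exact interval).  The extension
    models population-shared homozygous cores whose individual runs reach
    variably beyond the core, the way severe cohorts show extensions of the
    runs present in mild cohorts.  Private segments are placed per sample at
    a Poisson rate of `private_roh_rate` per chromosome with exponential
    lengths of mean `private_roh_mean_len_bp`.  Homozygote class (HOM_A vs
    HOM_B) is assigned per locus by a random allele-frequency draw.

    Every planted segment recorded in the returned CohortTruth covers at
    least one locus and carries at least one homozygous call.
    """
    for name, r in [
        ("het_rate", het_rate),
        ("error_rate", error_rate),
        ("nocall_rate", nocall_rate),
    ]:
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [0,1]")
    if private_roh_rate < 0:
        raise ValueError("private_roh_rate must be >= 0")
    spots = _validate_hotspots(snp_map, hotspots)

    rng = np.random.default_rng(seed)
    sample_ids = [f"{sample_prefix}{i:03d}" for i in range(n_samples)]
    n_loci = len(snp_map)

    segments: list[PlantedSegment] = []
    carriers: dict[int, list[str]] = {i: [] for i in range(len(spots))}
    for sid in sample_ids:
        for k, h in enumerate(spots):
            if rng.random() < h.frequency:
                carriers[k].append(sid)
                lo, hi = snp_map.chrom_range(h.chromosome)
                ext_l = ext_r = 0
                if hotspot_extension_mean_bp > 0:
                    ext_l = int(rng.exponential(hotspot_extension_mean_bp))
                    ext_r = int(rng.exponential(hotspot_extension_mean_bp))
                segments.append(
                    PlantedSegment(
                        sid, h.chromosome,
                        max(lo, h.start_bp - ext_l),
                        min(hi, h.end_bp + ext_r),
                    )
                )
        if private_roh_rate > 0:
            segments.extend(
                _place_private_segments(
                    rng, snp_map, sid, private_roh_rate, private_roh_mean_len_bp
                )
            )
    # Truth keeps only segments that cover >= 1 mapped locus.
    segments = [
        s
        for s in segments
        if len(snp_map.locus_indices(s.chromosome, s.start_bp, s.end_bp)) > 0
    ]

    sample_index = {s: i for i, s in enumerate(sample_ids)}
    state = np.zeros((n_samples, n_loci), dtype=bool)
    for seg in segments:
        loci = snp_map.locus_indices(seg.chromosome, seg.start_bp, seg.end_bp)
        state[sample_index[seg.sample_id], loci] = True

    het_prob = np.where(state, error_rate, het_rate)
    is_het = rng.random((n_samples, n_loci)) < het_prob
    # Per-locus allele frequency decides HOM_A vs HOM_B among homozygotes.
    allele_freq = rng.uniform(0.05, 0.95, size=n_loci)
    is_hom_a = rng.random((n_samples, n_loci)) < allele_freq[None, :]
    calls = np.where(is_het, HET, np.where(is_hom_a, HOM_A, HOM_B)).astype(np.int8)
    calls[rng.random((n_samples, n_loci)) < nocall_rate] = NOCALL

    # Guarantee every truth segment carries >= 1 homozygous call: if the
    # error/NoCall overlay wiped a (tiny) segment clean, pin its middle locus.
    hom_mask = (calls == HOM_A) | (calls == HOM_B)
    for seg in segments:
        loci = snp_map.locus_indices(seg.chromosome, seg.start_bp, seg.end_bp)
        row = sample_index[seg.sample_id]
        if not hom_mask[row, loci].any():
            mid = loci[len(loci) // 2]
            calls[row, mid] = HOM_A
            hom_mask[row, mid] = True

    genotypes = GenotypeMatrix(sample_ids, calls, snp_map)
    truth = CohortTruth(
        planted_segments=segments,
        hotspots=spots,
        generator_params={
            "n_samples": n_samples,
            "het_rate": het_rate,
            "error_rate": error_rate,
            "nocall_rate": nocall_rate,
            "private_roh_rate": private_roh_rate,
            "private_roh_mean_len_bp": private_roh_mean_len_bp,
            "hotspot_extension_mean_bp": hotspot_extension_mean_bp,
            "sample_prefix": sample_prefix,
        },
        seed=seed,
        hotspot_carriers=carriers,
    )
    return genotypes, truth


def generate_copy_number(
    snp_map: SnpMap,
    sample_ids: Sequence[str],
    hemi_del_segment_rate: float = 0.5,
    mean_len_bp: float = 2_000_000.0,
    seed: int = 0,
) -> CopyNumberMatrix:
    """Integer copy-number matrix: background cn=2 with planted cn=1 segments.

    `hemi_del_segment_rate` is the Poisson rate of hemizygous-deletion
    segments per sample per chromosome; lengths are exponential with mean
    `mean_len_bp`.
    """
    if hemi_del_segment_rate < 0 or mean_len_bp <= 0:
        raise ValueError("rates must be non-negative, mean length positive")
    rng = np.random.default_rng(seed)
    cn = np.full((len(sample_ids), len(snp_map)), 2, dtype=np.int64)
    for i, _sid in enumerate(sample_ids):
        for c in snp_map.chromosomes:
            lo, hi = snp_map.chrom_range(int(c))
            for _ in range(rng.poisson(hemi_del_segment_rate)):
                start = int(rng.integers(lo, hi + 1))
                length = max(1, int(rng.exponential(mean_len_bp)))
                loci = snp_map.locus_indices(int(c), start, min(hi, start + length - 1))
                cn[i, loci] = 1
    return CopyNumberMatrix(list(sample_ids), cn, snp_map)


class AnnotationSet:
    """Toy annotation fixtures: gene table, fragile-site records, miRNA points.

    `fra_truth` maps each fragile-site name to its ground-truth genomic
    region (chromosome, start, end) computed from the planted gene spans,
    for oracle tests of the cytoband-to-genomic mapping.
    """

    def __init__(
        self,
        gene_table: pd.DataFrame,
        fra_records: pd.DataFrame,
        mirna: pd.DataFrame,
        fra_truth: dict[str, tuple[int, int, int]],
    ) -> None:
        self.gene_table = gene_table
        self.fra_records = fra_records
        self.mirna = mirna
        self.fra_truth = fra_truth


def generate_annotations(
    snp_map: SnpMap,
    n_fras: int,
    genes_per_band: int = 3,
    n_mirna: int = 50,
    seed: int = 0,
) -> AnnotationSet:
    """Generate a consistent gene table, fragile-site cytoband records and
    miRNA point annotations over the map's chromosomes.

    Each fragile site gets its own cytogenetic band with `genes_per_band`
    genes whose spans overlap; the ground-truth mapped region is the
    (min start, max end) envelope of those spans.
    """
    if n_fras < 1 or genes_per_band < 1 or n_mirna < 0:
        raise ValueError("counts must be positive")
    rng = np.random.default_rng(seed)
    chroms = snp_map.chromosomes
    genes, fras, truth = [], [], {}
    letters = "ABCDEFGHJK"
    for k in range(n_fras):
        c = int(chroms[k % len(chroms)])
        lo, hi = snp_map.chrom_range(c)
        arm = "p" if rng.random() < 0.5 else "q"
        band = f"{c}{arm}{21 + k // len(chroms)}"
        name = f"FRA{c}{letters[k // len(chroms) % len(letters)]}"
        center = int(rng.integers(lo, hi + 1))
        starts, ends = [], []
        for g in range(genes_per_band):
            g_start = max(lo, center + int(rng.integers(-2_000_000, 2_000_000)))
            g_len = int(rng.integers(20_000, 1_500_000))
            g_end = min(hi, g_start + g_len)
            g_start = min(g_start, g_end)
            genes.append(
                {
                    "symbol": f"GENE_{name}_{g}",
                    "band": band,
                    "chromosome": c,
                    "start_bp": g_start,
                    "end_bp": g_end,
                }
            )
            starts.append(g_start)
            ends.append(g_end)
        fras.append(
            {"name": name, "band": band, "rare_flag": bool(rng.random() < 0.25)}
        )
        truth[name] = (c, min(starts), max(ends))
    mirna = []
    for m in range(n_mirna):
        c = int(rng.choice(chroms))
        lo, hi = snp_map.chrom_range(c)
        mirna.append(
            {
                "name": f"mir-{m}",
                "chromosome": c,
                "position_bp": int(rng.integers(lo, hi + 1)),
            }
        )
    return AnnotationSet(
        gene_table=pd.DataFrame(genes),
        fra_records=pd.DataFrame(fras),
        mirna=pd.DataFrame(mirna, columns=["name", "chromosome", "position_bp"]),
        fra_truth=truth,
    )
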