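"""Core in-memory containers: SNP map, genotype/copy-number matrices, truth.

Coordinates are 1-based inclusive base pairs throughout the core; BED output
converts to 0-based half-open at the writer boundary only.  Autosomes only
(chromosomes 1-22): sex chromosomes are excluded from this kind of
homozygosity analysis because hemizygous male X calls masquerade as ROH.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, NamedTuple

import numpy as np
import pandas as pd

# Genotype call codes.  The analysis never distinguishes the two homozygote
# classes (only HOM vs HET vs NOCALL), but both are carried so that callers
# can be checked for invariance under HOM_A <-> HOM_B relabeling.
HOM_A: int = 0
HET: int = 1
HOM_B: int = 2
NOCALL: int = 3

CALL_LABELS = {HOM_A: "AA", HET: "AB", HOM_B: "BB", NOCALL: "NC"}
LABEL_CALLS = {v: k for k, v in CALL_LABELS.items()}


@dataclass(frozen=True)
class SnpMap:
    """Genome-ordered SNP coordinate system.

    Records are sorted by (chromosome, position_bp); positions are strictly
    increasing within a chromosome and snp_ids are unique.
    """

    snp_id: np.ndarray        # object/str, shape (n_loci,)
    chromosome: np.ndarray    # int, values in 1..22
    position_bp: np.ndarray   # int, 1-based

    def __post_init__(self) -> None:
        n = len(self.snp_id)
        if not (len(self.chromosome) == len(self.position_bp) == n):
            raise ValueError("SnpMap field lengths differ")
        if n == 0:
            raise ValueError("empty SnpMap")
        order = np.lexsort((self.position_bp, self.chromosome))
        if not np.array_equal(order, np.arange(n)):
            raise ValueError("SnpMap not sorted by (chromosome, position)")
        for c in np.unique(self.chromosome):
            pos = self.position_bp[self.chromosome == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c}"
                )
        if len(np.unique(self.snp_id)) != n:
            raise ValueError("duplicate snp_id in SnpMap")

    def __len__(self) -> int:
        return len(self.snp_id)

    @property
    def chromosomes(self) -> np.ndarray:
        return np.unique(self.chromosome)

    def chrom_slice(self, chromosome: int) -> slice:
        """Contiguous index slice of one chromosome's loci."""
        lo = int(np.searchsorted(self.chromosome, chromosome, side="left"))
        hi = int(np.searchsorted(self.chromosome, chromosome, side="right"))
        return slice(lo, hi)

    def chrom_range(self, chromosome: int) -> tuple[int, int]:
        """(min, max) position covered by SNPs on a chromosome."""
        s = self.chrom_slice(chromosome)
        if s.start == s.stop:
            raise ValueError(f"no loci on chromosome {chromosome}")
        return int(self.position_bp[s.start]), int(self.position_bp[s.stop - 1])

    def locus_indices(self, chromosome: int, start_bp: int, end_bp: int) -> np.ndarray:
        """Indices of loci on `chromosome` with start_bp <= pos <= end_bp."""
        s = self.chrom_slice(chromosome)
        pos = self.position_bp[s]
        lo = np.searchsorted(pos, start_bp, side="left")
        hi = np.searchsorted(pos, end_bp, side="right")
        return np.arange(s.start + lo, s.start + hi)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_id,
                "chromosome": self.chromosome,
                "position_bp": self.position_bp,
            }
        )


@dataclass
class GenotypeMatrix:
    """Samples x loci genotype calls aligned to a SnpMap."""

    sample_ids: list[str]
    calls: np.ndarray  # int8, shape (n_samples, n_loci)
    snp_map: SnpMap

    def __post_init__(self) -> None:
        if self.calls.shape != (len(self.sample_ids), len(self.snp_map)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_map)} loci"
            )
        bad = ~np.isin(self.calls, [HOM_A, HET, HOM_B, NOCALL])
        if bad.any():
            raise ValueError("calls contain values outside the genotype alphabet")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.snp_map)

    def nocall_fraction(self) -> np.ndarray:
        """Per-sample fraction of NoCall genotypes."""
        return (self.calls == NOCALL).mean(axis=1)


@dataclass
class CopyNumberMatrix:
    """Samples x loci integer copy-number estimates aligned to a SnpMap.

    cn == 1 entries are the hemizygous-deletion events counted by the
    hemizygous deletion frequency (HDF) track.
    """

    sample_ids: list[str]
    cn: np.ndarray  # int, shape (n_samples, n_loci), >= 0
    snp_map: SnpMap

    def __post_init__(self) -> None:
        if self.cn.shape != (len(self.sample_ids), len(self.snp_map)):
            raise ValueError("cn shape does not match samples x map")
        if (self.cn < 0).any():
            raise ValueError("negative copy number")


class PlantedSegment(NamedTuple):
    sample_id: str
    chromosome: int
    start_bp: int
    end_bp: int


class Hotspot(NamedTuple):
    """A population-shared ROH interval with a cohort carrier frequency."""

    chromosome: int
    start_bp: int
    end_bp: int
    frequency: float


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, for parameter-recovery tests."""

    planted_segments: list[PlantedSegment]
    hotspots: list[Hotspot]
    generator_params: dict[str, Any]
    seed: int
    hotspot_carriers: dict[int, list[str]] = field(default_factory=dict)

    def state_matrix(self, snp_map: SnpMap, sample_ids: list[str]) -> np.ndarray:
        """Boolean samples x loci matrix: True where a planted segment covers."""
        idx = {s: i for i, s in enumerate(sample_ids)}
        out = np.zeros((len(sample_ids), len(snp_map)), dtype=bool)
        for seg in self.planted_segments:
            loci = snp_map.locus_indices(seg.chromosome, seg.start_bp, seg.end_bp)
            out[idx[seg.sample_id], loci] = True
        return out

    def segments_min_size(
        self, snp_map: SnpMap, min_snps: int = 1, min_length_bp: int = 1
    ) -> list[PlantedSegment]:
        """Planted segments spanning at least `min_snps` loci and `min_length_bp`."""
        keep = []
        for seg in self.planted_segments:
            n = len(snp_map.locus_indices(seg.chromosome, seg.start_bp, seg.end_bp))
            if n >= min_snps and (seg.end_bp - seg.start_bp + 1) >= min_length_bp:
                keep.append(seg)
        return keep
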