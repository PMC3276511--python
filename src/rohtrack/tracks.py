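"""Per-locus frequency tracks (ROHF, HDF) and regional summaries.

ROHF (ROH frequency) at a locus is the fraction of cohort samples whose
called ROH segments cover that locus; HDF (hemizygous deletion frequency)
is the fraction of samples with integer copy number exactly 1.  The regional
summary around an anchor (e.g. a fragile site) is the mean of the track
values at or above the upper 95th percentile within a +/- radius window,
which suppresses background noise relative to a plain regional mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .types import CopyNumberMatrix, SnpMap

__all__ = [
    "FrequencyTrack",
    "RegionalSummary",
    "compute_rohf",
    "compute_hdf",
    "regional_upper_percentile",
    "fold_change",
]


@dataclass
class FrequencyTrack:
    """Per-locus fraction in [0,1] aligned to a SnpMap."""

    values: np.ndarray
    kind: str  # "rohf" or "hdf"
    cohort: str
    n_samples: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("track values must be 1-D")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("track values outside [0,1]")


@dataclass(frozen=True)
class RegionalSummary:
    """Mean of the retained upper tail of a track in a +/- radius window."""

    anchor_bp: int
    chromosome: int
    radius_bp: int
    percentile: float
    value: float
    n_loci: int


def compute_rohf(
    state_matrix: np.ndarray, cohort: str = "", kind: str = "rohf"
) -> FrequencyTrack:
    """ROHF track from a boolean samples x loci ROH-state matrix.

    Every sample counts in the denominator at every locus (NoCall samples
    included): the frequency is defined over samples, not called genotypes.
    """
    state_matrix = np.asarray(state_matrix)
    if state_matrix.ndim != 2 or state_matrix.shape[0] == 0:
        raise ValueError("state matrix must be 2-D with >= 1 sample")
    return FrequencyTrack(
        values=state_matrix.mean(axis=0),
        kind=kind,
        cohort=cohort,
        n_samples=state_matrix.shape[0],
    )


def compute_hdf(copy_number: CopyNumberMatrix, cohort: str = "") -> FrequencyTrack:
    """HDF track: per-locus fraction of samples with copy number exactly 1."""
    return FrequencyTrack(
        values=(copy_number.cn == 1).mean(axis=0),
        kind="hdf",
        cohort=cohort,
        n_samples=len(copy_number.sample_ids),
    )


def regional_upper_percentile(
    track: FrequencyTrack,
    snp_map: SnpMap,
    anchor_bp: int,
    chromosome: int,
    radius_bp: int = 5_000_000,
    percentile: float = 95.0,
) -> RegionalSummary:
    """Mean of track values >= the percentile cutoff in [anchor-r, anchor+r].

    The window is closed on both ends; the percentile uses linear
    interpolation between order statistics, and values equal to the cutoff
    are retained.  percentile=0 degenerates to the plain window mean.
    """
    if radius_bp <= 0:
        raise ValueError("radius_bp must be > 0")
    loci = snp_map.locus_indices(chromosome, anchor_bp - radius_bp, anchor_bp + radius_bp)
    if len(loci) == 0:
        raise ValueError(
            f"no loci within {radius_bp} bp of {anchor_bp} on chromosome {chromosome}"
        )
    vals = track.values[loci]
    cutoff = np.percentile(vals, percentile)
    tail = vals[vals >= cutoff]
    return RegionalSummary(
        anchor_bp=int(anchor_bp),
        chromosome=int(chromosome),
        radius_bp=int(radius_bp),
        percentile=float(percentile),
        value=float(tail.mean()),
        n_loci=len(loci),
    )


def fold_change(numerator: float, denominator: float, round_digits: int = 0) -> float:
    """numerator/denominator rounded half-up to `round_digits` decimals.

    round_digits=0 returns the nearest integer (half away from zero), the
    convention used when quoting cohort-level fold changes like "11 fold".
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    q = Decimal(1).scaleb(-round_digits)
    ratio = float(numerator) / float(denominator)
    rounded = Decimal(repr(ratio)).quantize(q, rounding=ROUND_HALF_UP)
    return float(rounded)
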