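"""Fragile-site mapping and proximity statistics.

Fragile sites (FRAs) are catalogued by cytogenetic band only; a gene table
carrying both band labels and genomic coordinates converts them to base-pair
regions: the mapped region is the (minimum start, maximum end) envelope of
the genes whose band label matches exactly, and the site's anchor point is
the region midpoint.  Proximity statistics (miRNA counts, ROHF summaries)
are measured from feature points to FRA anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracks import FrequencyTrack, regional_upper_percentile
from .types import SnpMap

__all__ = [
    "FragileSite",
    "FeaturePoint",
    "map_fra_to_genomic",
    "count_within",
    "proximity_ratio_round",
    "fra_rohf_table",
    "high_rohf_bands_without_fra",
]


@dataclass(frozen=True)
class FragileSite:
    """A named fragile site with its mapped genomic region and anchor."""

    name: str
    cyto_band: str
    chromosome: int
    region_start_bp: int
    region_end_bp: int
    anchor_bp: int
    rare_flag: bool = False

    def __post_init__(self) -> None:
        if not self.region_start_bp <= self.anchor_bp <= self.region_end_bp:
            raise ValueError(f"{self.name}: anchor outside region")


@dataclass(frozen=True)
class FeaturePoint:
    """A point annotation (e.g. one miRNA gene)."""

    name: str
    chromosome: int
    position_bp: int

    def __post_init__(self) -> None:
        if self.position_bp < 1:
            raise ValueError("position_bp must be >= 1")


def _band_chromosome(band: str) -> int:
    """Chromosome number prefix of a cytogenetic band label like '7q31.2'."""
    digits = ""
    for ch in band:
        if ch.isdigit():
            digits += ch
        else:
            break
    if not digits:
        raise ValueError(f"band label {band!r} has no chromosome prefix")
    return int(digits)


def map_fra_to_genomic(
    fra_records: pd.DataFrame,
    gene_table: pd.DataFrame,
) -> tuple[list[FragileSite], list[str]]:
    """Map fragile sites from cytogenetic bands to genomic regions.

    ``fra_records`` needs columns (name, band, rare_flag); ``gene_table``
    needs (symbol, band, chromosome, start_bp, end_bp).  Band matching is
    exact string equality ("9p21" does not match "9p21.3").  Returns the
    mapped sites plus the names of sites whose band has no matching gene
    (reported, not silently dropped).
    """
    sites: list[FragileSite] = []
    unmapped: list[str] = []
    by_band = dict(tuple(gene_table.groupby("band", sort=False)))
    for rec in fra_records.itertuples(index=False):
        genes = by_band.get(rec.band)
        if genes is None or len(genes) == 0:
            unmapped.append(rec.name)
            continue
        chroms = genes["chromosome"].unique()
        band_chrom = _band_chromosome(rec.band)
        if len(chroms) != 1 or int(chroms[0]) != band_chrom:
            raise ValueError(
                f"inconsistent gene table: band {rec.band} genes on "
                f"chromosome(s) {sorted(int(c) for c in chroms)}, "
                f"band prefix says {band_chrom}"
            )
        start = int(genes["start_bp"].min())
        end = int(genes["end_bp"].max())
        sites.append(
            FragileSite(
                name=rec.name,
                cyto_band=rec.band,
                chromosome=band_chrom,
                region_start_bp=start,
                region_end_bp=end,
                anchor_bp=(start + end) // 2,
                rare_flag=bool(getattr(rec, "rare_flag", False)),
            )
        )
    return sites, unmapped


def proximity_ratio_round(count: int, total: int) -> float:
    """Proximity ratio with mixed precision: 3 decimals below 0.1, else 2."""
    if total <= 0:
        raise ValueError("total must be > 0")
    r = count / total
    return round(r, 3) if r < 0.1 else round(r, 2)


def count_within(
    features: list[FeaturePoint] | pd.DataFrame,
    sites: list[FragileSite],
    radius_bp: int,
) -> tuple[int, float]:
    """Number (and ratio) of features within `radius_bp` of any site anchor.

    Each feature is counted once even if near several sites; distance is
    point-to-anchor on the same chromosome, bounds inclusive.
    """
    if radius_bp <= 0:
        raise ValueError("radius_bp must be > 0")
    feats = _as_feature_list(features)
    anchors: dict[int, np.ndarray] = {}
    for s in sites:
        anchors.setdefault(s.chromosome, [])
    for s in sites:
        anchors[s.chromosome].append(s.anchor_bp)  # type: ignore[attr-defined]
    anchors = {c: np.sort(np.asarray(a)) for c, a in anchors.items()}
    count = 0
    for f in feats:
        a = anchors.get(f.chromosome)
        if a is None or len(a) == 0:
            continue
        i = np.searchsorted(a, f.position_bp)
        near = min(
            abs(f.position_bp - a[j]) for j in (max(i - 1, 0), min(i, len(a) - 1))
        )
        if near <= radius_bp:
            count += 1
    return count, proximity_ratio_round(count, len(feats))


def _as_feature_list(features: list[FeaturePoint] | pd.DataFrame) -> list[FeaturePoint]:
    if isinstance(features, pd.DataFrame):
        return [
            FeaturePoint(str(r.name), int(r.chromosome), int(r.position_bp))
            for r in features.itertuples(index=False)
        ]
    return list(features)


def fra_rohf_table(
    fras: list[FragileSite],
    track_a: FrequencyTrack,
    track_b: FrequencyTrack,
    snp_map: SnpMap,
    radius_bp: int = 5_000_000,
    percentile: float = 95.0,
    features: list[FeaturePoint] | pd.DataFrame | None = None,
    feature_radii_bp: tuple[int, int] = (5_000_000, 1_000_000),
) -> pd.DataFrame:
    """Per-fragile-site regional ROHF summary table.

    One row per site: the upper-percentile regional summary of each track
    around the anchor, their difference, and the number of features (miRNAs)
    within each radius of the anchor.  Sites whose window contains no locus
    get NaN summaries rather than an error, so a genome-wide table is robust
    to sparse maps.
    """
    feats = _as_feature_list(features) if features is not None else []
    rows = []
    for s in fras:
        try:
            a = regional_upper_percentile(
                track_a, snp_map, s.anchor_bp, s.chromosome, radius_bp, percentile
            ).value
            b = regional_upper_percentile(
                track_b, snp_map, s.anchor_bp, s.chromosome, radius_bp, percentile
            ).value
        except ValueError:
            a = b = float("nan")
        counts = []
        for r in feature_radii_bp:
            counts.append(
                sum(
                    1
                    for f in feats
                    if f.chromosome == s.chromosome
                    and abs(f.position_bp - s.anchor_bp) <= r
                )
            )
        rows.append(
            {
                "name": s.name,
                "chromosome": s.chromosome,
                "band": s.cyto_band,
                "rohf_a": a,
                "rohf_b": b,
                "rohf_diff": a - b,
                **{
                    f"n_features_{r // 1_000_000}mb": c
                    for r, c in zip(feature_radii_bp, counts)
                },
            }
        )
    return pd.DataFrame(rows)


def high_rohf_bands_without_fra(
    track: FrequencyTrack,
    snp_map: SnpMap,
    fras: list[FragileSite],
    radius_bp: int = 5_000_000,
    threshold: float = 0.6,
    percentile: float = 95.0,
) -> list[dict]:
    """Maximal bands of loci with high regional ROHF but no fragile site nearby.

    A locus qualifies when the upper-percentile regional summary centered on
    it is >= threshold and no FRA anchor lies within `radius_bp`.  Each
    maximal run of qualifying loci is reported with its peak: the locus of
    maximum raw track value, taking the middle locus when several tie.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0,1)")
    anchors: dict[int, np.ndarray] = {}
    for s in fras:
        anchors.setdefault(s.chromosome, []).append(s.anchor_bp)
    anchors = {c: np.sort(np.asarray(a)) for c, a in anchors.items()}
    bands = []
    for c in snp_map.chromosomes:
        sl = snp_map.chrom_slice(int(c))
        pos = snp_map.position_bp[sl]
        vals = track.values[sl]
        # Per-locus regional summary via a sliding closed window.
        lo = np.searchsorted(pos, pos - radius_bp, side="left")
        hi = np.searchsorted(pos, pos + radius_bp, side="right")
        summary = np.empty(len(pos))
        for i in range(len(pos)):
            w = vals[lo[i]:hi[i]]
            cutoff = np.percentile(w, percentile)
            summary[i] = w[w >= cutoff].mean()
        a = anchors.get(int(c), np.array([]))
        if len(a):
            j = np.searchsorted(a, pos)
            left = np.abs(pos - a[np.clip(j - 1, 0, len(a) - 1)])
            right = np.abs(pos - a[np.clip(j, 0, len(a) - 1)])
            fra_free = np.minimum(left, right) > radius_bp
        else:
            fra_free = np.ones(len(pos), dtype=bool)
        qual = (summary >= threshold) & fra_free
        if not qual.any():
            continue
        padded = np.concatenate([[False], qual, [False]])
        d = np.diff(padded.astype(np.int8))
        for s0, s1 in zip(np.nonzero(d == 1)[0], np.nonzero(d == -1)[0] - 1):
            band_vals = vals[s0:s1 + 1]
            tied = np.nonzero(band_vals == band_vals.max())[0]
            peak = s0 + tied[(len(tied) - 1) // 2]
            bands.append(
                {
                    "chromosome": int(c),
                    "peak_position_bp": int(pos[peak]),
                    "band_start_bp": int(pos[s0]),
                    "band_end_bp": int(pos[s1]),
                    "summary": float(summary[peak]),
                }
            )
    return bands
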