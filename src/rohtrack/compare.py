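"""Cohort-comparison statistics over per-locus frequency tracks.

Implements covariate-adjusted (partial) correlation between two cohorts'
ROHF tracks, point-biserial correlation between ROHF and fragile-site
proximity, a stepwise-cutoff correlation series, top-difference SNP
selection, and the adult-vs-young subsample-resampling test: the larger
cohort is repeatedly shrunk to the smaller cohort's size by sampling
without replacement, each subsample's ROHF track is compared to the
reference track with a per-dataset t-test across loci under a Bonferroni
threshold, and power is summarized by the proportion of significant
datasets whose mean ROHF difference is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .annotation import FragileSite
from .tracks import FrequencyTrack
from .types import SnpMap

__all__ = [
    "AdjustedCorrelation",
    "ResamplingResult",
    "TopDiffResult",
    "local_snp_density",
    "adjusted_correlation",
    "fra_proximity_correlation",
    "stepwise_cutoff_correlation",
    "adult_young_resampling",
    "top_diff_snps",
]


@dataclass(frozen=True)
class AdjustedCorrelation:
    """Correlation after residualizing both tracks on shared covariates.

    ``undefined`` is True when either residual vector is (numerically)
    constant, in which case r and the p-values are NaN — flagged, never
    silently propagated.
    """

    r: float
    p_raw: float
    p_bonferroni: float
    covariates_used: tuple[str, ...]
    n_loci: int
    undefined: bool = False


def local_snp_density(snp_map: SnpMap, window_bp: int = 1_000_000) -> np.ndarray:
    """Per-locus SNP density covariate: SNPs/Mb in a centered window.

    The value at a locus is the number of map SNPs within +/- window_bp/2 on
    the same chromosome (the locus itself included), divided by the window
    width in Mb.  Returned as a raw map-aligned array: it is a density, not
    a frequency, so the FrequencyTrack [0,1] bound does not apply.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    half = window_bp / 2.0
    out = np.empty(len(snp_map))
    for c in snp_map.chromosomes:
        sl = snp_map.chrom_slice(int(c))
        pos = snp_map.position_bp[sl]
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        out[sl] = (hi - lo) / (window_bp / 1e6)
    return out


def _residualize(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ coef


def adjusted_correlation(
    track_a: np.ndarray | FrequencyTrack,
    track_b: np.ndarray | FrequencyTrack,
    covariates: dict[str, np.ndarray] | None = None,
    alpha_adjust_n: int = 1,
) -> AdjustedCorrelation:
    """Pearson correlation of the two tracks after covariate adjustment.

    Both tracks are residualized on the covariates (least squares with an
    intercept); r is the Pearson correlation of the residuals, the p-value
    comes from the t-distribution with n - k - 2 degrees of freedom (k
    covariates), and p_bonferroni = min(1, p_raw * alpha_adjust_n).  With no
    covariates this is exactly the plain Pearson correlation.
    """
    a = np.asarray(track_a.values if isinstance(track_a, FrequencyTrack) else track_a, float)
    b = np.asarray(track_b.values if isinstance(track_b, FrequencyTrack) else track_b, float)
    covariates = covariates or {}
    n = len(a)
    k = len(covariates)
    if len(b) != n or any(len(v) != n for v in covariates.values()):
        raise ValueError("tracks and covariates must be locus-aligned")
    if n < k + 3:
        raise ValueError("need at least 3 more loci than covariates")
    names = tuple(covariates.keys())
    design = np.column_stack([np.ones(n)] + [np.asarray(covariates[c], float) for c in names])
    ra = _residualize(a, design)
    rb = _residualize(b, design)
    tol = 1e-12 * max(1.0, float(np.abs(a).max()), float(np.abs(b).max()))
    if ra.std() <= tol or rb.std() <= tol:
        return AdjustedCorrelation(
            r=float("nan"), p_raw=float("nan"), p_bonferroni=float("nan"),
            covariates_used=names, n_loci=n, undefined=True,
        )
    r = float(np.corrcoef(ra, rb)[0, 1])
    df = n - k - 2
    r_clip = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return AdjustedCorrelation(
        r=r, p_raw=p, p_bonferroni=min(1.0, p * alpha_adjust_n),
        covariates_used=names, n_loci=n,
    )


def fra_proximity_correlation(
    track: FrequencyTrack,
    snp_map: SnpMap,
    fras: list[FragileSite],
    radius_bp: int = 5_000_000,
) -> dict[str, AdjustedCorrelation]:
    """Point-biserial correlation between a track and fragile-site proximity.

    A per-locus 0/1 indicator marks loci within `radius_bp` of any FRA
    anchor; Pearson correlation with the track is computed per chromosome
    and genome-wide (key "all").  Chromosomes with a constant indicator
    (e.g. no FRA at all) come back flagged undefined, mirroring an "NA"
    entry in a per-chromosome table.
    """
    indicator = np.zeros(len(snp_map))
    for s in fras:
        loci = snp_map.locus_indices(
            s.chromosome, s.anchor_bp - radius_bp, s.anchor_bp + radius_bp
        )
        indicator[loci] = 1.0
    out: dict[str, AdjustedCorrelation] = {}
    for c in snp_map.chromosomes:
        sl = snp_map.chrom_slice(int(c))
        out[str(int(c))] = adjusted_correlation(track.values[sl], indicator[sl])
    out["all"] = adjusted_correlation(track.values, indicator)
    return out


def stepwise_cutoff_correlation(
    track_a: FrequencyTrack | np.ndarray,
    track_b: FrequencyTrack | np.ndarray,
    quantiles: list[float],
) -> list[tuple[float, int, float]]:
    """Correlation of the tracks restricted to loci above rising track_b cutoffs.

    For each quantile q the loci where track_b exceeds its q-quantile are
    retained and the Pearson r of the two tracks on that subset is computed.
    Returns (quantile, n_loci_retained, r) triples; r is NaN when the subset
    is degenerate.
    """
    a = np.asarray(track_a.values if isinstance(track_a, FrequencyTrack) else track_a, float)
    b = np.asarray(track_b.values if isinstance(track_b, FrequencyTrack) else track_b, float)
    if list(quantiles) != sorted(quantiles) or len(set(quantiles)) != len(quantiles):
        raise ValueError("quantiles must be strictly increasing")
    if any(not 0.0 <= q < 1.0 for q in quantiles):
        raise ValueError("quantiles must lie in [0,1)")
    out = []
    for q in quantiles:
        thr = np.quantile(b, q) if q > 0 else -np.inf
        mask = b > thr
        n = int(mask.sum())
        if n < 3 or a[mask].std() == 0 or b[mask].std() == 0:
            out.append((q, n, float("nan")))
            continue
        out.append((q, n, float(np.corrcoef(a[mask], b[mask])[0, 1])))
    return out


@dataclass
class ResamplingResult:
    """Summary of the subsample-resampling cohort comparison."""

    n_iter: int
    subsample_size: int
    n_positive: int
    n_significant: int
    n_significant_positive: int
    proportion: float | None  # None when no dataset is significant
    mean_adult_track: np.ndarray = field(repr=False)
    seed: int = 0
    alpha: float = 0.05
    n_tests: int = 1
    paired: bool = True

    def __post_init__(self) -> None:
        if not (
            self.n_significant_positive <= self.n_significant <= self.n_iter
            and self.n_positive <= self.n_iter
        ):
            raise ValueError("inconsistent resampling counts")


def adult_young_resampling(
    adult_states: np.ndarray,
    young_states: np.ndarray,
    n_iter: int = 1000,
    subsample_size: int = 30,
    alpha: float = 0.05,
    n_tests: int | None = None,
    paired: bool = True,
    seed: int = 0,
) -> ResamplingResult:
    """Non-redundant subsample-resampling comparison of two cohorts' ROHF.

    Repeats `n_iter` times: draw `subsample_size` adults without replacement
    (subsets are kept distinct across iterations), compute the subsample's
    ROHF track, and form the difference track against the young cohort's
    ROHF.  The sign of the mean difference feeds n_positive; a per-dataset
    t-test across loci against zero mean difference (paired by locus when
    `paired`, otherwise two-sample) is significant when p < alpha/n_tests
    (n_tests defaults to the locus count).  The proportion reported is
    n_significant_positive / n_significant; with zero significant datasets
    it is None, flagged rather than NaN-silent.
    """
    adult_states = np.asarray(adult_states, dtype=float)
    young_states = np.asarray(young_states, dtype=float)
    n_adults, n_loci = adult_states.shape
    if young_states.shape[1] != n_loci:
        raise ValueError("cohort matrices are not locus-aligned")
    if subsample_size > n_adults:
        raise ValueError(
            f"subsample_size {subsample_size} exceeds adult count {n_adults}"
        )
    if n_tests is None:
        n_tests = n_loci
    rng = np.random.default_rng(seed)
    young_rohf = young_states.mean(axis=0)
    threshold = alpha / n_tests

    seen: set[tuple[int, ...]] = set()
    n_positive = n_significant = n_significant_positive = 0
    mean_adult = np.zeros(n_loci)
    full_subsample = subsample_size == n_adults
    for _ in range(n_iter):
        while True:
            idx = np.sort(rng.choice(n_adults, size=subsample_size, replace=False))
            key = tuple(idx.tolist())
            if full_subsample or key not in seen:
                seen.add(key)
                break
        sub_rohf = adult_states[idx].mean(axis=0)
        mean_adult += sub_rohf
        diff = sub_rohf - young_rohf
        mean_diff = diff.mean()
        positive = mean_diff > 0
        n_positive += positive
        if paired:
            res = stats.ttest_rel(sub_rohf, young_rohf)
        else:
            res = stats.ttest_ind(sub_rohf, young_rohf)
        p = float(res.pvalue)
        if np.isfinite(p) and p < threshold:
            n_significant += 1
            n_significant_positive += positive
    return ResamplingResult(
        n_iter=n_iter,
        subsample_size=subsample_size,
        n_positive=int(n_positive),
        n_significant=int(n_significant),
        n_significant_positive=int(n_significant_positive),
        proportion=(
            n_significant_positive / n_significant if n_significant else None
        ),
        mean_adult_track=mean_adult / n_iter,
        seed=seed,
        alpha=alpha,
        n_tests=n_tests,
        paired=paired,
    )


@dataclass(frozen=True)
class TopDiffResult:
    """Top-N loci by track difference, with the cutoff at rank N."""

    indices: np.ndarray
    cutoff_value: float
    n_ties_at_cutoff: int


def top_diff_snps(
    track_a: FrequencyTrack | np.ndarray,
    track_b: FrequencyTrack | np.ndarray,
    top_n: int,
) -> TopDiffResult:
    """Select the `top_n` loci with the largest track_a - track_b difference.

    Ranking is by difference descending; ties are broken by map order
    (chromosome, position), i.e. by locus index.  The cutoff is the
    difference value at rank `top_n`; the count of loci exactly at the
    cutoff (selected or not) is reported alongside.
    """
    a = np.asarray(track_a.values if isinstance(track_a, FrequencyTrack) else track_a, float)
    b = np.asarray(track_b.values if isinstance(track_b, FrequencyTrack) else track_b, float)
    d = a - b
    if not 1 <= top_n <= len(d):
        raise ValueError("top_n must be in 1..n_loci")
    order = np.argsort(-d, kind="stable")  # stable: ties keep map order
    selected = order[:top_n]
    cutoff = float(d[selected[-1]])
    return TopDiffResult(
        indices=np.sort(selected),
        cutoff_value=cutoff,
        n_ties_at_cutoff=int(np.sum(d == cutoff)),
    )
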