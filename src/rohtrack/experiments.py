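"""Desk-scale simulation experiments exercising the full pipeline.

These functions define the package's reference study conditions: a
genome-like synthetic cohort (10 chromosomes x 2,000 loci at ~30 kb spacing,
200 samples) for caller recovery, and a thinned genome-wide map (2,000 loci
at ~1.3 Mb spacing) for the resampling experiments, where ROH segments span
few loci and per-locus noise dominates.  Every function takes a single seed
and returns plain dictionaries of measured quantities; nothing is cached.
"""

from __future__ import annotations

import numpy as np

from .calling import HmmParams, WindowParams, call_roh_hmm, call_roh_window, segments_to_locus_state
from .compare import adult_young_resampling, stepwise_cutoff_correlation
from .simulate import generate_cohort, generate_snp_map
from .tracks import compute_rohf
from .types import CohortTruth, Hotspot

__all__ = [
    "recovery_experiment",
    "resampling_null_experiment",
    "resampling_power_experiment",
    "stepwise_experiment",
    "RECOVERY_HMM_PARAMS",
    "RECOVERY_WINDOW_PARAMS",
]

# Caller parameters for the synthetic recovery map (~30 kb SNP spacing).
# The HMM emission rates match the generator's data model; the window scan
# is scaled so that 50-SNP (1.5 Mb) segments are callable at this density.
RECOVERY_HMM_PARAMS = HmmParams(het_rate=0.30, error_rate=0.01)
RECOVERY_WINDOW_PARAMS = WindowParams(
    window_snps=25,
    max_het_per_window=1,
    max_missing_per_window=2,
    min_snps_per_segment=50,
    min_length_kb=1000.0,
)


def recovery_experiment(
    seed: int,
    n_samples: int = 200,
    n_chromosomes: int = 10,
    snps_per_chromosome: int = 2000,
    chromosome_length_bp: int = 60_000_000,
    hotspot_frequency: float = 0.4,
    het_rate: float = 0.3,
    error_rate: float = 0.01,
    nocall_rate: float = 0.01,
) -> dict:
    """Per-locus ROH-calling sensitivity/precision against planted truth.

    One 6 Mb hotspot per chromosome at `hotspot_frequency` plus private
    segments (exponential, mean 5 Mb).  Sensitivity is measured against
    planted segments spanning >= 50 SNPs and >= 1 Mb; precision against all
    planted state (a call inside any planted segment is correct).  Hotspot
    ROHF recovery is summarized as the maximum |ROHF - carrier fraction|
    z-score over hotspots, in binomial standard deviations of the target
    frequency.
    """
    snp_map = generate_snp_map(
        n_chromosomes, snps_per_chromosome, chromosome_length_bp, seed=seed
    )
    spots = []
    for c in snp_map.chromosomes:
        lo, hi = snp_map.chrom_range(int(c))
        mid = (lo + hi) // 2
        spots.append(Hotspot(int(c), mid - 3_000_000, mid + 3_000_000, hotspot_frequency))
    genotypes, truth = generate_cohort(
        snp_map, n_samples, het_rate, error_rate, nocall_rate, spots,
        private_roh_rate=0.3, private_roh_mean_len_bp=5_000_000,
        seed=seed + 1,
    )
    big = truth.segments_min_size(snp_map, min_snps=50, min_length_bp=1_000_000)
    truth_big = CohortTruth(big, truth.hotspots, {}, seed).state_matrix(
        snp_map, genotypes.sample_ids
    )
    truth_all = truth.state_matrix(snp_map, genotypes.sample_ids)
    out: dict = {"n_samples": n_samples, "n_loci": len(snp_map), "seed": seed}
    for caller, fn, params in (
        ("hmm", call_roh_hmm, RECOVERY_HMM_PARAMS),
        ("window", call_roh_window, RECOVERY_WINDOW_PARAMS),
    ):
        state = segments_to_locus_state(fn(genotypes, params), snp_map,
                                        genotypes.sample_ids)
        tp_s = int((state & truth_big).sum())
        fn_s = int((~state & truth_big).sum())
        tp_p = int((state & truth_all).sum())
        fp_p = int((state & ~truth_all).sum())
        rohf = compute_rohf(state)
        max_z = 0.0
        sd = np.sqrt(hotspot_frequency * (1 - hotspot_frequency) / n_samples)
        for k, h in enumerate(spots):
            carriers = len(truth.hotspot_carriers[k]) / n_samples
            interior = snp_map.locus_indices(
                h.chromosome, h.start_bp + 500_000, h.end_bp - 500_000
            )
            err = abs(float(rohf.values[interior].mean()) - carriers)
            max_z = max(max_z, err / sd)
        out[caller] = {
            "sensitivity": tp_s / (tp_s + fn_s),
            "precision": tp_p / (tp_p + fp_p),
            "hotspot_max_z": max_z,
        }
    return out


def _thinned_map(seed: int):
    """Genome-wide thinned map: 2,000 loci over 10 x 260 Mb chromosomes."""
    return generate_snp_map(10, 200, 260_000_000, seed=seed)


def _shared_hotspots(snp_map, frequency: float) -> list[Hotspot]:
    """Two 10 Mb hotspots per chromosome (~8% of loci covered)."""
    spots = []
    for c in snp_map.chromosomes:
        lo, hi = snp_map.chrom_range(int(c))
        for frac in (0.3, 0.7):
            mid = lo + int((hi - lo) * frac)
            spots.append(Hotspot(int(c), mid - 5_000_000, mid + 5_000_000, frequency))
    return spots


def _null_cohort_states(snp_map, spots, n_samples, seed, prefix):
    _, truth = generate_cohort(
        snp_map, n_samples, het_rate=0.3, error_rate=0.01, nocall_rate=0.005,
        hotspots=spots, private_roh_rate=0.3, private_roh_mean_len_bp=2_500_000,
        seed=seed, sample_prefix=prefix,
    )
    ids = [f"{prefix}{i:03d}" for i in range(n_samples)]
    return truth.state_matrix(snp_map, ids)


def resampling_null_experiment(
    seed: int,
    n_reps: int = 50,
    n_iter: int = 100,
    n_adults: int = 60,
    n_young: int = 30,
    subsample_size: int = 30,
    alpha: float = 0.05,
    relaxed_alpha: float = 0.5,
) -> dict:
    """Resampling test under the null: both cohorts from one distribution.

    Repeats the whole procedure `n_reps` times with fresh cohorts (shared
    hotspot frequencies, no planted delta).  Reports the family-wise
    declaration rate (fraction of repetitions with any Bonferroni-significant
    dataset) and, at a relaxed per-dataset alpha, the sign balance of
    significant datasets summarized per repetition (majority sign), since
    datasets within a repetition share the realized cohorts.
    """
    snp_map = _thinned_map(seed)
    spots = _shared_hotspots(snp_map, 0.10)
    n_declare = 0
    majority_positive = 0
    runs_with_significant = 0
    for rep in range(n_reps):
        st_a = _null_cohort_states(snp_map, spots, n_adults, seed + 1000 + rep, "A")
        st_y = _null_cohort_states(snp_map, spots, n_young, seed + 5000 + rep, "Y")
        strict = adult_young_resampling(
            st_a, st_y, n_iter=n_iter, subsample_size=subsample_size,
            alpha=alpha, seed=seed + rep,
        )
        n_declare += strict.n_significant > 0
        relaxed = adult_young_resampling(
            st_a, st_y, n_iter=n_iter, subsample_size=subsample_size,
            alpha=relaxed_alpha, seed=seed + rep,
        )
        if relaxed.n_significant:
            runs_with_significant += 1
            majority_positive += (
                relaxed.n_significant_positive > relaxed.n_significant / 2
            )
    return {
        "n_reps": n_reps,
        "fwer": n_declare / n_reps,
        "runs_with_significant_relaxed": runs_with_significant,
        "majority_positive_fraction": (
            majority_positive / runs_with_significant
            if runs_with_significant
            else None
        ),
        "seed": seed,
    }


def resampling_power_experiment(
    seed: int,
    n_iter: int = 200,
    n_reps: int = 10,
    excess: float = 0.05,
    base_frequency: float = 0.10,
) -> dict:
    """Resampling test with a planted adult hotspot-frequency excess.

    Adults carry every shared hotspot at base_frequency + excess, young at
    base_frequency.  The procedure is repeated over `n_reps` fresh cohort
    pairs (one realized cohort pair decides little: whether the Bonferroni
    threshold fires at all is dominated by cohort-level noise) and the
    positive proportion among significant datasets is pooled across
    repetitions — the procedure's power summary.
    """
    snp_map = _thinned_map(seed)
    spots_y = _shared_hotspots(snp_map, base_frequency)
    spots_a = _shared_hotspots(snp_map, base_frequency + excess)
    tot_sig = tot_sig_pos = tot_pos = 0
    for rep in range(n_reps):
        st_a = _null_cohort_states(snp_map, spots_a, 60, seed + 100 + rep, "A")
        st_y = _null_cohort_states(snp_map, spots_y, 30, seed + 500 + rep, "Y")
        res = adult_young_resampling(
            st_a, st_y, n_iter=n_iter, subsample_size=30, seed=seed + rep
        )
        tot_sig += res.n_significant
        tot_sig_pos += res.n_significant_positive
        tot_pos += res.n_positive
    return {
        "n_iter": n_iter,
        "n_reps": n_reps,
        "n_significant": tot_sig,
        "n_significant_positive": tot_sig_pos,
        "proportion": tot_sig_pos / tot_sig if tot_sig else None,
        "n_positive": tot_pos,
        "seed": seed,
    }


def stepwise_experiment(
    seed: int,
    n_reps: int = 10,
    quantiles: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75),
) -> dict:
    """Stepwise-cutoff correlation on shared-hotspot cohorts.

    A tumor-like and a control-like cohort share 1 Mb hotspot cores whose
    control frequencies are heavy-tailed (log-uniform 0.02-0.5, tumor
    3x + 0.1, capped at 0.9); carriers' runs extend variably beyond the
    core (exponential, mean 6 Mb tumor / 1 Mb control), so the severe
    cohort's runs are extensions of the mild cohort's — and both cohorts
    carry independent private segments that form a cohort-specific noise
    floor.  Restricting to loci above rising control-ROHF quantiles removes
    that noise floor, so the correlation rises; the series is averaged over
    `n_reps` replicate cohort pairs (Monte-Carlo smoothing).

    The quantile grid stops at 0.75: in the extreme tail the selection
    collapses the retained loci onto a handful of hotspot plateaus and
    classical range restriction takes over, which at desk-scale locus
    counts reverses the rise.
    """
    series_all = []
    for rep in range(n_reps):
        s = seed + 10 * rep
        snp_map = generate_snp_map(5, 400, 60_000_000, seed=s)
        rng = np.random.default_rng(s + 1)
        spots_c, spots_t = [], []
        for c in snp_map.chromosomes:
            lo, hi = snp_map.chrom_range(int(c))
            for i in range(4):
                mid = lo + int((hi - lo) * (0.12 + 0.76 * i / 3))
                f = float(np.exp(rng.uniform(np.log(0.02), np.log(0.5))))
                spots_c.append(Hotspot(int(c), mid - 500_000, mid + 500_000, f))
                spots_t.append(
                    Hotspot(int(c), mid - 500_000, mid + 500_000, min(0.9, 3 * f + 0.1))
                )
        _, truth_t = generate_cohort(
            snp_map, 60, hotspots=spots_t, private_roh_rate=1.0,
            private_roh_mean_len_bp=3_000_000, seed=s + 2, sample_prefix="T",
            hotspot_extension_mean_bp=6_000_000,
        )
        _, truth_c = generate_cohort(
            snp_map, 90, hotspots=spots_c, private_roh_rate=1.0,
            private_roh_mean_len_bp=3_000_000, seed=s + 3, sample_prefix="C",
            hotspot_extension_mean_bp=1_000_000,
        )
        rohf_t = compute_rohf(
            truth_t.state_matrix(snp_map, [f"T{i:03d}" for i in range(60)])
        )
        rohf_c = compute_rohf(
            truth_c.state_matrix(snp_map, [f"C{i:03d}" for i in range(90)])
        )
        series = stepwise_cutoff_correlation(rohf_t, rohf_c, list(quantiles))
        series_all.append([r for _, _, r in series])
    mean_r = np.mean(series_all, axis=0)
    return {
        "quantiles": list(quantiles),
        "mean_r": [float(v) for v in mean_r],
        "n_reps": n_reps,
        "seed": seed,
    }
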