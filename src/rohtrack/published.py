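"""Desk-scale recomputation over the packaged published summary tables.

The package ships a transcription of the published per-fragile-site regional
ROHF summary table (NCI-60 vs HapMap cohorts, Affymetrix 500K array) and the
published cohort-level counts.  The functions here recompute the headline
derived quantities — threshold counts, mean miRNA counts, proximity ratios,
fold changes and resampling proportions — from those inputs with the
package's own arithmetic, so they can be checked end to end without the
(unpublishable-at-desk-scale) raw genotype data.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

from .annotation import proximity_ratio_round
from .tracks import fold_change

__all__ = [
    "load_fra_summary",
    "load_printed_counts",
    "fra_threshold_counts",
    "mirna_summary",
    "cohort_fold_changes",
    "resampling_proportions",
]


def _data(name: str):
    return resources.files("rohtrack.data").joinpath(name)


def load_fra_summary() -> pd.DataFrame:
    """Transcribed per-fragile-site table: regional upper-95th-percentile
    ROHF for both cohorts, their difference, and nearby miRNA counts."""
    with resources.as_file(_data("fra_summary_printed.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def load_printed_counts() -> dict:
    with resources.as_file(_data("printed_counts.json")) as p:
        return json.loads(p.read_text())


def fra_threshold_counts(
    table: pd.DataFrame | None = None,
    rohf_threshold: float = 0.5,
    diff_threshold: float = 0.5,
) -> dict:
    """Threshold counts over the per-fragile-site summary table.

    Returns the number of sites whose tumor-cohort regional ROHF exceeds
    `rohf_threshold`, the number whose cohort difference is at least
    `diff_threshold` (with their names), and the complement count of
    catalogued sites without such an elevation.
    """
    t = load_fra_summary() if table is None else table
    counts = load_printed_counts()
    high = t[t["rohf_nci60"] > rohf_threshold]
    big_diff = t[t["rohf_diff"] >= diff_threshold]
    return {
        "n_high_rohf": int(len(high)),
        "n_big_diff": int(len(big_diff)),
        "big_diff_names": sorted(big_diff["name"].tolist()),
        "n_without_elevation": int(counts["n_fras_total"] - len(high)),
        "mean_mirna_5mb_high": round(float(high["n_mirna_5mb"].mean()), 2),
    }


def mirna_summary() -> dict:
    """miRNA-to-fragile-site proximity ratios from published counts."""
    c = load_printed_counts()
    return {
        "ratio_1mb": proximity_ratio_round(
            c["mirna_within_1mb_of_fra"], c["n_mirna_autosomal"]
        ),
        "ratio_5mb": proximity_ratio_round(
            c["mirna_within_5mb_of_fra"], c["n_mirna_autosomal"]
        ),
        "ratio_prior_study_1mb": proximity_ratio_round(
            c["prior_study_mirna_within_1mb"], c["prior_study_mirna_total"]
        ),
    }


def cohort_fold_changes() -> dict:
    """Cohort-level ROHF fold changes and the adult-young percent difference."""
    c = load_printed_counts()
    return {
        "fold_tumor_vs_control": fold_change(
            c["mean_rohf_nci60"], c["mean_rohf_hapmap"], 0
        ),
        "fold_adult_vs_young": fold_change(
            c["mean_rohf_adult_pct"], c["mean_rohf_young_pct"], 2
        ),
        "adult_young_diff_pct": round(
            c["mean_rohf_adult_pct"] - c["mean_rohf_young_pct"], 2
        ),
    }


def resampling_proportions() -> dict:
    """Positive proportions among significant resampled datasets, per caller,
    recomputed from the published counts (reported in percent)."""
    c = load_printed_counts()["resampling"]
    out = {}
    for caller in ("hmm", "window"):
        r = c[caller]
        out[caller] = round(
            100.0 * r["n_significant_positive"] / r["n_significant"], 1
        )
    return out
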