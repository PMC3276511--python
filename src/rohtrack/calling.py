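"""ROH segment calling from genotype calls.

Two callers are provided, mirroring the dual strategy common in
homozygosity mapping:

* a two-state hidden-Markov segmentation (``call_roh_hmm``) with
  distance-dependent transition probabilities and Viterbi decoding, and
* a PLINK-style fixed-size sliding-window scan (``call_roh_window``).

Both emit per-sample, per-chromosome non-overlapping ``RohSegment`` records
with endpoints snapped to observed SNP positions (1-based inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .types import HET, NOCALL, GenotypeMatrix, SnpMap

__all__ = [
    "HmmParams",
    "WindowParams",
    "RohSegment",
    "call_roh_hmm",
    "call_roh_window",
    "segments_to_locus_state",
]


@dataclass(frozen=True)
class HmmParams:
    """Two-state (non-ROH / ROH) HMM parameters.

    het_rate
        P(HET call | non-ROH state).  Default 0.30 matches typical 500K-array
        background heterozygosity in outbred samples.
    error_rate
        P(HET call | ROH state): the residual genotyping-error heterozygote
        rate inside a true homozygous run.
    transition_scale_bp
        Distance constant of the inhomogeneous transition model: the
        per-step probability of leaving either state at inter-SNP distance
        d is ``max_switch_prob * (1 - exp(-d / transition_scale_bp))``.
    max_switch_prob
        Ceiling on the per-step switch probability (reached as d -> inf).
    initial_roh_prob
        Prior probability that a chromosome starts in the ROH state.
    min_posterior
        Reserved for posterior-filtering variants; unused by Viterbi decoding.
    """

    het_rate: float = 0.30
    error_rate: float = 0.02
    transition_scale_bp: float = 10_000_000.0
    max_switch_prob: float = 0.05
    initial_roh_prob: float = 0.1
    min_posterior: float = 0.0

    def __post_init__(self) -> None:
        for name in ("het_rate", "error_rate", "max_switch_prob", "initial_roh_prob"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} must be in (0,1)")
        if self.error_rate >= self.het_rate:
            raise ValueError("error_rate must be < het_rate")
        if self.transition_scale_bp <= 0:
            raise ValueError("transition_scale_bp must be > 0")


@dataclass(frozen=True)
class WindowParams:
    """Fixed-size sliding-window scan parameters (PLINK ``--homozyg`` style).

    A window of ``window_snps`` consecutive loci (discarded if it spans more
    than ``window_kb``) is homozygous when it contains at most
    ``max_het_per_window`` HET and ``max_missing_per_window`` NoCall calls.
    A locus is in ROH state when at least ``hit_fraction`` of the retained
    windows overlapping it are homozygous.  Maximal ROH-state runs are split
    where adjacent SNPs are more than ``max_gap_kb`` apart, then filtered by
    ``min_snps_per_segment``, ``min_length_kb`` and the maximum average
    spacing ``max_density_kb_per_snp``.
    """

    window_snps: int = 50
    window_kb: float = 5000.0
    max_het_per_window: int = 1
    max_missing_per_window: int = 5
    hit_fraction: float = 0.05
    min_snps_per_segment: int = 100
    min_length_kb: float = 1000.0
    max_gap_kb: float = 1000.0
    max_density_kb_per_snp: float = 50.0

    def __post_init__(self) -> None:
        if self.window_snps < 1:
            raise ValueError("window_snps must be >= 1")
        if min(self.max_het_per_window, self.max_missing_per_window) < 0:
            raise ValueError("window tolerances must be >= 0")
        if not 0.0 < self.hit_fraction <= 1.0:
            raise ValueError("hit_fraction must be in (0,1]")
        if self.min_length_kb <= 0 or self.window_kb <= 0:
            raise ValueError("lengths must be positive")


@dataclass(frozen=True)
class RohSegment:
    """One contiguous called homozygous run in one sample.

    Coordinates are 1-based inclusive and coincide with SNP positions;
    ``n_snps`` counts the map loci spanned.
    """

    sample_id: str
    chromosome: int
    start_bp: int
    end_bp: int
    n_snps: int
    caller: str  # "hmm" or "window"

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp > end_bp")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _switch_probs(positions: np.ndarray, params: HmmParams) -> np.ndarray:
    d = np.diff(positions).astype(float)
    return params.max_switch_prob * (1.0 - np.exp(-d / params.transition_scale_bp))


def _emission_loglik(calls_chrom: np.ndarray, params: HmmParams) -> np.ndarray:
    """log P(call | state) for states (non-ROH, ROH); NoCall is neutral.

    Returns an array of shape (2, n_samples, n_loci).
    """
    het = calls_chrom == HET
    missing = calls_chrom == NOCALL
    hom = ~het & ~missing
    e = np.zeros((2,) + calls_chrom.shape)
    e[0][het] = np.log(params.het_rate)
    e[0][hom] = np.log(1.0 - params.het_rate)
    e[1][het] = np.log(params.error_rate)
    e[1][hom] = np.log(1.0 - params.error_rate)
    # NoCall: equal likelihood in both states (log 1 = 0) so the
    # distance-dependent transitions still accumulate across missing loci.
    return e


def _viterbi_paths(
    calls_chrom: np.ndarray, positions: np.ndarray, params: HmmParams
) -> np.ndarray:
    """Batched 2-state Viterbi decoding over one chromosome.

    calls_chrom: (n_samples, n_loci); returns boolean ROH-state paths of the
    same shape.  Ties are broken toward the non-ROH state, both in the
    per-step predecessor choice and in the terminal state, so decoding is
    deterministic and conservative.
    """
    n_samples, n_loci = calls_chrom.shape
    e = _emission_loglik(calls_chrom, params)
    p_switch = _switch_probs(positions, params)
    log_stay = np.log1p(-p_switch)
    log_switch = np.log(p_switch)

    v0 = np.full(n_samples, np.log(1.0 - params.initial_roh_prob)) + e[0, :, 0]
    v1 = np.full(n_samples, np.log(params.initial_roh_prob)) + e[1, :, 0]
    back = np.zeros((n_loci, 2, n_samples), dtype=np.uint8)
    for i in range(1, n_loci):
        from0_to0 = v0 + log_stay[i - 1]
        from1_to0 = v1 + log_switch[i - 1]
        from0_to1 = v0 + log_switch[i - 1]
        from1_to1 = v1 + log_stay[i - 1]
        take1_for0 = from1_to0 > from0_to0          # tie -> predecessor 0
        take1_for1 = from1_to1 > from0_to1
        back[i, 0] = take1_for0
        back[i, 1] = take1_for1
        v0 = np.where(take1_for0, from1_to0, from0_to0) + e[0, :, i]
        v1 = np.where(take1_for1, from1_to1, from0_to1) + e[1, :, i]

    paths = np.zeros((n_samples, n_loci), dtype=np.uint8)
    state = (v1 > v0).astype(np.uint8)               # tie -> non-ROH
    paths[:, n_loci - 1] = state
    cols = np.arange(n_samples)
    for i in range(n_loci - 1, 0, -1):
        state = back[i, state, cols]
        paths[:, i - 1] = state
    return paths.astype(bool)


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, end) index pairs (inclusive) of maximal True runs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def _state_to_segments(
    state: np.ndarray,
    positions: np.ndarray,
    chromosome: int,
    sample_ids: list[str],
    caller: str,
) -> list[RohSegment]:
    segs = []
    for row, sid in enumerate(sample_ids):
        for a, b in _runs_of_true(state[row]):
            segs.append(
                RohSegment(
                    sample_id=sid,
                    chromosome=chromosome,
                    start_bp=int(positions[a]),
                    end_bp=int(positions[b]),
                    n_snps=b - a + 1,
                    caller=caller,
                )
            )
    return segs


def call_roh_hmm(
    genotypes: GenotypeMatrix,
    params: HmmParams | None = None,
) -> list[RohSegment]:
    """Call ROH segments per sample by 2-state Viterbi segmentation.

    Chromosomes with fewer than 2 loci yield no segments (with a warning).
    """
    params = params or HmmParams()
    snp_map = genotypes.snp_map
    out: list[RohSegment] = []
    for c in snp_map.chromosomes:
        s = snp_map.chrom_slice(int(c))
        if s.stop - s.start < 2:
            warnings.warn(
                f"chromosome {c}: fewer than 2 loci, no HMM segments called",
                stacklevel=2,
            )
            continue
        paths = _viterbi_paths(
            genotypes.calls[:, s], snp_map.position_bp[s], params
        )
        out.extend(
            _state_to_segments(
                paths, snp_map.position_bp[s], int(c), genotypes.sample_ids, "hmm"
            )
        )
    return out


def _window_state_row(
    calls_row: np.ndarray, positions: np.ndarray, params: WindowParams
) -> np.ndarray:
    """Per-locus ROH state for one sample on one chromosome."""
    n = len(calls_row)
    w = params.window_snps
    if w > n:
        return np.zeros(n, dtype=bool)
    het = (calls_row == HET).astype(np.int64)
    miss = (calls_row == NOCALL).astype(np.int64)
    chet = np.concatenate([[0], np.cumsum(het)])
    cmiss = np.concatenate([[0], np.cumsum(miss)])
    starts = np.arange(n - w + 1)
    span_ok = (positions[starts + w - 1] - positions[starts]) <= params.window_kb * 1000
    hom_win = (
        span_ok
        & ((chet[starts + w] - chet[starts]) <= params.max_het_per_window)
        & ((cmiss[starts + w] - cmiss[starts]) <= params.max_missing_per_window)
    )
    cvalid = np.concatenate([[0], np.cumsum(span_ok.astype(np.int64))])
    chom = np.concatenate([[0], np.cumsum(hom_win.astype(np.int64))])
    idx = np.arange(n)
    lo = np.maximum(0, idx - w + 1)
    hi = np.minimum(idx, n - w)
    n_valid = np.where(hi >= lo, cvalid[hi + 1] - cvalid[lo], 0)
    n_hom = np.where(hi >= lo, chom[hi + 1] - chom[lo], 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_valid > 0, n_hom / np.maximum(n_valid, 1), 0.0)
    return frac >= params.hit_fraction


def _filter_and_split_runs(
    state_row: np.ndarray, positions: np.ndarray, params: WindowParams
) -> list[tuple[int, int]]:
    out = []
    for a, b in _runs_of_true(state_row):
        # Split where adjacent-SNP gaps exceed max_gap_kb.
        pieces, start = [], a
        for i in range(a, b):
            if positions[i + 1] - positions[i] > params.max_gap_kb * 1000:
                pieces.append((start, i))
                start = i + 1
        pieces.append((start, b))
        for p, q in pieces:
            n_snps = q - p + 1
            length_kb = (positions[q] - positions[p] + 1) / 1000.0
            if n_snps < params.min_snps_per_segment:
                continue
            if length_kb < params.min_length_kb:
                continue
            if length_kb / n_snps > params.max_density_kb_per_snp:
                continue
            out.append((p, q))
    return out


def call_roh_window(
    genotypes: GenotypeMatrix,
    params: WindowParams | None = None,
) -> list[RohSegment]:
    """Call ROH segments per sample by the fixed-window homozygosity scan."""
    params = params or WindowParams()
    snp_map = genotypes.snp_map
    out: list[RohSegment] = []
    for c in snp_map.chromosomes:
        s = snp_map.chrom_slice(int(c))
        n = s.stop - s.start
        if params.window_snps > n:
            warnings.warn(
                f"chromosome {c}: window ({params.window_snps} SNPs) exceeds "
                f"locus count ({n}), no window segments called",
                stacklevel=2,
            )
            continue
        positions = snp_map.position_bp[s]
        for row, sid in enumerate(genotypes.sample_ids):
            state = _window_state_row(genotypes.calls[row, s], positions, params)
            for p, q in _filter_and_split_runs(state, positions, params):
                out.append(
                    RohSegment(
                        sample_id=sid,
                        chromosome=int(c),
                        start_bp=int(positions[p]),
                        end_bp=int(positions[q]),
                        n_snps=q - p + 1,
                        caller="window",
                    )
                )
    return out


def segments_to_locus_state(
    segments: list[RohSegment],
    snp_map: SnpMap,
    sample_ids: list[str],
) -> np.ndarray:
    """Boolean samples x loci matrix: True where a segment covers the locus."""
    idx = {s: i for i, s in enumerate(sample_ids)}
    out = np.zeros((len(sample_ids), len(snp_map)), dtype=bool)
    for seg in segments:
        loci = snp_map.locus_indices(seg.chromosome, seg.start_bp, seg.end_bp)
        if len(loci) == 0 or seg.start_bp < 1:
            raise ValueError(f"segment outside map range: {seg}")
        out[idx[seg.sample_id], loci] = True
    return out
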