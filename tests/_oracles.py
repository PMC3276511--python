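"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct method available
(exhaustive enumeration, nested loops, closed forms), sharing no code with
the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from rohtrack.types import HET, NOCALL


def enumerate_viterbi(calls: np.ndarray, positions: np.ndarray, params) -> tuple[float, list[np.ndarray]]:
    """Exhaustive maximization over all 2^n state paths of one sample.

    Returns (max log score, list of all argmax paths as boolean arrays).
    """
    n = len(calls)
    log_emit = np.zeros((2, n))
    for i, c in enumerate(calls):
        if c == HET:
            log_emit[0, i] = math.log(params.het_rate)
            log_emit[1, i] = math.log(params.error_rate)
        elif c != NOCALL:
            log_emit[0, i] = math.log(1 - params.het_rate)
            log_emit[1, i] = math.log(1 - params.error_rate)
    d = np.diff(positions)
    p_sw = params.max_switch_prob * (1 - np.exp(-d / params.transition_scale_bp))
    log_init = [math.log(1 - params.initial_roh_prob), math.log(params.initial_roh_prob)]
    best, argmax = -math.inf, []
    for path in itertools.product((0, 1), repeat=n):
        score = log_init[path[0]] + log_emit[path[0], 0]
        for i in range(1, n):
            score += math.log(p_sw[i - 1]) if path[i] != path[i - 1] else math.log(1 - p_sw[i - 1])
            score += log_emit[path[i], i]
        if score > best + 1e-9:
            best, argmax = score, [np.array(path, dtype=bool)]
        elif score > best - 1e-9:
            argmax.append(np.array(path, dtype=bool))
    return best, argmax


def path_log_score(path: np.ndarray, calls: np.ndarray, positions: np.ndarray, params) -> float:
    """Log score of one explicit state path (for comparing against the max)."""
    n = len(calls)
    d = np.diff(positions)
    p_sw = params.max_switch_prob * (1 - np.exp(-d / params.transition_scale_bp))

    def emit(state, c):
        if c == NOCALL:
            return 0.0
        rate = params.error_rate if state else params.het_rate
        return math.log(rate) if c == HET else math.log(1 - rate)

    score = math.log(params.initial_roh_prob if path[0] else 1 - params.initial_roh_prob)
    score += emit(path[0], calls[0])
    for i in range(1, n):
        score += math.log(p_sw[i - 1]) if path[i] != path[i - 1] else math.log(1 - p_sw[i - 1])
        score += emit(path[i], calls[i])
    return score


def brute_window_state(calls: np.ndarray, positions: np.ndarray, params) -> np.ndarray:
    """Direct nested-loop implementation of the fixed-window locus state."""
    n = len(calls)
    w = params.window_snps
    state = np.zeros(n, dtype=bool)
    if w > n:
        return state
    windows = []
    for i in range(n - w + 1):
        if positions[i + w - 1] - positions[i] > params.window_kb * 1000:
            continue
        block = calls[i:i + w]
        hom = (
            int((block == HET).sum()) <= params.max_het_per_window
            and int((block == NOCALL).sum()) <= params.max_missing_per_window
        )
        windows.append((i, hom))
    for j in range(n):
        overlapping = [hom for (i, hom) in windows if i <= j <= i + w - 1]
        if overlapping:
            frac = sum(overlapping) / len(overlapping)
            state[j] = frac >= params.hit_fraction
    return state


def brute_window_segments(calls: np.ndarray, positions: np.ndarray, params) -> list[tuple[int, int]]:
    """(start_idx, end_idx) segments after gap splitting and filtering."""
    state = brute_window_state(calls, positions, params)
    runs, start = [], None
    for j in range(len(state) + 1):
        on = j < len(state) and state[j]
        if on and start is None:
            start = j
        elif not on and start is not None:
            runs.append((start, j - 1))
            start = None
    pieces = []
    for a, b in runs:
        s = a
        for i in range(a, b):
            if positions[i + 1] - positions[i] > params.max_gap_kb * 1000:
                pieces.append((s, i))
                s = i + 1
        pieces.append((s, b))
    out = []
    for p, q in pieces:
        n_snps = q - p + 1
        length_kb = (positions[q] - positions[p] + 1) / 1000
        if (
            n_snps >= params.min_snps_per_segment
            and length_kb >= params.min_length_kb
            and length_kb / n_snps <= params.max_density_kb_per_snp
        ):
            out.append((p, q))
    return out


def sorted_upper_tail_mean(values: np.ndarray, percentile: float) -> float:
    """Sort-based upper-tail mean: keep values >= interpolated percentile."""
    v = np.sort(np.asarray(values, float))
    n = len(v)
    if n == 1:
        return float(v[0])
    rank = (percentile / 100.0) * (n - 1)
    lo = int(math.floor(rank))
    frac = rank - lo
    cutoff = v[lo] if frac == 0 else v[lo] * (1 - frac) + v[lo + 1] * frac
    tail = v[v >= cutoff]
    return float(tail.mean())


def partial_correlation_one_covariate(a, b, c) -> float:
    """Textbook recursion: r_ab.c from the three pairwise correlations."""
    r_ab = np.corrcoef(a, b)[0, 1]
    r_ac = np.corrcoef(a, c)[0, 1]
    r_bc = np.corrcoef(b, c)[0, 1]
    return (r_ab - r_ac * r_bc) / math.sqrt((1 - r_ac**2) * (1 - r_bc**2))
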