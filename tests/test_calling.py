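"""ROH caller behavior: oracle equivalence, planted-segment recovery,
tolerance properties and symmetry."""

import numpy as np
import pytest

import rohtrack as rt
from rohtrack.calling import _viterbi_paths, _window_state_row
from rohtrack.types import HET, HOM_A, HOM_B, NOCALL

from _oracles import (
    brute_window_segments,
    brute_window_state,
    enumerate_viterbi,
    path_log_score,
)


def _matrix_from_row(calls_row, positions, chromosome=1):
    m = rt.SnpMap(
        snp_id=np.array([f"s{i}" for i in range(len(positions))], dtype=object),
        chromosome=np.full(len(positions), chromosome),
        position_bp=np.asarray(positions),
    )
    return rt.GenotypeMatrix(["x"], np.asarray([calls_row], dtype=np.int8), m)


class TestHmm:
    def test_all_het_yields_no_segments(self):
        g = _matrix_from_row([HET] * 50, np.arange(1, 51) * 10_000)
        assert rt.call_roh_hmm(g) == []

    def test_planted_block_recovered_with_tight_boundaries(self):
        rng = np.random.default_rng(0)
        n = 200
        calls = np.where(rng.random(n) < 0.3, HET, HOM_A)
        block = np.where(rng.random(100) < 0.01, HET, HOM_B)
        calls[50:150] = block
        positions = np.sort(rng.choice(np.arange(1, 10_000_000), n, replace=False))
        g = _matrix_from_row(calls, positions)
        segs = rt.call_roh_hmm(g, rt.HmmParams(error_rate=0.01))
        assert len(segs) == 1
        start_idx = int(np.searchsorted(positions, segs[0].start_bp))
        end_idx = int(np.searchsorted(positions, segs[0].end_bp))
        assert abs(start_idx - 50) <= 2
        assert abs(end_idx - 149) <= 2

    def test_viterbi_equals_exhaustive_enumeration_small(self):
        """Decoded path attains the global maximum over all 2^n paths."""
        rng = np.random.default_rng(1)
        params = rt.HmmParams()
        for _ in range(25):
            n = int(rng.integers(2, 13))
            calls = rng.choice([HOM_A, HET, HOM_B, NOCALL], size=n,
                               p=[0.4, 0.25, 0.3, 0.05]).astype(np.int8)
            positions = np.sort(rng.choice(np.arange(1, 50_000_000), n, replace=False))
            best, argmax = enumerate_viterbi(calls, positions, params)
            paths = _viterbi_paths(calls[None, :], positions, params)
            got = path_log_score(paths[0], calls, positions, params)
            assert got == pytest.approx(best, abs=1e-9)
            assert any(np.array_equal(paths[0], p) for p in argmax)

    def test_short_chromosome_warns_and_skips(self):
        m = rt.SnpMap(
            snp_id=np.array(["a", "b"], dtype=object),
            chromosome=np.array([1, 2]),
            position_bp=np.array([100, 100]),
        )
        g = rt.GenotypeMatrix(["x"], np.array([[HOM_A, HOM_A]], dtype=np.int8), m)
        with pytest.warns(UserWarning, match="fewer than 2 loci"):
            assert rt.call_roh_hmm(g) == []

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            rt.HmmParams(het_rate=0.1, error_rate=0.2)
        with pytest.raises(ValueError):
            rt.HmmParams(transition_scale_bp=-1)

    def test_near_degenerate_error_rate_calls_less(self, hotspot_cohort, small_map):
        """When the two states' emissions nearly coincide, the conservative
        tie handling suppresses calls relative to well-separated rates."""
        g, _, _ = hotspot_cohort
        matched = rt.segments_to_locus_state(
            rt.call_roh_hmm(g, rt.HmmParams(error_rate=0.01)), small_map, g.sample_ids
        )
        degenerate = rt.segments_to_locus_state(
            rt.call_roh_hmm(g, rt.HmmParams(error_rate=0.299)), small_map, g.sample_ids
        )
        assert degenerate.sum() <= matched.sum()


class TestWindow:
    def test_all_het_yields_no_segments(self):
        g = _matrix_from_row([HET] * 120, np.arange(1, 121) * 10_000)
        assert rt.call_roh_window(g) == []

    def test_planted_hom_run_single_segment(self):
        """60 homozygous loci over 2 Mb come back as one 60-SNP segment."""
        rng = np.random.default_rng(2)
        params = rt.WindowParams(
            window_snps=10, max_het_per_window=1, max_missing_per_window=2,
            min_snps_per_segment=20, min_length_kb=500,
        )
        calls = np.where(rng.random(200) < 0.3, HET, HOM_A).astype(np.int8)
        calls[70:130] = HOM_B
        positions = np.concatenate([
            np.sort(rng.choice(np.arange(1, 2_300_000), 70, replace=False)),
            np.sort(rng.choice(np.arange(2_400_000, 4_400_000), 60, replace=False)),
            np.sort(rng.choice(np.arange(4_500_000, 6_800_000), 70, replace=False)),
        ])
        g = _matrix_from_row(calls, positions)
        segs = rt.call_roh_window(g, params)
        assert len(segs) == 1
        # covers the whole planted run; boundary windows may absorb a few
        # flanking homozygotes (hit_fraction is permissive by design)
        assert segs[0].start_bp <= positions[70]
        assert segs[0].end_bp >= positions[129]
        assert 60 <= segs[0].n_snps < 60 + 2 * params.window_snps
        assert brute_window_segments(calls, positions, params) == [
            (int(np.searchsorted(positions, segs[0].start_bp)),
             int(np.searchsorted(positions, segs[0].end_bp)))
        ]

    def test_single_interior_het_tolerated(self):
        rng = np.random.default_rng(3)
        params = rt.WindowParams(
            window_snps=10, max_het_per_window=1, max_missing_per_window=2,
            min_snps_per_segment=40, min_length_kb=500,
        )
        calls = np.where(rng.random(200) < 0.3, HET, HOM_A).astype(np.int8)
        calls[70:130] = HOM_A
        calls[100] = HET
        positions = np.concatenate([
            np.sort(rng.choice(np.arange(1, 2_300_000), 70, replace=False)),
            np.sort(rng.choice(np.arange(2_400_000, 4_400_000), 60, replace=False)),
            np.sort(rng.choice(np.arange(4_500_000, 6_800_000), 70, replace=False)),
        ])
        g = _matrix_from_row(calls, positions)
        segs = rt.call_roh_window(g, params)
        assert len(segs) == 1
        assert segs[0].start_bp <= positions[70]
        assert segs[0].end_bp >= positions[129]

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_window_rule(self, seed):
        rng = np.random.default_rng(seed)
        params = rt.WindowParams(
            window_snps=8, max_het_per_window=1, max_missing_per_window=1,
            hit_fraction=0.05, min_snps_per_segment=10, min_length_kb=50,
            max_gap_kb=300, max_density_kb_per_snp=80,
        )
        n = 100
        calls = rng.choice([HOM_A, HET, HOM_B, NOCALL], size=n,
                           p=[0.45, 0.2, 0.3, 0.05]).astype(np.int8)
        calls[30:70] = HOM_A  # ensure some signal
        positions = np.sort(rng.choice(np.arange(1, 3_000_000), n, replace=False))
        state = _window_state_row(calls, positions, params)
        assert np.array_equal(state, brute_window_state(calls, positions, params))
        g = _matrix_from_row(calls, positions)
        got = [
            (int(np.searchsorted(positions, s.start_bp)),
             int(np.searchsorted(positions, s.end_bp)))
            for s in rt.call_roh_window(g, params)
        ]
        assert got == brute_window_segments(calls, positions, params)

    def test_het_tolerance_monotone(self, hotspot_cohort, small_map):
        """Raising the per-window HET allowance never shrinks the called
        locus set (density filter not binding)."""
        g, _, _ = hotspot_cohort
        base = dict(window_snps=15, max_missing_per_window=2,
                    min_snps_per_segment=25, min_length_kb=500,
                    max_density_kb_per_snp=float("inf"))
        prev = -1
        for h in (0, 1, 2, 3):
            params = rt.WindowParams(max_het_per_window=h, **base)
            st = rt.segments_to_locus_state(
                rt.call_roh_window(g, params), small_map, g.sample_ids
            )
            assert st.sum() >= prev
            prev = st.sum()

    def test_window_larger_than_chromosome_warns(self):
        g = _matrix_from_row([HOM_A] * 30, np.arange(1, 31) * 10_000)
        with pytest.warns(UserWarning, match="exceeds"):
            assert rt.call_roh_window(g, rt.WindowParams(window_snps=50)) == []


class TestCallerSymmetry:
    def test_hom_relabeling_invariance(self, hotspot_cohort, small_map, rng):
        """Swapping HOM_A and HOM_B at random loci changes nothing."""
        g, _, _ = hotspot_cohort
        calls = g.calls.copy()
        swap = rng.random(calls.shape[1]) < 0.5
        block = calls[:, swap]
        block[block == HOM_A] = 99
        block[block == HOM_B] = HOM_A
        block[block == 99] = HOM_B
        calls[:, swap] = block
        g2 = rt.GenotypeMatrix(g.sample_ids, calls, small_map)
        assert rt.call_roh_hmm(g) == rt.call_roh_hmm(g2)
        assert rt.call_roh_window(g) == rt.call_roh_window(g2)


class TestLocusState:
    def test_empty_and_full(self, small_map):
        ids = ["a", "b"]
        assert not rt.segments_to_locus_state([], small_map, ids).any()
        lo, hi = small_map.chrom_range(1)
        seg = rt.RohSegment("a", 1, lo, hi, small_map.chrom_slice(1).stop, "hmm")
        st = rt.segments_to_locus_state([seg], small_map, ids)
        assert st[0, small_map.chrom_slice(1)].all()
        assert not st[0, small_map.chrom_slice(2)].any()
        assert not st[1].any()

    def test_matches_linear_scan(self, small_map, rng):
        ids = [f"s{i}" for i in range(4)]
        segs = []
        for _ in range(12):
            c = int(rng.integers(1, 3))
            lo, hi = small_map.chrom_range(c)
            a = int(rng.integers(lo, hi))
            b = min(hi, a + int(rng.integers(1, 2_000_000)))
            loci = small_map.locus_indices(c, a, b)
            if len(loci) == 0:
                continue
            segs.append(rt.RohSegment(ids[int(rng.integers(0, 4))], c, a, b, len(loci), "hmm"))
        st = rt.segments_to_locus_state(segs, small_map, ids)
        # independent per-locus membership scan
        expected = np.zeros_like(st)
        for j in range(len(small_map)):
            c, p = small_map.chromosome[j], small_map.position_bp[j]
            for s in segs:
                if s.chromosome == c and s.start_bp <= p <= s.end_bp:
                    expected[ids.index(s.sample_id), j] = True
        assert np.array_equal(st, expected)
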