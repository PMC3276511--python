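"""Fragile-site mapping, proximity counting and high-ROHF band detection."""

import numpy as np
import pandas as pd
import pytest

import rohtrack as rt
from rohtrack.annotation import proximity_ratio_round


def _gene_table(rows):
    return pd.DataFrame(rows, columns=["symbol", "band", "chromosome", "start_bp", "end_bp"])


def _fra_records(rows):
    return pd.DataFrame(rows, columns=["name", "band", "rare_flag"])


class TestMapFra:
    def test_single_gene_band(self):
        genes = _gene_table([("G1", "7q31.2", 7, 10_000_000, 12_000_000)])
        fras, unmapped = rt.map_fra_to_genomic(
            _fra_records([("FRA7G", "7q31.2", False)]), genes
        )
        assert unmapped == []
        (s,) = fras
        assert (s.region_start_bp, s.region_end_bp) == (10_000_000, 12_000_000)
        assert s.anchor_bp == 11_000_000
        assert s.chromosome == 7

    def test_min_max_envelope(self):
        genes = _gene_table([
            ("G1", "9p21", 9, 10_000_000, 20_000_000),
            ("G2", "9p21", 9, 15_000_000, 30_000_000),
        ])
        fras, _ = rt.map_fra_to_genomic(_fra_records([("FRA9A", "9p21", False)]), genes)
        assert (fras[0].region_start_bp, fras[0].region_end_bp) == (10_000_000, 30_000_000)
        assert fras[0].anchor_bp == 20_000_000

    def test_exact_band_matching_no_subband_expansion(self):
        genes = _gene_table([("G1", "9p21.3", 9, 10_000_000, 12_000_000)])
        fras, unmapped = rt.map_fra_to_genomic(
            _fra_records([("FRA9A", "9p21", False)]), genes
        )
        assert fras == [] and unmapped == ["FRA9A"]

    def test_inconsistent_chromosome_rejected(self):
        genes = _gene_table([("G1", "9p21", 7, 10_000_000, 12_000_000)])
        with pytest.raises(ValueError, match="inconsistent"):
            rt.map_fra_to_genomic(_fra_records([("FRA9A", "9p21", False)]), genes)

    def test_random_tables_match_linear_scan(self, small_map, rng):
        ann = rt.generate_annotations(small_map, n_fras=6, genes_per_band=4, seed=17)
        fras, unmapped = rt.map_fra_to_genomic(ann.fra_records, ann.gene_table)
        assert not unmapped
        for s in fras:
            chrom, start, end = ann.fra_truth[s.name]
            assert (s.chromosome, s.region_start_bp, s.region_end_bp) == (chrom, start, end)
            # superset property: every matching gene inside the region
            genes = ann.gene_table[ann.gene_table["band"] == s.cyto_band]
            assert (genes["start_bp"] >= start).all()
            assert (genes["end_bp"] <= end).all()


class TestCountWithin:
    @staticmethod
    def _sites():
        return [
            rt.FragileSite("FRA1A", "1q21", 1, 9_000_000, 11_000_000, 10_000_000),
            rt.FragileSite("FRA2B", "2q22", 2, 29_000_000, 31_000_000, 30_000_000),
        ]

    def test_none_near(self):
        feats = [rt.FeaturePoint("m1", 1, 50_000_000)]
        assert rt.count_within(feats, self._sites(), 1_000_000) == (0, 0.0)

    def test_each_feature_counted_once(self):
        sites = [
            rt.FragileSite("FRA1A", "1q21", 1, 9_000_000, 11_000_000, 10_000_000),
            rt.FragileSite("FRA1B", "1q22", 1, 10_000_000, 12_000_000, 11_000_000),
        ]
        feats = [rt.FeaturePoint("m1", 1, 10_500_000)]
        count, _ = rt.count_within(feats, sites, 1_000_000)
        assert count == 1

    def test_published_precision_convention(self):
        assert proximity_ratio_round(63, 955) == 0.066
        assert proximity_ratio_round(334, 955) == 0.35
        assert proximity_ratio_round(13, 186) == 0.07

    def test_monotone_in_radius_and_matches_scan(self, small_map, rng):
        ann = rt.generate_annotations(small_map, n_fras=4, n_mirna=60, seed=23)
        fras, _ = rt.map_fra_to_genomic(ann.fra_records, ann.gene_table)
        prev = -1
        for radius in (100_000, 500_000, 2_000_000, 8_000_000):
            count, ratio = rt.count_within(ann.mirna, fras, radius)
            # all-pairs distance scan oracle
            expected = sum(
                1
                for f in ann.mirna.itertuples(index=False)
                if any(
                    s.chromosome == f.chromosome
                    and abs(s.anchor_bp - f.position_bp) <= radius
                    for s in fras
                )
            )
            assert count == expected
            assert count >= prev
            prev = count


class TestFraRohfTable:
    def test_columns_and_thresholding(self, small_map, rng):
        ann = rt.generate_annotations(small_map, n_fras=4, n_mirna=40, seed=29)
        fras, _ = rt.map_fra_to_genomic(ann.fra_records, ann.gene_table)
        a = rt.FrequencyTrack(rng.random(len(small_map)) * 0.8, "rohf", "tumor", 60)
        b = rt.FrequencyTrack(rng.random(len(small_map)) * 0.2, "rohf", "control", 90)
        table = rt.fra_rohf_table(fras, a, b, small_map, radius_bp=3_000_000,
                                  features=ann.mirna)
        assert len(table) == len(fras)
        assert {"rohf_a", "rohf_b", "rohf_diff", "n_features_5mb", "n_features_1mb"} <= set(table.columns)
        np.testing.assert_allclose(table["rohf_diff"], table["rohf_a"] - table["rohf_b"])
        # summaries agree with direct regional computation
        for row, s in zip(table.itertuples(index=False), fras):
            direct = rt.regional_upper_percentile(a, small_map, s.anchor_bp,
                                                  s.chromosome, 3_000_000)
            assert row.rohf_a == pytest.approx(direct.value)


class TestHighRohfBands:
    def test_uniform_below_threshold_empty(self, small_map):
        track = rt.FrequencyTrack(np.full(len(small_map), 0.2), "rohf", "", 10)
        assert rt.high_rohf_bands_without_fra(track, small_map, [], threshold=0.6) == []

    def test_planted_peak_far_from_fras(self, small_map):
        vals = np.full(len(small_map), 0.1)
        loci = small_map.locus_indices(2, 8_000_000, 10_000_000)
        vals[loci] = 0.9
        peak_locus = loci[len(loci) // 3]
        vals[peak_locus] = 0.95
        track = rt.FrequencyTrack(vals, "rohf", "", 10)
        fras = [rt.FragileSite("FRA1A", "1q21", 1, 1_000_000, 2_000_000, 1_500_000)]
        bands = rt.high_rohf_bands_without_fra(track, small_map, fras,
                                               radius_bp=2_000_000, threshold=0.6)
        assert len(bands) == 1
        band = bands[0]
        assert band["chromosome"] == 2
        assert band["peak_position_bp"] == small_map.position_bp[peak_locus]
        assert band["band_start_bp"] <= 8_000_000 <= band["band_end_bp"] or band["band_start_bp"] >= 8_000_000

    def test_plateau_reports_middle_locus(self, small_map):
        vals = np.full(len(small_map), 0.05)
        loci = small_map.locus_indices(1, 4_000_000, 8_000_000)
        vals[loci] = 0.9  # flat plateau: every locus ties at the maximum
        track = rt.FrequencyTrack(vals, "rohf", "", 10)
        bands = rt.high_rohf_bands_without_fra(track, small_map, [],
                                               radius_bp=1_000_000, threshold=0.5)
        assert len(bands) >= 1
        widest = max(bands, key=lambda b: b["band_end_bp"] - b["band_start_bp"])
        in_band = small_map.locus_indices(
            widest["chromosome"], widest["band_start_bp"], widest["band_end_bp"]
        )
        tied = [j for j in in_band if vals[j] == 0.9]
        assert widest["peak_position_bp"] == small_map.position_bp[tied[(len(tied) - 1) // 2]]

    def test_fra_vicinity_excluded(self, small_map):
        vals = np.full(len(small_map), 0.9)  # uniformly high
        track = rt.FrequencyTrack(vals, "rohf", "", 10)
        # an FRA anchored mid-chromosome-1 masks +/- radius around it
        fras = [rt.FragileSite("FRA1A", "1q21", 1, 5_000_000, 7_000_000, 6_000_000)]
        bands = rt.high_rohf_bands_without_fra(track, small_map, fras,
                                               radius_bp=3_000_000, threshold=0.5)
        for b in bands:
            if b["chromosome"] == 1:
                assert abs(b["peak_position_bp"] - 6_000_000) > 3_000_000
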