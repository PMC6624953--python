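import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import nested_coverage
from utriso.isoform_catalog import UtrIsoform, catalog, merge_ends
from utriso.quantify_profile import (
    classify_profile,
    length_stats,
    relative_abundance,
    segment_depths,
)


def steps(*pairs):
    return np.concatenate([np.full(n, d, dtype=float) for d, n in pairs])


class TestSegmentDepths:
    def test_three_segment_means(self):
        v = steps((10, 100), (4, 100), (1, 100))
        d = segment_depths(v, [100, 200, 300])
        assert [s.mean_depth for s in d] == [10, 4, 1]
        assert [(s.start, s.end) for s in d] == [(1, 101), (101, 201), (201, 301)]

    def test_single_segment(self):
        d = segment_depths(steps((5, 300)), [300])
        assert [s.mean_depth for s in d] == [5]

    def test_gap_zeros_lower_the_segment_mean(self):
        v = steps((10, 50), (0, 50), (10, 100))
        d = segment_depths(v, [100, 200])
        # oracle: per-base mean including the zero run
        assert d[0].mean_depth == pytest.approx(v[:100].mean())
        assert d[1].mean_depth == pytest.approx(10)

    def test_segments_tile_without_overlap(self):
        d = segment_depths(steps((3, 500)), [120, 300, 500])
        for a, b in zip(d, d[1:]):
            assert a.end == b.start

    def test_duplicate_ends_rejected(self):
        with pytest.raises(ValueError):
            segment_depths(steps((3, 400)), [100, 100, 300])


class TestRelativeAbundance:
    def test_textbook_vector(self):
        raw, norm = relative_abundance([10, 4, 1])
        assert raw == pytest.approx([0.6, 0.3, 0.1])
        assert norm == pytest.approx([0.6, 0.3, 0.1])

    def test_single_isoform_identity(self):
        assert relative_abundance([5.0]) == ([1.0], [1.0])

    def test_noise_inversion_clamped_and_renormalized(self):
        raw, norm = relative_abundance([4, 5])
        assert raw == pytest.approx([-0.25, 1.25])
        assert norm == pytest.approx([0.0, 1.0])

    def test_zero_proximal_depth_unquantifiable(self):
        with pytest.raises(ValueError, match="unquantifiable"):
            relative_abundance([0.0, 1.0])

    @settings(deadline=None, max_examples=60)
    @given(
        st.lists(st.floats(0.05, 1), min_size=1, max_size=5),
        st.lists(st.integers(100, 800), min_size=1, max_size=5),
    )
    def test_planted_abundances_recovered_exactly_from_noiseless_coverage(
        self, weights, gaps
    ):
        """Parameter-recovery identity: the module's core oracle."""
        k = min(len(weights), len(gaps))
        ab = np.array(weights[:k]) / sum(weights[:k])
        ends = np.cumsum(gaps[:k]).tolist()
        v = np.array(nested_coverage(ends, ab.tolist(), depth0=50.0))
        d = segment_depths(v, ends)
        _, norm = relative_abundance(d)
        assert norm == pytest.approx(ab.tolist(), abs=1e-9)

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(0.01, 100), min_size=1, max_size=6))
    def test_normalized_vector_is_a_probability_vector(self, d):
        d = [max(d[0], 0.01)] + d[1:]
        _, norm = relative_abundance(d)
        assert sum(norm) == pytest.approx(1.0, abs=1e-9)
        assert all(0 <= x <= 1 for x in norm)


class TestClassifyProfile:
    @pytest.mark.parametrize(
        "vector, expected",
        [
            ((1.0,), "P1"),
            ((0.9, 0.1), "P2"),
            ((0.60, 0.35, 0.05), "P3"),
            ((0.5, 0.2, 0.2, 0.1), "P4"),  # distal sum 0.3 > 0.1
        ],
    )
    def test_rule_examples(self, vector, expected):
        assert classify_profile(vector) == expected

    def test_boundary_80_percent_is_not_p2(self):
        assert classify_profile((0.80, 0.15, 0.05)) == "P3"

    def test_boundary_distal_sum_10_percent_is_p4(self):
        assert classify_profile((0.70, 0.20, 0.10)) == "P4"


class TestLengthStats:
    def cat(self, gid, lengths):
        return catalog(gid, merge_ends(lengths, gene_id=gid))

    def test_ratio_median_from_two_gene_example(self):
        stats = length_stats([self.cat("A", [100, 300]), self.cat("B", [200, 400])])
        assert stats["median_dutr1_putr_ratio"] == pytest.approx(2.5)
        assert stats["apa_fraction"] == 1.0

    def test_no_multi_isoform_genes_yields_nan_ratio(self):
        stats = length_stats([self.cat("A", [500])])
        assert np.isnan(stats["median_dutr1_putr_ratio"])
        assert stats["median_sutr"] == 500

    def test_single_gene_medians_equal_its_values(self):
        stats = length_stats([self.cat("A", [100, 300, 900])])
        assert stats["median_putr"] == 100
        assert stats["median_dutr"] == 600  # median of 300, 900
        assert stats["isoform_count_bins"] == {3: 1}

    def test_genes_beyond_isoform_cap_excluded(self):
        many = self.cat("A", [500, 1000, 1500, 2000, 2500, 3000])
        stats = length_stats([many, self.cat("B", [100, 300])])
        assert stats["n_genes"] == 1
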