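import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import changepoints_naive
from utriso.coverage_io import CoverageTrack
from utriso.end_detection import (
    SegmentationParams,
    TerminalEnd,
    filter_ends,
    scan_region,
    segment_changepoints,
    truncate_at_gap,
)
from utriso.gene_models import GeneModel

P = SegmentationParams()


def steps(*pairs):
    """Piecewise-constant vector from (depth, length) pairs."""
    return np.concatenate([np.full(n, d, dtype=float) for d, n in pairs])


def positions(ends):
    return [e.utr_pos for e in ends]


class TestSegmentChangepoints:
    def test_noiseless_two_step_profile(self):
        v = steps((100, 500), (20, 400))
        assert positions(segment_changepoints(v, P)) == [500, 900]

    def test_shallow_step_rejected_by_min_fold(self):
        v = steps((100, 500), (90, 400))  # ratio 0.9 > 0.8
        assert positions(segment_changepoints(v, P)) == [900]

    def test_constant_coverage_gives_single_extinction_end(self):
        v = steps((7, 1000))
        ends = segment_changepoints(v, P)
        assert positions(ends) == [1000]
        assert ends[0].downstream_mean == 0.0

    def test_all_zero_vector_gives_no_ends(self):
        assert segment_changepoints(np.zeros(500), P) == []

    def test_trailing_zero_invariance(self):
        v = steps((50, 400), (10, 300))
        a = segment_changepoints(v, P)
        b = segment_changepoints(np.concatenate([v, np.zeros(777)]), P)
        assert a == b

    def test_end_metadata_means_and_ratio(self):
        v = steps((100, 500), (20, 400))
        cp, ext = segment_changepoints(v, P)
        assert cp.upstream_mean == pytest.approx(100)
        assert cp.downstream_mean == pytest.approx(20)
        assert cp.drop_ratio == pytest.approx(0.2)
        assert ext.drop_ratio == 0.0

    def test_min_fold_monotonicity_on_noiseless_steps(self):
        # raising min_fold (more permissive) never loses ends
        v = steps((100, 400), (60, 400), (20, 400))
        counts = [
            len(segment_changepoints(v, SegmentationParams(min_fold=f)))
            for f in (0.3, 0.5, 0.8, 0.9)
        ]
        assert counts == sorted(counts)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_poisson_oracle(self, seed):
        """Vectorized detector equals the brute-force search on noisy arrays."""
        rng = np.random.default_rng(seed)
        n_steps = rng.integers(1, 4)
        mu, parts = 8.0, []
        for _ in range(n_steps):
            parts.append((mu, int(rng.integers(120, 600))))
            mu *= rng.uniform(0.1, 0.9)
        v = rng.poisson(steps(*parts)).astype(float)
        assert positions(segment_changepoints(v, P)) == changepoints_naive(v)

    def test_max_isoform_caps_segment_count(self):
        v = steps((1000, 200), (500, 200), (250, 200), (100, 200), (40, 200))
        capped = segment_changepoints(v, SegmentationParams(max_isoform=2))
        assert len(capped) == 2  # one accepted split + extinction end


class TestGapHandling:
    def test_internal_gap_within_merge_radius_retained(self):
        v = np.concatenate([np.full(300, 5.0), np.zeros(150), np.full(200, 5.0)])
        assert len(truncate_at_gap(v, 200)) == 650

    def test_gap_beyond_merge_radius_truncates(self):
        v = np.concatenate([np.full(300, 5.0), np.zeros(250), np.full(200, 5.0)])
        assert len(truncate_at_gap(v, 200)) == 300

    def test_leading_gap_beyond_radius_empties_scan(self):
        v = np.concatenate([np.zeros(250), np.full(200, 5.0)])
        assert truncate_at_gap(v, 200).size == 0


class TestScanRegion:
    def make(self, strand="+", depth_len=3000):
        depth = np.zeros(10_000)
        gene = GeneModel("G", "chr7", strand, 4000, 5000,
                         5000 if strand == "+" else 4000, True)
        if strand == "+":
            depth[5000 : 5000 + depth_len] = 5.0
        else:
            depth[4000 - depth_len : 4000] = 5.0
        return CoverageTrack("chr7", 0, 10_000, depth), gene

    def test_plus_strand_simple_extent(self):
        track, gene = self.make("+", 300)
        v = scan_region(track, gene, [], P)
        assert len(v) == 300 and v[0] == 5.0

    def test_minus_strand_reads_reversed(self):
        track, gene = self.make("-", 300)
        v = scan_region(track, gene, [], P)
        assert len(v) == 300 and v[0] == 5.0  # utr_pos 1 = base just 5' of anchor

    def test_bounded_by_neighbor_cds_edge(self):
        track, gene = self.make("+", 4000)
        neighbor = GeneModel("N", "chr7", "+", 6500, 7000, 7000, True)
        v = scan_region(track, gene, [neighbor], P)
        assert len(v) == 1500

    def test_bounded_by_scan_cap(self):
        track, gene = self.make("+", 4900)
        v = scan_region(track, gene, [], SegmentationParams(scan_cap=1000))
        assert len(v) == 1000

    def test_anchor_at_region_edge_is_unannotatable(self):
        depth = np.ones(1000)
        gene = GeneModel("G", "chr7", "+", 500, 1000, 1000, True)
        track = CoverageTrack("chr7", 0, 1000, depth)
        assert scan_region(track, gene, [], P).size == 0


class TestFilterEnds:
    def end(self, pos):
        return TerminalEnd("G", pos, 10.0, 0.0)

    def test_very_short_flag_strictly_below_100(self):
        out = filter_ends([self.end(69), self.end(100), self.end(500)])
        assert [e.very_short for e in out] == [True, False, False]

    def test_empty_input(self):
        assert filter_ends([]) == []


@settings(deadline=None, max_examples=25)
@given(
    data=st.lists(
        st.tuples(st.floats(1, 200), st.integers(110, 400)), min_size=1, max_size=4
    ),
    pad=st.integers(0, 300),
)
def test_property_detector_equals_oracle_and_ignores_padding(data, pad):
    """Noiseless piecewise profiles: oracle equivalence and zero-padding invariance."""
    v = steps(*data)
    padded = np.concatenate([v, np.zeros(pad)])
    got = positions(segment_changepoints(padded, P))
    assert got == changepoints_naive(v)
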