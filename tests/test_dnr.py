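import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dimnp import (
    DNR,
    AnnotationScheme,
    annotate_dnrs,
    attach_fdr,
    call_dnrs,
    candidate_regions,
    filter_and_merge,
    finalize_dnrs,
)


def brute_force_filter_merge(intervals, min_len=10, merge_gap=5):
    """Independent re-statement of the two rules: drop length < min_len,
    then left-to-right merge gaps < merge_gap."""
    kept = [iv for iv in intervals if iv[1] - iv[0] >= min_len]
    out = []
    for iv in kept:
        if out and iv[0] - out[-1][1] < merge_gap:
            out[-1] = (out[-1][0], iv[1])
        else:
            out.append(iv)
    return out


def interval_sets(axis=100, max_intervals=4):
    """Sorted non-overlapping interval sets on [0, axis)."""

    @st.composite
    def _sets(draw):
        k = draw(st.integers(0, max_intervals))
        points = sorted(draw(st.lists(st.integers(0, axis), min_size=2 * k, max_size=2 * k, unique=True)))
        return [(points[2 * i], points[2 * i + 1]) for i in range(k)]

    return _sets()


class TestCandidateRegions:
    def test_runs_below_cutoff_detected(self, track_from_pvalues):
        track = track_from_pvalues([1, 1e-6, 1e-6, 1, 1e-7])
        assert candidate_regions(track, cutoff=1e-5) == [(1, 3), (4, 5)]

    def test_no_base_below_cutoff_gives_empty(self, track_from_pvalues):
        assert candidate_regions(track_from_pvalues([1.0] * 20)) == []

    def test_cutoff_one_spans_every_sub_one_base(self, track_from_pvalues):
        track = track_from_pvalues([0.5] * 10)
        assert candidate_regions(track, cutoff=1.0) == [(0, 10)]

    def test_cutoff_is_strict(self, track_from_pvalues):
        track = track_from_pvalues([1e-5, 1e-6])
        assert candidate_regions(track, cutoff=1e-5) == [(1, 2)]

    def test_invalid_cutoff_rejected(self, track_from_pvalues):
        with pytest.raises(ValueError):
            candidate_regions(track_from_pvalues([0.5]), cutoff=0.0)


class TestFilterAndMerge:
    def test_worked_example_drop_then_merge(self):
        assert filter_and_merge([(0, 8), (20, 40), (43, 60)]) == [(20, 60)]

    def test_gap_exactly_five_not_merged(self):
        assert filter_and_merge([(0, 15), (20, 35)]) == [(0, 15), (20, 35)]

    def test_length_exactly_ten_kept(self):
        assert filter_and_merge([(0, 10)]) == [(0, 10)]

    def test_length_nine_dropped(self):
        assert filter_and_merge([(0, 9)]) == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError):
            filter_and_merge([(20, 40), (0, 15)])

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError):
            filter_and_merge([(0, 20), (10, 40)])

    @given(interval_sets())
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, intervals):
        assert filter_and_merge(intervals) == brute_force_filter_merge(intervals)

    def test_exhaustive_small_axis(self):
        """Every sorted non-overlapping configuration of up to 3 intervals
        with endpoints on a coarse grid."""
        from itertools import combinations

        grid = list(range(0, 34, 3))
        count = 0
        for k in (1, 2, 3):
            for points in combinations(grid, 2 * k):
                ivs = [(points[2 * i], points[2 * i + 1]) for i in range(k)]
                assert filter_and_merge(ivs) == brute_force_filter_merge(ivs)
                count += 1
        assert count > 1000

    @given(interval_sets())
    @settings(max_examples=200, deadline=None)
    def test_output_invariants(self, intervals):
        out = filter_and_merge(intervals)
        for (s1, e1), (s2, e2) in zip(out, out[1:]):
            assert s2 - e1 >= 5
        assert all(e - s >= 10 for s, e in out)


class TestFinalizeDnrs:
    def test_center_is_midpoint(self, track_from_pvalues):
        track = track_from_pvalues([1e-7] * 200)
        (d,) = finalize_dnrs([(100, 160)], track)
        assert d.center == 130

    def test_representative_p_is_minimum(self, track_from_pvalues):
        p = np.ones(30)
        p[10:13] = [1e-6, 1e-9, 1e-7]
        (d,) = finalize_dnrs([(10, 13)], track_from_pvalues(p))
        assert d.p_value == pytest.approx(1e-9)

    def test_empty_interval_list(self, track_from_pvalues):
        assert finalize_dnrs([], track_from_pvalues([1.0])) == []

    def test_interval_outside_track_rejected(self, track_from_pvalues):
        with pytest.raises(ValueError, match="outside"):
            finalize_dnrs([(0, 50)], track_from_pvalues([1e-7] * 10))

    def test_ids_are_sequential(self, track_from_pvalues):
        track = track_from_pvalues([1e-7] * 100)
        dnrs = finalize_dnrs([(0, 20), (40, 60)], track)
        assert [d.id for d in dnrs] == ["DNR_chrT_1", "DNR_chrT_2"]


def _dnr(p, start=0):
    return DNR("chr1", start, start + 20, start + 10, p, float("nan"), f"d{start}")


class TestAttachFdr:
    def test_single_dnr_fdr_equals_p(self):
        (d,) = attach_fdr([_dnr(0.03)])
        assert d.fdr == pytest.approx(0.03)

    def test_ties_get_equal_fdr(self):
        out = attach_fdr([_dnr(0.01, 0), _dnr(0.01, 100)])
        assert out[0].fdr == pytest.approx(out[1].fdr)

    def test_hand_computed_step_down_example(self):
        out = attach_fdr([_dnr(p, i * 100) for i, p in enumerate((0.01, 0.02, 0.03, 0.04))])
        assert [d.fdr for d in out] == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_monotone_in_p_and_order_invariant(self):
        rng = np.random.default_rng(2)
        ps = rng.uniform(0, 1, 25)
        fwd = attach_fdr([_dnr(p, i * 100) for i, p in enumerate(ps)])
        order = np.argsort(ps)
        sorted_fdr = np.array([fwd[i].fdr for i in order])
        assert np.all(np.diff(sorted_fdr) >= -1e-12)
        rev = attach_fdr([_dnr(p, i * 100) for i, p in enumerate(ps[::-1])])
        assert fwd[0].fdr == pytest.approx(rev[-1].fdr)


class TestCallDnrs:
    def test_end_to_end_on_synthetic_track(self, track_from_pvalues):
        p = np.ones(200)
        p[50:80] = 1e-8   # kept
        p[82:95] = 1e-8   # merged in (gap 2)
        p[120:125] = 1e-8  # dropped (length 5)
        dnrs = call_dnrs(track_from_pvalues(p))
        assert [(d.start, d.end) for d in dnrs] == [(50, 95)]
        assert dnrs[0].p_value == pytest.approx(1e-8)
        assert dnrs[0].fdr == pytest.approx(1e-8)

    def test_determinism(self, track_from_pvalues):
        p = np.ones(500)
        p[100:140] = 1e-9
        track = track_from_pvalues(p)
        assert call_dnrs(track) == call_dnrs(track)


class TestAnnotateDnrs:
    @pytest.fixture
    def scheme(self):
        tss = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "tss": [10_000, 30_000],
                "strand": ["+", "-"],
                "gene_id": ["g1", "g2"],
            }
        )
        return AnnotationScheme(tss_table=tss)

    @pytest.fixture
    def gene_spans(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [10_000, 28_000],
                "end": [12_000, 30_000],
                "strand": ["+", "-"],
                "gene_id": ["g1", "g2"],
            }
        )

    def _dnr_at(self, center):
        return DNR("chr1", center - 30, center + 30, center, 1e-8, 1e-6, f"d{center}")

    def test_upstream_center_is_promoter(self, scheme, gene_spans):
        cats, _ = annotate_dnrs([self._dnr_at(10_000 - 100)], scheme, gene_spans)
        assert cats == ["promoter"]

    def test_gene_body_center_is_intragenic(self, scheme, gene_spans):
        cats, _ = annotate_dnrs([self._dnr_at(10_000 + 400)], scheme, gene_spans)
        assert cats == ["intragenic"]

    def test_minus_strand_promoter_window_is_oriented(self, scheme, gene_spans):
        # upstream of a minus-strand TSS means larger coordinates
        cats, _ = annotate_dnrs([self._dnr_at(30_000 + 400)], scheme, gene_spans)
        assert cats == ["promoter"]

    def test_far_center_is_intergenic_and_summary_fractions(self, scheme, gene_spans):
        dnrs = [self._dnr_at(50_000), self._dnr_at(10_000 - 100)]
        cats, summary = annotate_dnrs(dnrs, scheme, gene_spans)
        assert cats == ["intergenic", "promoter"]
        assert summary["fraction"].sum() == pytest.approx(1.0)
        assert summary.set_index("category").loc["promoter", "count"] == 1

    def test_unknown_chromosome_rejected(self, scheme, gene_spans):
        bad = DNR("chrX", 0, 60, 30, 1e-8, 1e-6, "d")
        with pytest.raises(ValueError, match="absent"):
            annotate_dnrs([bad], scheme, gene_spans)
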