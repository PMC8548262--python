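import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from methencroach import GenomeLayout, GenomicInterval
from methencroach.encroachment import (
    aggregate_class_profiles,
    bin_methylation,
    build_diff_matrix,
    detect_encroachment,
    prefilter_cgis,
    qualifying_cpg_ratios,
    rank_and_select,
    segment_profile,
    BinnedDiffTrack,
)

from conftest import make_track


def brute_force_segments(cgi, positions, ratios, n_segments=40):
    """Oracle: scan all segment intervals for membership of every CpG."""
    L = cgi.end - cgi.start
    values = np.full(n_segments, np.nan)
    for k in range(n_segments):
        # p in [start + kL/n, start + (k+1)L/n) <=> kL <= (p-start)*n < (k+1)L,
        # tested in exact integer arithmetic
        member = [r for p, r in zip(positions, ratios)
                  if cgi.start <= p < cgi.end
                  and k * L <= (p - cgi.start) * n_segments < (k + 1) * L]
        if member:
            values[k] = np.mean(member)
    return values


def diff_track(diffs, bin_width=40):
    """A one-chromosome BinnedDiffTrack with the given diff values."""
    d = np.asarray(diffs, dtype=float)
    wt = np.zeros_like(d)
    return BinnedDiffTrack(bin_width, {"chr1": (wt, wt + d, d)})


class TestBinning:
    def test_bin_means_and_difference(self):
        # CpGs at ratios WT {0.1, 0.3}, KO {0.6, 0.8} in one 40-bp bin
        wt = make_track([("chr1", 5, 1, 10), ("chr1", 25, 3, 10)])
        ko = make_track([("chr1", 5, 6, 10), ("chr1", 25, 8, 10)])
        genome = GenomeLayout((("chr1", 80),))
        binned = bin_methylation([wt], [ko], genome)
        w, k, d = binned.data["chr1"]
        assert w[0] == pytest.approx(0.2)
        assert k[0] == pytest.approx(0.7)
        assert d[0] == pytest.approx(0.5)

    def test_empty_bin_is_nan(self):
        wt = make_track([("chr1", 5, 1, 10)])
        ko = make_track([("chr1", 5, 6, 10)])
        genome = GenomeLayout((("chr1", 120),))
        binned = bin_methylation([wt], [ko], genome)
        w, k, d = binned.data["chr1"]
        assert np.isnan(w[2]) and np.isnan(k[2]) and np.isnan(d[2])  # [80,120) empty

    def test_low_coverage_replicate_excludes_site_everywhere(self):
        wt = [make_track([("chr1", 5, 1, 10)]), make_track([("chr1", 5, 1, 3)])]
        ko = [make_track([("chr1", 5, 6, 10)]), make_track([("chr1", 5, 6, 10)])]
        genome = GenomeLayout((("chr1", 40),))
        binned = bin_methylation(wt, ko, genome, min_cov=4)
        w, k, d = binned.data["chr1"]
        assert np.isnan(w[0]) and np.isnan(k[0]) and np.isnan(d[0])

    def test_condition_level_is_mean_of_replicate_ratios(self):
        wt = [make_track([("chr1", 5, 2, 10)]), make_track([("chr1", 5, 6, 10)])]
        ko = [make_track([("chr1", 5, 5, 10)]), make_track([("chr1", 5, 5, 10)])]
        sites = qualifying_cpg_ratios(wt, ko)
        assert sites.iloc[0]["wt"] == pytest.approx(0.4)  # (0.2 + 0.6) / 2

    def test_invalid_bin_width(self):
        genome = GenomeLayout((("chr1", 100),))
        t = make_track([("chr1", 5, 1, 10)])
        with pytest.raises(ValueError):
            bin_methylation([t], [t], genome, bin_width=0)


class TestPrefilter:
    CGI = [GenomicInterval("chr1", 0, 200, "c")]

    def test_passes_with_four_weak_and_one_strong(self):
        track = diff_track([0.30, 0.27, 0.26, 0.55, np.nan])
        assert prefilter_cgis(self.CGI, track) == self.CGI

    def test_fails_without_strong_bin(self):
        track = diff_track([0.30, 0.30, 0.30, 0.30, np.nan])
        assert prefilter_cgis(self.CGI, track) == []

    def test_fails_with_only_three_weak_bins(self):
        track = diff_track([0.60, 0.60, 0.60, np.nan, 0.10])
        assert prefilter_cgis(self.CGI, track) == []

    def test_overlap_includes_partial_bins(self):
        # CGI [35, 45) touches bins [0,40) and [40,80)
        cgi = [GenomicInterval("chr1", 35, 45, "edge")]
        track = diff_track([0.6, 0.6, 0.6])
        got = prefilter_cgis(cgi, track, min_bins=2)
        assert got == cgi


class TestSegmentProfile:
    def test_last_position_in_last_segment(self):
        cgi = GenomicInterval("chr1", 0, 400, "c")
        prof = segment_profile(cgi, np.array([399]), np.array([1.0]))
        assert prof[39] == 1.0 and np.isnan(prof[:39]).all()

    def test_single_cpg_assignment(self):
        # pos 3 in CGI [0,100): floor(3*40/100) = segment index 1
        cgi = GenomicInterval("chr1", 0, 100, "c")
        prof = segment_profile(cgi, np.array([3]), np.array([0.2]))
        expected = brute_force_segments(cgi, [3], [0.2])
        np.testing.assert_array_equal(np.isnan(prof), np.isnan(expected))
        assert prof[1] == pytest.approx(0.2)
        assert np.isnan(np.delete(prof, 1)).all()

    def test_constant_field_gives_constant_profile(self):
        cgi = GenomicInterval("chr1", 0, 400, "c")
        pos = np.arange(0, 400)
        prof = segment_profile(cgi, pos, np.full(400, 0.5))
        np.testing.assert_allclose(prof, 0.5)

    def test_cpgs_outside_island_ignored(self):
        cgi = GenomicInterval("chr1", 100, 200, "c")
        prof = segment_profile(cgi, np.array([50, 99, 200, 500]), np.ones(4))
        assert np.isnan(prof).all()

    @given(st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_brute_force_oracle(self, data):
        """Vectorised segmentation equals the per-CpG membership scan."""
        start = data.draw(st.integers(0, 5_000))
        length = data.draw(st.integers(1, 2_000))
        cgi = GenomicInterval("chr1", start, start + length, "c")
        n_cpg = data.draw(st.integers(0, 80))
        pos = data.draw(
            st.lists(st.integers(start - 50, start + length + 50),
                     min_size=n_cpg, max_size=n_cpg, unique=True)
        )
        pos = np.array(sorted(pos), dtype=np.int64)
        ratios = np.linspace(0, 1, len(pos)) if len(pos) else np.array([])
        got = segment_profile(cgi, pos, ratios)
        expected = brute_force_segments(cgi, pos, ratios)
        np.testing.assert_allclose(got, expected, atol=1e-12, equal_nan=True)

    def test_partition_each_inside_cpg_in_exactly_one_segment(self, rng):
        cgi = GenomicInterval("chr1", 1000, 1777, "c")
        pos = np.arange(900, 1900)
        L, n = 777, 40
        seg = (pos - 1000) * n // L
        inside = (pos >= 1000) & (pos < 1777)
        # each inside CpG lands in exactly one valid segment index
        assert ((seg[inside] >= 0) & (seg[inside] < n)).all()
        counts = np.bincount(seg[inside], minlength=n)
        assert counts.sum() == inside.sum()

    def test_zero_length_cgi_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10, "c")


class TestDiffMatrix:
    def _profiles(self, nan_count):
        vals = np.zeros(40)
        vals[:nan_count] = np.nan
        wt = pd.DataFrame([np.zeros(40)], index=["c"])
        ko = pd.DataFrame([vals], index=["c"])
        return wt, ko

    def test_thirty_one_nans_excluded(self):
        matrix, excluded = build_diff_matrix(*self._profiles(31))
        assert matrix.empty and list(excluded["name"]) == ["c"]

    def test_exactly_thirty_nans_retained(self):
        matrix, excluded = build_diff_matrix(*self._profiles(30))
        assert list(matrix.index) == ["c"] and excluded.empty

    def test_identical_profiles_give_zero_rows(self):
        prof = pd.DataFrame(np.random.default_rng(1).random((5, 40)),
                            index=[f"c{i}" for i in range(5)])
        matrix, _ = build_diff_matrix(prof, prof)
        assert (matrix.to_numpy() == 0).all()

    def test_nan_propagates_from_either_side(self):
        wt, ko = self._profiles(0)
        wt.iloc[0, 3] = np.nan
        matrix, _ = build_diff_matrix(wt, ko)
        assert np.isnan(matrix.iloc[0, 3])

    def test_mismatched_cgi_sets_rejected(self):
        wt = pd.DataFrame([np.zeros(40)], index=["a"])
        ko = pd.DataFrame([np.zeros(40)], index=["b"])
        with pytest.raises(ValueError):
            build_diff_matrix(wt, ko)


class TestRankAndSelect:
    def _separable_matrix(self):
        rows = {}
        a = np.zeros(40); a[:10] = 0.6
        b = np.zeros(40); b[10:30] = 0.6
        c = np.zeros(40); c[30:] = 0.6
        rows["A"], rows["B"], rows["C"] = a, b, c
        return pd.DataFrame.from_dict(rows, orient="index")

    def test_separable_rows_selected_by_matching_rankings(self):
        calls = rank_and_select(self._separable_matrix(), top_n=1)
        assert calls.loc["A", "selected_5prime"]
        assert calls.loc["B", "selected_central"]
        assert calls.loc["C", "selected_3prime"]
        assert calls.loc["A", "class"] == "5prime"
        assert calls.loc["B", "class"] == "bidirectional"
        assert calls.loc["C", "class"] == "3prime"

    def test_identical_rows_union_is_top_n(self):
        m = pd.DataFrame(np.full((6, 40), 0.3), index=[f"c{i}" for i in range(6)])
        calls = rank_and_select(m, top_n=3)
        assert len(calls) == 3
        # deterministic name tie-break
        assert list(calls.index) == ["c0", "c1", "c2"]

    def test_row_order_invariance(self):
        m = self._separable_matrix()
        a = rank_and_select(m, top_n=2)
        b = rank_and_select(m.iloc[::-1], top_n=2)
        pd.testing.assert_frame_equal(a.sort_index(), b.sort_index())

    def test_all_nan_span_disqualifies_single_ranking(self):
        m = self._separable_matrix()
        m.iloc[0, :10] = np.nan  # A loses its 5' score only
        calls = rank_and_select(m, top_n=3)
        assert np.isnan(calls.loc["A", "score_5prime"])
        assert not calls.loc["A", "selected_5prime"]
        assert not np.isnan(calls.loc["A", "score_central"])

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            rank_and_select(self._separable_matrix(), top_n=0)
        with pytest.raises(ValueError):
            rank_and_select(pd.DataFrame())


class TestAggregateProfiles:
    def test_single_member_class_equals_its_row(self):
        m = pd.DataFrame([np.linspace(0, 1, 40)], index=["A"])
        calls = pd.DataFrame({"class": ["5prime"]}, index=["A"])
        prof = aggregate_class_profiles(calls, m)
        np.testing.assert_allclose(prof.loc["5prime"].to_numpy(), m.loc["A"].to_numpy())

    def test_zero_matrix_gives_zero_curves(self):
        m = pd.DataFrame(np.zeros((4, 40)), index=list("abcd"))
        calls = pd.DataFrame({"class": ["5prime", "bidirectional", "3prime", "3prime"]},
                             index=list("abcd"))
        prof = aggregate_class_profiles(calls, m)
        assert (prof.to_numpy() == 0).all()

    def test_empty_class_omitted(self):
        m = pd.DataFrame(np.zeros((1, 40)), index=["a"])
        calls = pd.DataFrame({"class": ["5prime"]}, index=["a"])
        prof = aggregate_class_profiles(calls, m)
        assert list(prof.index) == ["5prime"]


class TestPipelineSignConvention:
    def test_planted_ko_hypermethylation_scores_positive(self, default_simulation):
        """Planting a gain in KO must surface as positive scores."""
        sim = default_simulation
        det = detect_encroachment(sim["wt"], sim["ko"], sim["cgis"], sim["genome"],
                                  top_n=20)
        calls = det["calls"]
        assert len(calls) > 0
        scores = calls[["score_5prime", "score_central", "score_3prime"]].to_numpy()
        assert np.nanmax(scores, axis=1).min() > 0

    def test_planted_5prime_class_curve_decreases_rightward(self, default_simulation):
        sim = default_simulation
        det = detect_encroachment(sim["wt"], sim["ko"], sim["cgis"], sim["genome"],
                                  top_n=20)
        prof = det["class_profiles"]
        assert "5prime" in prof.index
        curve = prof.loc["5prime"].to_numpy(dtype=float)
        # maximal near the 5' end, decaying toward the 3' end
        assert np.nanmean(curve[:10]) > np.nanmean(curve[10:30]) > np.nanmean(curve[30:])
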