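import numpy as np
import pandas as pd
import pytest

from methencroach import (
    count_fragments,
    differential_binding,
    intersect_signatures,
    reproducible_peaks,
    union_across_antibodies,
)
from methencroach.peaks import merge_intervals


def frags(intervals):
    return pd.DataFrame(intervals, columns=["chrom", "start", "end"])


def brute_force_reproducible(replicates, max_pos=3_000):
    """Per-base oracle: maximal union-coverage intervals containing at
    least one base covered by every replicate."""
    union_cov = np.zeros(max_pos, dtype=bool)
    all_cov = np.ones(max_pos, dtype=bool)
    for rep in replicates:
        cov = np.zeros(max_pos, dtype=bool)
        for _, s, e in rep:
            cov[s:e] = True
        union_cov |= cov
        all_cov &= cov
    out = []
    i = 0
    while i < max_pos:
        if union_cov[i]:
            j = i
            while j < max_pos and union_cov[j]:
                j += 1
            if all_cov[i:j].any():
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


class TestReproduciblePeaks:
    def test_overlapping_replicates_merge(self):
        rep1 = [("chr1", 100, 200)]
        rep2 = [("chr1", 150, 250)]
        out = reproducible_peaks([rep1, rep2])
        assert [(r.Chromosome, r.Start, r.End) for r in out.itertuples()] == \
            [("chr1", 100, 250)]

    def test_disjoint_replicates_empty(self):
        out = reproducible_peaks([[("chr1", 100, 200)], [("chr1", 300, 400)]])
        assert out.empty

    def test_single_replicate_returns_high_confidence_unchanged(self):
        hc = [("chr1", 0, 50, "p1")]
        out = reproducible_peaks([hc])
        assert [(r.Chromosome, r.Start, r.End) for r in out.itertuples()] == \
            [("chr1", 0, 50)]

    def test_empty_replicate_list_rejected(self):
        with pytest.raises(ValueError):
            reproducible_peaks([])

    def test_matches_per_base_oracle_random_instances(self, rng):
        for _ in range(60):
            n_reps = int(rng.integers(2, 5))
            reps = []
            for _ in range(n_reps):
                n = int(rng.integers(0, 8))
                rep = []
                for _ in range(n):
                    s = int(rng.integers(0, 2_500))
                    rep.append(("chr1", s, s + int(rng.integers(1, 300))))
                reps.append(rep)
            got = reproducible_peaks(reps)
            expected = brute_force_reproducible(reps)
            assert [(r.Start, r.End) for r in got.itertuples()] == expected

    def test_all_covered_bases_never_grow_with_extra_replicate(self, rng):
        """The set of bases supported by every replicate is anti-monotone."""
        for _ in range(20):
            reps = []
            for _ in range(3):
                s = int(rng.integers(0, 1_000))
                reps.append([("chr1", s, s + int(rng.integers(50, 400)))])

            def covered(replicates):
                cov = np.ones(2_000, dtype=bool)
                for rep in replicates:
                    c = np.zeros(2_000, dtype=bool)
                    for _, s, e in rep:
                        c[s:e] = True
                    cov &= c
                return cov

            assert not (covered(reps) & ~covered(reps[:2])).any()


class TestOccupancy:
    def test_rpkm_closed_form(self):
        peaks = [("chr1", 0, 1_000, "p1")]
        far = np.full(10**6 - 10, 500_000)
        lib = pd.DataFrame({"chrom": "chr1",
                            "start": np.concatenate([np.full(10, 100), far]),
                            "end": np.concatenate([np.full(10, 300), far + 100])})
        occ = count_fragments(peaks, {"s": lib})
        assert occ.library_sizes["s"] == 10**6
        assert occ.counts.loc["p1", "s"] == 10
        assert occ.rpkm.loc["p1", "s"] == pytest.approx(10.0)

    def test_abutting_fragment_not_counted(self):
        peaks = [("chr1", 0, 1_000, "p1")]
        occ = count_fragments(peaks, {"s": frags([("chr1", 1_000, 1_200),
                                                  ("chr1", 999, 1_200)])})
        assert occ.counts.loc["p1", "s"] == 1  # half-open: [1000,1200) misses

    def test_scale_invariance(self):
        peaks = [("chr1", 0, 500, "p1")]
        base = [("chr1", 10, 110)] * 7 + [("chr1", 9_000, 9_100)] * 93
        occ1 = count_fragments(peaks, {"s": frags(base)})
        occ3 = count_fragments(peaks, {"s": frags(base * 3)})
        assert occ1.rpkm.loc["p1", "s"] == pytest.approx(occ3.rpkm.loc["p1", "s"])

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError, match="library"):
            count_fragments([("chr1", 0, 500, "p1")], {"s": frags([])})


class TestDifferentialBinding:
    def _occ(self, counts_per_peak, names=("p1",)):
        peaks = [("chr1", 1_000 * i, 1_000 * i + 1_000, n) for i, n in enumerate(names)]
        lib = []
        for i, count in enumerate(counts_per_peak):
            lib += [("chr1", 1_000 * i + 10, 1_000 * i + 110)] * int(count)
        pad = [("chr1", 900_000, 900_100)] * (10_000 - len(lib))
        return count_fragments(peaks, {"s": frags(lib + pad)})

    def test_fourfold_gain_is_up(self):
        # KO 8x vs WT 2x RPKM at equal library size
        out = differential_binding(self._occ([8]), self._occ([2]), pseudocount=0)
        assert out.iloc[0]["fold_change"] == pytest.approx(4.0)
        assert out.iloc[0]["direction"] == "up"

    def test_equal_occupancy_unchanged(self):
        out = differential_binding(self._occ([2]), self._occ([2]))
        assert out.iloc[0]["direction"] == "unchanged"

    def test_exact_threshold_is_unchanged(self):
        # fold-change must be strictly higher than the threshold
        out = differential_binding(self._occ([4]), self._occ([2]), pseudocount=0)
        assert out.iloc[0]["fold_change"] == pytest.approx(2.0)
        assert out.iloc[0]["direction"] == "unchanged"

    def test_mismatched_peaks_rejected(self):
        with pytest.raises(ValueError):
            differential_binding(self._occ([2]), self._occ([2, 2], names=("p1", "p2")))


class TestUnionIntersect:
    def _calls(self, rows):
        return pd.DataFrame(rows, columns=["Chromosome", "Start", "End", "direction"])

    def test_down_sets_merge_across_antibodies(self):
        a = self._calls([("chr1", 0, 100, "down")])
        b = self._calls([("chr1", 50, 150, "down")])
        out = union_across_antibodies([a, b])
        assert [(r.Chromosome, r.Start, r.End, r.direction) for r in out.itertuples()] == \
            [("chr1", 0, 150, "down")]

    def test_single_antibody_identity(self):
        a = self._calls([("chr1", 0, 100, "up"), ("chr1", 500, 600, "down")])
        out = union_across_antibodies([a])
        assert len(out) == 2

    def test_disjoint_up_sets_concatenate(self):
        a = self._calls([("chr1", i * 1_000, i * 1_000 + 100, "up") for i in range(3)])
        b = self._calls([("chr2", i * 1_000, i * 1_000 + 100, "up") for i in range(4)])
        out = union_across_antibodies([a, b])
        assert len(out) == 7

    def test_intersection_returns_overlap_portion_with_parents(self):
        out = intersect_signatures([("chr1", 0, 100, "a1")], [("chr1", 50, 150, "b1")])
        row = out.iloc[0]
        assert (row["Start"], row["End"]) == (50, 100)
        assert row["ParentsA"] == "a1" and row["ParentsB"] == "b1"

    def test_disjoint_sets_intersect_empty(self):
        out = intersect_signatures([("chr1", 0, 100, "a")], [("chr1", 200, 300, "b")])
        assert out.empty

    def test_subset_intersection_is_subset(self):
        a = [("chr1", 10, 90, "a")]
        b = [("chr1", 0, 100, "b")]
        out = intersect_signatures(a, b)
        assert [(r.Start, r.End) for r in out.itertuples()] == [(10, 90)]

    def test_intersection_commutes_and_is_idempotent(self, rng):
        def random_set(tag):
            out = []
            for i in range(int(rng.integers(1, 6))):
                s = int(rng.integers(0, 2_000))
                out.append(("chr1", s, s + int(rng.integers(1, 400)), f"{tag}{i}"))
            return out

        for _ in range(25):
            a, b = random_set("a"), random_set("b")
            ab = intersect_signatures(a, b)[["Chromosome", "Start", "End"]]
            ba = intersect_signatures(b, a)[["Chromosome", "Start", "End"]]
            pd.testing.assert_frame_equal(ab, ba)
            aa = intersect_signatures(a, a)[["Chromosome", "Start", "End"]]
            merged_a = merge_intervals(
                pd.DataFrame(a, columns=["Chromosome", "Start", "End", "Name"]))
            pd.testing.assert_frame_equal(aa, merged_a)
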