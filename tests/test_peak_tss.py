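import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from tftarget.genome_io import GeneModel, Peak
from tftarget.peak_tss import (
    assign_nearest_tss,
    distance_histogram,
    pool_peaks,
    promoter_fraction,
    promoter_occupancy,
)


def mk_peak(start, end, chrom="chr1", name="p"):
    return Peak(chrom=chrom, start=start, end=end, name=name)


def mk_gene(gene_id, tss, strand="+", chrom="chr1"):
    if strand == "+":
        return GeneModel(gene_id, gene_id, chrom, strand, tss, tss + 1000)
    return GeneModel(gene_id, gene_id, chrom, strand, max(tss - 999, 0), tss + 1)


def brute_force_merge(peak_sets, merge_gap=0):
    """Per-base occupancy scan oracle for union merging (gap<=merge_gap joins)."""
    by_chrom = {}
    for ps in peak_sets:
        for p in ps:
            by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    out = {}
    for chrom, ivs in by_chrom.items():
        hi = max(e for _, e in ivs)
        occupied = np.zeros(hi + merge_gap + 2, dtype=bool)
        for s, e in ivs:
            occupied[s:e] = True
        # positions whose gap to the next occupied base is <= merge_gap act as joined
        merged = []
        pos = 0
        idx = np.flatnonzero(occupied)
        start = prev = None
        for i in idx:
            if start is None:
                start = prev = i
            elif i - (prev + 1) <= merge_gap:
                prev = i
            else:
                merged.append((start, prev + 1))
                start = prev = i
        merged.append((start, prev + 1))
        out[chrom] = merged
    return out


class TestPoolPeaks:
    def test_single_disjoint_set_is_identity(self):
        peaks = [mk_peak(100, 200), mk_peak(300, 400)]
        pooled = pool_peaks([peaks], mode="union_merge", merge_gap=0)
        assert [(p.start, p.end) for p in pooled] == [(100, 200), (300, 400)]

    def test_overlap_merges_to_single_locus(self):
        pooled = pool_peaks([[mk_peak(100, 200)], [mk_peak(150, 250)]], merge_gap=0)
        assert [(p.start, p.end) for p in pooled] == [(100, 250)]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pool_peaks([])
        with pytest.raises(ValueError):
            pool_peaks([[], []])

    def test_intersection_requires_every_set(self):
        s1 = [mk_peak(100, 200), mk_peak(500, 600)]
        s2 = [mk_peak(150, 250)]
        pooled = pool_peaks([s1, s2], mode="intersection")
        assert [(p.start, p.end) for p in pooled] == [(100, 250)]

    @pytest.mark.parametrize("merge_gap", [0, 5, 50])
    def test_union_merge_matches_base_occupancy_oracle(self, merge_gap):
        rng = np.random.default_rng(42 + merge_gap)
        sets = []
        for _ in range(3):
            starts = rng.integers(0, 5000, size=30)
            sets.append([mk_peak(int(s), int(s + rng.integers(1, 120))) for s in starts])
        pooled = pool_peaks(sets, merge_gap=merge_gap)
        expected = brute_force_merge(sets, merge_gap)["chr1"]
        assert [(p.start, p.end) for p in pooled] == expected

    def test_merged_loci_disjoint_and_coverage_preserved(self):
        rng = np.random.default_rng(7)
        peaks = [mk_peak(int(s), int(s) + int(w)) for s, w in zip(rng.integers(0, 3000, 50), rng.integers(1, 100, 50))]
        pooled = pool_peaks([peaks], merge_gap=0)
        for a, b in zip(pooled, pooled[1:]):
            assert a.end < b.start  # strictly disjoint, not even touching
        cover = np.zeros(4000, dtype=bool)
        for p in peaks:
            cover[p.start:p.end] = True
        pooled_cover = np.zeros(4000, dtype=bool)
        for p in pooled:
            pooled_cover[p.start:p.end] = True
        assert (cover == pooled_cover).all()


class TestAssignNearestTss:
    def test_midpoint_at_tss_gives_zero(self):
        genes = [mk_gene("g1", 10_000)]
        res = assign_nearest_tss([mk_peak(9_500, 10_500)], genes)
        assert res.assignments[0].distance == 0

    def test_sign_convention_mirror(self):
        genes = [mk_gene("g1", 10_000, strand="+")]
        peak = mk_peak(9_400, 9_600)  # midpoint 9500, upstream of + strand tss
        neg = assign_nearest_tss([peak], genes, sign_convention="upstream_negative")
        pos = assign_nearest_tss([peak], genes, sign_convention="upstream_positive")
        assert neg.assignments[0].distance == -500
        assert pos.assignments[0].distance == +500

    def test_minus_strand_orientation(self):
        genes = [mk_gene("g1", 10_000, strand="-")]
        peak = mk_peak(10_400, 10_600)  # midpoint 10500: upstream in reading direction
        res = assign_nearest_tss([peak], genes, sign_convention="upstream_negative")
        assert res.assignments[0].distance == -500

    def test_equidistant_tie_breaks_to_smallest_gene_id(self):
        genes = [mk_gene("gB", 10_000), mk_gene("gA", 11_000)]
        peak = mk_peak(10_400, 10_600)  # midpoint 10500, both TSSs 500 away
        res = assign_nearest_tss([peak], genes)
        assert res.assignments[0].gene_id == "gA"

    def test_summit_reference_point(self):
        genes = [mk_gene("g1", 10_000)]
        peak = Peak(chrom="chr1", start=9_000, end=9_800, name="p", summit_offset=700)
        res = assign_nearest_tss([peak], genes, reference_point="summit")
        assert res.assignments[0].distance == 9_700 - 10_000

    def test_nearest_edge_uses_tss_closest_edge(self):
        genes = [mk_gene("g1", 10_000)]
        peak = mk_peak(9_000, 9_500)
        res = assign_nearest_tss([peak], genes, reference_point="nearest_edge")
        assert res.assignments[0].distance == 9_499 - 10_000

    def test_peak_on_unknown_chromosome_reported_unassigned(self):
        res = assign_nearest_tss(
            [mk_peak(0, 100, chrom="chr9"), mk_peak(100, 200)], [mk_gene("g1", 5_000)]
        )
        assert len(res.assignments) == 1
        assert len(res.unassigned) == 1
        assert res.unassigned[0].chrom == "chr9"

    def test_no_genes_rejected(self):
        with pytest.raises(ValueError):
            assign_nearest_tss([mk_peak(0, 10)], [])

    def test_no_shared_chromosome_rejected(self):
        with pytest.raises(ValueError, match="share no chromosome"):
            assign_nearest_tss([mk_peak(0, 10, chrom="chr5")], [mk_gene("g1", 100)])

    def test_unknown_options_rejected(self):
        with pytest.raises(ValueError):
            assign_nearest_tss([mk_peak(0, 10)], [mk_gene("g1", 100)], sign_convention="bogus")
        with pytest.raises(ValueError):
            assign_nearest_tss([mk_peak(0, 10)], [mk_gene("g1", 100)], reference_point="bogus")

    def test_matches_exhaustive_search_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(5):
            genes = [
                mk_gene(f"g{i:03d}", int(t), strand=rng.choice(["+", "-"]))
                for i, t in enumerate(rng.choice(1_000_000, size=50, replace=False))
            ]
            peaks = [mk_peak(int(s), int(s) + 200, name=f"p{j}") for j, s in enumerate(rng.integers(0, 999_800, 200))]
            res = assign_nearest_tss(peaks, genes)
            by_name = {a.peak.name: a for a in res.assignments}
            for peak in peaks:
                p = (peak.start + peak.end) // 2
                dists = {g.gene_id: abs(p - g.tss) for g in genes}
                dmin = min(dists.values())
                expected_gene = min(gid for gid, d in dists.items() if d == dmin)
                a = by_name[peak.name]
                assert a.gene_id == expected_gene
                assert abs(a.distance) == dmin

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        genes = [mk_gene(f"g{i}", int(t)) for i, t in enumerate(rng.choice(100_000, 20, replace=False))]
        peaks = [mk_peak(int(s), int(s) + 100, name=f"p{j}") for j, s in enumerate(rng.integers(0, 99_900, 40))]
        base = {a.peak.name: (a.gene_id, a.distance) for a in assign_nearest_tss(peaks, genes).assignments}
        shuffled = {
            a.peak.name: (a.gene_id, a.distance)
            for a in assign_nearest_tss(peaks[::-1], genes[::-1]).assignments
        }
        assert base == shuffled


class TestDistanceHistogram:
    @staticmethod
    def _assignments(distances):
        genes = [mk_gene("g1", 100_000)]
        peaks = []
        for i, d in enumerate(distances):
            mid = 100_000 + d
            peaks.append(mk_peak(mid - 50, mid + 50, name=f"p{i}"))
        return assign_nearest_tss(peaks, genes)

    def test_all_zero_distances_fill_one_bin(self):
        res = self._assignments([0, 0, 0])
        hist = distance_histogram(res, bin_width=100, max_bp=200)
        assert hist.counts[50.0] == 3
        assert sum(hist.counts.values()) == 3

    def test_hand_counted_bins(self):
        res = self._assignments([-150, -50, 50])
        hist = distance_histogram(res, bin_width=100, max_bp=200)
        assert hist.counts[-150.0] == 1
        assert hist.counts[-50.0] == 1
        assert hist.counts[50.0] == 1
        assert hist.n_out_of_range == 0

    def test_counts_conserved_with_out_of_range(self):
        res = self._assignments([-500, -150, 0, 75, 900])
        hist = distance_histogram(res, bin_width=100, max_bp=200)
        assert sum(hist.counts.values()) + hist.n_out_of_range == hist.n_total == 5
        assert hist.n_upstream == 2 and hist.n_downstream == 2 and hist.n_zero == 1

    def test_invalid_binning_rejected(self):
        res = self._assignments([0])
        with pytest.raises(ValueError):
            distance_histogram(res, bin_width=0, max_bp=200)
        with pytest.raises(ValueError):
            distance_histogram(res, bin_width=300, max_bp=200)


class TestPromoterFraction:
    def test_all_at_tss_gives_one(self):
        res = TestDistanceHistogram._assignments([0, 0])
        assert promoter_fraction(res, window=2000).fraction == 1.0

    def test_all_outside_window_gives_zero(self):
        res = TestDistanceHistogram._assignments([5000, -4000])
        assert promoter_fraction(res, window=2000).fraction == 0.0

    def test_window_boundary_is_inclusive(self):
        res = TestDistanceHistogram._assignments([2000, -2000, 2001])
        stats = promoter_fraction(res, window=2000)
        assert stats.n_within == 2
        assert stats.fraction == pytest.approx(2 / 3)

    def test_no_assignments_rejected(self):
        from tftarget.peak_tss import AssignmentSet

        with pytest.raises(ValueError):
            promoter_fraction(AssignmentSet(assignments=[], unassigned=[]), 2000)


class TestPromoterOccupancy:
    def test_proximal_assignment_marks_bound(self):
        res = TestDistanceHistogram._assignments([152])
        occ = promoter_occupancy(res, window=2000)
        assert bool(occ.loc["g1", "bound"]) is True
        assert occ.loc["g1", "best_distance"] == 152

    def test_long_range_assignment_not_bound_but_kept(self):
        genes = [mk_gene("g1", 100_000)]
        peak = mk_peak(621_121, 621_221)  # 521,171 bp downstream of the TSS
        res = assign_nearest_tss([peak], genes)
        occ = promoter_occupancy(res, window=2000)
        assert bool(occ.loc["g1", "bound"]) is False
        assert occ.loc["g1", "best_distance"] == 521_171

    def test_best_distance_minimizes_absolute_value(self):
        res = TestDistanceHistogram._assignments([500, -100])
        occ = promoter_occupancy(res, window=2000)
        assert occ.loc["g1", "best_distance"] == -100

    def test_tie_between_signs_prefers_upstream(self):
        res = TestDistanceHistogram._assignments([300, -300])
        occ = promoter_occupancy(res, window=2000)
        assert occ.loc["g1", "best_distance"] == -300

    def test_unbound_genes_listed_when_gene_set_given(self):
        genes = [mk_gene("g1", 100_000), mk_gene("g2", 900_000)]
        res = assign_nearest_tss([mk_peak(99_950, 100_050)], genes)
        occ = promoter_occupancy(res, window=2000, genes=genes)
        assert bool(occ.loc["g2", "bound"]) is False
        assert pd.isna(occ.loc["g2", "best_distance"])
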