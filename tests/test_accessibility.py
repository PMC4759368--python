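"""MaxD normalization, replicate concordance, differential tests, Venns."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dhslink import accessibility as acc
from dhslink.types import GeneModel
from conftest import make_set, random_intervals


class TestNormalizeMaxd:
    @pytest.mark.parametrize(
        "raw, depth, expected",
        [(12, 10_000_000, 12.0), (12, 5_000_000, 24.0), (0, 123, 0.0)],
    )
    def test_reference_depth_scaling(self, raw, depth, expected):
        assert acc.normalize_maxd(raw, depth) == expected

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            acc.normalize_maxd(5, 0)

    @given(raw=st.integers(0, 10_000), k=st.integers(1, 50),
           depth=st.integers(1, 10**8))
    @settings(max_examples=100, deadline=None)
    def test_linearity_in_raw_counts(self, raw, k, depth):
        assert acc.normalize_maxd(raw * k, depth) == pytest.approx(
            k * acc.normalize_maxd(raw, depth)
        )


class TestReplicateConcordant:
    def test_identical_sets_pass_through(self):
        ivs = [("chr1", 0, 100), ("chr1", 500, 700)]
        r1 = make_set(ivs, "A", "r1")
        r2 = make_set(ivs, "A", "r2")
        rc = acc.replicate_concordant(r1, r2)
        assert [(h.chrom, h.start, h.end) for h in rc.sites] == ivs

    def test_disjoint_replicates_give_empty_set(self):
        r1 = make_set([("chr1", 0, 100)], "A", "r1")
        r2 = make_set([("chr1", 200, 300)], "A", "r2")
        assert len(acc.replicate_concordant(r1, r2)) == 0

    def test_overlap_merges_to_union(self):
        r1 = make_set([("chr1", 0, 100)], "A", "r1", raws=[8])
        r2 = make_set([("chr1", 50, 150)], "A", "r2", raws=[12])
        rc = acc.replicate_concordant(r1, r2)
        (h,) = rc.sites
        assert (h.start, h.end) == (0, 150)
        assert h.raw_pair == (8, 12)
        # mean of the two per-replicate normalized MaxD values
        assert h.norm_maxd == pytest.approx((8.0 + 12.0) / 2)

    def test_commutative_in_replicates(self):
        rng = np.random.default_rng(5)
        r1 = make_set(random_intervals(rng, 40), "A", "r1")
        r2 = make_set(random_intervals(rng, 40), "A", "r2")
        a = acc.replicate_concordant(r1, r2)
        b = acc.replicate_concordant(r2, r1)
        assert [(h.chrom, h.start, h.end, h.norm_maxd) for h in a.sites] == [
            (h.chrom, h.start, h.end, h.norm_maxd) for h in b.sites
        ]

    def test_mixed_conditions_rejected(self):
        r1 = make_set([("chr1", 0, 100)], "A")
        r2 = make_set([("chr1", 0, 100)], "B")
        with pytest.raises(ValueError, match="condition"):
            acc.replicate_concordant(r1, r2)


class TestMaxdDifferenceTest:
    def test_equal_counts_equal_depths_central(self):
        p, sig = acc.maxd_difference_test(15, 10**7, 15, 10**7)
        assert p == pytest.approx(1.0)
        assert not sig

    def test_one_sided_extreme_exact_tail(self):
        p, sig = acc.maxd_difference_test(30, 10**7, 0, 10**7)
        assert p == pytest.approx(2 * 0.5**30, rel=1e-9)
        assert sig

    def test_empty_counts_give_p_one(self):
        p, sig = acc.maxd_difference_test(0, 10**7, 0, 10**7)
        assert (p, sig) == (1.0, False)

    def test_depth_offset_shifts_null(self):
        # 20 vs 10 at 2:1 depths is exactly the null expectation
        p, sig = acc.maxd_difference_test(20, 2 * 10**7, 10, 10**7)
        assert p > 0.5
        assert not sig


def brute_force_mask(sites, other_sets):
    """O(n^2) overlap oracle: membership mask per site across set lists."""
    masks = []
    for h in sites:
        mask = ""
        for sset in other_sets:
            hit = any(
                h.chrom == o.chrom and h.start < o.end and o.start < h.end
                for o in sset.sites
            )
            mask += "1" if hit else "0"
        masks.append(mask)
    return masks


class TestCompareTwo:
    def test_identical_sets_all_common(self):
        s = make_set([("chr1", 0, 100), ("chr1", 500, 700)], "A")
        t = make_set([("chr1", 0, 100), ("chr1", 500, 700)], "B")
        venn, diffs = acc.compare_two(s, t)
        assert venn.region_counts == {"11": 4}
        assert all(d.status.startswith("common") for d in diffs)

    def test_worked_partition_example(self):
        a = make_set([("chr1", 0, 100), ("chr1", 200, 300)], "A")
        b = make_set([("chr1", 50, 150)], "B")
        venn, diffs = acc.compare_two(a, b)
        assert venn.region_counts == {"11": 2, "10": 1}
        statuses = sorted(d.status for d in diffs)
        assert statuses.count("unique_a") == 1
        merged = [d for d in diffs if d.status.startswith("common")]
        assert len(merged) == 1 and (merged[0].start, merged[0].end) == (0, 150)

    def test_disjoint_sets_all_unique(self):
        a = make_set([("chr1", 0, 100)], "A")
        b = make_set([("chr2", 0, 100)], "B")
        venn, diffs = acc.compare_two(a, b)
        assert venn.region_counts == {"10": 1, "01": 1}
        assert sorted(d.status for d in diffs) == ["unique_a", "unique_b"]

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = make_set(random_intervals(rng, 120), "A")
        b = make_set(random_intervals(rng, 120), "B")
        venn, diffs = acc.compare_two(a, b)
        for sites, idx, other in ((a.sites, 0, b), (b.sites, 1, a)):
            oracle = brute_force_mask(sites, [other])
            for h, hit in zip(sites, oracle):
                expected = "11" if hit == "1" else ("10" if idx == 0 else "01")
                assert venn.assignments[(idx, h.site_id)] == expected
        # every input site assigned exactly once
        assert len(venn.assignments) == len(a.sites) + len(b.sites)
        assert venn.per_set_total(0) == len(a.sites)
        assert venn.per_set_total(1) == len(b.sites)

    def test_delta_sign_is_b_minus_a(self):
        a = make_set([("chr1", 0, 100)], "A", raws=[10])
        b = make_set([("chr1", 0, 100)], "B", raws=[30])
        _venn, (d,) = acc.compare_two(a, b)
        assert d.delta_norm_maxd == pytest.approx(20.0)


class TestCompareThree:
    def test_identical_sets_triple_common(self):
        ivs = [("chr1", 0, 100), ("chr1", 400, 500)]
        sets = [make_set(ivs, c) for c in "ABC"]
        venn, uniques = acc.compare_three(*sets)
        assert venn.region_counts == {"111": 6}
        assert all(not v for v in uniques.values())

    def test_pairwise_disjoint_pure_uniques(self):
        a = make_set([("chr1", 0, 100)], "A")
        b = make_set([("chr1", 200, 300)], "B")
        c = make_set([("chr2", 0, 100)], "C")
        venn, uniques = acc.compare_three(a, b, c)
        assert venn.region_counts == {"100": 1, "010": 1, "001": 1}
        assert {k: len(v) for k, v in uniques.items()} == {"A": 1, "B": 1, "C": 1}

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        sets = [make_set(random_intervals(rng, 150), c) for c in "ABC"]
        venn, _uniques = acc.compare_three(*sets)
        for idx, s in enumerate(sets):
            others = [sets[j] for j in range(3) if j != idx]
            oracle = brute_force_mask(s.sites, others)
            for h, hits in zip(s.sites, oracle):
                mask = list(hits)
                mask.insert(idx, "1")
                assert venn.assignments[(idx, h.site_id)] == "".join(mask)
        assert sum(venn.region_counts.values()) == sum(len(s.sites) for s in sets)


class TestTopChangedSites:
    def _diffs(self, deltas, starts, chrom="chr1"):
        from dhslink.types import DifferentialSite

        return [
            DifferentialSite(
                chrom=chrom, start=s, end=s + 100, condition_a="A",
                condition_b="B", count_a=1, count_b=1, depth_a=1, depth_b=1,
                norm_a=0, norm_b=0, delta_norm_maxd=d, p_value=0.5,
                status="unique_b",
            )
            for d, s in zip(deltas, starts)
        ]

    def test_returns_all_when_fewer_than_n(self, simple_genes):
        diffs = self._diffs([5.0, -3.0], [99_500, 100_500])
        assert len(acc.top_changed_sites(diffs, simple_genes, n=1500)) == 2

    def test_tss_flank_excludes_distal_sites(self, simple_genes):
        # GA TSS at 100_000; a site 2 kb away with flank 1 kb is excluded
        diffs = self._diffs([9.0], [102_000])
        assert acc.top_changed_sites(diffs, simple_genes, tss_flank=1000) == []

    def test_equal_magnitude_ties_broken_by_position(self, simple_genes):
        diffs = self._diffs([4.0, -4.0], [100_500, 99_500])
        top = acc.top_changed_sites(diffs, simple_genes, n=1)
        assert top[0].start == 99_500


class TestExportMotifWindows:
    def _site(self, start, end, peak=None, chrom="chr1"):
        from dhslink.types import DifferentialSite

        return DifferentialSite(
            chrom=chrom, start=start, end=end, condition_a="A", condition_b="B",
            count_a=1, count_b=1, depth_a=1, depth_b=1, norm_a=0, norm_b=0,
            delta_norm_maxd=1.0, p_value=0.5, status="unique_b",
            site_ids_a=("x",), peak_pos=peak,
        )

    def test_window_centered_on_peak(self):
        rows = acc.export_motif_windows(
            [self._site(1000, 1100, peak=1050)], {"chr1": 10_000}
        )
        assert rows[0][1:3] == (950, 1150)

    def test_clipped_at_chromosome_start_with_flag(self):
        rows = acc.export_motif_windows(
            [self._site(20, 120, peak=50)], {"chr1": 10_000}
        )
        chrom, start, end, _label, clipped = rows[0]
        assert (start, end, clipped) == (0, 200, True)

    def test_odd_width_and_unknown_chrom_rejected(self):
        with pytest.raises(ValueError, match="even"):
            acc.export_motif_windows([self._site(0, 10)], {"chr1": 100}, width=201)
        with pytest.raises(ValueError, match="chromosome"):
            acc.export_motif_windows(
                [self._site(0, 10, chrom="chrX")], {"chr1": 100}
            )
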