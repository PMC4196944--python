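"""Pooled-heterozygosity windows, the -log2 transform, and sweep calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poolsweep import (
    GeneFeature,
    annotate_sweeps,
    call_sweeps,
    transform_hp,
    window_hp,
)
from poolsweep.snp_calling import SnpRecord
from poolsweep.sweep_scan import WindowStat


def dom_snp(pos, major, minor, chrom="chr1"):
    """A SNP with a single (domestic) pool of reads."""
    return SnpRecord(
        chrom=chrom, pos=pos, major_allele="A", minor_allele="G",
        per_pool_major=np.array([major]), per_pool_minor=np.array([minor]),
        total_depth=major + minor, maf=minor / (major + minor),
    )


def window(chrom, start, hp, transformed, n=6):
    return WindowStat(
        chrom=chrom, start=start, end=start + 20_000, n_snps=n,
        sum_maj=100, sum_min=10, hp=hp, hp_transformed=transformed,
    )


class TestTransform:
    def test_maximal_heterozygosity(self):
        assert transform_hp(0.5) == pytest.approx(1.0)

    @pytest.mark.parametrize("hp,score", [(0.012, 6.38), (0.058, 4.11), (0.062, 4.01)])
    def test_reported_scores_at_two_decimals(self, hp, score):
        assert round(transform_hp(hp), 2) == score

    def test_fixed_window_gets_cap(self):
        assert transform_hp(0.0) == 7.0
        assert transform_hp(0.0, cap=9.0) == 9.0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            transform_hp(0.6)
        with pytest.raises(ValueError):
            transform_hp(-0.01)


class TestWindowHp:
    def test_balanced_window_is_maximal(self):
        snps = [dom_snp(1000 + i, 10, 10) for i in range(5)]
        (w,) = window_hp(snps)
        assert (w.sum_maj, w.sum_min) == (50, 50)
        assert w.hp == pytest.approx(0.5)
        assert w.n_snps == 5

    def test_formula_on_skewed_window(self):
        # direct formula evaluation: 2*150*5 / 155^2 = 0.0624
        minors = [2, 1, 2, 0, 0]
        snps = [dom_snp(1000 + i, 30, m) for i, m in enumerate(minors)]
        (w,) = window_hp(snps)
        assert (w.sum_maj, w.sum_min) == (150, 5)
        assert w.hp == pytest.approx(2 * 150 * 5 / 155**2)
        assert round(w.hp, 4) == 0.0624

    def test_sparse_window_not_emitted(self):
        snps = [dom_snp(1000 + i, 10, 10) for i in range(4)]
        assert window_hp(snps) == []

    def test_window_membership_is_half_open(self):
        # 1-based position 20000 is internal 19999 (first window);
        # 20001 is internal 20000 (second window)
        snps = [dom_snp(p, 10, 10) for p in (1, 5000, 10000, 15000, 20000)]
        (w,) = window_hp(snps)
        assert (w.start, w.end, w.n_snps) == (0, 20_000, 5)
        snps[-1] = dom_snp(20_001, 10, 10)
        assert window_hp(snps) == []

    def test_orientation_recomputed_within_scope(self):
        # catalogue labels A major, but the scanned pool is minor-heavy:
        # Hp must use the scanned pool's own balance (and stay <= 0.5)
        snps = [
            SnpRecord(
                chrom="chr1", pos=1000 + i, major_allele="A", minor_allele="G",
                per_pool_major=np.array([5, 100]), per_pool_minor=np.array([45, 0]),
                total_depth=150, maf=0.3,
            )
            for i in range(5)
        ]
        (w,) = window_hp(snps, domestic_pools=[0])
        assert (w.sum_maj, w.sum_min) == (45 * 5, 5 * 5)

    def test_wild_pool_excluded_from_sums(self):
        snps = [
            SnpRecord(
                chrom="chr1", pos=1000 + i, major_allele="A", minor_allele="G",
                per_pool_major=np.array([30, 10]), per_pool_minor=np.array([0, 10]),
                total_depth=50, maf=0.2,
            )
            for i in range(5)
        ]
        (w,) = window_hp(snps, domestic_pools=[0])
        assert (w.sum_maj, w.sum_min) == (150, 0)
        assert w.hp == 0.0 and w.hp_transformed == 7.0

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(
        counts=st.lists(
            st.tuples(st.integers(0, 200), st.integers(0, 200)).filter(
                lambda ab: sum(ab) > 0
            ),
            min_size=5, max_size=30,
        )
    )
    def test_hp_bounds_and_label_swap_invariance(self, counts):
        snps = [dom_snp(1000 + i, a, b) for i, (a, b) in enumerate(counts)]
        swapped = [dom_snp(1000 + i, b, a) for i, (a, b) in enumerate(counts)]
        w1 = window_hp(snps)
        w2 = window_hp(swapped)
        if not w1:
            return
        assert 0.0 <= w1[0].hp <= 0.5
        # Hp depends only on the combined allele balance, not the labels
        assert w1[0].hp == pytest.approx(w2[0].hp)

    def test_fixed_snp_depresses_hp_balanced_snp_raises_it(self):
        base = [dom_snp(1000 + i, 30, 10) for i in range(5)]
        (w0,) = window_hp(base)
        (w_fixed,) = window_hp(base + [dom_snp(1900, 40, 0)])
        (w_bal,) = window_hp(base + [dom_snp(1900, 20, 20)])
        assert w_fixed.hp < w0.hp < w_bal.hp <= 0.5

    def test_non_overlapping_tiling_conserves_snps(self, small_study):
        from poolsweep import FilterCriteria, apply_filter, call_candidates

        cfg, _, sites = small_study
        snps, _ = apply_filter(call_candidates(sites), FilterCriteria())
        windows = window_hp(snps, domestic_pools=list(cfg.pool_roles.domestic), min_snps=1)
        assert sum(w.n_snps for w in windows) == len(snps)


class TestCallSweeps:
    def test_threshold_inclusive_at_four(self):
        windows = [
            window("chr1", 0, 0.4, 1.2),
            window("chr1", 40_000, 0.0625, 4.0),
            window("chr1", 80_000, 0.067, 3.9),
        ]
        regions = call_sweeps(windows)
        assert len(regions) == 1
        assert (regions[0].start, regions[0].end) == (40_000, 60_000)

    def test_adjacent_windows_merge(self):
        windows = [
            window("chr1", 20_000, 0.05, 4.3),
            window("chr1", 40_000, 0.03, 5.1),
            window("chr2", 40_000, 0.03, 5.1),
        ]
        regions = call_sweeps(windows)
        spans = {(r.chrom, r.start, r.end) for r in regions}
        assert spans == {("chr1", 20_000, 60_000), ("chr2", 40_000, 60_000)}
        merged = next(r for r in regions if r.chrom == "chr1")
        assert merged.min_hp == 0.03 and merged.max_transformed == 5.1

    def test_fixed_regions_rank_first(self):
        windows = [
            window("chr1", 0, 0.05, 4.32),
            window("chr2", 0, 0.0, 7.0),
            window("chr3", 0, 0.01, 6.64),
        ]
        regions = call_sweeps(windows)
        assert [r.chrom for r in regions] == ["chr2", "chr3", "chr1"]

    def test_planted_sweeps_recovered_end_to_end(self, small_study):
        from poolsweep import run_domestication_scan

        cfg, _, sites = small_study
        res = run_domestication_scan(sites, cfg.pool_roles)
        assert len(res.regions) == 1
        (region,) = res.regions
        (chrom, s, e) = cfg.sweeps[0]
        assert region.chrom == chrom
        assert abs(region.start - s) <= 20_000 and abs(region.end - e) <= 20_000


class TestAnnotateSweeps:
    region_windows = [window("chr1", 40_000, 0.01, 6.6)]

    def test_contained_gene_attached(self):
        (r,) = call_sweeps(self.region_windows)
        genes = [GeneFeature("chr1", 45_000, 47_000, "+", "g1")]
        (out,) = annotate_sweeps([r], genes)
        assert [g.feature_id for g in out.genes] == ["g1"]

    def test_one_bp_overlap_counts(self):
        (r,) = call_sweeps(self.region_windows)
        genes = [GeneFeature("chr1", 59_999, 62_000, "+", "edge")]
        (out,) = annotate_sweeps([r], genes)
        assert [g.feature_id for g in out.genes] == ["edge"]
        outside = [GeneFeature("chr1", 60_000, 62_000, "+", "out")]
        (out2,) = annotate_sweeps([r], outside)
        assert out2.genes == []

    def test_gene_desert_keeps_empty_list(self):
        (r,) = call_sweeps(self.region_windows)
        genes = [GeneFeature("chr2", 45_000, 47_000, "+", "elsewhere")]
        (out,) = annotate_sweeps([r], genes)
        assert out.genes == []
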