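"""Fisher exact testing, FDR correction, location categories and binning."""

from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poolsweep import (
    GeneFeature,
    SignificantSnp,
    bh_fdr,
    categorize_location,
    chromosome_bins,
    differentiation_table,
    find_significant,
    fisher_allele_test,
    location_summary,
)
from poolsweep.snp_calling import SnpRecord


def exact_two_sided(a, b, c, d):
    """Independent oracle: exact integer-weight enumeration of all tables
    with the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [comb(r1, x) * comb(r2, c1 - x) for x in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    return sum(w for w in weights if w <= w_obs) / comb(r1 + r2, c1)


def snp_at(pos, dom_major, dom_minor, wild_major, wild_minor, chrom="chr1"):
    return SnpRecord(
        chrom=chrom, pos=pos, major_allele="A", minor_allele="G",
        per_pool_major=np.array([dom_major, wild_major]),
        per_pool_minor=np.array([dom_minor, wild_minor]),
        total_depth=dom_major + dom_minor + wild_major + wild_minor,
        maf=0.1,
    )


class TestFisher:
    def test_identical_proportions_give_p_one(self):
        assert fisher_allele_test(10, 10, 10, 10) == pytest.approx(1.0)

    def test_row_swap_symmetry(self):
        assert fisher_allele_test(12, 3, 5, 9) == pytest.approx(
            fisher_allele_test(5, 9, 12, 3), abs=1e-12
        )

    def test_matches_exhaustive_enumeration(self):
        assert fisher_allele_test(50, 0, 25, 25) == pytest.approx(
            exact_two_sided(50, 0, 25, 25), abs=1e-12
        )

    def test_zero_margin_warns_and_returns_one(self):
        with pytest.warns(UserWarning, match="zero margin"):
            assert fisher_allele_test(0, 0, 5, 5) == 1.0

    @settings(max_examples=150, derandomize=True, deadline=None)
    @given(
        a=st.integers(0, 40), b=st.integers(0, 40),
        c=st.integers(0, 40), d=st.integers(0, 40),
    )
    def test_agrees_with_scipy(self, a, b, c, d):
        """Cross-check against the reference implementation."""
        from scipy.stats import fisher_exact

        if min(a + b, c + d, a + c, b + d) == 0:
            return
        expected = fisher_exact([[a, b], [c, d]]).pvalue
        assert fisher_allele_test(a, b, c, d) == pytest.approx(expected, abs=1e-9)


class TestFdr:
    def test_step_up_rejection_count(self):
        # literal step-up oracle: largest k with p(k) <= 0.01*k/4 is k=3
        q = bh_fdr([0.001, 0.004, 0.0075, 0.5])
        assert (q <= 0.01).sum() == 3

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]).tolist() == [1.0, 1.0, 1.0]

    def test_single_p_unchanged(self):
        assert bh_fdr([0.037])[0] == pytest.approx(0.037)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40),
        alpha=st.sampled_from([0.01, 0.05, 0.1]),
    )
    def test_bh_rejections_superset_of_bonferroni(self, p, alpha):
        q = bh_fdr(p)
        bonf = np.minimum(np.array(p) * len(p), 1.0)
        assert np.all((q <= alpha) | (bonf > alpha))

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_matches_literal_step_up(self, p):
        """q(i) = min over j>=rank(i) of n*p(j)/j, capped at 1."""
        q = bh_fdr(p)
        n = len(p)
        order = np.argsort(p, kind="stable")
        expected = np.empty(n)
        running = 1.0
        for rank in range(n, 0, -1):
            i = order[rank - 1]
            running = min(running, n * p[i] / rank)
            expected[i] = running
        assert q == pytest.approx(expected, abs=1e-12)


class TestFindSignificant:
    def test_planted_differentiated_snps_recovered(self):
        # strongly differentiated (wild 0.5 vs domestic ~0.02) among nulls
        rng = np.random.default_rng(2)
        snps = []
        for i in range(200):
            maj = rng.binomial(150, 0.7)
            snps.append(snp_at(i * 1000 + 1, maj, 150 - maj, *_wild_split(rng, 0.7)))
        planted = [snp_at(999_001, 147, 3, 15, 15)]
        sig = find_significant(snps + planted, domestic_pools=[0], wild_pool=1)
        assert any(s.snp.pos == 999_001 for s in sig)

    def test_alpha_zero_gives_empty_result(self):
        snps = [snp_at(1, 100, 1, 50, 40)]
        assert find_significant(snps, [0], 1, alpha=0.0) == []

    def test_missing_wild_pool_errors(self):
        with pytest.raises(ValueError, match="wild"):
            find_significant([], [0], None)

    def test_null_panel_rejects_at_most_alpha(self, null_study):
        """Full null: q <= 0.01 fraction bounded by alpha + 3 sigma."""
        cfg, _, sites = null_study
        from poolsweep import FilterCriteria, apply_filter, call_candidates

        snps, _ = apply_filter(call_candidates(sites), FilterCriteria())
        table = differentiation_table(
            snps, list(cfg.pool_roles.domestic), cfg.wild_pool
        )
        n = len(table)
        frac = (table["q_value"].to_numpy() <= 0.01).mean()
        assert n > 3000
        assert frac <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / n)


def _wild_split(rng, f):
    maj = rng.binomial(30, f)
    return maj, 30 - maj


class TestCategorize:
    cds = [GeneFeature("chr1", 1000, 2000, "+", "cds1", is_coding=True)]

    def sig(self, pos):
        return SignificantSnp(snp=snp_at(pos, 10, 10, 10, 10), p_value=0.001, q_value=0.005)

    @pytest.mark.parametrize(
        "pos1,expected",
        [
            (1500, "coding"),
            (1001, "coding"),      # first base of the interval (1-based)
            (2000, "coding"),      # last base (end is exclusive internally)
            (901, "near_coding"),  # exactly 100 bp upstream
            (2100, "near_coding"), # exactly 100 bp downstream
            (900, "non_coding"),   # 101 bp upstream
            (2101, "non_coding"),  # 101 bp downstream
        ],
    )
    def test_boundaries(self, pos1, expected):
        (s,) = categorize_location([self.sig(pos1)], self.cds)
        assert s.category == expected

    def test_counts_conserved_and_order_independent(self):
        feats = [
            GeneFeature("chr1", 1000, 2000, "+", "a", is_coding=True),
            GeneFeature("chr1", 5000, 6000, "-", "b", is_coding=True),
            GeneFeature("chr1", 100, 9000, ".", "gene", is_coding=False),
        ]
        snps = [self.sig(p) for p in range(500, 8000, 73)]
        out = categorize_location(snps, feats)
        summary = location_summary(out)
        assert sum(summary.values()) == len(snps)
        snps2 = [self.sig(p) for p in range(500, 8000, 73)]
        out2 = categorize_location(snps2, feats[::-1])
        assert [s.category for s in out] == [s.category for s in out2]


class TestChromosomeBins:
    def sig(self, pos, chrom="chr1"):
        return SignificantSnp(
            snp=snp_at(pos, 10, 10, 10, 10, chrom=chrom), p_value=0.001, q_value=0.005
        )

    def test_bin_counts(self):
        bins, unassigned = chromosome_bins(
            [self.sig(p) for p in (10, 150_000, 250_000)]
        )
        assert bins["chr1"].tolist() == [2, 1]
        assert unassigned == 0

    def test_empty_input(self):
        bins, unassigned = chromosome_bins([], assigned_chroms=["chr1"])
        assert bins["chr1"].size == 0 and unassigned == 0

    def test_unassigned_reported_separately(self):
        snps = [self.sig(10), self.sig(20, chrom="scaffold_99")]
        bins, unassigned = chromosome_bins(snps, assigned_chroms=["chr1"])
        assert unassigned == 1
        assert sum(arr.sum() for arr in bins.values()) == 1
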