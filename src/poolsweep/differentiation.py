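"""Domestic-vs-wild allele-frequency differentiation of SNPs.

For each SNP the major/minor read counts of the domestic pools (summed by
default) and the wild pool form a 2x2 table tested with a two-tailed Fisher's
exact test; p-values are corrected for multiple testing (Benjamini–Hochberg
by default) and SNPs with q <= alpha are the *significant* SNPs.  Significant
SNPs are then categorised by genomic location relative to coding intervals
(coding / near-coding within 100 bp / non-coding) and binned along
chromosomes for distribution plots.

The exact-test units are read counts, not individuals, as is inherent to the
pooled design; the resulting pseudo-replication is discussed in the methods
documentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

from .io_formats import GeneFeature
from .snp_calling import SnpRecord

#: Relative tolerance when comparing table probabilities for the two-sided
#: tail sum, absorbing floating-point noise in exact ties (the convention
#: used by the standard implementations).
_TIE_REL = 1e-7


@dataclass(slots=True)
class SignificantSnp:
    """A differentiated SNP with its test results and location category."""

    snp: SnpRecord
    p_value: float
    q_value: float
    category: str | None = None  # {"coding", "near_coding", "non_coding"}
    chrom_bin: int | None = None


def _log_comb(n, k):
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def fisher_allele_test(
    domestic_major: int, domestic_minor: int, wild_major: int, wild_minor: int
) -> float:
    """Two-tailed Fisher's exact p-value for the 2x2 allele-count table
    ``[[domestic_major, domestic_minor], [wild_major, wild_minor]]``.

    Two-sidedness is by summing the probabilities of all tables with the same
    margins whose probability does not exceed that of the observed table.  A
    zero margin carries no information: p = 1 with a warning.
    """
    a, b, c, d = (int(domestic_major), int(domestic_minor),
                  int(wild_major), int(wild_minor))
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        warnings.warn("zero margin in Fisher table; p = 1 (no information)")
        return 1.0
    return float(_two_sided_from_margins(r1, r2, c1, a))


def _two_sided_from_margins(r1: int, r2: int, c1: int, a: int) -> float:
    """Tail sum over the hypergeometric support for margins (r1, r2, c1)."""
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    logpmf = (
        _log_comb(r1, support)
        + _log_comb(r2, c1 - support)
        - _log_comb(r1 + r2, c1)
    )
    pmf = np.exp(logpmf - logpmf.max())
    pmf /= pmf.sum()  # renormalise to tame rounding at large margins
    p_obs = pmf[a - lo]
    return min(1.0, float(pmf[pmf <= p_obs * (1 + _TIE_REL)].sum()))


def differentiation_table(
    snps: Sequence[SnpRecord],
    domestic_pools: Sequence[int],
    wild_pool: int,
    method: str = "bh",
) -> pd.DataFrame:
    """Test every SNP; returns chrom, pos, the four counts, p and q.

    Domestic major/minor reads are summed across ``domestic_pools``; q-values
    come from :func:`bh_fdr` over all tested SNPs, input order preserved.
    """
    dom = list(domestic_pools)
    rows = np.empty((len(snps), 4), dtype=np.int64)
    for i, s in enumerate(snps):
        rows[i] = (
            s.per_pool_major[dom].sum(),
            s.per_pool_minor[dom].sum(),
            s.per_pool_major[wild_pool],
            s.per_pool_minor[wild_pool],
        )
    p = np.ones(len(snps))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, (dm, dn, wm, wn) in enumerate(rows):
            p[i] = fisher_allele_test(dm, dn, wm, wn)
    q = bh_fdr(p, method=method) if len(p) else np.array([])
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in snps],
            "pos": [s.pos for s in snps],
            "dom_major": rows[:, 0],
            "dom_minor": rows[:, 1],
            "wild_major": rows[:, 2],
            "wild_minor": rows[:, 3],
            "p_value": p,
            "q_value": q,
        }
    )


def bh_fdr(p_values, method: str = "bh") -> np.ndarray:
    """Step-up FDR-adjusted q-values (Benjamini–Hochberg, or ``"by"`` for the
    Benjamini–Yekutieli variant); monotone, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([])
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    stats_method = {"bh": "fdr_bh", "by": "fdr_by"}.get(method)
    if stats_method is None:
        raise ValueError(f"unknown FDR method {method!r}")
    return multipletests(p, method=stats_method)[1]


def find_significant(
    snps: Sequence[SnpRecord],
    domestic_pools: Sequence[int],
    wild_pool: int | None,
    alpha: float = 0.01,
    mode: str = "pooled",
    method: str = "bh",
) -> list[SignificantSnp]:
    """SNPs whose domestic-vs-wild allele frequencies differ at q <= alpha.

    ``mode="pooled"`` (default) sums the domestic pools into one margin;
    ``mode="per_strain"`` tests each domestic pool separately (FDR within
    each strain) and returns the union, with each SNP's smallest q.
    """
    if wild_pool is None:
        raise ValueError("no wild pool configured")
    if mode == "pooled":
        table = differentiation_table(snps, domestic_pools, wild_pool, method=method)
        keep = table["q_value"].to_numpy() <= alpha
        return [
            SignificantSnp(snp=s, p_value=float(p), q_value=float(q))
            for s, p, q, k in zip(
                snps, table["p_value"], table["q_value"], keep
            )
            if k
        ]
    if mode == "per_strain":
        best_p = np.ones(len(snps))
        best_q = np.ones(len(snps))
        for pool in domestic_pools:
            t = differentiation_table(snps, [pool], wild_pool, method=method)
            q = t["q_value"].to_numpy()
            better = q < best_q
            best_q[better] = q[better]
            best_p[better] = t["p_value"].to_numpy()[better]
        return [
            SignificantSnp(snp=s, p_value=float(p), q_value=float(q))
            for s, p, q in zip(snps, best_p, best_q)
            if q <= alpha
        ]
    raise ValueError(f"unknown mode {mode!r}")


def categorize_location(
    sig_snps: Iterable[SignificantSnp],
    features: Sequence[GeneFeature],
    near_bp: int = 100,
) -> list[SignificantSnp]:
    """Assign each significant SNP a location category in place.

    ``coding`` if the position lies inside a coding interval; ``near_coding``
    if within ``near_bp`` of a coding interval boundary (inclusive at exactly
    ``near_bp``) but not inside; else ``non_coding``.  Only features flagged
    ``is_coding`` define the coding intervals; strand and input order are
    irrelevant.
    """
    coding: dict[str, IntervalTree] = {}
    near: dict[str, IntervalTree] = {}
    for f in features:
        if not f.is_coding:
            continue
        coding.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end)
        near.setdefault(f.chrom, IntervalTree()).addi(
            max(0, f.start - near_bp), f.end + near_bp
        )
    out = []
    for s in sig_snps:
        p0 = s.snp.pos - 1  # internal 0-based position
        chrom = s.snp.chrom
        if chrom in coding and coding[chrom].overlaps_point(p0):
            s.category = "coding"
        elif chrom in near and near[chrom].overlaps_point(p0):
            s.category = "near_coding"
        else:
            s.category = "non_coding"
        out.append(s)
    return out


def location_summary(sig_snps: Iterable[SignificantSnp]) -> dict[str, int]:
    """Counts per location category; values sum to the number of SNPs."""
    counts = {"coding": 0, "near_coding": 0, "non_coding": 0}
    for s in sig_snps:
        if s.category is None:
            raise ValueError("SNPs are not categorised; run categorize_location")
        counts[s.category] += 1
    return counts


def chromosome_bins(
    sig_snps: Iterable[SignificantSnp],
    bin_size: int = 200_000,
    assigned_chroms: Sequence[str] | None = None,
) -> tuple[dict[str, np.ndarray], int]:
    """Per-chromosome counts of significant SNPs in consecutive bins.

    SNPs on chromosomes outside ``assigned_chroms`` (when given) are not
    binned; their number is returned separately as the unassigned count.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    assigned = set(assigned_chroms) if assigned_chroms is not None else None
    per_chrom: dict[str, list[int]] = {}
    n_unassigned = 0
    for s in sig_snps:
        if assigned is not None and s.snp.chrom not in assigned:
            n_unassigned += 1
            continue
        b = (s.snp.pos - 1) // bin_size
        s.chrom_bin = int(b)
        per_chrom.setdefault(s.snp.chrom, []).append(int(b))
    bins = {}
    for chrom, idx in per_chrom.items():
        arr = np.bincount(np.array(idx, dtype=np.int64))
        bins[chrom] = arr.astype(np.int64)
    if assigned is not None:
        for chrom in assigned:
            bins.setdefault(chrom, np.zeros(0, dtype=np.int64))
    return bins, n_unassigned
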