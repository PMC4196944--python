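"""Windowed pooled-heterozygosity (Hp) scan and sweep calling.

Over each window the major and minor allele reads of the in-scope (domestic)
pools are summed across the window's significant SNPs and

    Hp = 2 * sum_maj * sum_min / (sum_maj + sum_min)**2

is a read-weighted heterozygosity in [0, 0.5]: 0.5 when major and minor
reads balance, 0 when the window is fixed.  Hp is reported as -log2(Hp);
a fully fixed window (Hp = 0) is assigned the cap value (default 7).
Windows with fewer than ``min_snps`` significant SNPs are not evaluated, and
windows whose transformed score reaches the threshold (default >= 4) are
merged into putative sweep regions and annotated with overlapping genes.

Major/minor orientation is recomputed per SNP within the in-scope pools, so
the statistic reflects the scanned population's own allele balance, not the
catalogue-wide orientation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import GeneFeature
from .differentiation import SignificantSnp
from .snp_calling import SnpRecord

DEFAULT_HP_CAP = 7.0


@dataclass(slots=True)
class WindowStat:
    """Hp accounting for one genomic window (0-based half-open interval)."""

    chrom: str
    start: int
    end: int
    n_snps: int
    sum_maj: int
    sum_min: int
    hp: float
    hp_transformed: float


@dataclass(slots=True)
class SweepRegion:
    """A run of threshold-passing windows merged into one putative sweep."""

    chrom: str
    start: int
    end: int
    min_hp: float
    max_transformed: float
    window_ids: list[int]
    genes: list[GeneFeature] = field(default_factory=list)


def transform_hp(hp: float, cap: float = DEFAULT_HP_CAP) -> float:
    """-log2(Hp), with the cap value substituted when Hp is exactly 0."""
    if not 0.0 <= hp <= 0.5 + 1e-12:
        raise ValueError(f"Hp must lie in [0, 0.5], got {hp}")
    if hp == 0.0:
        return float(cap)
    return -math.log2(hp)


def _as_snp(record) -> SnpRecord:
    return record.snp if isinstance(record, SignificantSnp) else record


def window_hp(
    sig_snps: Sequence,
    domestic_pools: Sequence[int] | None = None,
    window_size: int = 20_000,
    step: int = 20_000,
    min_snps: int = 5,
    cap: float = DEFAULT_HP_CAP,
) -> list[WindowStat]:
    """Hp per window over the significant SNPs.

    Windows tile each chromosome from 0 with the given size and step (the
    default non-overlapping tiling restarts at every chromosome).  A SNP at
    1-based position ``pos`` belongs to a window ``[ws, ws + window_size)``
    iff ``ws <= pos - 1 < ws + window_size``.  ``domestic_pools`` selects the
    pool columns whose reads enter the sums (default: all pools present on
    the records — the wild pool should not be in scope for a domestication
    scan).  Windows with fewer than ``min_snps`` SNPs are omitted.
    """
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    by_chrom: dict[str, list[SnpRecord]] = {}
    for rec in sig_snps:
        snp = _as_snp(rec)
        by_chrom.setdefault(snp.chrom, []).append(snp)
    windows: list[WindowStat] = []
    for chrom in sorted(by_chrom):
        snps = sorted(by_chrom[chrom], key=lambda s: s.pos)
        pos0 = np.array([s.pos - 1 for s in snps], dtype=np.int64)
        dom = list(domestic_pools) if domestic_pools is not None else None
        maj = np.empty(len(snps), dtype=np.int64)
        mnr = np.empty(len(snps), dtype=np.int64)
        for i, s in enumerate(snps):
            a = s.per_pool_major.sum() if dom is None else s.per_pool_major[dom].sum()
            b = s.per_pool_minor.sum() if dom is None else s.per_pool_minor[dom].sum()
            # re-orient within the scanned pools
            maj[i], mnr[i] = (a, b) if a >= b else (b, a)
        cum_maj = np.concatenate([[0], np.cumsum(maj)])
        cum_min = np.concatenate([[0], np.cumsum(mnr)])
        last_start = int(pos0.max()) // step * step
        for ws in range(0, last_start + 1, step):
            we = ws + window_size
            lo = int(np.searchsorted(pos0, ws, side="left"))
            hi = int(np.searchsorted(pos0, we, side="left"))
            n = hi - lo
            if n < min_snps:
                continue
            s_maj = int(cum_maj[hi] - cum_maj[lo])
            s_min = int(cum_min[hi] - cum_min[lo])
            total = s_maj + s_min
            hp = 2.0 * s_maj * s_min / (total * total) if total else 0.0
            windows.append(
                WindowStat(
                    chrom=chrom, start=ws, end=we, n_snps=n,
                    sum_maj=s_maj, sum_min=s_min, hp=hp,
                    hp_transformed=transform_hp(hp, cap=cap),
                )
            )
    return windows


def call_sweeps(windows: Sequence[WindowStat], threshold: float = 4.0) -> list[SweepRegion]:
    """Merge threshold-passing windows into sweep regions.

    The threshold is inclusive.  Overlapping or boundary-sharing selected
    windows on the same chromosome merge into one region.  Regions are
    returned most-extreme first: ordered by minimum Hp ascending, so fully
    fixed (Hp = 0) regions rank first regardless of the cap value.
    """
    selected = [
        (i, w) for i, w in enumerate(windows) if w.hp_transformed >= threshold
    ]
    selected.sort(key=lambda iw: (iw[1].chrom, iw[1].start))
    regions: list[SweepRegion] = []
    for i, w in selected:
        if regions and regions[-1].chrom == w.chrom and w.start <= regions[-1].end:
            r = regions[-1]
            r.end = max(r.end, w.end)
            r.min_hp = min(r.min_hp, w.hp)
            r.max_transformed = max(r.max_transformed, w.hp_transformed)
            r.window_ids.append(i)
        else:
            regions.append(
                SweepRegion(
                    chrom=w.chrom, start=w.start, end=w.end,
                    min_hp=w.hp, max_transformed=w.hp_transformed,
                    window_ids=[i],
                )
            )
    regions.sort(key=lambda r: (r.min_hp, -r.max_transformed, r.chrom, r.start))
    return regions


def annotate_sweeps(
    regions: Iterable[SweepRegion], features: Sequence[GeneFeature]
) -> list[SweepRegion]:
    """Attach features overlapping each region (any overlap counts).

    Typically called with gene-level features; regions in gene deserts keep
    empty lists.  Attached genes are ordered by start coordinate.
    """
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)
    out = []
    for r in regions:
        hits = trees[r.chrom].overlap(r.start, r.end) if r.chrom in trees else set()
        genes = sorted((iv.data for iv in hits), key=lambda g: (g.start, g.feature_id))
        out.append(replace_genes(r, genes))
    return out


def replace_genes(region: SweepRegion, genes: list[GeneFeature]) -> SweepRegion:
    return SweepRegion(
        chrom=region.chrom, start=region.start, end=region.end,
        min_hp=region.min_hp, max_transformed=region.max_transformed,
        window_ids=list(region.window_ids), genes=genes,
    )
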