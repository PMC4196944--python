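"""End-to-end convenience: counts -> SNPs -> significant SNPs -> sweeps."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .io_formats import GeneFeature, PoolRoles, PoolSiteCounts
from .snp_calling import FilterCriteria, FilterStats, SnpRecord, apply_filter, call_candidates
from .differentiation import (
    SignificantSnp,
    categorize_location,
    find_significant,
)
from .sweep_scan import SweepRegion, WindowStat, annotate_sweeps, call_sweeps, window_hp


@dataclass(slots=True)
class PipelineResult:
    candidates: list[SnpRecord]
    snps: list[SnpRecord]
    filter_stats: FilterStats
    significant: list[SignificantSnp]
    windows: list[WindowStat]
    regions: list[SweepRegion]


def run_domestication_scan(
    sites: Sequence[PoolSiteCounts],
    roles: PoolRoles,
    criteria: FilterCriteria = FilterCriteria(),
    alpha: float = 0.01,
    window_size: int = 20_000,
    step: int = 20_000,
    min_snps: int = 5,
    threshold: float = 4.0,
    features: Sequence[GeneFeature] | None = None,
) -> PipelineResult:
    """Run the full domestication-signature analysis on a counts panel.

    Candidate SNPs are called on the combined pools, screened by ``criteria``,
    tested for domestic-vs-wild differentiation at FDR ``alpha``, and the
    significant SNPs scanned for pooled-heterozygosity troughs over the
    domestic pools.  When ``features`` is given, significant SNPs are
    location-categorised against its coding intervals and sweep regions are
    annotated with its gene-level entries.
    """
    candidates = call_candidates(sites)
    snps, stats = apply_filter(candidates, criteria)
    significant = find_significant(snps, roles.domestic, roles.wild, alpha=alpha)
    if features is not None:
        significant = categorize_location(significant, features)
    windows = window_hp(
        significant,
        domestic_pools=roles.domestic,
        window_size=window_size,
        step=step,
        min_snps=min_snps,
    )
    regions = call_sweeps(windows, threshold=threshold)
    if features is not None:
        genes = [f for f in features if not f.is_coding]
        regions = annotate_sweeps(regions, genes)
    return PipelineResult(
        candidates=candidates,
        snps=snps,
        filter_stats=stats,
        significant=significant,
        windows=windows,
        regions=regions,
    )
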