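"""Candidate SNP identification from pooled counts and the three-factor filter.

A site becomes a candidate SNP when, over the in-scope pools, its second most
frequent nucleotide is seen at least twice (the relaxed calling floor) and no
credible third allele is present (biallelic enforcement: the third-ranked
count must stay below the minor-allele floor).  Candidates are then screened
by three criteria — minimum total depth, maximum total depth (absolute or a
"top q%" quantile spec), and minimum minor-allele read count — whose joint
optimisation grid, minor-allele-frequency spectrum, and common/strain-specific
classification are produced here.

Depth is the total A+C+G+T read count over the in-scope pools; N and deletion
reads never form alleles and are excluded from depth.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import ACGT_SYNC_INDICES, PoolSiteCounts

_ACGT = np.array(["A", "C", "G", "T"])

#: Relaxed minor-allele floor used at the candidate-calling stage.
CANDIDATE_MINOR_FLOOR = 2


@dataclass(frozen=True, slots=True)
class FilterCriteria:
    """One setting of the three SNP-screening factors.

    ``max_depth`` is either an absolute read count or a quantile spec such as
    ``"top2%"`` (exclude the deepest 2% of sites), resolved against the
    observed site-depth distribution.
    """

    min_depth: int = 30
    max_depth: int | str = 300
    min_minor_count: int = 5

    def __post_init__(self) -> None:
        if self.min_depth < 1:
            raise ValueError("min_depth must be >= 1")
        if self.min_minor_count < 1:
            raise ValueError("min_minor_count must be >= 1")
        if isinstance(self.max_depth, str):
            self._parse_quantile(self.max_depth)  # validate eagerly
        elif self.max_depth <= self.min_depth:
            raise ValueError("max_depth must exceed min_depth")

    @staticmethod
    def _parse_quantile(spec: str) -> float:
        m = re.fullmatch(r"top[_ ]?(\d+(?:\.\d+)?)%", spec.strip(), re.IGNORECASE)
        if not m:
            raise ValueError(f"bad max_depth spec {spec!r}; expected e.g. 'top2%'")
        q = float(m.group(1))
        if not 0 < q < 100:
            raise ValueError("quantile must be in (0, 100)")
        return q

    def resolve_max_depth(self, depth_distribution: np.ndarray | None = None) -> int:
        """Absolute maximum depth, resolving a ``top q%`` spec if present."""
        if not isinstance(self.max_depth, str):
            return int(self.max_depth)
        if depth_distribution is None or len(depth_distribution) == 0:
            raise ValueError(
                f"max_depth {self.max_depth!r} needs a depth distribution to resolve"
            )
        q = self._parse_quantile(self.max_depth)
        resolved = int(np.percentile(np.asarray(depth_distribution), 100 - q))
        if resolved <= self.min_depth:
            raise ValueError("resolved max_depth does not exceed min_depth")
        return resolved


@dataclass(slots=True)
class SnpRecord:
    """A biallelic candidate SNP with per-pool major/minor read counts.

    ``maf`` is the read-count minor-allele frequency over the in-scope pools,
    bounded by 0.5 by the major/minor orientation.
    """

    chrom: str
    pos: int  # 1-based, as in the sync input
    major_allele: str
    minor_allele: str
    per_pool_major: np.ndarray
    per_pool_minor: np.ndarray
    total_depth: int
    maf: float

    @property
    def minor_count(self) -> int:
        return int(self.per_pool_minor.sum())


def _acgt_matrix(sites: Sequence[PoolSiteCounts], pools: Sequence[int] | None) -> np.ndarray:
    """Stack counts into an (n_sites, n_scope_pools, 4) A,C,G,T array."""
    stacked = np.stack([s.counts for s in sites])
    if pools is not None:
        stacked = stacked[:, list(pools), :]
    return stacked[:, :, ACGT_SYNC_INDICES]


def call_candidates(
    sites: Iterable[PoolSiteCounts],
    scope: str = "combined",
    pools: Sequence[int] | None = None,
    min_minor: int = CANDIDATE_MINOR_FLOOR,
):
    """Identify candidate SNPs from per-pool counts.

    With ``scope="combined"`` (the default, used for the genome-wide
    catalogue) counts are summed over the in-scope pools before calling and a
    single list of :class:`SnpRecord` is returned, whose per-pool vectors
    cover the in-scope pools.  With ``scope="per_pool"`` calling is repeated
    independently within each pool and a dict ``{pool_index: [SnpRecord]}``
    is returned.  Major/minor ties are broken alphabetically; sites with a
    credible third allele (third-ranked count >= ``min_minor``) are dropped.
    """
    sites = list(sites)
    if scope == "per_pool":
        n_pools = sites[0].counts.shape[0] if sites else 0
        indices = list(pools) if pools is not None else list(range(n_pools))
        return {
            p: call_candidates(sites, scope="combined", pools=[p], min_minor=min_minor)
            for p in indices
        }
    if scope != "combined":
        raise ValueError(f"unknown scope {scope!r}")
    if not sites:
        return []
    acgt = _acgt_matrix(sites, pools)
    totals = acgt.sum(axis=1)  # (n_sites, 4)
    # stable argsort of descending counts: alphabetical order breaks ties
    order = np.argsort(-totals, axis=1, kind="stable")
    ranked = np.take_along_axis(totals, order, axis=1)
    major_ct, minor_ct, third_ct = ranked[:, 0], ranked[:, 1], ranked[:, 2]
    keep = (minor_ct >= min_minor) & (third_ct < min_minor)
    records: list[SnpRecord] = []
    idx = np.nonzero(keep)[0]
    major_i, minor_i = order[:, 0], order[:, 1]
    depth = totals.sum(axis=1)
    for i in idx:
        records.append(
            SnpRecord(
                chrom=sites[i].chrom,
                pos=sites[i].pos,
                major_allele=str(_ACGT[major_i[i]]),
                minor_allele=str(_ACGT[minor_i[i]]),
                per_pool_major=acgt[i, :, major_i[i]].copy(),
                per_pool_minor=acgt[i, :, minor_i[i]].copy(),
                total_depth=int(depth[i]),
                maf=float(minor_ct[i] / (major_ct[i] + minor_ct[i])),
            )
        )
    return records


@dataclass(slots=True)
class FilterStats:
    """Accounting for one application of :class:`FilterCriteria`."""

    n_candidates: int
    n_snps: int
    pct_reads_included: float
    resolved_max_depth: int


def apply_filter(
    candidates: Sequence[SnpRecord],
    criteria: FilterCriteria,
    depth_distribution: np.ndarray | None = None,
) -> tuple[list[SnpRecord], FilterStats]:
    """Screen candidates by the three criteria.

    ``pct_reads_included`` is depth-weighted site coverage retained: the sum
    of depths at sites passing the depth bounds over the total depth of all
    sites (``depth_distribution`` when given, else the candidates' own
    depths), times 100.
    """
    depths = np.array([c.total_depth for c in candidates], dtype=np.int64)
    dist = depths if depth_distribution is None else np.asarray(depth_distribution)
    max_depth = criteria.resolve_max_depth(dist)
    pass_depth = (depths >= criteria.min_depth) & (depths <= max_depth)
    minor = np.array([c.minor_count for c in candidates], dtype=np.int64)
    keep = pass_depth & (minor >= criteria.min_minor_count)
    denom = dist.sum()
    pct = 100.0 * depths[pass_depth].sum() / denom if denom else 0.0
    snps = [c for c, k in zip(candidates, keep) if k]
    return snps, FilterStats(
        n_candidates=len(candidates),
        n_snps=len(snps),
        pct_reads_included=float(pct),
        resolved_max_depth=max_depth,
    )


def criteria_grid(
    candidates: Sequence[SnpRecord],
    criteria_list: Sequence[FilterCriteria],
    depth_distribution: np.ndarray | None = None,
) -> pd.DataFrame:
    """Evaluate a list of criteria sets; one row per set, mirroring
    :func:`apply_filter` exactly."""
    if not criteria_list:
        raise ValueError("need at least one criteria set")
    rows = []
    for i, crit in enumerate(criteria_list, start=1):
        _, stats = apply_filter(candidates, crit, depth_distribution)
        rows.append(
            {
                "criteria_set": i,
                "min_depth": crit.min_depth,
                "max_depth": crit.max_depth,
                "resolved_max_depth": stats.resolved_max_depth,
                "min_minor_count": crit.min_minor_count,
                "n_snps": stats.n_snps,
                "pct_reads_included": stats.pct_reads_included,
            }
        )
    return pd.DataFrame(rows)


#: The eight screening settings evaluated by the optimisation grid.
STANDARD_GRID = (
    FilterCriteria(20, "top2%", 2),
    FilterCriteria(30, "top2%", 2),
    FilterCriteria(30, 300, 3),
    FilterCriteria(30, 150, 3),
    FilterCriteria(30, 300, 5),
    FilterCriteria(30, 150, 5),
    FilterCriteria(50, 300, 5),
    FilterCriteria(50, 150, 5),
)


@dataclass(slots=True)
class MafSpectrum:
    """MAF histogram with left-open right-closed bins.

    ``n_half`` separately counts SNPs whose minor and major read counts are
    exactly equal (MAF = 0.5); those SNPs are also included in the last bin.
    """

    bin_edges: tuple[float, ...]
    counts: np.ndarray
    n_half: int

    @property
    def total(self) -> int:
        return int(self.counts.sum())


DEFAULT_MAF_EDGES = (0.0, 0.05, 0.10, 0.20, 0.30, 0.40, 0.50)


def maf_spectrum(
    snps: Sequence[SnpRecord], bin_edges: Sequence[float] = DEFAULT_MAF_EDGES
) -> MafSpectrum:
    """Histogram of minor-allele frequencies over ``(edge, next-edge]`` bins."""
    edges = tuple(float(e) for e in bin_edges)
    maf = np.array([s.maf for s in snps], dtype=float)
    if maf.size and (maf.min() <= edges[0] or maf.max() > edges[-1]):
        raise ValueError("MAF outside the bin range")
    idx = np.searchsorted(edges, maf, side="left") - 1
    counts = np.bincount(idx, minlength=len(edges) - 1) if maf.size else np.zeros(
        len(edges) - 1, dtype=np.int64
    )
    return MafSpectrum(
        bin_edges=edges, counts=counts.astype(np.int64), n_half=int((maf == 0.5).sum())
    )


# ---------------------------------------------------------------------------
# common / strain-specific classification
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class StrainClassification:
    """Per-pool polymorphism classification of sites.

    ``common`` holds sites polymorphic in every pool; ``strain_specific[p]``
    sites polymorphic only in pool ``p`` while every other pool is adequately
    covered and monomorphic; ``other`` sites polymorphic somewhere but
    unclassifiable (some other pool fails the depth bounds).  Site keys are
    ``(chrom, pos)`` tuples.  ``quality_per_pool[p]`` counts all sites
    polymorphic in pool ``p`` (the per-strain SNP totals).
    """

    common: set
    strain_specific: dict[int, set]
    other: set
    quality_per_pool: dict[int, int]

    def summary_table(self) -> pd.DataFrame:
        return strain_summary_table(
            self.quality_per_pool,
            {p: len(s) for p, s in self.strain_specific.items()},
        )


def strain_summary_table(
    quality_counts: dict, specific_counts: dict
) -> pd.DataFrame:
    """Per-strain SNP summary: totals, strain-specific counts, and the
    strain-specific percentage (100 * specific / total, reported to 1 dp)."""
    rows = []
    for pool in quality_counts:
        q = int(quality_counts[pool])
        s = int(specific_counts.get(pool, 0))
        rows.append(
            {
                "strain": pool,
                "quality_snps": q,
                "strain_specific_snps": s,
                "pct_strain_specific": round(100.0 * s / q, 1) if q else 0.0,
            }
        )
    return pd.DataFrame(rows)


def classify_strain_snps(
    sites: Sequence[PoolSiteCounts],
    criteria: FilterCriteria = FilterCriteria(),
) -> StrainClassification:
    """Classify sites as common, strain-specific, or other.

    A pool is *polymorphic* at a site when its own depth lies within the
    (per-pool-resolved) bounds, its minor count reaches ``min_minor_count``
    and no credible third allele is present; *monomorphic* when depth
    qualifies but the minor count falls short; otherwise the pool has no
    qualifying data there and any polymorphism elsewhere is unclassifiable.
    """
    sites = list(sites)
    if not sites:
        return StrainClassification(set(), {}, set(), {})
    acgt = _acgt_matrix(sites, None)  # (S, P, 4)
    n_pools = acgt.shape[1]
    depth = acgt.sum(axis=2)  # (S, P)
    ranked = -np.sort(-acgt, axis=2)  # descending counts per pool
    minor, third = ranked[:, :, 1], ranked[:, :, 2]
    max_depths = np.array(
        [criteria.resolve_max_depth(depth[:, p]) for p in range(n_pools)]
    )
    depth_ok = (depth >= criteria.min_depth) & (depth <= max_depths[None, :])
    poly = depth_ok & (minor >= criteria.min_minor_count) & (third < criteria.min_minor_count)
    mono = depth_ok & ~poly
    n_poly = poly.sum(axis=1)
    keys = [(s.chrom, s.pos) for s in sites]
    common = {k for k, n in zip(keys, n_poly) if n == n_pools}
    specific: dict[int, set] = {p: set() for p in range(n_pools)}
    other = set()
    is_specific = (n_poly == 1) & (mono.sum(axis=1) == n_pools - 1)
    for i in np.nonzero(n_poly > 0)[0]:
        k = keys[i]
        if n_poly[i] == n_pools:
            continue
        if is_specific[i]:
            specific[int(np.nonzero(poly[i])[0][0])].add(k)
        else:
            other.add(k)
    quality = {p: int(poly[:, p].sum()) for p in range(n_pools)}
    return StrainClassification(
        common=common, strain_specific=specific, other=other, quality_per_pool=quality
    )
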