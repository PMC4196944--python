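"""Synthetic Pool-seq inputs with known ground truth.

The generator emulates the study design the pipeline assumes: five pools
(four domestic strains and one wild population) of 30 diploid individuals
each, sequenced to ~30X per pool.  Polymorphic sites are placed by a
memoryless spacing process (about one SNP per 116 bp by default); the wild
pool's minor-allele frequency is drawn from a neutral-like spectrum
concentrated at low MAF (log-uniform on [1/(2*pool_size), 0.5]); each
domestic pool's frequency drifts from the wild value under a
Balding–Nichols Beta distribution with differentiation parameter ``drift_c``.
Inside planted sweep regions every domestic pool is fixed for the same
allele while the wild pool stays polymorphic, producing hard-sweep troughs
for the scan to recover.  Read counts are Poisson-depth binomial draws with
read-wise sequencing errors, so the minor-allele-count filter has true
errors to reject.

Everything is deterministic under the configured seed; independent stages
draw from seed-sequence streams spawned from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import GeneFeature, PoolSiteCounts, PoolRoles, write_annotation
from .read_trim import QualityRead

_BASES = np.array(["A", "C", "G", "T"])
_BASE_TO_SYNC = {"A": 0, "T": 1, "C": 2, "G": 3}

DEFAULT_GENOME = tuple((f"chr{i}", 2_000_000) for i in range(1, 6))
DEFAULT_SWEEPS = (
    ("chr1", 500_000, 560_000),
    ("chr3", 1_200_000, 1_240_000),
    ("chr5", 700_000, 760_000),
)


@dataclass(frozen=True, slots=True, kw_only=True)
class SimulationConfig:
    """Study conditions for the generator.

    Defaults mirror the analysis design: a 10-Mb toy genome over five
    chromosomes, 4 domestic pools + 1 wild pool of 30 diploids each, ~30X
    mean depth per pool, one SNP per 116 bp, per-base error rate 0.002, and
    three planted hard-sweep regions.  ``drift_c`` is the Balding–Nichols
    differentiation of each domestic pool from the wild source population.
    """

    seed: int
    genome: tuple = DEFAULT_GENOME
    n_domestic_pools: int = 4
    pool_size: int = 30
    coverage: float = 30.0
    error_rate: float = 0.002
    snp_density: float = 1.0 / 116.0
    drift_c: float = 0.05
    sweeps: tuple = DEFAULT_SWEEPS
    # FASTQ stage
    n_reads: int = 2000
    read_length: int = 100
    bad_read_fraction: float = 0.04

    def __post_init__(self) -> None:
        if not 0 <= self.drift_c < 1:
            raise ValueError("drift_c must lie in [0, 1)")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if not 0 < self.snp_density < 1:
            raise ValueError("snp_density must lie in (0, 1)")
        if not 0 <= self.bad_read_fraction <= 1:
            raise ValueError("bad_read_fraction must lie in [0, 1]")
        if self.coverage <= 0 or self.pool_size < 1 or self.n_domestic_pools < 1:
            raise ValueError("coverage, pool_size, n_domestic_pools must be positive")
        lengths = dict(self.genome)
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, s, e in self.sweeps:
            if chrom not in lengths or not (0 <= s < e <= lengths[chrom]):
                raise ValueError(f"sweep ({chrom}, {s}, {e}) outside the genome")
            by_chrom.setdefault(chrom, []).append((s, e))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError("sweep regions overlap")

    @property
    def n_pools(self) -> int:
        return self.n_domestic_pools + 1

    @property
    def wild_pool(self) -> int:
        return self.n_domestic_pools

    @property
    def pool_roles(self) -> PoolRoles:
        return PoolRoles(domestic=tuple(range(self.n_domestic_pools)), wild=self.wild_pool)

    @property
    def maf_floor(self) -> float:
        """Lowest representable allele frequency, 1/(2*pool_size)."""
        return 1.0 / (2 * self.pool_size)

    def rng(self, stream: int) -> np.random.Generator:
        """Deterministic generator for one stage (stream id keeps stages
        independent under a shared seed)."""
        return np.random.default_rng([self.seed % (2**31), stream])


@dataclass(slots=True)
class GroundTruth:
    """Generating frequencies and planted structure behind a simulated panel.

    ``dom_freqs`` has shape (n_sites, n_domestic_pools); ``wild_freqs`` is
    the wild pool's frequency of the alternate allele (its minor allele, so
    wild MAF equals ``wild_freqs``).  ``strain_specific_sites`` lists sites
    where exactly one pool's truth frequency is polymorphic above the
    representable floor; ``differentiated_sites`` lists sites whose mean
    domestic frequency differs from the wild frequency by at least 0.3.
    """

    chroms: np.ndarray
    positions: np.ndarray  # 1-based
    ref_alleles: np.ndarray
    alt_alleles: np.ndarray
    wild_freqs: np.ndarray
    dom_freqs: np.ndarray
    sweep_regions: tuple
    in_sweep: np.ndarray
    strain_specific_sites: list = field(default_factory=list)
    differentiated_sites: list = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.positions)


def simulate_frequencies(cfg: SimulationConfig) -> GroundTruth:
    """Place polymorphic sites and draw their per-pool truth frequencies."""
    rng = cfg.rng(1)
    chroms, positions = [], []
    for chrom, length in cfg.genome:
        # memoryless spacing at the configured density
        n_draw = int(length * cfg.snp_density * 1.3) + 50
        pos = np.cumsum(rng.geometric(cfg.snp_density, size=n_draw))
        while pos[-1] <= length:
            pos = np.concatenate([pos, pos[-1] + np.cumsum(rng.geometric(cfg.snp_density, size=n_draw))])
        pos = pos[pos <= length]
        chroms.append(np.full(len(pos), chrom, dtype=object))
        positions.append(pos)
    chrom_arr = np.concatenate(chroms)
    pos_arr = np.concatenate(positions).astype(np.int64)
    n = len(pos_arr)

    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    # neutral-like wild spectrum: log-uniform minor allele frequency
    f0 = cfg.maf_floor
    wild = np.exp(rng.uniform(np.log(f0), np.log(0.5), size=n))

    if cfg.drift_c > 0:
        c = cfg.drift_c
        a = wild * (1 - c) / c
        b = (1 - wild) * (1 - c) / c
        dom = rng.beta(
            np.repeat(a[:, None], cfg.n_domestic_pools, axis=1),
            np.repeat(b[:, None], cfg.n_domestic_pools, axis=1),
        )
    else:
        dom = np.repeat(wild[:, None], cfg.n_domestic_pools, axis=1)

    in_sweep = np.zeros(n, dtype=bool)
    for chrom, s, e in cfg.sweeps:
        mask = (chrom_arr == chrom) & (pos_arr - 1 >= s) & (pos_arr - 1 < e)
        in_sweep |= mask
        fixed_allele = float(rng.integers(0, 2))  # 0 -> ref fixed, 1 -> alt fixed
        dom[mask, :] = fixed_allele

    truth = GroundTruth(
        chroms=chrom_arr,
        positions=pos_arr,
        ref_alleles=_BASES[ref_idx],
        alt_alleles=_BASES[alt_idx],
        wild_freqs=wild,
        dom_freqs=dom,
        sweep_regions=cfg.sweeps,
        in_sweep=in_sweep,
    )
    floor = cfg.maf_floor
    all_freqs = np.column_stack([dom, wild])
    poly = np.minimum(all_freqs, 1 - all_freqs) >= floor
    one_poly = poly.sum(axis=1) == 1
    truth.strain_specific_sites = [
        (chrom_arr[i], int(pos_arr[i])) for i in np.nonzero(one_poly)[0]
    ]
    diff = np.abs(dom.mean(axis=1) - wild) >= 0.3
    truth.differentiated_sites = [
        (chrom_arr[i], int(pos_arr[i])) for i in np.nonzero(diff)[0]
    ]
    return truth


def simulate_counts(truth: GroundTruth, cfg: SimulationConfig) -> list[PoolSiteCounts]:
    """Draw per-pool read counts for every site in the truth panel.

    Depth per pool per site is Poisson(coverage); alternate-allele reads are
    Binomial(depth, pool frequency); each read is then flipped to a uniform
    other base with probability ``error_rate``.
    """
    rng = cfg.rng(2)
    n, p = truth.n_sites, cfg.n_pools
    freqs = np.column_stack([truth.dom_freqs, truth.wild_freqs])  # (n, p)
    depth = rng.poisson(cfg.coverage, size=(n, p))
    alt = rng.binomial(depth, freqs)
    ref = depth - alt

    counts = np.zeros((n, p, 6), dtype=np.int64)
    ref_sync = np.array([_BASE_TO_SYNC[b] for b in truth.ref_alleles])
    alt_sync = np.array([_BASE_TO_SYNC[b] for b in truth.alt_alleles])

    for source_reads, source_sync in ((ref, ref_sync), (alt, alt_sync)):
        err = rng.binomial(source_reads, cfg.error_rate)
        correct = source_reads - err
        # distribute errors uniformly over the three other bases
        split = rng.multinomial(err.ravel(), [1 / 3] * 3).reshape(n, p, 3)
        counts[np.arange(n)[:, None], np.arange(p)[None, :], source_sync[:, None]] += correct
        for b in range(4):
            mask = source_sync == b
            if not mask.any():
                continue
            rows = np.nonzero(mask)[0]
            for j, o in enumerate(o for o in range(4) if o != b):
                counts[rows[:, None], np.arange(p)[None, :], o] += split[rows, :, j]
    return [
        PoolSiteCounts(
            chrom=str(truth.chroms[i]),
            pos=int(truth.positions[i]),
            ref_allele=str(truth.ref_alleles[i]),
            counts=counts[i],
        )
        for i in range(n)
    ]


def simulate_sync(cfg: SimulationConfig) -> tuple[GroundTruth, list[PoolSiteCounts]]:
    """Convenience: frequencies plus counts in one call."""
    truth = simulate_frequencies(cfg)
    return truth, simulate_counts(truth, cfg)


# ---------------------------------------------------------------------------
# FASTQ stage
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class FastqTruth:
    """Planted composition of a simulated FASTQ batch."""

    n_reads: int
    n_bad: int

    @property
    def expected_kept_fraction(self) -> float:
        return 1.0 - self.n_bad / self.n_reads if self.n_reads else 0.0


def simulate_fastq(cfg: SimulationConfig, path: str | Path | None = None):
    """Simulate ~100-bp reads with a planted fraction of unusable reads.

    Good reads carry a high-quality profile (Phred 35–40) and survive
    trimming intact; bad reads (``bad_read_fraction`` of the batch) are one
    of three planted failure modes — uniformly low quality, an embedded N,
    or a high-quality stretch too short to keep.  Returns
    ``(reads, FastqTruth)`` and writes FASTQ when ``path`` is given.
    """
    rng = cfg.rng(3)
    n_bad = int(round(cfg.n_reads * cfg.bad_read_fraction))
    reads: list[QualityRead] = []
    L = cfg.read_length
    bad_flags = np.zeros(cfg.n_reads, dtype=bool)
    bad_flags[:n_bad] = True
    rng.shuffle(bad_flags)
    for i in range(cfg.n_reads):
        bases = "".join(rng.choice(_BASES, size=L))
        if not bad_flags[i]:
            quals = rng.integers(35, 41, size=L).tolist()
        else:
            mode = rng.integers(0, 3)
            if mode == 0:  # hopelessly low quality throughout
                quals = rng.integers(2, 11, size=L).tolist()
            elif mode == 1:  # N in the retained core
                quals = rng.integers(35, 41, size=L).tolist()
                k = int(rng.integers(L // 4, 3 * L // 4))
                bases = bases[:k] + "N" + bases[k + 1:]
            else:  # good stretch shorter than min_length
                quals = rng.integers(2, 11, size=L).tolist()
                k = int(rng.integers(5, 25))
                s = int(rng.integers(0, L - k))
                for j in range(s, s + k):
                    quals[j] = int(rng.integers(35, 41))
        reads.append(QualityRead(read_id=f"sim_{i}", bases=bases, quals=quals))
    if path is not None:
        from .io_formats import write_fastq

        write_fastq(reads, path)
    return reads, FastqTruth(n_reads=cfg.n_reads, n_bad=n_bad)


# ---------------------------------------------------------------------------
# annotation stage
# ---------------------------------------------------------------------------

def make_annotation(
    cfg: SimulationConfig,
    gene_density: float = 1.0 / 50_000,
    gene_length: int = 2_000,
    path: str | Path | None = None,
) -> list[GeneFeature]:
    """Place non-overlapping genes (each with a CDS) across the genome.

    Two of every three sweep regions receive a gene centred inside them, the
    third is left a gene desert, so sweep annotation has both outcomes to
    recover.  Background genes land uniformly at ``gene_density`` outside
    the sweeps; overlapping draws are rejected.  Writes GFF3 when ``path``
    is given.
    """
    rng = cfg.rng(4)
    features: list[GeneFeature] = []
    occupied: dict[str, list[tuple[int, int]]] = {}

    def try_place(chrom: str, start: int, name: str) -> bool:
        end = start + gene_length
        for s, e in occupied.get(chrom, []):
            if start < e and s < end:
                return False
        occupied.setdefault(chrom, []).append((start, end))
        features.append(GeneFeature(chrom, start, end, "+", name, is_coding=False))
        cds_s = start + gene_length // 5
        cds_e = end - gene_length // 5
        features.append(GeneFeature(chrom, cds_s, cds_e, "+", f"{name}.cds", is_coding=True))
        return True

    for i, (chrom, s, e) in enumerate(cfg.sweeps):
        if i % 3 == 2:
            continue  # leave every third sweep region a gene desert
        mid = (s + e) // 2
        try_place(chrom, max(0, mid - gene_length // 2), f"sweep_gene_{i + 1}")

    lengths = dict(cfg.genome)
    for chrom, length in cfg.genome:
        n_genes = rng.poisson(length * gene_density)
        placed, attempts = 0, 0
        while placed < n_genes and attempts < 20 * n_genes + 100:
            attempts += 1
            start = int(rng.integers(0, max(1, length - gene_length)))
            in_sweep = any(
                c == chrom and start < e and s < start + gene_length
                for c, s, e in cfg.sweeps
            )
            if in_sweep:
                continue
            if try_place(chrom, start, f"{chrom}_gene_{placed + 1}"):
                placed += 1
    features.sort(key=lambda f: (f.chrom, f.start, f.is_coding))
    if path is not None:
        write_annotation(features, path)
    return features
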