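"""Quality trimming of sequencing reads (modified-Mott running sum) and QC.

Each base quality Q is converted to an error probability ``P = 10^(-Q/10)``
and scored against a threshold quality ``A`` (default Phred 20):
``v = P(A) - P(Q)``, positive for bases better than the threshold.  A running
sum of ``v`` is accumulated along the read, clamped at zero when it would go
negative (the clamp is configurable); the retained span runs from the first
position where the sum becomes positive to the position of the (rightmost)
maximum of the sum.  Reads whose retained span is shorter than ``min_length``
or contains ambiguous bases are then discarded by :func:`qc_filter`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


@dataclass(slots=True)
class QualityRead:
    """A sequencing read with per-base Phred quality scores."""

    read_id: str
    bases: str
    quals: Sequence[int]

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True, slots=True)
class TrimConfig:
    """Trimming and QC parameters.

    quality_threshold
        Phred threshold A of the running-sum score (default 20, i.e. a 1%
        error ceiling).
    min_length
        Minimum retained length in bp; shorter reads are discarded.
    drop_n
        Discard reads whose retained span contains an N.
    clamp
        Clamp the running sum at zero (standard modified-Mott behaviour).
        With ``clamp=False`` the literal unclamped running sum is used, so a
        long low-quality prefix can sink a high-quality suffix.
    mean_quality_min
        Optional whole-read mean-quality floor applied to the retained span;
        off by default.
    """

    quality_threshold: int = 20
    min_length: int = 30
    drop_n: bool = True
    clamp: bool = True
    mean_quality_min: float | None = None

    def __post_init__(self) -> None:
        if self.quality_threshold < 0:
            raise ValueError("quality_threshold must be >= 0")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


def phred_to_error(q):
    """Error probability ``10^(-Q/10)`` of a Phred score (scalar or array)."""
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("Phred scores must be >= 0")
    p = np.power(10.0, -q / 10.0)
    return float(p) if p.ndim == 0 else p


def mott_trim(read: QualityRead, cfg: TrimConfig = TrimConfig()) -> tuple[int, int]:
    """Retained span ``[i, j)`` of a read under the running-sum criterion.

    Returns ``(0, 0)`` when the running sum never becomes positive (the read
    is discarded entirely).  The span starts at the first position where the
    sum is positive and ends just after the rightmost position attaining the
    maximum, so trailing bases with Q exactly equal to the threshold are kept.
    """
    if len(read) == 0:
        return (0, 0)
    v = phred_to_error(cfg.quality_threshold) - phred_to_error(np.asarray(read.quals))
    cs = np.cumsum(v)
    if cfg.clamp:
        # clamped-at-zero running sum: s[i] = cs[i] - min(0, min_{j<=i} cs[j])
        s = cs - np.minimum(np.minimum.accumulate(cs), 0.0)
    else:
        s = cs
    positive = s > 0
    if not positive.any():
        return (0, 0)
    start = int(np.argmax(positive))
    end = len(s) - int(np.argmax(s[::-1] == s.max()))  # rightmost max, exclusive
    return (start, end)


def mott_score(read: QualityRead, cfg: TrimConfig = TrimConfig()) -> float:
    """Maximum of the running sum — the total retained value of the read.

    Zero when nothing is retained.  Non-increasing in the threshold quality
    (a stricter threshold lowers every per-base value, hence the maximum).
    """
    if len(read) == 0:
        return 0.0
    v = phred_to_error(cfg.quality_threshold) - phred_to_error(np.asarray(read.quals))
    cs = np.cumsum(v)
    s = cs - np.minimum(np.minimum.accumulate(cs), 0.0) if cfg.clamp else cs
    return float(max(s.max(), 0.0))


def trim_read(read: QualityRead, cfg: TrimConfig = TrimConfig()) -> QualityRead:
    """The read restricted to its retained span (possibly empty)."""
    i, j = mott_trim(read, cfg)
    return QualityRead(read_id=read.read_id, bases=read.bases[i:j], quals=list(read.quals[i:j]))


@dataclass(slots=True)
class TrimSummary:
    """QC accounting for a batch of reads."""

    n_input: int = 0
    n_kept: int = 0
    mean_retained_length: float = 0.0

    @property
    def kept_fraction(self) -> float:
        return self.n_kept / self.n_input if self.n_input else 0.0


def qc_filter(
    reads: Iterable[QualityRead], cfg: TrimConfig = TrimConfig()
) -> tuple[list[QualityRead], TrimSummary]:
    """Discard already-trimmed reads failing the length / N / quality rules."""
    kept: list[QualityRead] = []
    summary = TrimSummary()
    total_len = 0
    for r in reads:
        summary.n_input += 1
        if len(r) < cfg.min_length:
            continue
        if cfg.drop_n and "N" in r.bases:
            continue
        if cfg.mean_quality_min is not None and np.mean(r.quals) < cfg.mean_quality_min:
            continue
        kept.append(r)
        total_len += len(r)
    summary.n_kept = len(kept)
    summary.mean_retained_length = total_len / len(kept) if kept else 0.0
    return kept, summary


def trim_and_filter(
    reads: Iterable[QualityRead], cfg: TrimConfig = TrimConfig()
) -> tuple[list[QualityRead], TrimSummary]:
    """Trim each read, then apply :func:`qc_filter`; the full cleaning stage."""
    return qc_filter((trim_read(r, cfg) for r in reads), cfg)
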