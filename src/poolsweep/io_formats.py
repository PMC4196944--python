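"""Readers and writers for the external formats the pipeline touches.

Formats
-------
* FASTQ (Sanger, Phred+33) for the read-trimming stage, via Biopython.
* ``sync`` tab format for per-pool nucleotide counts: one line per site with
  ``chrom  pos  ref`` followed by one ``A:T:C:G:N:del`` count string per pool.
  Positions are 1-based in the file.
* GFF3 (1-based inclusive) and BED (0-based half-open) gene annotation,
  normalised on read to the package-wide 0-based half-open convention.
* Tab-separated report tables mirroring the pipeline's summary outputs
  (SNP catalogue, significant SNPs, Hp windows, sweep regions, filter grid).

All internal coordinates in this package are 0-based half-open; the sync and
GFF3 readers/writers convert at the boundary.  Emitted report positions are
1-based except the sweep-region table, which follows the BED convention.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .read_trim import QualityRead

#: Column order of the count strings in a sync file.
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")

#: Index of each nucleotide within a sync count vector.
SYNC_INDEX = {"A": 0, "T": 1, "C": 2, "G": 3, "N": 4}

#: Sync-vector indices of A, C, G, T in alphabetical order.  Used wherever a
#: deterministic alphabetical tie-break over nucleotides is needed.
ACGT_SYNC_INDICES = np.array([0, 2, 3, 1])


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


@dataclass(frozen=True, slots=True)
class GeneFeature:
    """A gene or coding interval in internal (0-based half-open) coordinates.

    ``is_coding`` marks CDS/exon intervals; gene-level container features are
    recorded with ``is_coding=False``.  Strand is recorded but ignored by all
    downstream statistics.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    feature_id: str = ""
    is_coding: bool = False

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("GeneFeature.chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) for {self.feature_id!r}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass(slots=True)
class PoolSiteCounts:
    """Per-site, per-pool nucleotide counts — the pipeline's central substrate.

    ``pos`` is 1-based as in the sync file.  ``counts`` has shape
    ``(n_pools, 6)`` in sync allele order (A, T, C, G, N, del).
    """

    chrom: str
    pos: int
    ref_allele: str
    counts: np.ndarray

    def acgt(self, pools: Sequence[int] | None = None) -> np.ndarray:
        """Nucleotide counts in alphabetical (A, C, G, T) order.

        Returns the ``(len(pools), 4)`` slice of ``counts``; N and deletion
        columns are excluded from allele calling.
        """
        c = self.counts if pools is None else self.counts[list(pools)]
        return c[:, ACGT_SYNC_INDICES]


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[QualityRead]:
    """Stream :class:`QualityRead` records from a Sanger (Phred+33) FASTQ file.

    Raises :class:`ParseError` naming the approximate line number on a
    malformed record (length mismatch, bad header, quality out of range).
    """
    n = 0
    with open(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                quals = [ord(c) - 33 for c in qual]
                if any(q < 0 or q > 93 for q in quals):
                    raise ParseError(
                        f"{path}: quality out of Phred+33 range [0, 93] "
                        f"near line {4 * n + 1}"
                    )
                yield QualityRead(read_id=title.split()[0], bases=seq.upper(), quals=quals)
                n += 1
        except ValueError as err:  # biopython's malformed-record errors
            if isinstance(err, ParseError):
                raise
            raise ParseError(f"{path}: near line {4 * n + 1}: {err}") from err


def write_fastq(reads: Iterable[QualityRead], path: str | Path) -> None:
    """Write reads in Sanger FASTQ; inverse of :func:`read_fastq`."""
    with open(path, "w") as out:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quals)
            out.write(f"@{r.read_id}\n{r.bases}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# sync
# ---------------------------------------------------------------------------

def read_sync(path: str | Path, n_pools: int) -> Iterator[PoolSiteCounts]:
    """Stream :class:`PoolSiteCounts` from a sync file with ``n_pools`` pools.

    Validates the field count, integer counts, and strictly increasing
    positions within each chromosome block.
    """
    last: tuple[str, int] | None = None
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3 + n_pools:
                raise ParseError(
                    f"{path}:{lineno}: expected {3 + n_pools} fields "
                    f"(3 + {n_pools} pools), got {len(fields)}"
                )
            chrom, pos_s, ref = fields[0], fields[1], fields[2].upper()
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer position {pos_s!r}")
            if pos < 1:
                raise ParseError(f"{path}:{lineno}: position must be >= 1")
            if ref not in "ACGTN" or len(ref) != 1:
                raise ParseError(f"{path}:{lineno}: bad reference allele {ref!r}")
            if last is not None and last[0] == chrom and pos <= last[1]:
                raise ParseError(
                    f"{path}:{lineno}: positions not strictly increasing on {chrom}"
                )
            last = (chrom, pos)
            counts = np.empty((n_pools, 6), dtype=np.int64)
            for i, tup in enumerate(fields[3:]):
                parts = tup.split(":")
                if len(parts) != 6:
                    raise ParseError(
                        f"{path}:{lineno}: pool {i + 1} count string {tup!r} "
                        "is not a 6-tuple"
                    )
                try:
                    vals = [int(p) for p in parts]
                except ValueError:
                    raise ParseError(f"{path}:{lineno}: non-integer count in {tup!r}")
                if any(v < 0 for v in vals):
                    raise ParseError(f"{path}:{lineno}: negative count in {tup!r}")
                counts[i] = vals
            yield PoolSiteCounts(chrom=chrom, pos=pos, ref_allele=ref, counts=counts)


def write_sync(sites: Iterable[PoolSiteCounts], path: str | Path) -> None:
    """Write sites in sync format; inverse of :func:`read_sync`."""
    with open(path, "w") as out:
        for s in sites:
            pools = "\t".join(":".join(str(int(v)) for v in row) for row in s.counts)
            out.write(f"{s.chrom}\t{s.pos}\t{s.ref_allele}\t{pools}\n")


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

_CODING_TYPES = {"CDS", "exon"}


def read_annotation(path: str | Path, format: str | None = None) -> list[GeneFeature]:
    """Load gene features from GFF3 or BED into internal coordinates.

    GFF3 CDS and exon features are flagged ``is_coding``; BED intervals are
    treated as coding intervals (the BED route exists to supply plain lists of
    coding regions).  ``format`` is inferred from the file suffix when omitted.
    """
    path = Path(path)
    if format is None:
        suffix = path.suffix.lower()
        if suffix in (".gff", ".gff3"):
            format = "gff3"
        elif suffix == ".bed":
            format = "bed"
        else:
            raise ValueError(f"cannot infer annotation format from {path.name!r}")
    if format == "gff3":
        return _read_gff3(path)
    if format == "bed":
        return _read_bed(path)
    raise ValueError(f"unknown annotation format {format!r}")


def _read_gff3(path: Path) -> list[GeneFeature]:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", merge_strategy="create_unique", keep_order=True
    )
    feats = []
    for f in db.all_features():
        if f.end < f.start:
            raise ParseError(f"{path}: feature {f.id} has end < start")
        fid = f.attributes.get("ID", [f.id])[0]
        feats.append(
            GeneFeature(
                chrom=f.seqid,
                start=f.start - 1,  # GFF3 is 1-based inclusive
                end=f.end,
                strand=f.strand if f.strand in "+-" else ".",
                feature_id=fid,
                is_coding=f.featuretype in _CODING_TYPES,
            )
        )
    return feats


def _read_bed(path: Path) -> list[GeneFeature]:
    feats = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: BED line has < 3 fields")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if end <= start:
                raise ParseError(f"{path}:{lineno}: end <= start")
            name = fields[3] if len(fields) > 3 else f"{chrom}:{start}-{end}"
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "."
            feats.append(
                GeneFeature(
                    chrom=chrom, start=start, end=end, strand=strand,
                    feature_id=name, is_coding=True,
                )
            )
    return feats


def write_annotation(features: Iterable[GeneFeature], path: str | Path) -> None:
    """Write features as GFF3 (gene / CDS records, 1-based inclusive)."""
    with open(path, "w") as out:
        out.write("##gff-version 3\n")
        for f in features:
            ftype = "CDS" if f.is_coding else "gene"
            attrs = f"ID={f.feature_id}"
            out.write(
                f"{f.chrom}\tpoolsweep\t{ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# pool roles
# ---------------------------------------------------------------------------

@dataclass(frozen=True, slots=True)
class PoolRoles:
    """0-based sync-column indices of the domestic pools and the wild pool."""

    domestic: tuple[int, ...]
    wild: int

    @property
    def n_pools(self) -> int:
        return len(self.domestic) + 1

    @property
    def all_pools(self) -> tuple[int, ...]:
        return self.domestic + (self.wild,)


def parse_pool_spec(spec: str) -> PoolRoles:
    """Parse a pool-role spec like ``"domestic=1,2,3,4;wild=5"`` (1-based)."""
    roles: dict[str, list[int]] = {}
    for part in spec.split(";"):
        if "=" not in part:
            raise ValueError(f"bad pool spec component {part!r}")
        key, vals = part.split("=", 1)
        roles[key.strip()] = [int(v) - 1 for v in vals.split(",") if v.strip()]
    if "domestic" not in roles or "wild" not in roles:
        raise ValueError("pool spec must name both 'domestic' and 'wild' pools")
    if len(roles["wild"]) != 1:
        raise ValueError("exactly one wild pool is supported")
    dom = tuple(roles["domestic"])
    wild = roles["wild"][0]
    if min(dom + (wild,)) < 0:
        raise ValueError("pool numbers are 1-based")
    if wild in dom or len(set(dom)) != len(dom):
        raise ValueError("pool roles overlap")
    return PoolRoles(domestic=dom, wild=wild)


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

# Numeric formatting: Hp to 3 decimals, transformed Hp to 2 decimals,
# percentages to 1 decimal, MAF to 4 decimals, p/q in 3-significant-digit
# scientific form.
_TABLE_SCHEMAS: dict[str, dict[str, str | None]] = {
    "snp": {
        "chrom": None, "pos": None, "major_allele": None, "minor_allele": None,
        "total_depth": None, "maf": "%.4f",
        "per_pool_major": None, "per_pool_minor": None,
    },
    "significant": {
        "chrom": None, "pos": None, "major_allele": None, "minor_allele": None,
        "p_value": "%.3g", "q_value": "%.3g", "category": None,
    },
    "window": {
        "chrom": None, "start": None, "end": None, "n_snps": None,
        "sum_maj": None, "sum_min": None, "hp": "%.3f", "hp_transformed": "%.2f",
    },
    "region": {
        "chrom": None, "start": None, "end": None, "n_windows": None,
        "min_hp": "%.3f", "max_transformed": "%.2f", "genes": None,
    },
    "grid": {
        "criteria_set": None, "min_depth": None, "max_depth": None,
        "resolved_max_depth": None, "min_minor_count": None,
        "n_snps": None, "pct_reads_included": "%.1f",
    },
}

_INT_COLUMNS = {
    "pos", "start", "end", "n_snps", "sum_maj", "sum_min", "total_depth",
    "n_windows", "criteria_set", "min_depth", "resolved_max_depth",
    "min_minor_count",
}


def _records_to_frame(records, kind: str) -> pd.DataFrame:
    cols = list(_TABLE_SCHEMAS[kind])
    if isinstance(records, pd.DataFrame):
        missing = [c for c in cols if c not in records.columns]
        if missing:
            raise ValueError(f"records missing columns {missing} for kind={kind!r}")
        return records[cols]
    rows = []
    for r in records:
        rows.append({c: _extract(r, c, kind) for c in cols})
    return pd.DataFrame(rows, columns=cols)


def _extract(record, col: str, kind: str):
    # report-table views of the pipeline's dataclasses
    if kind == "significant" and col in ("chrom", "pos", "major_allele", "minor_allele"):
        return getattr(record.snp, col)
    if col == "genes":
        genes = getattr(record, "genes", [])
        return ",".join(g.feature_id for g in genes) if genes else "."
    if col in ("per_pool_major", "per_pool_minor"):
        return ",".join(str(int(v)) for v in getattr(record, col))
    if kind == "region" and col == "n_windows":
        return len(record.window_ids)
    if kind == "window" and col in ("start", "end"):
        # report positions are 1-based inclusive
        return record.start + 1 if col == "start" else record.end
    return getattr(record, col)


def write_tables(records, path: str | Path, kind: str) -> None:
    """Write a report table of the named ``kind`` as header-led TSV.

    ``records`` may be a list of the matching pipeline dataclasses or a
    DataFrame with the schema's columns (as returned by :func:`read_tables`).
    Sweep-region tables use BED-convention (0-based half-open) coordinates;
    every other table reports 1-based positions.
    """
    if kind not in _TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    frame = _records_to_frame(records, kind)
    schema = _TABLE_SCHEMAS[kind]
    with open(path, "w") as out:
        out.write("\t".join(schema) + "\n")
        for row in frame.itertuples(index=False):
            cells = []
            for col, value in zip(schema, row):
                fmt = schema[col]
                if fmt is not None:
                    cells.append(fmt % float(value))
                elif col in _INT_COLUMNS:
                    cells.append(str(int(value)))
                else:
                    cells.append(str(value))
            out.write("\t".join(cells) + "\n")


def read_tables(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a report table written by :func:`write_tables`."""
    if kind not in _TABLE_SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}")
    dtypes = {c: (np.int64 if c in _INT_COLUMNS else object) for c in _TABLE_SCHEMAS[kind]}
    for col, fmt in _TABLE_SCHEMAS[kind].items():
        if fmt is not None:
            dtypes[col] = np.float64
    df = pd.read_csv(path, sep="\t", dtype=dtypes)
    if list(df.columns) != list(_TABLE_SCHEMAS[kind]):
        raise ParseError(f"{path}: header does not match table kind {kind!r}")
    return df
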