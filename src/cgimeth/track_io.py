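"""Readers and writers for the on-disk formats the pipeline consumes.

All genomic coordinates are kept 0-based half-open internally. Bismark
coverage files (1-based point positions) are converted on read and
converted back on write, so a read/write round trip is the identity.
Every reader transparently accepts gzip-compressed input (``.gz``).
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ParseError",
    "GenomicInterval",
    "MethylationCall",
    "GeneRecord",
    "SignalTrack",
    "PointSignal",
    "read_methylation_coverage",
    "write_methylation_coverage",
    "read_bed",
    "write_bed",
    "read_signal_bedgraph",
    "write_bedgraph",
    "read_genes",
    "write_genes",
    "read_expression",
    "read_label_table",
    "define_promoter_cgis",
]

_STRANDS = {"+", "-", "."}


class ParseError(ValueError):
    """A malformed line in an input file; the message names the line number."""


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on ``chrom``; 0-based."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    id: str = ""
    metadata: Mapping | None = field(default=None, compare=False)

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class MethylationCall:
    """A single CpG site with read support; ``pos`` is a 0-based point."""

    chrom: str
    pos: int
    n_meth: int
    n_total: int

    def __post_init__(self):
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not (0 <= self.n_meth <= self.n_total):
            raise ValueError("need 0 <= n_meth <= n_total")

    @property
    def beta(self) -> float:
        return self.n_meth / self.n_total


@dataclass(frozen=True)
class GeneRecord:
    """A gene anchored at its canonical TSS with all transcript TSSs."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    transcript_tss: tuple[int, ...]

    def __post_init__(self):
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene strand must be +/-, got {self.strand!r}")
        if not self.transcript_tss:
            raise ValueError("transcript_tss must be non-empty")
        if self.tss not in self.transcript_tss:
            raise ValueError("canonical tss must be listed in transcript_tss")


class SignalTrack:
    """Sparse per-chromosome step function; positions not covered are 0.

    Intervals within a chromosome must be sorted and non-overlapping;
    this is validated on construction.
    """

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray, np.ndarray]]):
        self.data = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if not (len(starts) == len(ends) == len(values)):
                raise ValueError("starts/ends/values length mismatch")
            if np.any(ends <= starts):
                raise ValueError(f"empty or inverted interval on {chrom}")
            if np.any(~np.isfinite(values)) or np.any(values < 0):
                raise ValueError(f"signal values must be finite and >= 0 on {chrom}")
            order = np.argsort(starts, kind="stable")
            starts, ends, values = starts[order], ends[order], values[order]
            if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping intervals on {chrom}")
            self.data[chrom] = (starts, ends, values)

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int, float]]) -> "SignalTrack":
        by_chrom: dict[str, list] = {}
        for chrom, start, end, value in records:
            by_chrom.setdefault(chrom, []).append((start, end, value))
        data = {}
        for chrom, rows in by_chrom.items():
            arr = np.asarray(rows, dtype=float)
            data[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
        return cls(data)

    def value_at(self, chrom: str, pos: int) -> float:
        if chrom not in self.data:
            return 0.0
        starts, ends, values = self.data[chrom]
        i = np.searchsorted(starts, pos, side="right") - 1
        if i >= 0 and pos < ends[i]:
            return float(values[i])
        return 0.0

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Sum of value * covered-bp over [start, end)."""
        if chrom not in self.data or end <= start:
            return 0.0
        starts, ends, values = self.data[chrom]
        i = np.searchsorted(ends, start, side="right")
        j = np.searchsorted(starts, end, side="left")
        if i >= j:
            return 0.0
        overlap = np.minimum(ends[i:j], end) - np.maximum(starts[i:j], start)
        return float(np.sum(overlap * values[i:j]))

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        """Coverage-weighted mean over [start, end), zero-filled gaps included."""
        if end <= start:
            return 0.0
        return self.integral(chrom, start, end) / (end - start)

    def records(self):
        for chrom in sorted(self.data):
            starts, ends, values = self.data[chrom]
            for s, e, v in zip(starts, ends, values):
                yield chrom, int(s), int(e), float(v)


class PointSignal:
    """Per-chromosome sorted point measurements (e.g. CpG beta values)."""

    def __init__(self, data: Mapping[str, tuple[np.ndarray, np.ndarray]]):
        self.data = {}
        for chrom, (pos, values) in data.items():
            pos = np.asarray(pos, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(pos, kind="stable")
            self.data[chrom] = (pos[order], values[order])

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, value_col: str = "beta") -> "PointSignal":
        data = {}
        for chrom, sub in df.groupby("chrom", sort=True):
            data[chrom] = (sub["pos"].to_numpy(), sub[value_col].to_numpy())
        return cls(data)

    def points_in(self, chrom: str, start: int, end: int) -> tuple[np.ndarray, np.ndarray]:
        if chrom not in self.data:
            return np.empty(0, dtype=np.int64), np.empty(0)
        pos, values = self.data[chrom]
        i = np.searchsorted(pos, start, side="left")
        j = np.searchsorted(pos, end, side="left")
        return pos[i:j], values[i:j]


# ---------------------------------------------------------------------------
# Bismark coverage


def read_methylation_coverage(path, min_coverage: int = 10) -> pd.DataFrame:
    """Read a Bismark-coverage file into a CpG call table.

    Columns on disk: chrom, start (1-based), end, percent methylation,
    methylated count, unmethylated count (tab or space separated). The
    percent column is ignored; beta is recomputed from the counts. Sites
    with fewer than ``min_coverage`` total reads are dropped; sites with
    zero total reads are rejected with a warning.

    Returns a DataFrame with columns chrom, pos (0-based), n_meth,
    n_total, beta, sorted by (chrom, pos).
    """
    if min_coverage < 1:
        raise ValueError("min_coverage must be >= 1")
    chroms, poss, meths, totals = [], [], [], []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) != 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 fields, got {len(fields)}"
                )
            try:
                start1 = int(fields[1])
                n_meth = int(fields[4])
                n_unmeth = int(fields[5])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric field ({exc})") from None
            if n_meth < 0 or n_unmeth < 0:
                raise ParseError(f"{path}:{lineno}: negative read count")
            total = n_meth + n_unmeth
            if total == 0:
                warnings.warn(
                    f"{path}:{lineno}: site with zero total reads rejected",
                    stacklevel=2,
                )
                continue
            if total < min_coverage:
                continue
            chroms.append(fields[0])
            poss.append(start1 - 1)
            meths.append(n_meth)
            totals.append(total)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": np.asarray(poss, dtype=np.int64),
            "n_meth": np.asarray(meths, dtype=np.int64),
            "n_total": np.asarray(totals, dtype=np.int64),
        }
    )
    df["beta"] = df["n_meth"] / df["n_total"]
    return df.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def write_methylation_coverage(df: pd.DataFrame, path) -> None:
    """Write a call table back to Bismark-coverage dialect (1-based)."""
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            pct = 100.0 * row.n_meth / row.n_total
            n_unmeth = row.n_total - row.n_meth
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.pos + 1}\t{pct:.6g}\t"
                f"{row.n_meth}\t{n_unmeth}\n"
            )


# ---------------------------------------------------------------------------
# BED / narrowPeak

_NARROWPEAK_EXTRA = ("score", "signalValue", "pValue", "qValue", "peak")


def read_bed(path, kind: str = "bed3") -> list[GenomicInterval]:
    """Read BED3/BED6/narrowPeak intervals, validated and sorted.

    Overlap between records is permitted; narrowPeak columns beyond BED6
    are kept in ``metadata``.
    """
    if kind not in {"bed3", "bed6", "narrowPeak"}:
        raise ValueError(f"unknown BED kind {kind!r}")
    min_fields = {"bed3": 3, "bed6": 6, "narrowPeak": 10}[kind]
    intervals = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < min_fields:
                raise ParseError(
                    f"{path}:{lineno}: expected >= {min_fields} fields for "
                    f"{kind}, got {len(fields)}"
                )
            try:
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
            name, strand, metadata = "", ".", None
            if kind in {"bed6", "narrowPeak"}:
                name = fields[3]
                strand = fields[5] if fields[5] in _STRANDS else "."
            if kind == "narrowPeak":
                metadata = {
                    "score": int(fields[4]),
                    "signalValue": float(fields[6]),
                    "pValue": float(fields[7]),
                    "qValue": float(fields[8]),
                    "peak": int(fields[9]),
                }
            try:
                intervals.append(
                    GenomicInterval(chrom, start, end, strand, name, metadata)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    intervals.sort(key=lambda iv: (iv.chrom, iv.start, iv.end))
    return intervals


def write_bed(intervals: Iterable[GenomicInterval], path, kind: str = "bed6") -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            if kind == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif kind == "bed6":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t0\t{iv.strand}\n")
            elif kind == "narrowPeak":
                md = iv.metadata or {}
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.id}\t"
                    f"{md.get('score', 0)}\t{iv.strand}\t"
                    f"{md.get('signalValue', 0.0):.6g}\t{md.get('pValue', -1):.6g}\t"
                    f"{md.get('qValue', -1):.6g}\t{md.get('peak', -1)}\n"
                )
            else:
                raise ValueError(f"unknown BED kind {kind!r}")


# ---------------------------------------------------------------------------
# bedGraph


def read_signal_bedgraph(path) -> SignalTrack:
    """Read a 4-column bedGraph; overlapping intervals are an error."""
    records = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            try:
                records.append(
                    (fields[0], int(fields[1]), int(fields[2]), float(fields[3]))
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    try:
        return SignalTrack.from_records(records)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


def write_bedgraph(track: SignalTrack, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.records():
            fh.write(f"{chrom}\t{start}\t{end}\t{value:.6g}\n")


# ---------------------------------------------------------------------------
# Genes / expression / labels


def read_genes(path) -> list[GeneRecord]:
    """Read the gene annotation TSV.

    Columns (with header): gene_id, chrom, strand, tss_list where tss_list
    is a comma-separated list of 0-based transcript TSS positions; the
    first listed TSS is canonical.
    """
    genes = []
    with _open_text(path) as fh:
        header = fh.readline().strip().split("\t")
        expected = ["gene_id", "chrom", "strand", "tss_list"]
        if header != expected:
            raise ParseError(f"{path}:1: expected header {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(fields)}")
            try:
                tss_list = tuple(int(x) for x in fields[3].split(","))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric TSS list") from None
            try:
                genes.append(
                    GeneRecord(fields[0], fields[1], tss_list[0], fields[2], tss_list)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return genes


def write_genes(genes: Iterable[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss_list\n")
        for g in genes:
            tss_list = ",".join(str(t) for t in g.transcript_tss)
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{tss_list}\n")


def read_expression(path) -> pd.DataFrame:
    """Gene-by-tissue TPM matrix; first column = gene_id index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_label_table(path) -> pd.DataFrame:
    """Two-or-more-column TSV keyed by gene_id (e.g. bivalent or DEG labels)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ParseError(f"{path}: label table must have a gene_id column")
    return df


# ---------------------------------------------------------------------------
# Promoter CGIs


def define_promoter_cgis(
    cgis: Iterable[GenomicInterval], genes: Iterable[GeneRecord]
) -> dict[str, GenomicInterval]:
    """Map each gene to its promoter CGI.

    A gene qualifies iff at least one transcript TSS lies inside a CGI
    (point-in-half-open-interval). When several CGIs qualify the CGI
    containing the canonical (first-listed) TSS wins; remaining ties go
    to the longest CGI, then the lexicographically smallest id. Several
    genes may map to the same CGI.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for cgi in cgis:
        by_chrom.setdefault(cgi.chrom, []).append(cgi)
    for rows in by_chrom.values():
        rows.sort(key=lambda iv: (iv.start, iv.end))
    result: dict[str, GenomicInterval] = {}
    for gene in genes:
        rows = by_chrom.get(gene.chrom, [])
        candidates = [
            cgi
            for cgi in rows
            if any(cgi.contains_point(t) for t in gene.transcript_tss)
        ]
        if not candidates:
            continue
        canonical = [c for c in candidates if c.contains_point(gene.tss)]
        pool = canonical or candidates
        pool.sort(key=lambda c: (-len(c), c.id))
        result[gene.gene_id] = pool[0]
    return result


def with_strand(interval: GenomicInterval, strand: str) -> GenomicInterval:
    """Return a copy of ``interval`` carrying the given strand."""
    return replace(interval, strand=strand)
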