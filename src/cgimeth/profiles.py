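"""Region-by-bin signal matrices over promoter CGIs with scaled bodies.

The body of each region is split into a fixed number of near-equal bins
(any bp remainder goes to the leftmost bins) while flanks, when
requested, are binned at fixed width, mirroring the enriched-heatmap
style of metagene profiling. Methylation bins are unweighted means over
the CpG sites falling in the bin; histone (step-signal) bins are
coverage-weighted means with uncovered positions counting as zero.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .track_io import GenomicInterval, PointSignal, SignalTrack

__all__ = [
    "ProfileMatrix",
    "bin_edges",
    "bin_region_signal",
    "build_profile_matrix",
    "difference_matrix",
    "group_average_profile",
    "region_mean_signal",
    "impute_profile_rows",
]


def bin_edges(start: int, end: int, n_bins: int) -> np.ndarray:
    """Split [start, end) into n_bins near-equal half-open sub-intervals.

    The remainder of the integer division is distributed to the leftmost
    bins, so bin widths differ by at most 1 bp. Regions shorter than
    n_bins produce zero-width (empty) trailing bins.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if end < start:
        raise ValueError("end < start")
    length = end - start
    base, rem = divmod(length, n_bins)
    widths = np.full(n_bins, base, dtype=np.int64)
    widths[:rem] += 1
    return start + np.concatenate(([0], np.cumsum(widths)))


def _bin_point_signal(signal: PointSignal, chrom: str, edges: np.ndarray) -> np.ndarray:
    pos, values = signal.points_in(chrom, int(edges[0]), int(edges[-1]))
    n_bins = len(edges) - 1
    out = np.full(n_bins, np.nan)
    if len(pos) == 0:
        return out
    idx = np.searchsorted(edges, pos, side="right") - 1
    idx = np.clip(idx, 0, n_bins - 1)
    # canonical accumulation order (bin, then value) so that strand
    # reversal of region + signal reproduces the row bit-for-bit
    order = np.lexsort((values, idx))
    idx, values = idx[order], values[order]
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins)
    np.add.at(sums, idx, values)
    np.add.at(counts, idx, 1.0)
    mask = counts > 0
    out[mask] = sums[mask] / counts[mask]
    return out


def _bin_step_signal(signal: SignalTrack, chrom: str, edges: np.ndarray) -> np.ndarray:
    n_bins = len(edges) - 1
    out = np.full(n_bins, np.nan)
    for i in range(n_bins):
        s, e = int(edges[i]), int(edges[i + 1])
        if e > s:
            out[i] = signal.mean_over(chrom, s, e)
    return out


def bin_region_signal(
    signal,
    region: GenomicInterval,
    n_bins: int,
    orient_by_strand: bool = False,
) -> np.ndarray:
    """Bin a point or step signal over a region into ``n_bins`` values.

    Bins with no data carry NaN. With ``orient_by_strand`` and a '-'
    strand region the vector is reversed so bin 1 is always 5' of the
    gene.
    """
    edges = bin_edges(region.start, region.end, n_bins)
    if isinstance(signal, PointSignal):
        out = _bin_point_signal(signal, region.chrom, edges)
    elif isinstance(signal, SignalTrack):
        out = _bin_step_signal(signal, region.chrom, edges)
    else:
        raise TypeError(f"unsupported signal type {type(signal).__name__}")
    if np.all(np.isnan(out)):
        warnings.warn(
            f"region {region.id or region.chrom}:{region.start}-{region.end} "
            "has no signal in any bin",
            stacklevel=2,
        )
    if orient_by_strand and region.strand == "-":
        out = out[::-1]
    return out


@dataclass
class ProfileMatrix:
    """Regions x bins matrix with [upstream | body | downstream] layout."""

    region_ids: list[str]
    values: np.ndarray
    n_flank_bins: int
    n_body_bins: int
    signal_kind: str  # beta | beta_difference | coverage
    flank_bp: int = 0
    oriented: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        expected = 2 * self.n_flank_bins + self.n_body_bins
        if self.values.ndim != 2 or self.values.shape != (len(self.region_ids), expected):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.region_ids)} regions x {expected} bins"
            )
        finite = self.values[np.isfinite(self.values)]
        if self.signal_kind == "beta" and finite.size and (
            finite.min() < -1e-9 or finite.max() > 1 + 1e-9
        ):
            raise ValueError("beta entries must lie in [0, 1]")
        if self.signal_kind == "beta_difference" and finite.size and (
            finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9
        ):
            raise ValueError("beta_difference entries must lie in [-1, 1]")

    @property
    def n_bins(self) -> int:
        return 2 * self.n_flank_bins + self.n_body_bins

    @property
    def body_slice(self) -> slice:
        return slice(self.n_flank_bins, self.n_flank_bins + self.n_body_bins)

    def body_values(self) -> np.ndarray:
        return self.values[:, self.body_slice]

    def row(self, region_id: str) -> np.ndarray:
        return self.values[self.region_ids.index(region_id)]

    def bin_labels(self) -> list[str]:
        up = [f"u{i + 1}" for i in range(self.n_flank_bins)]
        body = [f"b{i + 1}" for i in range(self.n_body_bins)]
        down = [f"d{i + 1}" for i in range(self.n_flank_bins)]
        return up + body + down

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_ids, columns=self.bin_labels())

    def to_tsv(self, path, sidecar=None) -> None:
        """Write values as TSV plus a JSON sidecar with layout metadata."""
        path = Path(path)
        frame = self.to_frame()
        frame.index.name = "region_id"
        frame.to_csv(path, sep="\t", float_format="%.8g")
        meta = {
            "n_flank_bins": self.n_flank_bins,
            "n_body_bins": self.n_body_bins,
            "signal_kind": self.signal_kind,
            "flank_bp": self.flank_bp,
            "oriented": self.oriented,
        }
        sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(meta, indent=1, sort_keys=True))

    @classmethod
    def from_tsv(cls, path, sidecar=None) -> "ProfileMatrix":
        path = Path(path)
        sidecar = Path(sidecar) if sidecar else path.with_suffix(path.suffix + ".json")
        meta = json.loads(sidecar.read_text())
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(
            region_ids=list(frame.index.astype(str)),
            values=frame.to_numpy(dtype=float),
            **meta,
        )


def build_profile_matrix(
    regions: Mapping[str, GenomicInterval] | Iterable[GenomicInterval],
    signal,
    n_body_bins: int = 20,
    flank_bp: int = 0,
    n_flank_bins: int = 0,
    orient_by_strand: bool = False,
    signal_kind: str | None = None,
) -> ProfileMatrix:
    """Bin a signal over each region body plus fixed-width flanks.

    Each row is [upstream flank bins | body bins | downstream flank
    bins]; with strand orientation the whole row of a '-' region is
    reversed. Flanks running past position 0 are clipped.
    """
    if flank_bp < 0:
        raise ValueError("flank_bp must be >= 0")
    if flank_bp > 0 and n_flank_bins < 1:
        raise ValueError("n_flank_bins must be >= 1 when flank_bp > 0")
    if flank_bp == 0:
        n_flank_bins = 0
    if isinstance(regions, Mapping):
        items = list(regions.items())
    else:
        items = [(iv.id, iv) for iv in regions]
    ids = [rid for rid, _ in items]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate region ids")
    if signal_kind is None:
        signal_kind = "beta" if isinstance(signal, PointSignal) else "coverage"

    rows = []
    with warnings.catch_warnings():
        # per-sub-window emptiness is expected; only whole-row gaps matter here
        warnings.simplefilter("ignore")
        for rid, region in items:
            parts = []
            if n_flank_bins:
                up_start = max(0, region.start - flank_bp)
                if up_start < region.start:
                    up = GenomicInterval(region.chrom, up_start, region.start, region.strand)
                    parts.append(bin_region_signal(signal, up, n_flank_bins))
                else:
                    parts.append(np.full(n_flank_bins, np.nan))
            parts.append(bin_region_signal(signal, region, n_body_bins))
            if n_flank_bins:
                down = GenomicInterval(
                    region.chrom, region.end, region.end + flank_bp, region.strand
                )
                parts.append(bin_region_signal(signal, down, n_flank_bins))
            row = np.concatenate(parts)
            if orient_by_strand and region.strand == "-":
                row = row[::-1]
            rows.append(row)
    values = np.vstack(rows) if rows else np.empty((0, 2 * n_flank_bins + n_body_bins))
    return ProfileMatrix(
        region_ids=ids,
        values=values,
        n_flank_bins=n_flank_bins,
        n_body_bins=n_body_bins,
        signal_kind=signal_kind,
        flank_bp=flank_bp,
        oriented=orient_by_strand,
    )


def difference_matrix(a: ProfileMatrix, b: ProfileMatrix) -> ProfileMatrix:
    """Entrywise a - b of two beta matrices; missing propagates."""
    if a.region_ids != b.region_ids:
        raise ValueError("region id mismatch")
    if (a.n_flank_bins, a.n_body_bins) != (b.n_flank_bins, b.n_body_bins):
        raise ValueError("bin layout mismatch")
    if a.signal_kind != "beta" or b.signal_kind != "beta":
        raise ValueError("difference_matrix requires two beta matrices")
    return ProfileMatrix(
        region_ids=list(a.region_ids),
        values=a.values - b.values,
        n_flank_bins=a.n_flank_bins,
        n_body_bins=a.n_body_bins,
        signal_kind="beta_difference",
        flank_bp=a.flank_bp,
        oriented=a.oriented,
    )


def group_average_profile(m: ProfileMatrix, members: Iterable[str]) -> np.ndarray:
    """Per-bin mean over member rows, ignoring missing entries."""
    members = list(members)
    if not members:
        raise ValueError("empty member set")
    index = {rid: i for i, rid in enumerate(m.region_ids)}
    missing = [rid for rid in members if rid not in index]
    if missing:
        raise ValueError(f"unknown region ids: {missing[:5]}")
    sub = m.values[[index[rid] for rid in members]]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(sub, axis=0)


def region_mean_signal(signal: SignalTrack, interval: GenomicInterval) -> float:
    """Coverage-weighted mean of a step signal over an interval."""
    return signal.mean_over(interval.chrom, interval.start, interval.end)


def impute_profile_rows(
    m: ProfileMatrix, max_missing_frac: float = 0.25
) -> tuple[ProfileMatrix, list[str]]:
    """Drop rows with too many missing bins; interpolate the rest.

    Rows with more than ``max_missing_frac`` missing bins are dropped
    (their ids are returned); remaining missing bins are filled by
    row-wise linear interpolation over bin index, with edge gaps taking
    the nearest observed value.
    """
    keep_rows, keep_ids, dropped = [], [], []
    for rid, row in zip(m.region_ids, m.values):
        nan_mask = np.isnan(row)
        if nan_mask.mean() > max_missing_frac or nan_mask.all():
            dropped.append(rid)
            continue
        if nan_mask.any():
            x = np.arange(len(row))
            row = row.copy()
            row[nan_mask] = np.interp(x[nan_mask], x[~nan_mask], row[~nan_mask])
        keep_rows.append(row)
        keep_ids.append(rid)
    values = np.vstack(keep_rows) if keep_rows else np.empty((0, m.n_bins))
    out = ProfileMatrix(
        region_ids=keep_ids,
        values=values,
        n_flank_bins=m.n_flank_bins,
        n_body_bins=m.n_body_bins,
        signal_kind=m.signal_kind,
        flank_bp=m.flank_bp,
        oriented=m.oriented,
    )
    return out, dropped
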