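"""H3K4me1 promoter-shape calls and mark quantification.

Promoter CGIs carry H3K4me1 in one of two canonical spatial layouts: a
single peak over the island (unimodal, typical of poised promoters) or
two peaks flanking a central dip (bimodal, typical of active
promoters). The caller reduces a flank/body profile row to a center
mean and two flank-quarter peaks and applies a ratio test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from . import stats as _stats
from .profiles import ProfileMatrix
from .track_io import GeneRecord, SignalTrack

__all__ = [
    "PatternCall",
    "call_promoter_pattern",
    "call_patterns",
    "default_min_signal",
    "compare_methylation_gain",
    "mark_enrichment_at_promoters",
]

_EPS = 1e-12


@dataclass(frozen=True)
class PatternCall:
    region_id: str
    shape: str  # unimodal | bimodal | flat
    center_mean: float
    left_peak: float
    right_peak: float
    score: float  # min flank peak over center mean


def call_promoter_pattern(
    profile_row: np.ndarray,
    n_flank_bins: int,
    n_body_bins: int,
    min_signal: float,
    bimodal_ratio: float = 1.5,
    region_id: str = "",
) -> PatternCall:
    """Call unimodal/bimodal/flat from one flank/body profile row.

    center mean = mean of the middle 50% of body bins; each flank peak =
    max over the flank bins plus the adjacent outer quarter of the
    body. Flat if the overall max is below ``min_signal``; bimodal if
    both flank peaks reach ``bimodal_ratio`` times the center mean.
    """
    if bimodal_ratio <= 1:
        raise ValueError("bimodal_ratio must be > 1")
    row = np.asarray(profile_row, dtype=float)
    if len(row) != 2 * n_flank_bins + n_body_bins:
        raise ValueError("profile row does not match the declared bin layout")
    q = n_body_bins // 4
    body = row[n_flank_bins : n_flank_bins + n_body_bins]
    center = float(np.nanmean(body[q : n_body_bins - q]))
    left = float(np.nanmax(row[: n_flank_bins + q])) if n_flank_bins + q else np.nan
    right = float(np.nanmax(row[n_flank_bins + n_body_bins - q :]))
    overall = float(np.nanmax(row))
    score = float(min(left, right) / max(center, _EPS))
    if overall < min_signal:
        shape = "flat"
    elif left >= bimodal_ratio * center and right >= bimodal_ratio * center:
        shape = "bimodal"
    else:
        shape = "unimodal"
    return PatternCall(region_id, shape, center, left, right, score)


def default_min_signal(m: ProfileMatrix, fraction: float = 0.05) -> float:
    """Flat-call floor: ``fraction`` of the matrix-wide 95th percentile."""
    finite = m.values[np.isfinite(m.values)]
    if finite.size == 0:
        return 0.0
    return float(fraction * np.percentile(finite, 95))


def call_patterns(
    m: ProfileMatrix,
    min_signal: float | None = None,
    bimodal_ratio: float = 1.5,
) -> pd.DataFrame:
    """Pattern-call every row of a profile matrix; returns a tidy table."""
    if min_signal is None:
        min_signal = default_min_signal(m)
    calls = [
        call_promoter_pattern(
            row,
            m.n_flank_bins,
            m.n_body_bins,
            min_signal=min_signal,
            bimodal_ratio=bimodal_ratio,
            region_id=rid,
        )
        for rid, row in zip(m.region_ids, m.values)
    ]
    return pd.DataFrame(
        {
            "region_id": [c.region_id for c in calls],
            "shape": [c.shape for c in calls],
            "score": [c.score for c in calls],
            "center_mean": [c.center_mean for c in calls],
            "left_peak": [c.left_peak for c in calls],
            "right_peak": [c.right_peak for c in calls],
        }
    )


def compare_methylation_gain(
    gain: Mapping[str, float] | pd.Series,
    groups: Mapping[str, str] | pd.Series,
    alpha: float = 0.01,
) -> dict:
    """Compare tumor-minus-normal methylation gain between H3K4me1 groups.

    ``verdict`` is the raw direction (mean gain of the high group above
    the low group); ``significant`` additionally requires the two-sided
    rank-sum p-value below ``alpha``.
    """
    gain = pd.Series(gain, dtype=float)
    groups = pd.Series(groups)
    ids = gain.index.intersection(groups.index)
    high = gain[ids[groups[ids] == "high"]].dropna().to_numpy()
    low = gain[ids[groups[ids] == "low"]].dropna().to_numpy()
    if len(high) == 0 or len(low) == 0:
        raise ValueError("both H3K4me1 groups must be non-empty")
    p = _stats.rank_sum_test(high, low)
    verdict = bool(high.mean() > low.mean())
    return {
        "n_high": int(len(high)),
        "n_low": int(len(low)),
        "high_mean": float(high.mean()),
        "low_mean": float(low.mean()),
        "high_median": float(np.median(high)),
        "low_median": float(np.median(low)),
        "p_value": float(p),
        "verdict": verdict,
        "significant": bool(verdict and p < alpha),
    }


def mark_enrichment_at_promoters(
    track: SignalTrack,
    genes: Iterable[GeneRecord],
    window_bp: int = 2000,
) -> pd.Series:
    """Mean signal over TSS +/- window_bp per gene (zero-filled gaps).

    Windows extending past the contig start are truncated at 0 with a
    warning.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    out = {}
    truncated = 0
    for g in genes:
        start = g.tss - window_bp
        if start < 0:
            truncated += 1
            start = 0
        out[g.gene_id] = track.mean_over(g.chrom, start, g.tss + window_bp)
    if truncated:
        warnings.warn(f"{truncated} promoter windows truncated at contig start")
    return pd.Series(out, name="promoter_enrichment")
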