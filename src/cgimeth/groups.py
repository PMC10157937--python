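"""Classification of promoter CGIs into methylation-dynamics groups.

Two classifiers live here. The first clusters 20-bin tumor-minus-normal
beta profiles with k-means and names the clusters C1-C5 from their
centroid geometry: C1 = 5' hypermethylation accrual, C2 = 3' accrual,
C3 = island-wide hypermethylation, C4 = hypomethylation, C5 = no
change. The second assigns promoter CGIs to demethylation / unchanged /
other classes from mean beta values in wild-type versus DNMT1/DNMT3B
double-knockout (DKO) cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .profiles import ProfileMatrix, impute_profile_rows
from .track_io import GenomicInterval, PointSignal

__all__ = [
    "cluster_difference_profiles",
    "ClusterLabeling",
    "label_clusters",
    "assign_accrual_modes",
    "classify_wt_vs_dko",
    "cgi_mean_beta",
    "split_by_h3k4me1_groups",
]

C_LABELS = ("C1", "C2", "C3", "C4", "C5")


def _farthest_point_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy farthest-point seeding; the first center is drawn at random."""
    idx = [int(rng.integers(len(X)))]
    d = np.sum((X - X[idx[0]]) ** 2, axis=1)
    for _ in range(k - 1):
        nxt = int(np.argmax(d))
        idx.append(nxt)
        d = np.minimum(d, np.sum((X - X[nxt]) ** 2, axis=1))
    return X[idx].copy()


def cluster_difference_profiles(
    diff: ProfileMatrix | np.ndarray,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """K-means on difference profiles; best of ``n_restarts`` by inertia.

    Returns (cluster ids per row, centroids); centroids are ordered by
    descending overall mean difference and cluster ids refer to that
    canonical order. Deterministic given ``seed``.
    """
    X = diff.values if isinstance(diff, ProfileMatrix) else np.asarray(diff, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("difference matrix contains non-finite entries; impute first")
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(X) < k:
        raise ValueError(f"need at least k={k} rows, got {len(X)}")
    if np.allclose(X, X[0]):
        warnings.warn("all rows identical: degenerate clustering (zero inertia)")
        return np.zeros(len(X), dtype=int), np.tile(X[0], (k, 1))

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_restarts)):
        init = _farthest_point_init(X, k, rng)
        km = KMeans(n_clusters=k, init=init, n_init=1, max_iter=300, tol=1e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km.fit(X)
        if best is None or km.inertia_ < best.inertia_:
            best = km
    order = np.argsort(-best.cluster_centers_.mean(axis=1), kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[best.labels_], best.cluster_centers_[order]


def _centroid_summary(c: np.ndarray) -> tuple[float, float, float]:
    half = len(c) // 2
    return float(np.mean(c)), float(np.mean(c[:half])), float(np.mean(c[half:]))


@dataclass
class ClusterLabeling:
    """Raw-cluster to C-label mapping with the centroid summaries used."""

    mapping: dict[int, str]
    summaries: dict[int, tuple[float, float, float]]
    collisions: list[str]


def label_clusters(
    centroids: np.ndarray, t_change: float = 0.10, asym_ratio: float = 2.0
) -> ClusterLabeling:
    """Name k-means centroids C1-C5 from their mean-difference geometry.

    With m = overall centroid mean, m5/m3 = means of the 5'/3' halves:
    C4 if m <= -t_change; C5 if |m|, |m5|, |m3| all below t_change;
    otherwise hypermethylated, split into C1 (5'-dominant), C2
    (3'-dominant) or C3 (island-wide) by ``asym_ratio``. Duplicate
    labels are kept but flagged in ``collisions``.
    """
    if not (0 < t_change < 1):
        raise ValueError("t_change must be in (0, 1)")
    if asym_ratio <= 1:
        raise ValueError("asym_ratio must be > 1")
    centroids = np.asarray(centroids, dtype=float)
    if not np.all(np.isfinite(centroids)):
        raise ValueError("centroid with non-finite entries")
    mapping: dict[int, str] = {}
    summaries: dict[int, tuple[float, float, float]] = {}
    for i, c in enumerate(centroids):
        m, m5, m3 = _centroid_summary(c)
        summaries[i] = (m, m5, m3)
        if m <= -t_change:
            label = "C4"
        elif abs(m) < t_change and abs(m5) < t_change and abs(m3) < t_change:
            label = "C5"
        elif m5 >= asym_ratio * max(m3, t_change / 2):
            label = "C1"
        elif m3 >= asym_ratio * max(m5, t_change / 2):
            label = "C2"
        else:
            label = "C3"
        mapping[i] = label
    collisions = []
    seen: dict[str, int] = {}
    for i, label in mapping.items():
        if label in seen:
            collisions.append(
                f"clusters {seen[label]} and {i} both labeled {label}"
            )
        else:
            seen[label] = i
    for msg in collisions:
        warnings.warn(msg)
    return ClusterLabeling(mapping=mapping, summaries=summaries, collisions=collisions)


def assign_accrual_modes(
    diff: ProfileMatrix,
    k: int = 5,
    seed: int = 0,
    n_restarts: int = 10,
    t_change: float = 0.10,
    asym_ratio: float = 2.0,
    max_missing_frac: float = 0.25,
) -> tuple[pd.DataFrame, np.ndarray, ClusterLabeling]:
    """Impute, cluster and label difference profiles in one step.

    Returns (assignment table, centroids, labeling). The table has one
    row per retained region: region_id, raw_cluster, label and the
    region's own overall/5'/3' mean differences.
    """
    imputed, dropped = impute_profile_rows(diff, max_missing_frac)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} regions with too many missing bins")
    labels, centroids = cluster_difference_profiles(
        imputed, k=k, seed=seed, n_restarts=n_restarts
    )
    labeling = label_clusters(centroids, t_change=t_change, asym_ratio=asym_ratio)
    body = imputed.body_values() if imputed.n_flank_bins else imputed.values
    half = body.shape[1] // 2
    table = pd.DataFrame(
        {
            "region_id": imputed.region_ids,
            "raw_cluster": labels,
            "label": [labeling.mapping[int(c)] for c in labels],
            "overall_mean_diff": body.mean(axis=1),
            "mean5": body[:, :half].mean(axis=1),
            "mean3": body[:, half:].mean(axis=1),
        }
    )
    return table, centroids, labeling


def cgi_mean_beta(
    meth: PointSignal,
    regions: Mapping[str, GenomicInterval],
    min_sites: int = 3,
) -> pd.Series:
    """Unweighted mean beta over the CpG sites inside each region.

    Regions with fewer than ``min_sites`` covered CpGs get NaN (they
    fall to the 'other' class downstream).
    """
    out = {}
    for rid, iv in regions.items():
        _, values = meth.points_in(iv.chrom, iv.start, iv.end)
        out[rid] = float(np.mean(values)) if len(values) >= min_sites else np.nan
    return pd.Series(out, name="mean_beta")


def classify_wt_vs_dko(
    wt_beta: Mapping[str, float] | pd.Series,
    dko_beta: Mapping[str, float] | pd.Series,
    hyper_min: float = 0.5,
    unmeth_max: float = 0.2,
) -> pd.DataFrame:
    """Demethylation / unchanged / other classes from WT vs DKO betas.

    demethylation: methylated in WT (>= hyper_min) and demethylated in
    DKO (<= unmeth_max); unchanged: unmethylated in both; everything
    else (including CGIs with a missing beta) is 'other'.
    """
    if not (0 <= unmeth_max < hyper_min <= 1):
        raise ValueError("need 0 <= unmeth_max < hyper_min <= 1")
    wt = pd.Series(wt_beta, dtype=float)
    dko = pd.Series(dko_beta, dtype=float)
    ids = wt.index.union(dko.index)
    wt = wt.reindex(ids)
    dko = dko.reindex(ids)
    n_missing = int((wt.isna() | dko.isna()).sum())
    if n_missing:
        warnings.warn(f"{n_missing} CGIs with missing beta labeled 'other'")
    labels = np.where(
        (wt >= hyper_min) & (dko <= unmeth_max),
        "demethylation",
        np.where((wt <= unmeth_max) & (dko <= unmeth_max), "unchanged", "other"),
    )
    labels = np.where(wt.isna() | dko.isna(), "other", labels)
    return pd.DataFrame(
        {"region_id": ids, "label": labels, "wt_beta": wt.values, "dko_beta": dko.values}
    ).reset_index(drop=True)


def split_by_h3k4me1_groups(
    enrichment: Mapping[str, float] | pd.Series, seed: int = 0
) -> tuple[pd.Series, float]:
    """Two-class high/low split of per-CGI H3K4me1 enrichment.

    1-D two-means (Lloyd's from min/max initialization, deterministic);
    the reported threshold is the midpoint of the two final means and
    values at or above it are 'high'. All-identical input is an error.
    """
    s = pd.Series(enrichment, dtype=float)
    x = s.to_numpy()
    if np.any(~np.isfinite(x)) or np.any(x < 0):
        raise ValueError("enrichment values must be finite and >= 0")
    if np.ptp(x) == 0:
        raise ValueError("all enrichment values identical: no two-class split exists")
    lo, hi = float(x.min()), float(x.max())
    for _ in range(200):
        mid = (lo + hi) / 2
        high_mask = x >= mid
        new_lo = float(x[~high_mask].mean())
        new_hi = float(x[high_mask].mean())
        if new_lo == lo and new_hi == hi:
            break
        lo, hi = new_lo, new_hi
    threshold = (lo + hi) / 2
    labels = pd.Series(
        np.where(x >= threshold, "high", "low"), index=s.index, name="h3k4me1_group"
    )
    return labels, float(threshold)
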