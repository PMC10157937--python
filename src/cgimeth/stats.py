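"""Statistics shared across the analyses.

Tau tissue-specificity, Spearman correlation matrices, 2x2 chi-square,
Wilcoxon rank-sum (exact enumeration for small samples, tie-corrected
normal approximation otherwise), hypergeometric set enrichment with
Benjamini-Hochberg q-values, exclusive set-overlap counts, PMD/HMD
domain assignment and the ChIP-qPCR percent-input conversion.
"""

from __future__ import annotations

import warnings
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .track_io import GenomicInterval

__all__ = [
    "tau_index",
    "spearman_matrix",
    "chi_square_2x2",
    "rank_sum_test",
    "hypergeometric_enrichment",
    "overlap_counts",
    "domain_distribution",
    "group_domain_fractions",
    "percent_input",
]


def tau_index(x: Sequence[float], log_transform: bool = True) -> float:
    """Tau tissue-specificity index over an expression vector.

    tau = sum_i (1 - x_i / max(x)) / (N - 1); 1 means single-tissue
    expression, 0 uniform expression. With ``log_transform`` (the tspex
    convention, default) values are log2(x + 1)-transformed first.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("need a 1-D vector over at least 2 tissues")
    if np.any(~np.isfinite(x)) or np.any(x < 0):
        raise ValueError("expression values must be finite and >= 0")
    if log_transform:
        x = np.log2(x + 1.0)
    mx = x.max()
    if mx <= 0:
        raise ValueError("tau undefined for an all-zero vector")
    return float(np.sum(1.0 - x / mx) / (len(x) - 1))


def spearman_matrix(features: Mapping[str, pd.Series] | pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rho, pairwise-complete over shared ids.

    Spearman rho is the Pearson correlation of mid-ranks (ties get
    average ranks). Cells with fewer than 3 complete pairs are missing
    with a warning. The result is symmetric with a unit diagonal.
    """
    df = pd.DataFrame(features)
    if len(df) < 3:
        raise ValueError("need at least 3 common ids")
    names = list(df.columns)
    n = len(names)
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 1.0)
    for i, j in combinations(range(n), 2):
        pair = df.iloc[:, [i, j]].dropna()
        if len(pair) < 3:
            warnings.warn(
                f"fewer than 3 complete pairs for ({names[i]}, {names[j]}); "
                "entry left missing"
            )
            continue
        rho = sps.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1]).statistic
        out[i, j] = out[j, i] = rho
    return pd.DataFrame(out, index=names, columns=names)


def chi_square_2x2(table) -> tuple[float, float, dict[str, float]]:
    """Pearson chi-square (1 d.f., no continuity correction) on a 2x2 table.

    Returns (statistic, p-value, row-wise first-column proportions),
    using the closed form n(ad - bc)^2 / product of the four marginals.
    A zero marginal leaves the statistic undefined and raises.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("need a 2x2 table of non-negative integer counts")
    a, b, c, d = t.ravel()
    n = t.sum()
    if n <= 0:
        raise ValueError("empty table")
    marginals = np.array([a + b, c + d, a + c, b + d])
    if np.any(marginals == 0):
        raise ValueError("a zero marginal makes the chi-square statistic undefined")
    stat = n * (a * d - b * c) ** 2 / np.prod(marginals)
    p = float(sps.chi2.sf(stat, df=1))
    proportions = {
        "row1": float(a / (a + b)),
        "row2": float(c / (c + d)),
    }
    return float(stat), p, proportions


def _midranks(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def _exact_rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided p by full enumeration of C(na+nb, na) label assignments."""
    combined = np.concatenate([a, b])
    ranks = _midranks(combined)
    na = len(a)
    w_obs = ranks[:na].sum()
    n_le = n_ge = total = 0
    for idx in combinations(range(len(combined)), na):
        w = ranks[list(idx)].sum()
        total += 1
        if w <= w_obs + 1e-9:
            n_le += 1
        if w >= w_obs - 1e-9:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le, n_ge) / total)


def rank_sum_test(a, b, mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    ``exact`` enumerates every assignment of labels to the pooled
    sample (used automatically when n_a + n_b <= 12); ``normal_approx``
    uses the tie-corrected normal approximation with continuity
    correction. Identical pooled values give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 1.0
    if mode not in {"auto", "exact", "normal_approx"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "exact" or (mode == "auto" and len(a) + len(b) <= 12):
        return _exact_rank_sum_p(a, b)
    return float(
        sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        ).pvalue
    )


def hypergeometric_enrichment(
    query: set,
    annotation: Mapping[str, set],
    universe: set,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query set per annotation set.

    p = P(X >= overlap) for X hypergeometric(|universe|, |set|,
    |query|); fold = (overlap/|query|) / (|set|/|universe|) after
    intersecting each set with the universe. q-values are
    Benjamini-Hochberg across the annotation sets.
    """
    if not universe or not query:
        raise ValueError("universe and query must be non-empty")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    N, n = len(universe), len(query)
    rows = []
    for name, members in annotation.items():
        members = members & universe
        K = len(members)
        k = len(query & members)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if K > 0 else np.nan
        rows.append((name, K, k, fold, p))
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "fold", "p"])
    if len(df):
        df["q"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df


def overlap_counts(named_sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive intersection-combination counts (upset-plot style).

    Every element of the union is counted in exactly one combination,
    the tuple of set names that contain it; only non-empty combinations
    appear. Counts therefore sum to the size of the union.
    """
    names = list(named_sets)
    if len(names) < 2:
        raise ValueError("need at least 2 sets")
    signature: dict = {}
    for element in set().union(*named_sets.values()):
        combo = tuple(name for name in names if element in named_sets[name])
        signature[combo] = signature.get(combo, 0) + 1
    return signature


def _sorted_by_chrom(intervals: Iterable[GenomicInterval]):
    by_chrom: dict[str, list] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = {}
    for chrom, rows in by_chrom.items():
        rows.sort(key=lambda iv: iv.start)
        starts = np.array([iv.start for iv in rows])
        ends = np.array([iv.end for iv in rows])
        if len(starts) > 1 and np.any(starts[1:] < ends[:-1]):
            raise ValueError(f"domain intervals overlap on {chrom}")
        out[chrom] = (starts, ends)
    return out


def _overlap_len(region: GenomicInterval, domains) -> int:
    if region.chrom not in domains:
        return 0
    starts, ends = domains[region.chrom]
    ov = np.minimum(ends, region.end) - np.maximum(starts, region.start)
    return int(np.clip(ov, 0, None).sum())


def domain_distribution(
    regions: Mapping[str, GenomicInterval],
    pmds: Iterable[GenomicInterval],
    hmds: Iterable[GenomicInterval],
) -> pd.Series:
    """Assign each region to PMD, HMD or other by majority overlap.

    The domain class covering the larger fraction of the region wins;
    PMD wins exact ties, and regions touching neither class are
    'other'.
    """
    pmd_idx = _sorted_by_chrom(pmds)
    hmd_idx = _sorted_by_chrom(hmds)
    out = {}
    for rid, region in regions.items():
        p = _overlap_len(region, pmd_idx)
        h = _overlap_len(region, hmd_idx)
        if p == 0 and h == 0:
            out[rid] = "other"
        elif p >= h:
            out[rid] = "PMD"
        else:
            out[rid] = "HMD"
    return pd.Series(out, name="domain")


def group_domain_fractions(
    domains: pd.Series, groups: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-group fractions of regions in PMD / HMD / other."""
    groups = pd.Series(groups)
    df = pd.DataFrame({"domain": domains, "group": groups}).dropna()
    counts = df.groupby(["group", "domain"]).size().unstack(fill_value=0)
    for col in ("PMD", "HMD", "other"):
        if col not in counts:
            counts[col] = 0
    counts = counts[["PMD", "HMD", "other"]]
    return counts.div(counts.sum(axis=1), axis=0)


def percent_input(
    ct_input: float, ct_sample: float, input_fraction: float = 0.05
) -> float:
    """ChIP-qPCR signal as percent of input.

    percent = 100 * input_fraction * 2^(CT_input - CT_sample); with the
    conventional 5% input aliquot, equal CTs give 5%.
    """
    if not (np.isfinite(ct_input) and np.isfinite(ct_sample)):
        raise ValueError("CT values must be finite")
    if not (0 < input_fraction <= 1):
        raise ValueError("input_fraction must be in (0, 1]")
    return float(100.0 * input_fraction * 2.0 ** (ct_input - ct_sample))
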