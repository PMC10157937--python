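"""Orchestration of the headline analyses over on-disk inputs.

Three entry points mirror the study design: ``run_group_analysis``
(k-means accrual-mode classification of promoter CGIs with per-group
summaries), ``run_premark_analysis`` (H3K4me1 high/low split in normal
tissue versus tumor methylation gain), and ``run_wt_dko_analysis``
(demethylation/unchanged classification in DNMT-knockout cells). Each
consumes a :class:`RunConfig` of file paths plus thresholds, loads
through :mod:`cgimeth.track_io`, and returns an
:class:`AnalysisReport`; optional inputs that are absent skip their
summary with a logged notice rather than failing.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, groups, patterns, profiles, stats, track_io

logger = logging.getLogger("cgimeth")

__all__ = [
    "RunConfig",
    "AnalysisReport",
    "run_group_analysis",
    "run_premark_analysis",
    "run_wt_dko_analysis",
    "classify_dataset",
    "premark_dataset",
    "wtdko_dataset",
]


@dataclass
class RunConfig:
    """File paths and thresholds for one pipeline run."""

    # mandatory-per-analysis inputs
    normal_meth: str | None = None
    tumor_meth: str | None = None
    wt_meth: str | None = None
    dko_meth: str | None = None
    cgi_bed: str | None = None
    genes: str | None = None
    # optional inputs
    h3k4me1: str | None = None  # normal-tissue H3K4me1 bedGraph
    h3k4me1_tumor: str | None = None
    h3k4me3: str | None = None
    h3k27me3: str | None = None
    bivalent: str | None = None
    pmd_bed: str | None = None
    hmd_bed: str | None = None
    expression: str | None = None  # gene x tissue TPM
    expression_conditions: str | None = None  # normal/tumor TPM columns
    deg_table: str | None = None
    # parameters
    n_body_bins: int = 20
    flank_bp: int = 2000
    n_flank_bins: int = 20
    k: int = 5
    t_change: float = 0.10
    asym_ratio: float = 2.0
    hyper_min: float = 0.5
    unmeth_max: float = 0.2
    bimodal_ratio: float = 1.5
    min_signal: float | None = None
    min_coverage: int = 10
    seed: int = 0
    outdir: str | None = None

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValueError(
                "missing mandatory input(s): "
                + ", ".join(f"--{n.replace('_', '-')}" for n in missing)
            )
        for n in names:
            p = Path(getattr(self, n))
            if not p.exists():
                raise FileNotFoundError(f"{n}: {p} does not exist")


@dataclass
class AnalysisReport:
    """Named tables/dicts plus provenance; serializable as TSVs + JSON."""

    sections: dict = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def skip(self, what: str) -> None:
        self.skipped.append(what)
        logger.info("skipped: %s", what)

    def summary_dict(self, include_timestamp: bool = True) -> dict:
        out = {"skipped": self.skipped, "provenance": dict(self.provenance)}
        if not include_timestamp:
            out["provenance"].pop("timestamp", None)
        for name, section in self.sections.items():
            if isinstance(section, pd.DataFrame):
                out[name] = {"rows": len(section), "columns": list(section.columns)}
            else:
                out[name] = section
        return out

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, section in self.sections.items():
            if isinstance(section, pd.DataFrame):
                section.to_csv(outdir / f"{name}.tsv", sep="\t", index=False,
                               float_format="%.8g")
        (outdir / "summary.json").write_text(
            json.dumps(self.summary_dict(), indent=1, sort_keys=True, default=str)
        )


def _provenance(cfg: RunConfig) -> dict:
    return {
        "config": dataclasses.asdict(cfg),
        "version": __version__,
        "seed": cfg.seed,
        "timestamp": datetime.datetime.now().isoformat(),
    }


def _load_promoters(cfg: RunConfig):
    """Genes, promoter-CGI map and gene-stranded regions for binning."""
    cfg.require("cgi_bed", "genes")
    gene_list = track_io.read_genes(cfg.genes)
    cgis = track_io.read_bed(cfg.cgi_bed, kind="bed6")
    promoters = track_io.define_promoter_cgis(cgis, gene_list)
    if not promoters:
        raise ValueError("no gene has a promoter CGI; nothing to analyze")
    strand_of = {g.gene_id: g.strand for g in gene_list}
    regions = {
        gid: track_io.with_strand(cgi, strand_of[gid]) for gid, cgi in promoters.items()
    }
    return gene_list, promoters, regions


def _meth_point_signal(path, min_coverage: int) -> track_io.PointSignal:
    df = track_io.read_methylation_coverage(path, min_coverage=min_coverage)
    return track_io.PointSignal.from_dataframe(df)


def _bivalent_set(cfg: RunConfig) -> set[str] | None:
    if cfg.bivalent is None:
        return None
    return set(track_io.read_label_table(cfg.bivalent)["gene_id"])


def _bivalent_chi_square(
    group_a: list[str], group_b: list[str], bivalent: set[str], names=("group_a", "group_b")
) -> dict:
    a_biv = sum(g in bivalent for g in group_a)
    b_biv = sum(g in bivalent for g in group_b)
    table = [[a_biv, len(group_a) - a_biv], [b_biv, len(group_b) - b_biv]]
    stat, p, props = stats.chi_square_2x2(table)
    return {
        "table": table,
        "chi2": stat,
        "p_value": p,
        f"bivalent_pct_{names[0]}": 100.0 * props["row1"],
        f"bivalent_pct_{names[1]}": 100.0 * props["row2"],
    }


def run_group_analysis(cfg: RunConfig) -> AnalysisReport:
    """Accrual-mode classification (C1-C5) plus per-group summaries.

    Mandatory: normal/tumor methylomes, CGI BED, gene TSV. Optional
    summaries (skipped with a notice when inputs are absent): per-group
    expression, Tau tissue-specificity, PMD/HMD distribution, bivalent
    proportions with chi-square.
    """
    cfg.require("normal_meth", "tumor_meth", "cgi_bed", "genes")
    report = AnalysisReport(provenance=_provenance(cfg))
    _, _, regions = _load_promoters(cfg)
    normal = _meth_point_signal(cfg.normal_meth, cfg.min_coverage)
    tumor = _meth_point_signal(cfg.tumor_meth, cfg.min_coverage)

    kwargs = dict(n_body_bins=cfg.n_body_bins, flank_bp=0, orient_by_strand=True)
    m_normal = profiles.build_profile_matrix(regions, normal, **kwargs)
    m_tumor = profiles.build_profile_matrix(regions, tumor, **kwargs)
    diff = profiles.difference_matrix(m_tumor, m_normal)
    assignments, centroids, labeling = groups.assign_accrual_modes(
        diff,
        k=cfg.k,
        seed=cfg.seed,
        t_change=cfg.t_change,
        asym_ratio=cfg.asym_ratio,
    )
    report.sections["assignments"] = assignments
    report.sections["centroids"] = {
        "values": centroids.round(6).tolist(),
        "labels": [labeling.mapping[i] for i in range(len(centroids))],
        "collisions": labeling.collisions,
    }
    label_of = dict(zip(assignments["region_id"], assignments["label"]))
    hyper_genes = [g for g, l in label_of.items() if l in ("C1", "C2", "C3")]
    c5_genes = [g for g, l in label_of.items() if l == "C5"]

    bivalent = _bivalent_set(cfg)
    if bivalent is None:
        report.skip("bivalent proportions (no --bivalent table)")
    elif hyper_genes and c5_genes:
        report.sections["bivalent_enrichment"] = _bivalent_chi_square(
            hyper_genes, c5_genes, bivalent, names=("allhyper", "c5")
        )

    if cfg.pmd_bed is None or cfg.hmd_bed is None:
        report.skip("PMD/HMD distribution (no --pmd-bed/--hmd-bed)")
    else:
        pmds = track_io.read_bed(cfg.pmd_bed, kind="bed3")
        hmds = track_io.read_bed(cfg.hmd_bed, kind="bed3")
        domains = stats.domain_distribution(regions, pmds, hmds)
        fractions = stats.group_domain_fractions(domains, pd.Series(label_of))
        report.sections["domain_fractions"] = fractions.reset_index()

    if cfg.expression is None:
        report.skip("Tau tissue-specificity (no --expression matrix)")
    else:
        tpm = track_io.read_expression(cfg.expression)
        tau = {
            gid: stats.tau_index(tpm.loc[gid].to_numpy())
            for gid in label_of
            if gid in tpm.index
        }
        tau_df = pd.DataFrame(
            {"gene_id": list(tau), "tau": list(tau.values())}
        )
        tau_df["label"] = tau_df["gene_id"].map(label_of)
        report.sections["tau"] = tau_df
        hyper_tau = tau_df.loc[tau_df["label"].isin(["C1", "C2", "C3"]), "tau"]
        c5_tau = tau_df.loc[tau_df["label"] == "C5", "tau"]
        if len(hyper_tau) and len(c5_tau):
            report.sections["tau_comparison"] = {
                "allhyper_median": float(hyper_tau.median()),
                "c5_median": float(c5_tau.median()),
                "p_value": stats.rank_sum_test(hyper_tau, c5_tau),
            }

    if cfg.expression_conditions is None:
        report.skip("tumor/normal expression comparison (no --expression-conditions)")
    else:
        cond = track_io.read_expression(cfg.expression_conditions)
        cond = cond.loc[cond.index.intersection(list(label_of))]
        cond["label"] = [label_of[g] for g in cond.index]
        summary = (
            cond.groupby("label")[["normal_tpm", "tumor_tpm"]].mean().reset_index()
        )
        report.sections["expression_by_group"] = summary

    return report


def _regions_from_annotation(ann):
    promoters = track_io.define_promoter_cgis(ann.cgis, ann.genes)
    strand_of = {g.gene_id: g.strand for g in ann.genes}
    return {
        gid: track_io.with_strand(cgi, strand_of[gid]) for gid, cgi in promoters.items()
    }


def _difference_from_signals(regions, normal, tumor, n_body_bins=20):
    kwargs = dict(n_body_bins=n_body_bins, flank_bp=0, orient_by_strand=True)
    m_normal = profiles.build_profile_matrix(regions, normal, **kwargs)
    m_tumor = profiles.build_profile_matrix(regions, tumor, **kwargs)
    return profiles.difference_matrix(m_tumor, m_normal)


def classify_dataset(ds, seed: int | None = None, **params) -> pd.DataFrame:
    """Accrual-mode assignment table for an in-memory simulated dataset."""
    regions = _regions_from_annotation(ds.annotation)
    diff = _difference_from_signals(
        regions, ds.meth_signal("normal"), ds.meth_signal("tumor")
    )
    table, _, _ = groups.assign_accrual_modes(
        diff, seed=ds.config.seed if seed is None else seed, **params
    )
    return table


def premark_dataset(ds, alpha: float = 0.01) -> dict:
    """H3K4me1 high/low vs methylation-gain comparison, in memory."""
    regions = _regions_from_annotation(ds.annotation)
    k4me1 = ds.tracks["h3k4me1_normal"]
    enrichment = pd.Series(
        {gid: profiles.region_mean_signal(k4me1, iv) for gid, iv in regions.items()}
    )
    split, threshold = groups.split_by_h3k4me1_groups(enrichment)
    diff = _difference_from_signals(
        regions, ds.meth_signal("normal"), ds.meth_signal("tumor")
    )
    with np.errstate(invalid="ignore"):
        gain = pd.Series(np.nanmean(diff.values, axis=1), index=diff.region_ids)
    comparison = patterns.compare_methylation_gain(gain, split, alpha=alpha)
    return {"threshold": threshold, "groups": split, "gain": gain, **comparison}


def wtdko_dataset(ds, hyper_min: float = 0.5, unmeth_max: float = 0.2) -> pd.DataFrame:
    """WT-vs-DKO demethylation/unchanged classification, in memory."""
    regions = _regions_from_annotation(ds.annotation)
    wt_beta = groups.cgi_mean_beta(ds.meth_signal("wt"), regions)
    dko_beta = groups.cgi_mean_beta(ds.meth_signal("dko"), regions)
    return groups.classify_wt_vs_dko(
        wt_beta, dko_beta, hyper_min=hyper_min, unmeth_max=unmeth_max
    )


def run_premark_analysis(cfg: RunConfig) -> AnalysisReport:
    """H3K4me1 high/low split in normal tissue vs tumor methylation gain."""
    cfg.require("normal_meth", "tumor_meth", "cgi_bed", "genes", "h3k4me1")
    report = AnalysisReport(provenance=_provenance(cfg))
    _, _, regions = _load_promoters(cfg)
    normal = _meth_point_signal(cfg.normal_meth, cfg.min_coverage)
    tumor = _meth_point_signal(cfg.tumor_meth, cfg.min_coverage)
    k4me1 = track_io.read_signal_bedgraph(cfg.h3k4me1)

    enrichment = pd.Series(
        {gid: profiles.region_mean_signal(k4me1, iv) for gid, iv in regions.items()}
    )
    split, threshold = groups.split_by_h3k4me1_groups(enrichment)

    kwargs = dict(n_body_bins=cfg.n_body_bins, flank_bp=0, orient_by_strand=True)
    m_normal = profiles.build_profile_matrix(regions, normal, **kwargs)
    m_tumor = profiles.build_profile_matrix(regions, tumor, **kwargs)
    diff = profiles.difference_matrix(m_tumor, m_normal)
    with np.errstate(invalid="ignore"):
        gain = pd.Series(
            np.nanmean(diff.values, axis=1), index=diff.region_ids, name="gain"
        )
    comparison = patterns.compare_methylation_gain(gain, split)
    report.sections["premark"] = {"threshold": threshold, **comparison}
    report.sections["h3k4me1_groups"] = pd.DataFrame(
        {"region_id": split.index, "h3k4me1_group": split.values,
         "enrichment": enrichment[split.index].values,
         "methylation_gain": gain.reindex(split.index).values}
    )

    m_k4me1 = profiles.build_profile_matrix(
        regions,
        k4me1,
        n_body_bins=cfg.n_body_bins,
        flank_bp=cfg.flank_bp,
        n_flank_bins=cfg.n_flank_bins,
        orient_by_strand=True,
    )
    calls = patterns.call_patterns(
        m_k4me1, min_signal=cfg.min_signal, bimodal_ratio=cfg.bimodal_ratio
    )
    calls["h3k4me1_group"] = calls["region_id"].map(split)
    report.sections["pattern_calls"] = calls
    return report


def run_wt_dko_analysis(cfg: RunConfig) -> AnalysisReport:
    """Demethylation/unchanged classification in WT vs DKO cells."""
    cfg.require("wt_meth", "dko_meth", "cgi_bed", "genes")
    report = AnalysisReport(provenance=_provenance(cfg))
    gene_list, _, regions = _load_promoters(cfg)
    wt = _meth_point_signal(cfg.wt_meth, cfg.min_coverage)
    dko = _meth_point_signal(cfg.dko_meth, cfg.min_coverage)
    wt_beta = groups.cgi_mean_beta(wt, regions)
    dko_beta = groups.cgi_mean_beta(dko, regions)
    table = groups.classify_wt_vs_dko(
        wt_beta, dko_beta, hyper_min=cfg.hyper_min, unmeth_max=cfg.unmeth_max
    )
    report.sections["wtdko_assignments"] = table
    counts = table["label"].value_counts().to_dict()
    report.sections["wtdko_counts"] = {str(k): int(v) for k, v in counts.items()}

    bivalent = _bivalent_set(cfg)
    if bivalent is None:
        report.skip("bivalent proportions (no --bivalent table)")
    else:
        demeth = table.loc[table["label"] == "demethylation", "region_id"].tolist()
        unchanged = table.loc[table["label"] == "unchanged", "region_id"].tolist()
        if demeth and unchanged:
            report.sections["bivalent_enrichment"] = _bivalent_chi_square(
                demeth, unchanged, bivalent, names=("demethylation", "unchanged")
            )

    if cfg.h3k4me1 is None:
        report.skip("histone enrichment deltas (no --h3k4me1 track)")
    else:
        track = track_io.read_signal_bedgraph(cfg.h3k4me1)
        enrich = patterns.mark_enrichment_at_promoters(track, gene_list)
        merged = table.merge(
            enrich.rename("h3k4me1").reset_index(names="region_id"), on="region_id",
            how="left",
        )
        report.sections["h3k4me1_by_class"] = (
            merged.groupby("label")["h3k4me1"].mean().reset_index()
        )
    return report
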