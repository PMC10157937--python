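"""Synthetic paired tumor/normal epigenomes with planted ground truth.

One artificial chromosome ("chrS") carries regularly spaced genes, each
with a promoter CGI straddling its TSS. Every gene gets a planted
methylation accrual mode (C1 = 5' gain, C2 = 3' gain, C3 = island-wide
gain, C4 = loss, C5 = no change), a bivalent flag enriched in the
hypermethylated modes, a PMD/HMD background domain, an H3K4me1 promoter
class (high-unimodal / low / bimodal) coupled to the accrual mode, a
WT-vs-DKO demethylation intent coupled to bivalency, and a
tissue-specific expression profile. CpG read counts are drawn
beta-binomially, histone tracks carry multiplicative log-normal noise,
and everything is deterministic given the config seed.

The generated files use exactly the formats ``track_io`` reads, so the
full analysis pipeline can run against them without external data.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import track_io
from .track_io import GeneRecord, GenomicInterval, PointSignal, SignalTrack

__all__ = [
    "SimulationConfig",
    "SyntheticAnnotation",
    "SimulatedDataset",
    "generate_annotation",
    "generate_methylomes",
    "generate_histone_tracks",
    "generate_expression",
    "simulate_dataset",
]

CHROM = "chrS"
HYPER_GROUPS = ("C1", "C2", "C3")


@dataclass
class SimulationConfig:
    """All generator knobs; defaults define the reference study conditions."""

    n_genes: int = 300
    genome_size: int | None = None
    gene_spacing: int = 6000
    cgi_length_range: tuple[int, int] = (600, 1400)
    group_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"C1": 0.15, "C2": 0.15, "C3": 0.20, "C4": 0.10, "C5": 0.40}
    )
    effect_size: float = 0.3  # delta beta of hyper accrual
    depth: int = 30
    overdispersion: float = 0.1  # beta-binomial rho
    cgi_beta: float = 0.05
    c4_normal_beta: float = 0.5  # C4 promoters start partially methylated
    hmd_beta: float = 0.85
    pmd_beta: float = 0.55
    cpg_spacing_cgi: int = 20
    cpg_spacing_background: int = 150
    bivalent_frac_hyper: float = 0.60
    bivalent_frac_other: float = 0.15
    pmd_prob_hyper: float = 0.30
    pmd_prob_other: float = 0.06
    k4me1_amp: float = 8.0
    k4me1_low_amp: float = 1.5
    k4me3_amp: float = 6.0
    k27me3_amp: float = 4.0
    k27me3_baseline: float = 0.1
    reduction_factor: float = 0.4  # tumor H3K4me1 at high-unimodal promoters
    histone_noise_sd: float = 0.10  # sigma of multiplicative log-normal noise
    track_bin_bp: int = 50
    flank_bp: int = 2000
    peak_threshold: float = 1.0
    premark_coupling: bool = True
    wt_hyper_beta: float = 0.85
    wt_other_beta: float = 0.35
    dko_beta: float = 0.03
    demeth_prob_bivalent: float = 0.70
    demeth_prob_nonbivalent: float = 0.15
    n_tissues: int = 10
    ts_frac_hyper: float = 0.80
    ts_frac_other: float = 0.20
    ts_fold: float = 32.0
    base_tpm_hyper: float = 5.0
    base_tpm_other: float = 50.0
    tumor_downreg_factor: float = 0.3
    deg_down_prob_hyper: float = 0.8
    deg_up_prob_other: float = 0.05
    expr_noise_sd: float = 0.10
    seed: int = 1

    def __post_init__(self):
        fractions = dict(self.group_fractions)
        if set(fractions) != {"C1", "C2", "C3", "C4", "C5"}:
            raise ValueError("group_fractions must cover C1..C5")
        if abs(sum(fractions.values()) - 1.0) > 1e-9:
            raise ValueError("group fractions must sum to 1")
        if not (0 <= self.effect_size < 1):
            raise ValueError("effect_size must be in [0, 1)")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if not (0 < self.overdispersion < 1):
            raise ValueError("overdispersion must be in (0, 1)")
        lo, hi = self.cgi_length_range
        if not (0 < lo <= hi):
            raise ValueError("invalid cgi_length_range")
        if self.gene_spacing < hi + 2 * self.flank_bp + 2 * self.track_bin_bp:
            raise ValueError(
                "gene_spacing too small: promoter windows of adjacent genes overlap"
            )
        required = self.n_genes * self.gene_spacing + 2 * self.flank_bp + 1000
        if self.genome_size is None:
            self.genome_size = required
        elif self.genome_size < required:
            raise ValueError(
                f"genome_size {self.genome_size} too small for {self.n_genes} genes "
                f"(need >= {required})"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cgi_length_range"] = list(self.cgi_length_range)
        d["group_fractions"] = dict(self.group_fractions)
        return d


@dataclass
class SyntheticAnnotation:
    genes: list[GeneRecord]
    cgis: list[GenomicInterval]
    pmds: list[GenomicInterval]
    hmds: list[GenomicInterval]
    bivalent: set[str]
    truth: pd.DataFrame  # one row per gene, all planted labels


def _exact_allocation(fractions: Mapping[str, float], n: int) -> list[str]:
    """Largest-remainder allocation of n items to the C1..C5 fractions."""
    names = ["C1", "C2", "C3", "C4", "C5"]
    raw = np.array([fractions[name] * n for name in names])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in order[:remainder]:
        counts[i] += 1
    labels = []
    for name, c in zip(names, counts):
        labels.extend([name] * c)
    return labels


def generate_annotation(cfg: SimulationConfig) -> SyntheticAnnotation:
    """Place genes, promoter CGIs and PMD/HMD domains; emit all truth labels."""
    rng = np.random.default_rng([cfg.seed, 0])
    lo, hi = cfg.cgi_length_range
    offset0 = cfg.flank_bp + 500

    labels = _exact_allocation(cfg.group_fractions, cfg.n_genes)
    groups = [labels[i] for i in rng.permutation(cfg.n_genes)]

    genes: list[GeneRecord] = []
    cgis: list[GenomicInterval] = []
    rows = []
    domain_of_gene = []
    for i in range(cfg.n_genes):
        group = groups[i]
        block_start = offset0 + i * cfg.gene_spacing
        length = int(rng.integers(lo, hi + 1))
        cgi_start = block_start + (cfg.gene_spacing - length) // 2
        cgi = GenomicInterval(CHROM, cgi_start, cgi_start + length, ".", f"CGI{i:04d}")
        strand = "+" if rng.random() < 0.5 else "-"
        tss = cgi_start + length // 3 if strand == "+" else cgi_start + (2 * length) // 3
        transcript_tss = [tss]
        if rng.random() < 0.2:  # a second transcript TSS inside the same CGI
            alt = int(np.clip(tss + int(rng.integers(-length // 4, length // 4 + 1)),
                              cgi_start, cgi_start + length - 1))
            if alt != tss:
                transcript_tss.append(alt)
        gene = GeneRecord(f"G{i:04d}", CHROM, tss, strand, tuple(transcript_tss))
        genes.append(gene)
        cgis.append(cgi)

        hyper = group in HYPER_GROUPS
        bivalent = rng.random() < (
            cfg.bivalent_frac_hyper if hyper else cfg.bivalent_frac_other
        )
        domain = "PMD" if rng.random() < (
            cfg.pmd_prob_hyper if hyper else cfg.pmd_prob_other
        ) else "HMD"
        domain_of_gene.append(domain)
        if cfg.premark_coupling:
            k4me1_class = {"C4": "low", "C5": "bimodal"}.get(group, "high-unimodal")
        else:
            k4me1_class = None  # filled after the loop by an uncoupled shuffle
        if bivalent:
            demeth = rng.random() < cfg.demeth_prob_bivalent
        else:
            demeth = rng.random() < cfg.demeth_prob_nonbivalent
        if demeth:
            intent = "demethylation"
        else:
            intent = "unchanged" if rng.random() < 0.85 else "other"
        tissue_specific = rng.random() < (
            cfg.ts_frac_hyper if hyper else cfg.ts_frac_other
        )
        target_tissue = int(rng.integers(cfg.n_tissues)) if tissue_specific else -1
        rows.append(
            {
                "gene_id": gene.gene_id,
                "cgi_id": cgi.id,
                "chrom": CHROM,
                "strand": strand,
                "tss": tss,
                "cgi_start": cgi.start,
                "cgi_end": cgi.end,
                "group": group,
                "bivalent": bivalent,
                "domain": domain,
                "k4me1_class": k4me1_class,
                "wtdko_intent": intent,
                "tissue_specific": tissue_specific,
                "target_tissue": target_tissue,
            }
        )
    truth = pd.DataFrame(rows)
    if not cfg.premark_coupling:
        coupled = [
            {"C4": "low", "C5": "bimodal"}.get(g, "high-unimodal") for g in groups
        ]
        truth["k4me1_class"] = np.array(coupled)[rng.permutation(cfg.n_genes)]

    # one domain segment per gene block, tiled edge to edge; the tail -> HMD
    boundaries = [0]
    for i in range(cfg.n_genes):
        boundaries.append(offset0 + (i + 1) * cfg.gene_spacing)
    boundaries.append(cfg.genome_size)
    seg_labels = list(domain_of_gene) + ["HMD"]
    pmds, hmds = [], []
    # merge adjacent segments with the same label
    start = boundaries[0]
    for i in range(len(seg_labels)):
        if i + 1 == len(seg_labels) or seg_labels[i + 1] != seg_labels[i]:
            iv = GenomicInterval(CHROM, start, boundaries[i + 1], ".",
                                 f"{seg_labels[i]}_{len(pmds) + len(hmds):03d}")
            (pmds if seg_labels[i] == "PMD" else hmds).append(iv)
            start = boundaries[i + 1]
    bivalent = set(truth.loc[truth["bivalent"], "gene_id"])
    return SyntheticAnnotation(genes, cgis, pmds, hmds, bivalent, truth)


def _beta_binomial(rng, mu: np.ndarray, n_total: np.ndarray, rho: float) -> np.ndarray:
    mu = np.clip(mu, 0.02, 0.98)
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    p = rng.beta(a, b)
    return rng.binomial(n_total, p)


def _sites_and_mu(ann: SyntheticAnnotation, cfg: SimulationConfig):
    """CpG site positions plus planted per-site beta for every condition."""
    truth = ann.truth
    pos_list, mu = [], {k: [] for k in ("normal", "tumor", "wt", "dko")}
    for row in truth.itertuples(index=False):
        start, end = row.cgi_start, row.cgi_end
        pos = np.arange(start + cfg.cpg_spacing_cgi // 2, end, cfg.cpg_spacing_cgi)
        mid = (start + end) // 2
        base = np.full(len(pos), cfg.cgi_beta)
        normal = base.copy()
        tumor = base.copy()
        if row.group == "C4":
            normal[:] = cfg.c4_normal_beta
            tumor[:] = cfg.c4_normal_beta - cfg.effect_size
        elif row.group == "C3":
            tumor = base + cfg.effect_size
        elif row.group in ("C1", "C2"):
            # C1 gains on the gene's 5' half, C2 on the 3' half
            five_prime = pos < mid if row.strand == "+" else pos >= mid
            gain_mask = five_prime if row.group == "C1" else ~five_prime
            tumor = base.copy()
            tumor[gain_mask] += cfg.effect_size
        wt = {
            "demethylation": cfg.wt_hyper_beta,
            "unchanged": cfg.cgi_beta,
            "other": cfg.wt_other_beta,
        }[row.wtdko_intent]
        pos_list.append(pos)
        mu["normal"].append(normal)
        mu["tumor"].append(tumor)
        mu["wt"].append(np.full(len(pos), wt))
        mu["dko"].append(np.full(len(pos), cfg.dko_beta))

    # background CpGs across the domain tiling, skipping CGIs
    bg_pos = np.arange(
        cfg.cpg_spacing_background // 2, cfg.genome_size, cfg.cpg_spacing_background
    )
    cgi_starts = truth["cgi_start"].to_numpy()
    cgi_ends = truth["cgi_end"].to_numpy()
    idx = np.searchsorted(cgi_starts, bg_pos, side="right") - 1
    inside = (idx >= 0) & (bg_pos < cgi_ends[np.clip(idx, 0, None)])
    bg_pos = bg_pos[~inside]
    pmd_starts = np.array([iv.start for iv in ann.pmds])
    pmd_ends = np.array([iv.end for iv in ann.pmds])
    if len(pmd_starts):
        j = np.searchsorted(pmd_starts, bg_pos, side="right") - 1
        in_pmd = (j >= 0) & (bg_pos < pmd_ends[np.clip(j, 0, None)])
    else:
        in_pmd = np.zeros(len(bg_pos), dtype=bool)
    bg_beta = np.where(in_pmd, cfg.pmd_beta, cfg.hmd_beta)
    pos_list.append(bg_pos)
    mu["normal"].append(bg_beta)
    mu["tumor"].append(bg_beta)
    mu["wt"].append(bg_beta)
    mu["dko"].append(np.full(len(bg_pos), cfg.dko_beta))

    pos = np.concatenate(pos_list)
    order = np.argsort(pos, kind="stable")
    return pos[order], {k: np.concatenate(v)[order] for k, v in mu.items()}


def generate_methylomes(
    ann: SyntheticAnnotation, cfg: SimulationConfig
) -> dict[str, pd.DataFrame]:
    """Sample CpG call tables (normal/tumor and WT/DKO) at the planted betas."""
    rng = np.random.default_rng([cfg.seed, 1])
    pos, mu = _sites_and_mu(ann, cfg)
    out = {}
    for condition in ("normal", "tumor", "wt", "dko"):
        n_total = np.maximum(1, rng.poisson(cfg.depth, size=len(pos)))
        n_meth = _beta_binomial(rng, mu[condition], n_total, cfg.overdispersion)
        out[condition] = pd.DataFrame(
            {
                "chrom": CHROM,
                "pos": pos,
                "n_meth": n_meth,
                "n_total": n_total,
                "beta": n_meth / n_total,
            }
        )
    return out


def _gauss(x: np.ndarray, center: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - center) / sd) ** 2)


def generate_histone_tracks(
    ann: SyntheticAnnotation, cfg: SimulationConfig
) -> tuple[dict[str, SignalTrack], dict[str, list[GenomicInterval]]]:
    """Histone bedGraph-style tracks plus threshold-crossing peak calls.

    High-unimodal promoters carry a central H3K4me1 peak in normal,
    scaled by ``reduction_factor`` in tumor (same noise realization, so
    the reduction is exact); bimodal promoters have two flanking peaks
    identical in both conditions; H3K4me3 is unimodal everywhere with
    condition-independent amplitude; H3K27me3 is elevated only at
    bivalent promoters.
    """
    rng = np.random.default_rng([cfg.seed, 2])
    truth = ann.truth
    tracks_records: dict[str, list] = {
        "h3k4me1_normal": [],
        "h3k4me1_tumor": [],
        "h3k4me3_normal": [],
        "h3k4me3_tumor": [],
        "h3k27me3": [],
    }
    for row in truth.itertuples(index=False):
        start, end = row.cgi_start, row.cgi_end
        length = end - start
        w_start = start - cfg.flank_bp
        w_end = end + cfg.flank_bp
        edges = np.arange(w_start, w_end + cfg.track_bin_bp, cfg.track_bin_bp)
        centers = (edges[:-1] + edges[1:]) / 2.0
        mid = (start + end) / 2.0

        if row.k4me1_class == "high-unimodal":
            k4me1 = cfg.k4me1_amp * _gauss(centers, mid, length / 5)
        elif row.k4me1_class == "low":
            k4me1 = cfg.k4me1_low_amp * _gauss(centers, mid, length / 5)
        else:  # bimodal: flanking peaks just outside the island edges
            k4me1 = cfg.k4me1_amp * (
                _gauss(centers, start - 200, 150) + _gauss(centers, end + 200, 150)
            )
        noise = np.exp(rng.normal(0.0, cfg.histone_noise_sd, size=len(centers)))
        k4me1_normal = k4me1 * noise
        factor = cfg.reduction_factor if row.k4me1_class == "high-unimodal" else 1.0
        k4me1_tumor = k4me1_normal * factor

        k4me3 = cfg.k4me3_amp * _gauss(centers, mid, length / 5)
        k4me3_normal = k4me3 * np.exp(
            rng.normal(0.0, cfg.histone_noise_sd, size=len(centers))
        )
        k4me3_tumor = k4me3 * np.exp(
            rng.normal(0.0, cfg.histone_noise_sd, size=len(centers))
        )
        if row.bivalent:
            k27me3 = cfg.k27me3_amp * _gauss(centers, mid, length / 3)
        else:
            k27me3 = np.full(len(centers), cfg.k27me3_baseline)
        k27me3 = k27me3 * np.exp(
            rng.normal(0.0, cfg.histone_noise_sd, size=len(centers))
        )

        for name, values in (
            ("h3k4me1_normal", k4me1_normal),
            ("h3k4me1_tumor", k4me1_tumor),
            ("h3k4me3_normal", k4me3_normal),
            ("h3k4me3_tumor", k4me3_tumor),
            ("h3k27me3", k27me3),
        ):
            recs = tracks_records[name]
            for s, e, v in zip(edges[:-1], edges[1:], values):
                recs.append((CHROM, int(s), int(e), round(float(v), 6)))

    tracks = {name: SignalTrack.from_records(recs) for name, recs in tracks_records.items()}
    peaks = {
        name: _call_threshold_peaks(tracks[name], cfg.peak_threshold)
        for name in ("h3k4me1_normal", "h3k4me3_normal")
    }
    return tracks, peaks


def _call_threshold_peaks(track: SignalTrack, threshold: float) -> list[GenomicInterval]:
    """Contiguous runs of above-threshold bins become narrowPeak intervals."""
    peaks = []
    for chrom, (starts, ends, values) in track.data.items():
        run = None  # [start, end, height, summit]
        for s, e, v in zip(starts, ends, values):
            if v > threshold:
                if run is not None and s == run[1]:
                    run[1] = int(e)
                    if v > run[2]:
                        run[2], run[3] = float(v), int((s + e) // 2)
                else:
                    if run is not None:
                        peaks.append(_peak(chrom, *run, len(peaks)))
                    run = [int(s), int(e), float(v), int((s + e) // 2)]
            elif run is not None:
                peaks.append(_peak(chrom, *run, len(peaks)))
                run = None
        if run is not None:
            peaks.append(_peak(chrom, *run, len(peaks)))
    return peaks


def _peak(chrom, start, end, height, summit, i) -> GenomicInterval:
    return GenomicInterval(
        chrom,
        int(start),
        int(end),
        ".",
        f"peak_{i:05d}",
        {
            "score": int(min(1000, round(height * 100))),
            "signalValue": float(height),
            "pValue": -1.0,
            "qValue": -1.0,
            "peak": int(summit - start),
        },
    )


def generate_expression(
    ann: SyntheticAnnotation, cfg: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """TPM-by-tissue matrix, tumor/normal expression columns, DEG labels."""
    rng = np.random.default_rng([cfg.seed, 3])
    truth = ann.truth
    n = len(truth)
    hyper = truth["group"].isin(HYPER_GROUPS).to_numpy()
    base = np.where(hyper, cfg.base_tpm_hyper, cfg.base_tpm_other)

    tissues = [f"tissue_{j:02d}" for j in range(cfg.n_tissues)]
    tpm = np.tile(base[:, None], (1, cfg.n_tissues)).astype(float)
    ts = truth["tissue_specific"].to_numpy()
    target = truth["target_tissue"].to_numpy()
    for i in np.flatnonzero(ts):
        tpm[i, :] = base[i] / cfg.ts_fold
        tpm[i, target[i]] = base[i]
    tpm *= np.exp(rng.normal(0.0, cfg.expr_noise_sd, size=tpm.shape))
    tpm_df = pd.DataFrame(tpm, index=truth["gene_id"], columns=tissues)
    tpm_df.index.name = "gene_id"

    normal = base * np.exp(rng.normal(0.0, cfg.expr_noise_sd, size=n))
    tumor = normal * np.where(hyper, cfg.tumor_downreg_factor, 1.0)
    tumor = tumor * np.exp(rng.normal(0.0, cfg.expr_noise_sd, size=n))
    cond_df = pd.DataFrame(
        {"normal_tpm": normal, "tumor_tpm": tumor}, index=truth["gene_id"]
    )
    cond_df.index.name = "gene_id"

    u = rng.random(n)
    label = np.where(
        hyper & (u < cfg.deg_down_prob_hyper),
        "down",
        np.where(~hyper & (u < cfg.deg_up_prob_other), "up", "ns"),
    )
    q = np.where(label == "ns", 0.5, 0.001)
    deg_df = pd.DataFrame({"gene_id": truth["gene_id"], "label": label, "q": q})
    return tpm_df, cond_df, deg_df


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    annotation: SyntheticAnnotation
    methylomes: dict[str, pd.DataFrame]
    tracks: dict[str, SignalTrack]
    peaks: dict[str, list[GenomicInterval]]
    expression_tissues: pd.DataFrame
    expression_conditions: pd.DataFrame
    deg: pd.DataFrame

    def meth_signal(self, condition: str) -> PointSignal:
        return PointSignal.from_dataframe(self.methylomes[condition])


def simulate_dataset(cfg: SimulationConfig, outdir=None) -> SimulatedDataset:
    """Run all four generators; optionally write every output file.

    File output (all plain text, formats readable by ``track_io``):
    genes.tsv, cgis.bed, pmds.bed, hmds.bed, bivalent.tsv, truth.tsv,
    config.yaml, {normal,tumor,wt,dko}.cov, five bedGraph tracks, two
    narrowPeak files, expression_tissues.tsv,
    expression_conditions.tsv, deg.tsv. Byte-identical across runs for
    an identical config.
    """
    ann = generate_annotation(cfg)
    methylomes = generate_methylomes(ann, cfg)
    tracks, peaks = generate_histone_tracks(ann, cfg)
    tpm_df, cond_df, deg_df = generate_expression(ann, cfg)
    ds = SimulatedDataset(cfg, ann, methylomes, tracks, peaks, tpm_df, cond_df, deg_df)
    if outdir is not None:
        write_dataset(ds, outdir)
    return ds


def write_dataset(ds: SimulatedDataset, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = ds.annotation
    track_io.write_genes(ann.genes, outdir / "genes.tsv")
    track_io.write_bed(ann.cgis, outdir / "cgis.bed", kind="bed6")
    track_io.write_bed(ann.pmds, outdir / "pmds.bed", kind="bed3")
    track_io.write_bed(ann.hmds, outdir / "hmds.bed", kind="bed3")
    with open(outdir / "bivalent.tsv", "w") as fh:
        fh.write("gene_id\tlabel\n")
        for gid in sorted(ann.bivalent):
            fh.write(f"{gid}\tbivalent\n")
    ann.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(ds.config.to_dict(), sort_keys=True)
    )
    for condition, df in ds.methylomes.items():
        track_io.write_methylation_coverage(df, outdir / f"{condition}.cov")
    for name, track in ds.tracks.items():
        track_io.write_bedgraph(track, outdir / f"{name}.bedgraph")
    for name, peaks in ds.peaks.items():
        track_io.write_bed(peaks, outdir / f"{name}_peaks.narrowPeak", kind="narrowPeak")
    ds.expression_tissues.to_csv(
        outdir / "expression_tissues.tsv", sep="\t", float_format="%.6g"
    )
    ds.expression_conditions.to_csv(
        outdir / "expression_conditions.tsv", sep="\t", float_format="%.6g"
    )
    ds.deg.to_csv(outdir / "deg.tsv", sep="\t", index=False, float_format="%.6g")
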