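"""Synthetic ATAC-seq cohorts with planted ground truth.

The generator emulates the statistical structure of a stem-cell culture
cohort profiled by ATAC-seq: ~60 samples falling into 3 clusters, each
cluster defined by a program of peaks (mostly distal regulatory
elements) that are open only in that cluster's samples; negative-
binomial read counts scaled by per-sample library size; expression of
linked genes tracking the accessibility of their distal peak; motif
programs marking each cluster's peaks; and a paired mouse cohort sharing
part of its program through a one-to-one homolog map.  Everything is
planted, so every downstream stage of the pipeline can be tested against
exact truth without external data.

The toy genome is a single linear chromosome with genes on a regular
grid (TSS every 1.2 Mb), which makes promoter/DRE windows and
nearest-gene assignment unambiguous.  Coordinates are 0-based half-open.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .crossmap import HomologMap
from .matrixio import (
    CountMatrix,
    GeneAnnotation,
    PeakSet,
    write_bed,
    write_genes_tsv,
    write_matrix_tsv,
)

__all__ = [
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_paired_species",
    "generate_saturation_presence",
    "simulate_technical_replicates",
    "write_cohort",
]

_GENE_SPACING = 1_200_000
_TSS_OFFSET = 600_000
_PEAK_HALFWIDTH = 250
_DRE_CLUSTER_OFFSET = 50_000  # genomic offset of a planted distal peak from its gene


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the human arm of the study design: 60 samples in 3
    clusters, 20,000 peaks of which 2% per cluster are cluster-specific,
    ~70% of peaks at DRE coordinates, negative-binomial counts
    (dispersion 0.1) with open/closed mean ratio 8, and a motif universe
    of 414 with 10-motif cluster programs.
    """

    n_clusters: int = 3
    samples_per_cluster: tuple = (20, 20, 20)
    n_peaks: int = 20_000
    frac_cluster_specific: float = 0.02  # per cluster
    frac_dre: float = 0.7
    nb_dispersion: float = 0.1
    library_size_range: tuple = (150_000, 450_000)
    open_mean: float = 40.0
    closed_mean: float = 5.0
    link_noise_sd: float = 1.0
    link_target_r: float | None = None  # overrides link_noise_sd when set
    frac_background_linked: float = 0.3  # free genes with one linked distal peak
    bg_sample_jitter_sd: float = 0.5  # log-normal per-sample wobble of bg peaks
    n_genes: int = 2_000
    n_motifs: int = 414
    motif_program_size: int = 10
    motif_background_rate: float = 0.05
    replicate_noise_sd: float = 0.2
    presence_threshold: float = 1.0
    dre_bias: float = 0.9  # fraction of cluster-specific peaks at DRE coordinates
    sample_prefix: str = "s"
    gene_prefix: str = "gene"
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = {
            "frac_cluster_specific": self.frac_cluster_specific,
            "frac_dre": self.frac_dre,
            "motif_background_rate": self.motif_background_rate,
            "dre_bias": self.dre_bias,
            "frac_background_linked": self.frac_background_linked,
        }
        for name, v in fracs.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if len(self.samples_per_cluster) != self.n_clusters:
            raise ValueError("samples_per_cluster length must equal n_clusters")
        if sum(self.samples_per_cluster) < self.n_clusters:
            raise ValueError("need at least one sample per cluster")
        if not (self.open_mean > self.closed_mean > 0):
            raise ValueError("require open_mean > closed_mean > 0")
        n_specific = self.n_clusters * round(self.frac_cluster_specific * self.n_peaks)
        if n_specific > self.n_genes:
            raise ValueError(
                "n_genes must be >= total cluster-specific peaks "
                f"({n_specific}) so each planted link has its own gene"
            )
        if self.n_motifs < self.n_clusters * self.motif_program_size:
            raise ValueError("n_motifs too small for the cluster motif programs")

    @property
    def n_samples(self) -> int:
        return int(sum(self.samples_per_cluster))


@dataclass
class SyntheticCohort:
    """A generated cohort plus its planted truth."""

    config: CohortConfig
    peaks: PeakSet
    counts: CountMatrix
    presence: pd.DataFrame
    genes: GeneAnnotation
    expression: pd.DataFrame  # genes x samples
    true_labels: pd.Series  # sample -> cluster index (0-based)
    true_links: set  # cluster-program links {(peak_id, gene_id)}
    background_links: set  # planted links on background (uninformative) peaks
    true_motif_programs: dict  # cluster -> set of motif ids
    motif_membership: pd.DataFrame  # peaks x motifs, binary
    cluster_specific_peaks: dict  # cluster -> list of peak ids
    peak_region_truth: pd.Series  # peak -> planted region class


def _make_genes(cfg: CohortConfig) -> GeneAnnotation:
    idx = np.arange(cfg.n_genes)
    tss = idx * _GENE_SPACING + _TSS_OFFSET
    strand = np.where(idx % 2 == 0, "+", "-")
    sign = np.where(strand == "+", 1, -1)
    tts = tss + sign * 20_000
    exons = [
        [tuple(sorted((int(t), int(t + s * 2_000)))), tuple(sorted((int(e - s * 2_000), int(e))))]
        for t, e, s in zip(tss, tts, sign)
    ]
    return GeneAnnotation(
        pd.DataFrame(
            {
                "gene_id": [f"{cfg.gene_prefix}{i:05d}" for i in idx],
                "chrom": cfg.chrom,
                "strand": strand,
                "tss": tss,
                "tts": tts,
                "exons": exons,
            }
        )
    )


def _promoter_mid(tss: int, strand: str, slot: int) -> int:
    # keeps the signed TSS offset within the promoter window [-1000, 100]
    return tss - 150 * slot if strand == "+" else tss + 150 * slot


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate one cohort; deterministic under ``config.seed``."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_samples = cfg.n_samples
    sample_ids = [f"{cfg.sample_prefix}{j:03d}" for j in range(n_samples)]
    labels = np.repeat(np.arange(cfg.n_clusters), cfg.samples_per_cluster)
    genes = _make_genes(cfg)
    gdf = genes.df

    per_cluster = round(cfg.frac_cluster_specific * cfg.n_peaks)
    n_dre_per_cluster = round(cfg.dre_bias * per_cluster)
    n_defining = cfg.n_clusters * per_cluster

    # --- peak layout -----------------------------------------------------
    chroms, starts, ends = [], [], []
    peak_cluster = []  # cluster index or -1 for background
    region_truth = []
    host_gene = []  # gene index or -1

    gene_cursor = 0
    for c in range(cfg.n_clusters):
        for i in range(per_cluster):
            g = gene_cursor
            gene_cursor += 1
            tss = int(gdf.at[g, "tss"])
            strand = gdf.at[g, "strand"]
            if i < n_dre_per_cluster:
                mid = tss + _DRE_CLUSTER_OFFSET
                region_truth.append("DRE")
            else:
                mid = _promoter_mid(tss, strand, slot=0)
                region_truth.append("promoter")
            chroms.append(cfg.chrom)
            starts.append(mid - _PEAK_HALFWIDTH)
            ends.append(mid + _PEAK_HALFWIDTH)
            peak_cluster.append(c)
            host_gene.append(g)

    n_bg = cfg.n_peaks - n_defining
    n_dre_target = round(cfg.frac_dre * cfg.n_peaks)
    n_dre_bg = int(np.clip(n_dre_target - cfg.n_clusters * n_dre_per_cluster, 0, n_bg))
    n_prom_bg = round(0.6 * (n_bg - n_dre_bg))
    n_other_bg = n_bg - n_dre_bg - n_prom_bg

    free_genes = np.arange(n_defining, cfg.n_genes)
    if len(free_genes) == 0:
        raise ValueError("no free genes left for background peaks")

    def _bg_positions(n, kind):
        # round-robin over free genes; slot index grows per gene
        count = 0
        slot_of_gene = dict.fromkeys(free_genes.tolist(), 0)
        gi = 0
        while count < n:
            g = int(free_genes[gi % len(free_genes)])
            slot = slot_of_gene[g]
            slot_of_gene[g] = slot + 1
            gi += 1
            tss = int(gdf.at[g, "tss"])
            strand = gdf.at[g, "strand"]
            if kind == "DRE":
                off = 10_000 + 4_000 * slot
                if off > 450_000:
                    continue
                mid = tss + off
            elif kind == "promoter":
                if slot > 6:
                    continue
                mid = _promoter_mid(tss, strand, slot)
            else:  # "other": the gap beyond 500 kb of both flanking genes
                off = 500_000 + 4_000 * (slot + 1)
                if off > 690_000:
                    continue
                mid = tss + off
            chroms.append(cfg.chrom)
            starts.append(mid - _PEAK_HALFWIDTH)
            ends.append(mid + _PEAK_HALFWIDTH)
            peak_cluster.append(-1)
            region_truth.append(kind)
            host_gene.append(g if kind == "DRE" else -1)
            count += 1

    _bg_positions(n_dre_bg, "DRE")
    _bg_positions(n_prom_bg, "promoter")
    _bg_positions(n_other_bg, "other")

    peak_ids = [f"peak{i:06d}" for i in range(cfg.n_peaks)]
    peaks = PeakSet(
        pd.DataFrame(
            {"chrom": chroms, "start": starts, "end": ends, "peak_id": peak_ids}
        )
    )
    peak_cluster = np.asarray(peak_cluster)
    host_gene = np.asarray(host_gene)

    # --- counts ----------------------------------------------------------
    lib = rng.integers(
        cfg.library_size_range[0], cfg.library_size_range[1] + 1, size=n_samples
    ).astype(float)
    scale = lib / lib.mean()

    base = np.empty((cfg.n_peaks, n_samples))
    bg_mask = peak_cluster == -1
    bg_mu = np.exp(
        rng.uniform(np.log(cfg.closed_mean), np.log(cfg.open_mean), size=bg_mask.sum())
    )
    # background peaks wobble log-normally per sample (biological
    # sample-to-sample variation unrelated to the planted clusters)
    jitter = np.exp(
        rng.normal(0.0, cfg.bg_sample_jitter_sd, size=(int(bg_mask.sum()), n_samples))
    )
    base[bg_mask] = bg_mu[:, None] * jitter
    for c in range(cfg.n_clusters):
        rows = peak_cluster == c
        open_cols = labels == c
        base[np.ix_(rows, open_cols)] = cfg.open_mean
        base[np.ix_(rows, ~open_cols)] = cfg.closed_mean
    mu = base * scale[None, :]

    if cfg.nb_dispersion > 0:
        lam = rng.gamma(
            shape=1.0 / cfg.nb_dispersion, scale=mu * cfg.nb_dispersion
        )
    else:
        lam = mu
    raw = rng.poisson(lam).astype(np.int64)
    # planted order matches peak_ids construction order; PeakSet sorts by
    # coordinate, so index the matrix by id explicitly
    raw_df = pd.DataFrame(raw, index=pd.Index(peak_ids, name="peak_id"), columns=sample_ids)
    counts = CountMatrix(raw=raw_df)
    presence = (raw_df >= cfg.presence_threshold).astype(np.int8)

    # --- expression and planted links -----------------------------------
    expr = rng.normal(5.0, 1.0, size=(cfg.n_genes, n_samples))
    logcpm = counts.logcpm

    def _plant_link(peak_idx: int, g: int) -> tuple:
        acc = logcpm.loc[peak_ids[peak_idx]].to_numpy()
        if cfg.link_target_r is not None:
            sd = acc.std(ddof=1)
            r = cfg.link_target_r
            noise_sd = 0.0 if r >= 1.0 else sd * np.sqrt(1.0 / r**2 - 1.0)
        else:
            noise_sd = cfg.link_noise_sd
        expr[g] = (
            acc + rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else acc
        )
        return peak_ids[peak_idx], gdf.at[int(g), "gene_id"]

    true_links = set()
    for i in np.flatnonzero((peak_cluster >= 0) & (host_gene >= 0)):
        if region_truth[i] != "DRE":
            continue  # links pair DRE peaks with genes
        true_links.add(_plant_link(i, host_gene[i]))

    # background links: cluster-uninformative distal peaks whose host
    # gene's expression tracks them, one per selected free gene
    background_links = set()
    bg_dre_by_gene: dict = {}
    for i in np.flatnonzero((np.asarray(peak_cluster) == -1) & (host_gene >= 0)):
        bg_dre_by_gene.setdefault(int(host_gene[i]), []).append(int(i))
    linkable = sorted(bg_dre_by_gene)
    n_bg_links = round(cfg.frac_background_linked * len(linkable))
    chosen_genes = rng.choice(len(linkable), size=n_bg_links, replace=False)
    for gi in sorted(chosen_genes):
        g = linkable[gi]
        peak_idx = bg_dre_by_gene[g][0]
        background_links.add(_plant_link(peak_idx, g))
    expression = pd.DataFrame(
        expr, index=pd.Index(gdf["gene_id"], name="gene_id"), columns=sample_ids
    )

    # --- motif programs --------------------------------------------------
    motif_ids = [f"motif{m:03d}" for m in range(cfg.n_motifs)]
    membership = (
        rng.random((cfg.n_peaks, cfg.n_motifs)) < cfg.motif_background_rate
    ).astype(np.int8)
    programs = {}
    for c in range(cfg.n_clusters):
        prog = list(
            range(c * cfg.motif_program_size, (c + 1) * cfg.motif_program_size)
        )
        programs[c] = {motif_ids[m] for m in prog}
        rows = np.flatnonzero(peak_cluster == c)
        membership[np.ix_(rows, prog)] = 1
    for m in np.flatnonzero(membership.sum(axis=0) == 0):
        membership[rng.integers(cfg.n_peaks), m] = 1
    membership_df = pd.DataFrame(
        membership, index=pd.Index(peak_ids, name="peak_id"), columns=motif_ids
    )

    cluster_peaks = {
        c: [peak_ids[i] for i in np.flatnonzero(peak_cluster == c)]
        for c in range(cfg.n_clusters)
    }
    return SyntheticCohort(
        config=cfg,
        peaks=peaks,
        counts=counts,
        presence=presence,
        genes=genes,
        expression=expression,
        true_labels=pd.Series(labels, index=sample_ids, name="cluster"),
        true_links=true_links,
        background_links=background_links,
        true_motif_programs=programs,
        motif_membership=membership_df,
        cluster_specific_peaks=cluster_peaks,
        peak_region_truth=pd.Series(
            region_truth, index=pd.Index(peak_ids, name="peak_id"), name="region"
        ),
    )


def generate_paired_species(
    config_mouse: CohortConfig,
    config_human: CohortConfig,
    shared_program_frac: float,
    seed: int = 0,
):
    """Paired mouse/human cohorts sharing part of their cluster programs.

    The homolog map is one-to-one.  For ``shared_program_frac`` of each
    mouse cluster's defining genes the homolog is a defining gene of the
    *corresponding* human cluster (so its linked human peaks are open in
    that cluster); the rest map to non-defining human genes.  Motif
    cluster programs use a shared namespace and are identical across
    species when the program sizes agree.
    """
    if not (0.0 <= shared_program_frac <= 1.0):
        raise ValueError("shared_program_frac outside [0, 1]")
    if config_mouse.n_clusters != config_human.n_clusters:
        raise ValueError("species must use consistent cluster counts")
    if config_mouse.gene_prefix == config_human.gene_prefix:
        config_mouse = dataclasses.replace(config_mouse, gene_prefix="mgene")
        config_human = dataclasses.replace(config_human, gene_prefix="hgene")
    if config_mouse.sample_prefix == config_human.sample_prefix:
        config_mouse = dataclasses.replace(config_mouse, sample_prefix="m")
        config_human = dataclasses.replace(config_human, sample_prefix="h")

    mouse = generate_cohort(config_mouse)
    human = generate_cohort(config_human)
    rng = np.random.default_rng(seed)

    def _defining_genes(cohort):
        by_cluster = {}
        link_gene = {p: g for p, g in cohort.true_links}
        for c, peaks in cohort.cluster_specific_peaks.items():
            by_cluster[c] = [link_gene[p] for p in peaks if p in link_gene]
        return by_cluster

    m_def = _defining_genes(mouse)
    h_def = _defining_genes(human)
    all_h = list(human.genes.df["gene_id"])

    # first settle the shared part of each cluster's program, then map
    # every remaining mouse gene onto a uniformly random unused human
    # gene (defining or not): non-shared homology carries no cluster
    # information by construction
    pairs = []
    used_h: set = set()
    unshared_m = []
    for c in range(config_mouse.n_clusters):
        avail = list(h_def[c])
        for mg in m_def[c]:
            if avail and rng.random() < shared_program_frac:
                hg = avail.pop(0)
                pairs.append((mg, hg))
                used_h.add(hg)
            else:
                unshared_m.append(mg)
    m_def_all = {g for gs in m_def.values() for g in gs}
    m_rest = unshared_m + [
        g for g in mouse.genes.df["gene_id"] if g not in m_def_all
    ]
    h_rest = [g for g in all_h if g not in used_h]
    rng.shuffle(h_rest)
    for mg, hg in zip(m_rest, h_rest):
        pairs.append((mg, hg))

    homologs = HomologMap(pd.DataFrame(pairs, columns=["gene_a", "gene_b"]))
    return mouse, human, homologs


def generate_saturation_presence(
    n_samples: int, n_total_peaks: int, sharing_exponent: float, seed=None
) -> np.ndarray:
    """Binary presence matrix with power-law peak sharing.

    Each peak is present in m samples with P(m) proportional to
    m^(-sharing_exponent); the m samples are placed uniformly.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if sharing_exponent <= 0:
        raise ValueError("sharing_exponent must be > 0")
    rng = np.random.default_rng(seed)
    m_vals = np.arange(1, n_samples + 1, dtype=float)
    probs = m_vals**-sharing_exponent
    probs /= probs.sum()
    m = rng.choice(np.arange(1, n_samples + 1), size=n_total_peaks, p=probs)
    rand = rng.random((n_total_peaks, n_samples))
    rank = rand.argsort(axis=1).argsort(axis=1)
    return (rank < m[:, None]).astype(np.int8)


def simulate_technical_replicates(
    logcpm: pd.DataFrame, samples, noise_sd: float, seed=None
) -> pd.DataFrame:
    """Replicate columns = original log2(CPM+1) plus Gaussian noise."""
    rng = np.random.default_rng(seed)
    reps = {}
    for s in samples:
        reps[f"{s}_rep"] = logcpm[s].to_numpy() + rng.normal(
            0.0, noise_sd, size=len(logcpm)
        )
    return pd.DataFrame(reps, index=logcpm.index)


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write a cohort as plain-text BED/TSV/YAML files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_bed(cohort.peaks, out / "peaks.bed")
    write_matrix_tsv(cohort.counts.raw, out / "counts.tsv")
    write_matrix_tsv(cohort.expression, out / "expression.tsv")
    write_matrix_tsv(cohort.presence, out / "presence.tsv")
    write_matrix_tsv(cohort.motif_membership, out / "motif_membership.tsv")
    write_genes_tsv(cohort.genes, out / "genes.tsv")
    cohort.true_labels.rename("cluster").to_csv(out / "true_labels.tsv", sep="\t")
    pd.DataFrame(sorted(cohort.true_links), columns=["peak_id", "gene_id"]).to_csv(
        out / "true_links.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        sorted(cohort.background_links), columns=["peak_id", "gene_id"]
    ).to_csv(out / "background_links.tsv", sep="\t", index=False)
    cfg = dataclasses.asdict(cohort.config)
    for key, val in cfg.items():
        if isinstance(val, tuple):
            cfg[key] = list(val)
    (out / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
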