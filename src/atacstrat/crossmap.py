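"""Cross-species (mouse -> human) peak conversion and its null controls.

Mouse group-unique peaks are converted to human peaks through the chain

    mouse peaks -> nearest mouse genes -> human homologs
                -> significant peak-to-gene links -> union of human peaks,

recording the retention count at every step.  The mapped human peaks are
then used to re-cluster the human samples (guided clustering), and the
agreement with a reference clustering is compared against a null of
size-matched random peak draws; conservation of regulatory programs is
quantified by the overlap of the top-k enrichment-ranked motifs in the
mouse input set versus its mapped human set, again against a random-set
null.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .motifdev import top_k_overlap
from .nmf import cluster_agreement, consensus_cophenetic

__all__ = [
    "HomologMap",
    "CrossMapResult",
    "map_unique_peaks_cross_species",
    "guided_clustering_agreement",
    "random_peak_control",
    "NullDistribution",
    "rank_motifs_by_enrichment",
    "motif_overlap_control",
]


@dataclass
class HomologMap:
    """Gene correspondences between species A (mouse) and B (human)."""

    pairs: pd.DataFrame  # columns: gene_a, gene_b

    def __post_init__(self) -> None:
        df = self.pairs.reset_index(drop=True)
        if (df["gene_a"] == df["gene_b"]).any():
            raise ValueError("homolog map must not contain self-pairs")
        self.pairs = df

    def a_to_b(self) -> dict:
        return dict(zip(self.pairs["gene_a"], self.pairs["gene_b"]))

    def b_to_a(self) -> dict:
        return dict(zip(self.pairs["gene_b"], self.pairs["gene_a"]))

    def multiplicity_flags(self) -> pd.DataFrame:
        out = self.pairs.copy()
        out["a_multi"] = out["gene_a"].duplicated(keep=False)
        out["b_multi"] = out["gene_b"].duplicated(keep=False)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class CrossMapResult:
    n_input_peaks: int
    step_counts: dict  # ordered retention counts through the chain
    human_peaks: list
    guided_labels: object = None
    agreement: dict = field(default_factory=dict)
    null_summary: dict = field(default_factory=dict)


def map_unique_peaks_cross_species(
    mouse_unique_peaks,
    mouse_annotation: pd.DataFrame,
    homologs: HomologMap,
    human_links: pd.DataFrame,
    significant_only: bool = True,
) -> CrossMapResult:
    """Chain mouse peaks to human peaks; every step's count is recorded.

    ``mouse_annotation`` is a nearest-gene table (peak-indexed, column
    ``nearest_gene_id``) from :func:`atacstrat.matrixio.annotate_peaks`;
    ``human_links`` a table from
    :func:`atacstrat.linkage.link_peaks_to_genes`.  An empty set at any
    step yields an empty result with diagnostics, not an exception.
    """
    peak_ids = list(mouse_unique_peaks)
    known = [p for p in peak_ids if p in mouse_annotation.index]
    genes = (
        mouse_annotation.loc[known, "nearest_gene_id"].dropna().unique().tolist()
        if known
        else []
    )
    fwd = homologs.a_to_b()
    homolog_genes = sorted({fwd[g] for g in genes if g in fwd})
    links = human_links[human_links["significant"]] if significant_only else human_links
    linked = links[links["gene_id"].isin(homolog_genes)]
    linked_genes = linked["gene_id"].unique().tolist()
    human_peaks = sorted(linked["peak_id"].unique().tolist())
    return CrossMapResult(
        n_input_peaks=len(peak_ids),
        step_counts={
            "input_peaks": len(peak_ids),
            "mouse_genes": len(genes),
            "homolog_genes": len(homolog_genes),
            "linked_genes": len(linked_genes),
            "human_peaks": len(human_peaks),
        },
        human_peaks=human_peaks,
    )


def guided_clustering_agreement(
    human_logcpm: pd.DataFrame,
    mapped_peaks,
    reference_labels,
    k: int,
    n_runs: int = 10,
    seed=None,
    theta: float = 0.5,
    max_iter: int = 500,
    tol: float = 1e-7,
) -> dict:
    """Re-cluster human samples on the mapped peaks and score agreement.

    Consensus nsNMF at fixed k restricted to ``mapped_peaks``; returns
    matched agreement and ARI versus the reference labelling.
    """
    mapped = [p for p in mapped_peaks if p in human_logcpm.index]
    if len(mapped) < k:
        raise ValueError(f"need at least k={k} mapped peaks, got {len(mapped)}")
    V = human_logcpm.loc[mapped]
    est = consensus_cophenetic(
        V.to_numpy(),
        k_range=(k, k),
        n_runs=n_runs,
        theta=theta,
        seed=seed,
        max_iter=max_iter,
        tol=tol,
    )
    ref = (
        reference_labels.reindex(human_logcpm.columns)
        if isinstance(reference_labels, pd.Series)
        else pd.Series(reference_labels, index=human_logcpm.columns)
    )
    agg = cluster_agreement(pd.Series(est.labels_, index=human_logcpm.columns), ref)
    return {
        "labels": pd.Series(est.labels_, index=human_logcpm.columns),
        "matched_agreement": agg["matched_agreement"],
        "ari": agg["ari"],
        "n_peaks_used": len(mapped),
    }


@dataclass
class NullDistribution:
    values: np.ndarray
    mean: float
    sd: float
    se: float
    observed: float | None = None
    percentile: float | None = None  # empirical percentile of the observed value


def random_peak_control(
    human_logcpm: pd.DataFrame,
    candidate_peak_universe,
    set_size: int,
    reference_labels,
    k: int,
    n_iter: int = 1000,
    seed=None,
    observed: float | None = None,
    n_runs: int = 4,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> NullDistribution:
    """Agreement null from random peak sets of the mapped size.

    Each iteration draws ``set_size`` peaks without replacement from the
    candidate universe (the peaks-to-genes universe) and repeats the
    guided clustering; reduced ``n_iter`` is permitted for desk-scale
    runs, with the standard error of the null mean reported.
    """
    universe = list(candidate_peak_universe)
    if set_size > len(universe):
        raise ValueError("set_size exceeds universe size")
    rng = np.random.default_rng(seed)
    vals = np.empty(n_iter)
    for i in range(n_iter):
        draw = rng.choice(len(universe), size=set_size, replace=False)
        peaks = [universe[j] for j in draw]
        res = guided_clustering_agreement(
            human_logcpm,
            peaks,
            reference_labels,
            k=k,
            n_runs=n_runs,
            seed=int(rng.integers(0, 2**31 - 1)),
            max_iter=max_iter,
            tol=tol,
        )
        vals[i] = res["matched_agreement"]
    mean = float(vals.mean()) if n_iter else float("nan")
    sd = float(vals.std(ddof=1)) if n_iter > 1 else float("nan")
    pct = None
    if observed is not None and n_iter:
        pct = float(100.0 * np.mean(vals <= observed))
    return NullDistribution(
        values=vals,
        mean=mean,
        sd=sd,
        se=sd / np.sqrt(n_iter) if n_iter > 1 else float("nan"),
        observed=observed,
        percentile=pct,
    )


def rank_motifs_by_enrichment(
    peak_ids, membership: pd.DataFrame, universe=None
) -> pd.DataFrame:
    """Hypergeometric enrichment ranking of motifs within a peak set.

    For each motif: universe of N peaks with K members, a set of n peaks
    containing x members; p = P(X >= x).  Ranking is by p ascending with
    motif-id tie-break.  A surrogate for sequence-based motif enrichment:
    it preserves the rank structure of the comparison without PWM
    scanning.
    """
    if universe is not None:
        membership = membership.loc[list(universe)]
    peak_set = [p for p in peak_ids if p in membership.index]
    N = len(membership)
    n = len(peak_set)
    K = membership.sum(axis=0).to_numpy(dtype=int)
    x = membership.loc[peak_set].sum(axis=0).to_numpy(dtype=int)
    p = stats.hypergeom.sf(x - 1, N, K, n)
    out = pd.DataFrame(
        {"members_in_set": x, "members_in_universe": K, "p": p},
        index=membership.columns,
    )
    order = np.lexsort((out.index.to_numpy(), out["p"].to_numpy()))
    return out.iloc[order]


def motif_overlap_control(
    mouse_unique_peaks,
    mouse_membership: pd.DataFrame,
    human_membership: pd.DataFrame,
    mouse_annotation: pd.DataFrame,
    homologs: HomologMap,
    human_links: pd.DataFrame,
    mouse_universe=None,
    k: int = 10,
    n_iter: int = 1000,
    seed=None,
) -> dict:
    """Top-k motif-rank overlap between a mouse peak set and its mapped
    human set, against a random-mouse-set null.

    Motifs are enrichment-ranked (hypergeometric) within each species'
    peak set on the shared motif namespace; the observed statistic is the
    top-k overlap of the two rankings.  The null repeats the full chain
    with size-matched random mouse peak sets; ``n_iter=0`` reports the
    observed value only.
    """
    shared = [m for m in mouse_membership.columns if m in set(human_membership.columns)]
    if not shared:
        raise ValueError("shared motif namespace is empty")
    m_mem = mouse_membership[shared]
    h_mem = human_membership[shared]

    def _observed(peaks):
        res = map_unique_peaks_cross_species(
            peaks, mouse_annotation, homologs, human_links
        )
        if len(res.human_peaks) == 0:
            return None, res
        rank_m = rank_motifs_by_enrichment(peaks, m_mem).index.tolist()
        rank_h = rank_motifs_by_enrichment(res.human_peaks, h_mem).index.tolist()
        count, frac = top_k_overlap(rank_m, rank_h, k=k)
        return (count, frac), res

    mouse_unique_peaks = list(mouse_unique_peaks)
    obs, chain = _observed(mouse_unique_peaks)
    out = {
        "observed_overlap": obs[0] if obs else 0,
        "observed_fraction": obs[1] if obs else 0.0,
        "chain": chain,
        "null_mean": None,
        "null_sd": None,
        "null_values": None,
    }
    if n_iter:
        if mouse_universe is None:
            mouse_universe = list(mouse_annotation.index)
        rng = np.random.default_rng(seed)
        vals = []
        for _ in range(n_iter):
            draw = rng.choice(
                len(mouse_universe), size=len(mouse_unique_peaks), replace=False
            )
            peaks = [mouse_universe[j] for j in draw]
            o, _res = _observed(peaks)
            vals.append(o[0] if o else 0)
        vals = np.asarray(vals, dtype=float)
        out["null_mean"] = float(vals.mean())
        out["null_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
        out["null_values"] = vals
    return out
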