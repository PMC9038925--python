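"""TF-motif accessibility deviations with background correction.

For each motif m and sample j the raw deviation compares the observed
counts in motif-bearing peaks to the expectation under a constant
accessibility profile:

    Y[m, j] = (observed - expected) / expected,
    expected E[m, j] = (sum_i M[i, m] * f_i) * T_j,

where T_j is the sample's total count and f_i is the peak's expected
fraction of a library, taken as the mean over samples of the per-sample
count fraction so that deviations are exactly invariant to sequencing
depth (a motif covering every peak scores exactly zero).  Each deviation
is z-scored against ``n_background`` motif-matched background peak sets
sampled within mean-accessibility bins; a motif's variability is the SD
of its z-scores across samples and flags motifs that distinguish
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MotifDeviationResult",
    "compute_deviations",
    "cluster_enriched_motifs",
    "motif_expression_correlation",
    "top_k_overlap",
]


@dataclass
class MotifDeviationResult:
    deviations: pd.DataFrame  # motifs x samples, raw Y
    z: pd.DataFrame  # motifs x samples, background-corrected
    variability: pd.Series  # per motif, SD of z across samples
    n_background: int
    dropped_motifs: list
    seed: object = None


def _expected_fractions(X: np.ndarray) -> np.ndarray:
    """Per-peak expected library fraction: mean of per-sample compositions."""
    totals = X.sum(axis=0)
    comp = X / np.where(totals == 0, 1.0, totals)
    return comp.mean(axis=1)


def compute_deviations(
    raw_counts: pd.DataFrame,
    motif_membership: pd.DataFrame,
    n_background: int = 50,
    n_bins: int = 10,
    seed=None,
) -> MotifDeviationResult:
    """Bias-corrected motif deviation z-scores (peaks x samples counts,
    peaks x motifs binary membership).

    Background sets resample each member peak from its mean-accessibility
    bin (``n_bins`` quantile bins), preserving set size; z-scores are the
    raw deviation standardised by the background mean and SD.
    """
    if not raw_counts.index.equals(motif_membership.index):
        motif_membership = motif_membership.reindex(raw_counts.index)
        if motif_membership.isna().any().any():
            raise ValueError("membership rows do not align to the count matrix peaks")
    X = raw_counts.to_numpy(dtype=float)
    M = motif_membership.to_numpy(dtype=float)
    if not np.isin(M, (0.0, 1.0)).all():
        raise ValueError("motif membership must be binary")

    member_counts = M.sum(axis=0)
    empty = member_counts == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} motif(s) with no member peaks dropped", stacklevel=2
        )
    dropped = list(motif_membership.columns[empty])
    M = M[:, ~empty]
    motif_ids = motif_membership.columns[~empty]

    T = X.sum(axis=0)
    f = _expected_fractions(X)

    def _raw_dev(Mm: np.ndarray, fvec: np.ndarray, Xrows: np.ndarray) -> np.ndarray:
        obs = Mm.T @ Xrows
        exp = np.outer(Mm.T @ fvec, T)
        exp = np.where(exp == 0, np.inf, exp)
        return (obs - exp) / exp

    Y = _raw_dev(M, f, X)

    # accessibility-matched backgrounds: quantile bins on f
    rng = np.random.default_rng(seed)
    order = np.argsort(f, kind="stable")
    n_peaks = X.shape[0]
    bins = np.empty(n_peaks, dtype=int)
    bins[order] = np.arange(n_peaks) * n_bins // n_peaks
    bin_members = [np.flatnonzero(bins == b) for b in range(n_bins)]

    bg = np.empty((n_background, Y.shape[0], Y.shape[1]))
    for b in range(n_background):
        idx_map = np.empty(n_peaks, dtype=int)
        for members in bin_members:
            idx_map[members] = rng.choice(members, size=len(members), replace=True)
        bg[b] = _raw_dev(M, f[idx_map], X[idx_map])
    mean_bg = bg.mean(axis=0)
    sd_bg = bg.std(axis=0, ddof=1)
    sd_bg = np.where(sd_bg == 0, np.inf, sd_bg)
    Z = (Y - mean_bg) / sd_bg

    samples = raw_counts.columns
    z_df = pd.DataFrame(Z, index=motif_ids, columns=samples)
    return MotifDeviationResult(
        deviations=pd.DataFrame(Y, index=motif_ids, columns=samples),
        z=z_df,
        variability=z_df.std(axis=1, ddof=1).rename("variability"),
        n_background=n_background,
        dropped_motifs=dropped,
        seed=seed,
    )


def _row_indicator_correlation(Z: np.ndarray, ind: np.ndarray):
    """Vectorised Pearson r of each Z row with a binary indicator, plus
    two-sided p from the t distribution."""
    n = Z.shape[1]
    zc = Z - Z.mean(axis=1, keepdims=True)
    ic = ind - ind.mean()
    denom = np.sqrt((zc**2).sum(axis=1) * (ic**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (zc @ ic) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / np.clip(1.0 - r**2, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, p)
    return r, p


def cluster_enriched_motifs(
    z: pd.DataFrame,
    variability: pd.Series,
    labels,
    cluster,
    v_threshold: float = 1.5,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Motifs positively correlated with a cluster, variable and significant.

    Per motif: Pearson r of the deviation z-score row with the
    one-vs-rest cluster indicator; BH q over motifs; keep r > 0, q <
    ``q_threshold`` and variability > ``v_threshold``.
    """
    labels = pd.Series(labels, index=z.columns) if not isinstance(
        labels, pd.Series
    ) else labels.reindex(z.columns)
    if labels.nunique() < 2:
        raise ValueError("need at least two clusters in the labelling")
    ind = (labels == cluster).to_numpy(dtype=float)
    r, p = _row_indicator_correlation(z.to_numpy(dtype=float), ind)
    valid = ~np.isnan(p)
    q = np.full_like(p, np.nan)
    q[valid] = multipletests(p[valid], method="fdr_bh")[1]
    v = variability.reindex(z.index).to_numpy(dtype=float)
    out = pd.DataFrame(
        {"r": r, "p": p, "q": q, "variability": v},
        index=z.index,
    )
    out["selected"] = (
        (out["r"] > 0) & (out["q"] < q_threshold) & (out["variability"] > v_threshold)
    )
    return out


def motif_expression_correlation(
    z: pd.DataFrame,
    tf_expression: pd.DataFrame,
    motif_to_gene: dict,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pearson correlation between each motif's deviations and its TF's
    expression; retain positive-r, p < 0.05 motifs.

    Unmapped motifs and constant expression vectors are skipped and
    reported in the ``status`` column.
    """
    shared = [s for s in z.columns if s in set(tf_expression.columns)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared samples")
    recs = []
    for motif in z.index:
        gene = motif_to_gene.get(motif)
        if gene is None or gene not in tf_expression.index:
            recs.append((motif, gene, np.nan, np.nan, False, "unmapped"))
            continue
        x = z.loc[motif, shared].to_numpy(dtype=float)
        y = tf_expression.loc[gene, shared].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            recs.append((motif, gene, np.nan, np.nan, False, "constant"))
            continue
        r, p = stats.pearsonr(x, y)
        keep = (r > 0) and (p < p_threshold)
        recs.append((motif, gene, float(r), float(p), keep, "ok"))
    return pd.DataFrame(
        recs, columns=["motif_id", "gene_id", "r", "p", "keep", "status"]
    ).set_index("motif_id")


def top_k_overlap(ranking_a, ranking_b, k: int = 10):
    """Overlap of the top-k entries of two motif rankings.

    Returns (count, fraction).  Duplicate motifs within a ranking are an
    error.
    """
    a = list(ranking_a)
    b = list(ranking_b)
    if len(set(a)) != len(a) or len(set(b)) != len(b):
        raise ValueError("rankings must not contain duplicate motifs")
    if k > len(a) or k > len(b):
        raise ValueError("k exceeds ranking length")
    count = len(set(a[:k]) & set(b[:k]))
    return count, count / k
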