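"""Correlation-based peak-to-gene linkage with an empirical global null.

Candidate pairs are distal peak/gene combinations whose midpoint-to-TSS
distance lies in (3 kb, 500 kb].  For each pair the Pearson correlation r
between log2(CPM+1) accessibility and gene expression across samples is
computed; the mean and SD of r over *all* candidate pairs define the
nonspecific-correlation null, giving z = (r - mu)/sigma, a two-sided
normal p, and Benjamini-Hochberg FDR.  Links at FDR < 0.05 are
significant.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .matrixio import DRE_WINDOW, GeneAnnotation, PeakSet

__all__ = [
    "candidate_peak_gene_pairs",
    "link_peaks_to_genes",
    "genes_to_peaks",
]


def candidate_peak_gene_pairs(
    peaks: PeakSet, genes: GeneAnnotation, window=DRE_WINDOW
) -> pd.DataFrame:
    """All (peak, gene) pairs with 3 kb < |midpoint - TSS| <= 500 kb.

    A peak may pair with several genes and vice versa.  Distance is
    signed in the gene's transcriptional orientation.
    """
    lo, hi = window
    by_chrom = {}
    for chrom, sub in genes.df.groupby("chrom"):
        sub = sub.sort_values("tss", kind="mergesort")
        by_chrom[chrom] = (
            sub["tss"].to_numpy(dtype=np.int64),
            sub["gene_id"].to_numpy(),
            sub["strand"].to_numpy(),
        )
    mids = peaks.midpoints()
    recs = []
    for pid, chrom, mid in zip(
        peaks.df["peak_id"].to_numpy(), peaks.df["chrom"].to_numpy(), mids
    ):
        if chrom not in by_chrom:
            continue
        tss_arr, gid_arr, strand_arr = by_chrom[chrom]
        left = np.searchsorted(tss_arr, mid - hi)
        right = np.searchsorted(tss_arr, mid + hi, side="right")
        for i in range(left, right):
            d_abs = abs(int(mid) - int(tss_arr[i]))
            if lo < d_abs <= hi:
                d = int(mid) - int(tss_arr[i])
                if strand_arr[i] == "-":
                    d = -d
                recs.append((pid, gid_arr[i], d))
    return pd.DataFrame(recs, columns=["peak_id", "gene_id", "tss_distance"])


def link_peaks_to_genes(
    logcpm_acc: pd.DataFrame,
    expression: pd.DataFrame,
    pairs: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Score candidate pairs against the empirical all-pairs null.

    Sample ordering is matched by id between the accessibility and
    expression matrices (>= 4 shared samples required).  Pairs with a
    constant peak or gene vector are dropped with a warning.
    """
    shared = [s for s in logcpm_acc.columns if s in set(expression.columns)]
    if len(shared) < 4:
        raise ValueError("need >= 4 shared samples between accessibility and expression")
    acc = logcpm_acc[shared].to_numpy(dtype=float)
    expr = expression[shared].to_numpy(dtype=float)
    peak_pos = {p: i for i, p in enumerate(logcpm_acc.index)}
    gene_pos = {g: i for i, g in enumerate(expression.index)}

    pi = pairs["peak_id"].map(peak_pos)
    gi = pairs["gene_id"].map(gene_pos)
    known = pi.notna() & gi.notna()
    if not known.all():
        warnings.warn(
            f"{int((~known).sum())} pair(s) reference unknown peaks/genes; dropped",
            stacklevel=2,
        )
    pairs = pairs.loc[known].reset_index(drop=True)
    pi = pi[known].to_numpy(dtype=int)
    gi = gi[known].to_numpy(dtype=int)

    x = acc[pi]
    y = expr[gi]
    sx = x.std(axis=1)
    sy = y.std(axis=1)
    ok = (sx > 0) & (sy > 0)
    if not ok.all():
        warnings.warn(
            f"{int((~ok).sum())} pair(s) with constant vectors dropped", stacklevel=2
        )
    x, y = x[ok], y[ok]
    pairs = pairs.loc[ok].reset_index(drop=True)
    xz = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
    yz = (y - y.mean(axis=1, keepdims=True)) / y.std(axis=1, keepdims=True)
    r = np.clip((xz * yz).mean(axis=1), -1.0, 1.0)

    mu = float(r.mean())
    sigma = float(r.std(ddof=0))
    if sigma == 0:
        raise ValueError("degenerate null: all candidate correlations identical")
    z = (r - mu) / sigma
    p = 2.0 * stats.norm.sf(np.abs(z))
    fdr = multipletests(p, method="fdr_bh")[1]

    out = pairs.copy()
    out["r"] = r
    out["z"] = z
    out["p"] = p
    out["fdr"] = fdr
    out["significant"] = out["fdr"] < fdr_threshold
    return out


def genes_to_peaks(gene_ids, links: pd.DataFrame, significant_only: bool = True):
    """Union of peaks linked to any query gene (deduplicated).

    Returns (peak_id set, genes with no links).  With
    ``significant_only`` (default) only FDR-significant links count.
    """
    sub = links[links["significant"]] if significant_only else links
    by_gene = sub.groupby("gene_id")["peak_id"]
    gene_ids = list(gene_ids)
    peaks: set = set()
    missing = []
    groups = {g: set(v) for g, v in by_gene}
    for g in gene_ids:
        if g in groups:
            peaks |= groups[g]
        else:
            missing.append(g)
    return peaks, missing
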