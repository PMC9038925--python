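"""Differential accessibility testing and cluster-unique peak selection.

Accessibility counts are modelled as negative binomial.  The test is a
Wald test on the log2 fold change of size-factor-normalised group means
(pseudocount 1), with median-of-ratios size factors and per-peak
method-of-moments dispersion (floored at 1e-8) — a documented
approximation of the DESeq2 machinery; the cluster-unique selection
rules carry the published thresholds verbatim:

* human clusters: p < 0.01 and FDR < 0.01 and log2FC > 1 and
  mean CPM intensity > 30 and CV < 0.2 (strict inequalities);
* mouse groups:   log2FC > 1 and FDR < 0.05, required in every pairwise
  comparison of the group against each other group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "UniquePeakSet",
    "size_factors",
    "nb_differential",
    "cluster_unique_peaks",
    "mouse_group_unique_peaks",
    "HUMAN_FILTERS",
    "MOUSE_FILTERS",
]

_LN2 = np.log(2.0)

HUMAN_FILTERS = {
    "p": 0.01,
    "fdr": 0.01,
    "log2fc": 1.0,
    "mean_intensity": 30.0,
    "cv": 0.2,
}
MOUSE_FILTERS = {"log2fc": 1.0, "fdr": 0.05}


@dataclass
class UniquePeakSet:
    cluster: object
    peak_ids: list
    thresholds: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peak_ids)


def size_factors(raw: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (computed on all-positive peaks)."""
    mat = raw.to_numpy(dtype=float)
    pos = (mat > 0).all(axis=1)
    if pos.sum() == 0:
        # no peak observed in every sample: fall back to library-size ratios
        totals = mat.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(np.clip(totals, 1e-12, None))))
        return pd.Series(sf, index=raw.columns)
    logmat = np.log(mat[pos])
    loggeo = logmat.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logmat - loggeo, axis=0))
    return pd.Series(sf, index=raw.columns)


def nb_differential(raw: pd.DataFrame, group_labels, target_group) -> pd.DataFrame:
    """Negative-binomial Wald test of one group versus the rest.

    Returns a peak-indexed frame with ``log2fc`` (normalised group means,
    pseudocount 1), ``p`` (two-sided), ``fdr`` (Benjamini-Hochberg),
    ``mean_intensity`` (mean CPM over all samples) and ``cv`` (SD/mean of
    CPM over all samples).
    """
    labels = pd.Series(group_labels, index=raw.columns) if not isinstance(
        group_labels, pd.Series
    ) else group_labels.reindex(raw.columns)
    in_target = (labels == target_group).to_numpy()
    if in_target.sum() < 2 or (~in_target).sum() < 2:
        raise ValueError("each side of the contrast needs >= 2 samples")

    mat = raw.to_numpy(dtype=float)
    sf = size_factors(raw).to_numpy()
    norm = mat / sf

    def _group_moments(cols):
        sub = norm[:, cols]
        q = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        w = float(np.mean(1.0 / sf[cols]))  # E[1/sf] within the group
        return q, s2, w, cols.sum()

    qa, s2a, wa, na = _group_moments(in_target)
    qb, s2b, wb, nb = _group_moments(~in_target)

    # method-of-moments dispersion pooled over the two groups:
    # within-group variance of normalised counts ~ q*w + alpha*q^2
    dfa, dfb = na - 1, nb - 1
    pooled_s2 = (s2a * dfa + s2b * dfb) / (dfa + dfb)
    pooled_q = (qa * na + qb * nb) / (na + nb)
    pooled_w = (wa * na + wb * nb) / (na + nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha = (pooled_s2 - pooled_q * pooled_w) / pooled_q**2
    alpha = np.where(np.isfinite(alpha), alpha, 0.0)
    alpha = np.clip(alpha, 1e-8, None)
    # moderate the noisy per-peak moment estimate towards the matrix-wide
    # median (prior weight ~8 residual df); without this the Wald test is
    # anti-conservative at typical group sizes
    d0 = 8.0
    df_res = dfa + dfb
    alpha = (df_res * alpha + d0 * np.median(alpha)) / (df_res + d0)
    alpha = np.clip(alpha, 1e-8, None)

    # Wald z on log2((qa+1)/(qb+1)); delta method through the NB variance
    # of each group mean: Var(q_g) = (q_g * w_g + alpha q_g^2) / n_g
    var_qa = (qa * wa + alpha * qa**2) / na
    var_qb = (qb * wb + alpha * qb**2) / nb
    log2fc = np.log2(qa + 1.0) - np.log2(qb + 1.0)
    se2 = var_qa / ((qa + 1.0) ** 2 * _LN2**2) + var_qb / ((qb + 1.0) ** 2 * _LN2**2)
    se = np.sqrt(np.clip(se2, 1e-300, None))
    z = log2fc / se
    # t reference with the moderated (posterior) df: residual df plus the
    # dispersion prior weight.  A plain normal reference is visibly
    # anti-conservative at n ~ 10 per group, and the residual df alone
    # wastes the information pooled into the moderated dispersion
    p = 2.0 * stats.t.sf(np.abs(z), df=df_res + d0)

    allzero = mat.sum(axis=1) == 0
    if allzero.any():
        warnings.warn(f"{int(allzero.sum())} all-zero peak(s): p set to 1", stacklevel=2)
        p[allzero] = 1.0
        z[allzero] = 0.0
        log2fc[allzero] = 0.0

    fdr = multipletests(p, method="fdr_bh")[1]

    totals = mat.sum(axis=0)
    cpm = mat / np.where(totals == 0, 1.0, totals) * 1e6
    mean_int = cpm.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = cpm.std(axis=1, ddof=1) / mean_int
    cv = np.where(np.isfinite(cv), cv, np.inf)

    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "z": z,
            "p": p,
            "fdr": fdr,
            "mean_intensity": mean_int,
            "cv": cv,
        },
        index=raw.index,
    )


def cluster_unique_peaks(stats_df: pd.DataFrame, mode: str, cluster=None) -> UniquePeakSet:
    """Apply the published cluster-unique filter set to a stats table.

    ``mode='human'``: p<0.01 & FDR<0.01 & log2FC>1 & mean CPM>30 & CV<0.2.
    ``mode='mouse'``: log2FC>1 & FDR<0.05.
    All inequalities strict, as printed.
    """
    if mode == "human":
        t = HUMAN_FILTERS
        keep = (
            (stats_df["p"] < t["p"])
            & (stats_df["fdr"] < t["fdr"])
            & (stats_df["log2fc"] > t["log2fc"])
            & (stats_df["mean_intensity"] > t["mean_intensity"])
            & (stats_df["cv"] < t["cv"])
        )
    elif mode == "mouse":
        t = MOUSE_FILTERS
        keep = (stats_df["log2fc"] > t["log2fc"]) & (stats_df["fdr"] < t["fdr"])
    else:
        raise ValueError(f"unknown mode {mode!r}; expected 'human' or 'mouse'")
    return UniquePeakSet(
        cluster=cluster, peak_ids=list(stats_df.index[keep]), thresholds=dict(t)
    )


def mouse_group_unique_peaks(
    raw: pd.DataFrame, group_labels, target_group, rule: str = "intersection"
) -> UniquePeakSet:
    """Group-unique peaks from all pairwise mouse contrasts.

    A peak is group-unique when it passes the mouse filter (log2FC>1,
    FDR<0.05) in *both* pairwise comparisons of the target group against
    each other group (``rule='intersection'``), or in at least one
    (``rule='union'``).
    """
    labels = pd.Series(group_labels, index=raw.columns) if not isinstance(
        group_labels, pd.Series
    ) else group_labels.reindex(raw.columns)
    others = [g for g in labels.unique() if g != target_group]
    if not others:
        raise ValueError("need at least two groups")
    if rule not in ("intersection", "union"):
        raise ValueError("rule must be 'intersection' or 'union'")
    sets = []
    for other in others:
        cols = labels.isin([target_group, other])
        sub = raw.loc[:, cols.to_numpy()]
        st = nb_differential(sub, labels[cols.to_numpy()], target_group)
        sets.append(set(cluster_unique_peaks(st, "mouse", target_group).peak_ids))
    combined = set.intersection(*sets) if rule == "intersection" else set.union(*sets)
    ordered = [p for p in raw.index if p in combined]
    return UniquePeakSet(
        cluster=target_group,
        peak_ids=ordered,
        thresholds={**MOUSE_FILTERS, "pairwise_rule": rule},
    )
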